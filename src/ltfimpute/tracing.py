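"""Inverse-probability-of-complete-case weights from outcome tracing.

When patients lost to follow-up (LTF) are actively traced, the death fraction
among those found extrapolates to all LTF, and complete cases are reweighted
by the reciprocal of their estimated probability of being a complete case
within their outcome stratum.  When only a fraction ``f`` of the LTF are
found, each traced case additionally carries a ``1/f`` tracing weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateStratumError,
    EmptyDataError,
    SchemaError,
    TracingUninformativeError,
)


@dataclass
class TracingResult:
    """Outcome of attempting to trace every LTF patient.

    ``records`` has one row per LTF patient: ``patient_id``, ``found`` (0/1)
    and ``dead_if_found`` (0/1, NaN when not found).
    """

    n_ltf: int
    n_attempted: int
    n_found: int
    n_found_dead: int
    records: pd.DataFrame | None = None

    def __post_init__(self):
        if not (self.n_found <= self.n_attempted <= self.n_ltf):
            raise SchemaError(
                f"inconsistent tracing counts: found {self.n_found} <= "
                f"attempted {self.n_attempted} <= LTF {self.n_ltf} violated"
            )
        if self.n_found_dead > self.n_found:
            raise SchemaError("more traced deaths than traced patients")

    @property
    def trace_fraction(self) -> float:
        """Fraction f of LTF patients successfully traced."""
        return self.n_found / self.n_ltf if self.n_ltf else 1.0

    @property
    def n_found_alive(self) -> int:
        return self.n_found - self.n_found_dead


@dataclass
class LtfDeathEstimate:
    """Deaths among the LTF extrapolated from the traced subsample."""

    n_ltf: int
    death_fraction: float
    estimated_deaths: int
    estimated_alive: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_ltf_deaths(tracing: TracingResult) -> LtfDeathEstimate:
    """Extrapolate the traced death risk to everyone lost to follow-up.

    With 45 of 156 LTF found and 8 of those dead, the death fraction is
    8/45 = 18% and the estimated LTF deaths round(156 x 0.178) = 28.

    Raises
    ------
    TracingUninformativeError
        If nobody was found — an uninformative tracing must never silently
        yield an estimate of zero deaths.
    """
    if tracing.n_ltf == 0:
        # nobody is lost: nothing to extrapolate, downstream weights are 1
        return LtfDeathEstimate(
            n_ltf=0, death_fraction=0.0, estimated_deaths=0, estimated_alive=0
        )
    if tracing.n_found == 0:
        raise TracingUninformativeError(
            "no LTF patient was successfully traced; the death fraction "
            "among the lost cannot be estimated"
        )
    frac = tracing.n_found_dead / tracing.n_found
    deaths = _round_half_up(tracing.n_ltf * frac)
    return LtfDeathEstimate(
        n_ltf=tracing.n_ltf,
        death_fraction=frac,
        estimated_deaths=deaths,
        estimated_alive=tracing.n_ltf - deaths,
    )


@dataclass
class IpwWeights:
    """Per-stratum completeness probabilities and their reciprocal weights.

    ``stratum_table`` has one row per outcome stratum with columns
    ``stratum``, ``n_known``, ``n_estimated``, ``p_complete``, ``weight``.
    """

    stratum_table: pd.DataFrame
    trace_fraction: float = 1.0
    patient_weights: pd.Series | None = None

    def weight_for(self, stratum: str) -> float:
        row = self.stratum_table.set_index("stratum")
        return float(row.loc[stratum, "weight"])

    def weights_for_outcome(self, dead_indicator) -> pd.Series:
        """Map a 0/1 dead indicator of complete cases to stratum weights."""
        d = pd.Series(dead_indicator)
        table = self.stratum_table.set_index("stratum")["weight"]
        return d.map({1: table.get("dead", 1.0), 0: table.get("alive", 1.0)})


def stratum_ipw_weights(status_counts: dict, estimate: LtfDeathEstimate) -> IpwWeights:
    """Outcome-stratum inverse-probability-of-complete-case weights.

    ``p_complete(alive) = known_alive / (known_alive + estimated_alive)`` and
    symmetrically for the dead stratum; weights are the reciprocals.  With the
    cohort's 482 known alive and 128 LTF estimated alive this yields
    482/610 = 0.79 and weight 1/0.79.
    """
    known_dead = int(status_counts["known_dead"])
    known_alive = int(status_counts["known_alive"])
    n_ltf = int(status_counts.get("ltf", estimate.n_ltf))
    if known_dead < 0 or known_alive < 0 or n_ltf < 0:
        raise SchemaError("status counts must be non-negative")
    if n_ltf != estimate.n_ltf:
        raise SchemaError(
            f"LTF count {n_ltf} does not match the estimate's {estimate.n_ltf}"
        )

    rows = []
    for stratum, known, est in (
        ("dead", known_dead, estimate.estimated_deaths),
        ("alive", known_alive, estimate.estimated_alive),
    ):
        if known == 0 and est > 0:
            raise DegenerateStratumError(
                f"stratum '{stratum}' has {est} estimated cases but no "
                "complete cases to carry their weight"
            )
        p = 1.0 if known + est == 0 else known / (known + est)
        rows.append(
            {
                "stratum": stratum,
                "n_known": known,
                "n_estimated": est,
                "p_complete": p,
                "weight": 1.0 / p if p > 0 else np.nan,
            }
        )
    return IpwWeights(stratum_table=pd.DataFrame(rows))


def weighted_risk_comparison(
    table: pd.DataFrame,
    *,
    group_col: str = "group",
    dead_col: str = "dead",
    weight_col: str = "weight",
    count_col: str | None = "n",
    reference: str | None = None,
) -> dict:
    """Weighted death risk per group and risk ratios against a reference.

    Each row of ``table`` is a cell of complete cases: a group label, a 0/1
    dead indicator, a weight, and optionally a count of patients in the cell.
    The group risk is ``sum(w * dead) / sum(w)`` over its cells; in the
    two-by-two tracing example (men who died carrying weight 4) this gives
    20x4 / (20 + 20x4) = 80% mortality among men versus 50% among women,
    a risk ratio of 1.6.
    """
    for col in (group_col, dead_col, weight_col):
        if col not in table.columns:
            raise SchemaError(f"weighted_risk_comparison: missing column '{col}'")
    t = table.copy()
    n = t[count_col] if count_col and count_col in t.columns else 1.0
    t["_w"] = t[weight_col] * n
    risks = {}
    for g, sub in t.groupby(group_col, sort=False):
        total = sub["_w"].sum()
        if total <= 0:
            raise EmptyDataError(f"group '{g}' has zero total weight")
        risks[g] = float((sub["_w"] * sub[dead_col]).sum() / total)
    ref = reference if reference is not None else next(iter(risks))
    if ref not in risks:
        raise SchemaError(f"reference group '{ref}' not present")
    if risks[ref] == 0:
        ratios = {g: np.inf if r > 0 else 1.0 for g, r in risks.items()}
    else:
        ratios = {g: r / risks[ref] for g, r in risks.items()}
    return {"risk": risks, "risk_ratio": ratios, "reference": ref}


def covariate_ipw_weights(
    observed: pd.DataFrame,
    tracing: TracingResult,
    *,
    covariates: list[str] | None = None,
    trace_fraction: float | None = None,
    saturated: bool = False,
) -> IpwWeights:
    """Covariate-conditional completeness weights.

    Models P(complete case | covariates, resolved outcome) over the union of
    outcome-known patients (completeness 1) and traced LTF patients
    (completeness 0), the traced carrying a ``1/f`` tracing weight so that
    each found patient stands for the ``1/f`` lost patients they represent.
    Complete cases receive weight ``1 / p-hat``.

    By default the completeness model is logistic (main effects of the
    covariates plus the resolved outcome).  ``saturated=True`` instead uses
    the exact weighted cell proportion within every unique combination of
    covariate values and outcome — the "probability of being a complete case
    given the unique set of patient characteristics" — which is the right
    route for purely categorical covariates, where completeness probabilities
    of exactly one put the logistic MLE at infinity.  With no covariates the
    saturated route reproduces :func:`stratum_ipw_weights` (up to the
    latter's integer rounding of estimated deaths).

    ``observed`` must carry ``patient_id``, a ``dead10`` column (0/1, NaN for
    unresolved) and a ``status`` column marking 'ltf'; tracing records supply
    the resolved outcome of the found.
    """
    from scipy.special import expit

    from .estimators import logistic_fit  # local import to avoid cycles

    if tracing.n_found == 0:
        raise TracingUninformativeError("cannot model completeness: nobody found")
    if tracing.records is None:
        raise SchemaError("covariate weights need per-patient tracing records")
    covariates = list(covariates or [])
    f = trace_fraction if trace_fraction is not None else tracing.trace_fraction

    obs = observed.set_index("patient_id")
    rec = tracing.records.set_index("patient_id")
    if not rec.index.isin(obs.index).all():
        raise SchemaError("tracing records contain unknown patient ids")

    known = obs[obs["status"] != "ltf"].copy()
    known["_complete"] = 1.0
    known["_w"] = 1.0
    found = rec[rec["found"] == 1]
    traced = obs.loc[found.index].copy()
    traced["dead10"] = found["dead_if_found"].astype(float)
    traced["_complete"] = 0.0
    traced["_w"] = 1.0 / f

    model_df = pd.concat([known, traced])
    cols = covariates + ["dead10"]
    if saturated:
        grouped = model_df.groupby(cols, dropna=False)
        p_cell = grouped.apply(
            lambda g: g.loc[g["_complete"] == 1, "_w"].sum() / g["_w"].sum(),
            include_groups=False,
        )
        if len(cols) == 1:
            key = pd.Index(known[cols[0]])
        else:
            key = pd.MultiIndex.from_frame(known[cols])
        p_hat = pd.Series(p_cell.reindex(key).to_numpy(), index=known.index)
    else:
        fit = logistic_fit(model_df[cols], model_df["_complete"], weights=model_df["_w"])
        X = known[cols].copy()
        X.insert(0, "intercept", 1.0)
        keep = X.notna().all(axis=1)
        p_hat = pd.Series(np.nan, index=known.index)
        p_hat[keep] = expit(X[keep].to_numpy(float) @ fit.params.to_numpy())
    weights = 1.0 / p_hat
    weights.name = "weight"

    strata = known.assign(_p=p_hat).groupby(known["dead10"])["_p"].mean()
    table = pd.DataFrame(
        {
            "stratum": ["dead" if k == 1 else "alive" for k in strata.index],
            "n_known": known.groupby("dead10").size().reindex(strata.index).to_numpy(),
            "n_estimated": np.nan,
            "p_complete": strata.to_numpy(),
            "weight": 1.0 / strata.to_numpy(),
        }
    )
    return IpwWeights(stratum_table=table, trace_fraction=f, patient_weights=weights)
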