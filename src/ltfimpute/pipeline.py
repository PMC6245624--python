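"""Orchestration of the four analyses over one observed cohort.

The four routes differ only in how they treat the missing vital status of
patients lost to follow-up (LTF):

- **complete case** drops them (and drops rows with missing covariates per
  model);
- **IPW** reweights the complete cases by inverse
  probability-of-completeness weights built from outcome tracing, excluding
  the never-found;
- **MICE** imputes the missing outcome and covariates simultaneously and
  pools by Rubin's rules over all patients;
- **MICE-then-delete** imputes everything, then deletes the rows whose
  outcome was imputed before fitting (a sensitivity analysis trading a little
  information for outcome rows that are all genuinely observed).

Tracing-resolved patients are folded into the known statuses before every
analysis, so "LTF" downstream always means never-found.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cohort import (
    MODEL_COVARIATES,
    STATUS_ALIVE,
    STATUS_DEAD,
    STATUS_LTF,
    STATUS_TRANSFER,
)
from .estimators import (
    Estimate,
    logistic_fit,
    km_survival,
    rubin_pool,
    scale_covariates,
    survival_at_10,
)
from .exceptions import EmptyDataError, SchemaError
from .mice import ImputationSet, ImputationSpec, chained_imputation
from .tracing import TracingResult, estimate_ltf_deaths, stratum_ipw_weights

PREDICTORS = list(MODEL_COVARIATES)


@dataclass
class MethodResults:
    """One method's survival estimate and odds-ratio tables."""

    method: str
    survival: Estimate
    univariable: pd.DataFrame          # predictor, or, or_low, or_high, n
    multivariable: pd.DataFrame        # term, or, or_low, or_high
    n_multivariable: int
    params: pd.Series | None = None    # multivariable log-odds coefficients
    cov: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def fold_tracing(observed: pd.DataFrame, tracing: TracingResult) -> pd.DataFrame:
    """Fold tracing outcomes into the observed statuses.

    Found-dead patients become documented deaths; found-alive become
    alive-in-care with their censoring time moved to the end of follow-up
    (their survival to 10 years was confirmed).  Never-found patients remain
    LTF.
    """
    if tracing.records is None:
        raise SchemaError("folding requires per-patient tracing records")
    out = observed.copy()
    rec = tracing.records
    found = rec[rec["found"] == 1]
    idx = out.set_index("patient_id").index
    if not found["patient_id"].isin(idx).all():
        raise SchemaError("tracing records contain unknown patient ids")
    pos = out.index[out["patient_id"].isin(found["patient_id"])]
    mapped = found.set_index("patient_id")["dead_if_found"]
    resolved = out.loc[pos, "patient_id"].map(mapped)
    out.loc[pos, "dead10"] = resolved.to_numpy(dtype=float)
    out.loc[pos, "status"] = np.where(resolved == 1, STATUS_DEAD, STATUS_ALIVE)
    alive_pos = pos[resolved.to_numpy() == 0]
    out.loc[alive_pos, "last_visit_years"] = 10.0
    return out


def _scaled(observed: pd.DataFrame) -> pd.DataFrame:
    return scale_covariates(observed[PREDICTORS].astype(float).copy())


def _or_row(fit, term: str) -> dict:
    tab = fit.odds_ratios()
    return {
        "or": float(tab.loc[term, "or"]),
        "or_low": float(tab.loc[term, "or_low"]),
        "or_high": float(tab.loc[term, "or_high"]),
    }


def _km_inputs(observed: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    times = observed["last_visit_years"].to_numpy(dtype=float)
    events = (observed["status"] == STATUS_DEAD).astype(int).to_numpy()
    return times, events


def run_complete_case(observed: pd.DataFrame) -> MethodResults:
    """Unweighted fits on complete cases; survival by Kaplan-Meier.

    LTF rows are excluded from the outcome; each univariable model keeps the
    rows complete for its own predictor, so N varies by predictor; the
    multivariable model drops any row with any missing value.  The survival
    curve censors the remaining LTF at their last visit.
    """
    X = _scaled(observed)
    y = observed["dead10"]
    if y.notna().sum() == 0:
        raise EmptyDataError("no patient has a known outcome")

    uni = []
    for predictor in PREDICTORS:
        fit = logistic_fit(X[[predictor]], y)
        uni.append({"predictor": predictor, **_or_row(fit, predictor), "n": fit.n_used})
    multi_fit = logistic_fit(X, y)
    multi = pd.DataFrame(
        [{"term": t, **_or_row(multi_fit, t)} for t in PREDICTORS]
    )

    curve = km_survival(*_km_inputs(observed))
    surv = survival_at_10(curve)
    surv.method = "complete_case"

    known = y.dropna()
    return MethodResults(
        method="complete_case",
        survival=surv,
        univariable=pd.DataFrame(uni),
        multivariable=multi,
        n_multivariable=multi_fit.n_used,
        params=multi_fit.params,
        cov=multi_fit.cov,
        extras={
            "km_curve": curve,
            "alive_proportion_known": float(1.0 - known.mean()),
            "n_outcome_known": int(len(known)),
        },
    )


def run_ipw(observed: pd.DataFrame, tracing: TracingResult) -> MethodResults:
    """Weighted fits with outcome-stratum completeness weights.

    ``observed`` must already be tracing-folded; the stratum weights use the
    folded known counts against the death estimate extrapolated over ALL
    originally lost patients, mirroring the reference arithmetic (482 known
    alive against 128 estimated alive among 156 LTF gives 1/0.79).  The
    never-found remain excluded; covariance is the robust sandwich.
    """
    estimate = estimate_ltf_deaths(tracing)
    counts = {
        "known_dead": int((observed["status"] == STATUS_DEAD).sum()),
        "known_alive": int(
            observed["status"].isin([STATUS_ALIVE, STATUS_TRANSFER]).sum()
        ),
        "ltf": tracing.n_ltf,
    }
    weights = stratum_ipw_weights(counts, estimate)

    X = _scaled(observed)
    y = observed["dead10"]
    w = weights.weights_for_outcome(y.fillna(0)).where(y.notna())

    uni = []
    for predictor in PREDICTORS:
        fit = logistic_fit(X[[predictor]], y, weights=w)
        uni.append({"predictor": predictor, **_or_row(fit, predictor), "n": fit.n_used})
    multi_fit = logistic_fit(X, y, weights=w)
    multi = pd.DataFrame(
        [{"term": t, **_or_row(multi_fit, t)} for t in PREDICTORS]
    )

    known = y.notna()
    surv = survival_at_10(
        (1.0 - y[known]).to_numpy(), weights=w[known].to_numpy()
    )
    surv.method = "ipw"
    return MethodResults(
        method="ipw",
        survival=surv,
        univariable=pd.DataFrame(uni),
        multivariable=multi,
        n_multivariable=multi_fit.n_used,
        params=multi_fit.params,
        cov=multi_fit.cov,
        extras={
            "weights": weights,
            "ltf_death_estimate": estimate,
            "n_outcome_known": int(known.sum()),
        },
    )


def _pooled_tables(datasets, *, row_mask=None):
    """Fit the univariable and multivariable models on each completed dataset
    and pool by Rubin's rules.  Returns (uni_df, multi_df, pooled_multi, n)."""
    uni_fits = {p: ([], []) for p in PREDICTORS}
    multi_est, multi_cov = [], []
    n_used = None
    for df in datasets:
        sub = df if row_mask is None else df.loc[~row_mask]
        X = _scaled(sub)
        y = sub["dead10"].astype(float)
        fit = logistic_fit(X, y)
        multi_est.append(fit.params)
        multi_cov.append(fit.cov)
        n_used = fit.n_used
        for p in PREDICTORS:
            f = logistic_fit(X[[p]], y)
            uni_fits[p][0].append(f.params)
            uni_fits[p][1].append(f.cov)

    k = len(PREDICTORS) + 1
    pooled_multi = rubin_pool(multi_est, multi_cov, dof_complete=max(n_used - k, 1))
    ors = pooled_multi.odds_ratios()
    multi = pd.DataFrame(
        [
            {
                "term": t,
                "or": ors.loc[t, "or"],
                "or_low": ors.loc[t, "or_low"],
                "or_high": ors.loc[t, "or_high"],
            }
            for t in PREDICTORS
        ]
    )
    uni = []
    for p in PREDICTORS:
        pe = rubin_pool(uni_fits[p][0], uni_fits[p][1], dof_complete=max(n_used - 2, 1))
        o = pe.odds_ratios()
        uni.append(
            {
                "predictor": p,
                "or": o.loc[p, "or"],
                "or_low": o.loc[p, "or_low"],
                "or_high": o.loc[p, "or_high"],
                "n": n_used,
            }
        )
    return pd.DataFrame(uni), multi, pooled_multi, n_used


def run_mice(observed: pd.DataFrame, spec: ImputationSpec) -> MethodResults:
    """Chained-equation imputation of outcome and covariates, Rubin-pooled.

    Every model uses all N rows of the cohort — the point of imputing rather
    than dropping.
    """
    imp = chained_imputation(observed, spec)
    uni, multi, pooled, n_used = _pooled_tables(imp.datasets)
    alive = [(1 - d["dead10"]).to_numpy(dtype=float) for d in imp.datasets]
    surv = survival_at_10(alive)
    surv.method = "mice"
    return MethodResults(
        method="mice",
        survival=surv,
        univariable=uni,
        multivariable=multi,
        n_multivariable=n_used,
        params=pooled.estimates,
        cov=pd.DataFrame(
            np.diag(pooled.total), index=pooled.total.index, columns=pooled.total.index
        ),
        extras={"imputations": imp, "pooled": pooled},
    )


def mice_then_delete(imp: ImputationSet, observed: pd.DataFrame) -> MethodResults:
    """Sensitivity analysis: impute everything, then delete imputed outcomes.

    Within each completed dataset the rows whose OUTCOME was imputed are
    removed (imputed covariates are retained), and the fits are pooled as
    usual; N equals the count of outcome-observed rows.
    """
    mask = imp.missing_masks["dead10"]
    if mask.all():
        raise EmptyDataError("every outcome was imputed; nothing left after deletion")
    uni, multi, pooled, n_used = _pooled_tables(imp.datasets, row_mask=mask)
    alive = [
        (1 - d.loc[~mask, "dead10"]).to_numpy(dtype=float) for d in imp.datasets
    ]
    surv = survival_at_10(alive)
    surv.method = "mice_then_delete"
    return MethodResults(
        method="mice_then_delete",
        survival=surv,
        univariable=uni,
        multivariable=multi,
        n_multivariable=n_used,
        params=pooled.estimates,
        cov=pd.DataFrame(
            np.diag(pooled.total), index=pooled.total.index, columns=pooled.total.index
        ),
        extras={"pooled": pooled, "n_deleted": int(mask.sum())},
    )


@dataclass
class ComparisonReport:
    """Survival and odds-ratio comparison across the four methods."""

    survival: pd.DataFrame         # method, value, ci_low, ci_high, n
    univariable: pd.DataFrame      # method, predictor, or, ci, n
    multivariable: pd.DataFrame    # method, term, or, ci
    n_used: dict
    metadata: dict
    errors: dict = field(default_factory=dict)
    method_results: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Comparison of vital-status estimation methods", "=" * 46, ""]
        lines.append("Survival at 10 years")
        for _, r in self.survival.iterrows():
            lines.append(
                f"  {r['method']:<18} {r['value']:6.1%}  "
                f"(95% CI {r['ci_low']:.1%} - {r['ci_high']:.1%})"
            )
        lines.append("")
        lines.append("Multivariable odds ratios for death by 10 years")
        pivot = self.multivariable.pivot(index="term", columns="method", values="or")
        lines.append(pivot.round(2).to_string())
        if self.errors:
            lines.append("")
            lines.append("Method failures: " + ", ".join(self.errors))
        return "\n".join(lines)

    def to_manifest(self, outdir) -> None:
        """Write the report as delimited tables plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.survival.to_csv(outdir / "survival.csv", index=False)
        self.univariable.to_csv(outdir / "univariable_or.csv", index=False)
        self.multivariable.to_csv(outdir / "multivariable_or.csv", index=False)
        # wall-clock timing stays out of the manifest so regeneration from the
        # same inputs is byte-identical
        meta = {k: v for k, v in self.metadata.items() if k != "elapsed_s"}
        manifest = {
            "n_used": self.n_used,
            "metadata": meta,
            "errors": {k: str(v) for k, v in self.errors.items()},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str)
        )


def compare_methods(
    observed: pd.DataFrame,
    tracing: TracingResult | None = None,
    spec: ImputationSpec | None = None,
    metadata: dict | None = None,
) -> ComparisonReport:
    """Run all four analyses and assemble the comparison report.

    A failure in one method is recorded in ``errors`` and does not abort the
    others.  Without tracing the IPW route is skipped (there is nothing to
    build weights from) and no folding occurs.
    """
    t0 = time.perf_counter()
    spec = spec or ImputationSpec()
    folded = fold_tracing(observed, tracing) if tracing is not None else observed

    results: dict[str, MethodResults] = {}
    errors: dict[str, Exception] = {}

    def attempt(name, fn):
        try:
            results[name] = fn()
        except Exception as err:  # per-method isolation is the contract
            errors[name] = err

    attempt("complete_case", lambda: run_complete_case(folded))
    if tracing is not None:
        attempt("ipw", lambda: run_ipw(folded, tracing))
    attempt("mice", lambda: run_mice(folded, spec))
    if "mice" in results:
        attempt(
            "mice_then_delete",
            lambda: mice_then_delete(results["mice"].extras["imputations"], folded),
        )

    surv_rows, uni_rows, multi_rows, n_used = [], [], [], {}
    for name, res in results.items():
        surv_rows.append(
            {
                "method": name,
                "value": res.survival.value,
                "ci_low": res.survival.ci_low,
                "ci_high": res.survival.ci_high,
                "n": res.survival.n,
            }
        )
        uni_rows.extend({"method": name, **row} for row in res.univariable.to_dict("records"))
        multi_rows.extend(
            {"method": name, **row} for row in res.multivariable.to_dict("records")
        )
        n_used[name] = res.n_multivariable

    meta = {
        "version": _version,
        "spec_seed": spec.seed,
        "m": spec.m,
        "elapsed_s": round(time.perf_counter() - t0, 3),
        **(metadata or {}),
    }
    return ComparisonReport(
        survival=pd.DataFrame(
            surv_rows, columns=["method", "value", "ci_low", "ci_high", "n"]
        ),
        univariable=pd.DataFrame(
            uni_rows, columns=["method", "predictor", "or", "or_low", "or_high", "n"]
        ),
        multivariable=pd.DataFrame(
            multi_rows, columns=["method", "term", "or", "or_low", "or_high"]
        ),
        n_used=n_used,
        metadata=meta,
        errors=errors,
        method_results=results,
    )
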