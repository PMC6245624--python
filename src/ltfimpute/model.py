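"""Model/Results interface over the method pipeline.

``LtfCohortModel`` wraps an observed cohort (and optional tracing result);
``fit(method=...)`` runs one of the four analyses and returns an
``LtfCohortResults`` carrying the multivariable log-odds coefficients, their
uncertainty, the survival-at-10-years estimate and a ``summary()`` table;
``compare()`` runs all four and returns the :class:`ComparisonReport`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    GeneratorConfig,
    MODEL_COVARIATES,
    apply_missingness,
    generate_cohort,
    simulate_tracing,
)
from .exceptions import SchemaError
from .mice import ImputationSpec
from .pipeline import (
    ComparisonReport,
    MethodResults,
    compare_methods,
    fold_tracing,
    mice_then_delete,
    run_complete_case,
    run_ipw,
    run_mice,
)
from .tracing import TracingResult

_REQUIRED = set(MODEL_COVARIATES) | {"patient_id", "status", "dead10", "last_visit_years"}
_METHODS = ("complete_case", "ipw", "mice", "mice_then_delete")


class LtfCohortModel:
    """A 10-year mortality analysis of a cohort with loss to follow-up.

    Parameters
    ----------
    data : DataFrame
        One row per patient: baseline covariates, observed ``status``
        (alive_in_care / dead_documented / transferred / ltf), ``dead10``
        (0/1, NaN while lost), ``last_visit_years``.
    tracing : TracingResult, optional
        Outcome tracing of the lost; folded into the statuses before fitting.

    Examples
    --------
    >>> model = LtfCohortModel.simulate(seed=7)
    >>> res = model.fit(method="mice")
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, tracing: TracingResult | None = None):
        missing = _REQUIRED - set(data.columns)
        if missing:
            raise SchemaError(f"cohort data lacks column(s) {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.tracing = tracing
        self.truth: pd.DataFrame | None = None

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, tracing: TracingResult | None = None
    ) -> "LtfCohortModel":
        return cls(data, tracing=tracing)

    @classmethod
    def simulate(
        cls, config: GeneratorConfig | None = None, seed: int | None = None
    ) -> "LtfCohortModel":
        """Build a model from a synthetic cohort with known ground truth."""
        config = config or GeneratorConfig()
        if seed is not None:
            config = GeneratorConfig.from_dict({**config.__dict__, "seed": seed})
        truth = generate_cohort(config)
        observed = apply_missingness(truth, config)
        tracing = simulate_tracing(observed, truth, config)
        model = cls(observed, tracing=tracing)
        model.truth = truth
        model.config = config
        return model

    @property
    def folded(self) -> pd.DataFrame:
        if self.tracing is None:
            return self.data
        return fold_tracing(self.data, self.tracing)

    def fit(
        self,
        method: str = "mice",
        spec: ImputationSpec | None = None,
    ) -> "LtfCohortResults":
        """Fit one of the four analyses and return its results object."""
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got '{method}'")
        folded = self.folded
        if method == "complete_case":
            res = run_complete_case(folded)
        elif method == "ipw":
            if self.tracing is None:
                raise SchemaError("IPW requires a tracing result")
            res = run_ipw(folded, self.tracing)
        elif method == "mice":
            res = run_mice(folded, spec or ImputationSpec())
        else:
            mice_res = run_mice(folded, spec or ImputationSpec())
            res = mice_then_delete(mice_res.extras["imputations"], folded)
        return LtfCohortResults(self, res)

    def compare(self, spec: ImputationSpec | None = None) -> ComparisonReport:
        """Run complete-case, IPW, MICE and MICE-then-delete side by side."""
        return compare_methods(self.data, self.tracing, spec=spec)


class LtfCohortResults:
    """Results of one fitted method, statsmodels-flavoured."""

    def __init__(self, model: LtfCohortModel, res: MethodResults):
        self.model = model
        self._res = res
        self.method = res.method
        self.params = res.params
        self.nobs = res.n_multivariable
        self.survival10 = res.survival
        self.univariable = res.univariable
        self.multivariable = res.multivariable

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self._res.cov.to_numpy())), index=self._res.cov.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tab = self._res.multivariable.set_index("term")
        return np.log(tab[["or_low", "or_high"]]).rename(
            columns={"or_low": "ci_low", "or_high": "ci_high"}
        )

    def odds_ratios(self) -> pd.DataFrame:
        return self._res.multivariable.set_index("term")

    def summary(self) -> str:
        """Plain-text summary: survival at 10 years and the adjusted ORs."""
        s = self.survival10
        head = [
            f"Vital-status analysis ({self.method})",
            "-" * 44,
            f"N (multivariable model): {self.nobs}",
            f"Survival at 10 years: {s.value:.1%} "
            f"(95% CI {s.ci_low:.1%} - {s.ci_high:.1%})",
            "",
            "Adjusted odds ratios for death by 10 years",
            f"{'term':<20}{'OR':>7}{'2.5%':>8}{'97.5%':>8}",
        ]
        for _, r in self._res.multivariable.iterrows():
            head.append(
                f"{r['term']:<20}{r['or']:>7.2f}{r['or_low']:>8.2f}{r['or_high']:>8.2f}"
            )
        return "\n".join(head)

    def __repr__(self) -> str:
        return f"<LtfCohortResults method={self.method} nobs={self.nobs}>"
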