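"""Shared statistical estimators: weighted logistic regression, covariate
scaling, Rubin's-rules pooling across imputations, and Kaplan-Meier survival.

The logistic fitter is a plain iteratively reweighted least squares (IRLS)
maximum-likelihood routine with an optional sandwich (robust) covariance for
inverse-probability-weighted fits, where model-based standard errors would be
anti-conservative.  Rows containing any missing value are dropped before
fitting (the classic complete-case behaviour) and the dropped count is kept on
the result for bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .exceptions import EmptyDataError, FitError, PoolingError, SchemaError

logger = logging.getLogger(__name__)

#: raw-scale columns and their reporting divisors: odds ratios are reported
#: per 10 years of age, per 10 kg of weight and per 100 CD4 cells/uL.
SCALE_DIVISORS = {"age_years": 10.0, "weight_kg": 10.0, "cd4": 100.0}
_SCALED_FLAG = "ltfimpute_covariates_scaled"


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted (possibly weighted) logistic regression.

    Attributes
    ----------
    params : pd.Series
        Coefficients on the log-odds scale, indexed by term name.
    cov : pd.DataFrame
        Covariance of the coefficients (sandwich when ``weights_desc='ipw'``).
    n_used : int
        Rows entering the fit after complete-case dropping.
    n_dropped : int
        Rows dropped because of missing values.
    """

    params: pd.Series
    cov: pd.DataFrame
    n_used: int
    n_dropped: int
    converged: bool
    n_iter: int
    weights_desc: str = "none"
    loglike: float = float("nan")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald odds-ratio table (OR, CI bounds) on the exponentiated scale."""
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "or": np.exp(self.params),
                "or_low": np.exp(ci["ci_low"]),
                "or_high": np.exp(ci["ci_high"]),
            }
        )


def _as_design(design) -> pd.DataFrame:
    X = pd.DataFrame(design).copy()
    if "intercept" not in X.columns:
        X.insert(0, "intercept", 1.0)
    return X


def logistic_fit(
    design,
    outcome,
    weights=None,
    *,
    robust: bool | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> ModelFit:
    """Weighted maximum-likelihood logistic regression via IRLS.

    Parameters
    ----------
    design : DataFrame
        Covariate columns; an intercept column is added when absent.
    outcome : array-like of {0, 1}
        Binary response (NaN rows are dropped).
    weights : array-like, optional
        Positive case weights (e.g. inverse-probability-of-complete-case
        weights).  When supplied, the covariance defaults to the
        heteroskedasticity-robust sandwich estimator.
    robust : bool, optional
        Force the sandwich covariance on or off; default follows ``weights``.

    Raises
    ------
    FitError
        On separation, non-convergence, or a single-class outcome.
    EmptyDataError
        When no complete rows remain.
    """
    X = _as_design(design)
    y = pd.Series(np.asarray(outcome, dtype=float), index=X.index)
    w = pd.Series(
        np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float),
        index=X.index,
    )
    keep = X.notna().all(axis=1) & y.notna() & w.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("logistic_fit: dropped %d row(s) with missing values", n_dropped)
    X, y, w = X[keep], y[keep], w[keep]
    if len(X) == 0:
        raise EmptyDataError("no complete rows left to fit")
    if (w <= 0).any() or not np.isfinite(w).all():
        raise FitError("weights must be finite and positive")
    if y.nunique() < 2:
        raise FitError(
            "outcome has a single class; the logistic model is not identified",
            diagnostics={"class_counts": y.value_counts().to_dict()},
        )

    names = list(X.columns)
    Xa, ya, wa = X.to_numpy(float), y.to_numpy(), w.to_numpy()
    beta = np.zeros(Xa.shape[1])
    converged = False
    for it in range(1, max_iter + 1):
        eta = Xa @ beta
        mu = expit(eta)
        irls_w = wa * mu * (1 - mu)
        # guard against complete separation driving the working weights to 0
        info = (Xa * irls_w[:, None]).T @ Xa
        score = Xa.T @ (wa * (ya - mu))
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as err:
            raise FitError(
                "singular information matrix (separation or collinearity)",
                diagnostics={"iteration": it, "beta": dict(zip(names, beta))},
            ) from err
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged or np.max(np.abs(beta)) > 30:
        raise FitError(
            "IRLS did not converge to a finite solution (possible separation)",
            diagnostics={
                "converged": converged,
                "max_abs_beta": float(np.max(np.abs(beta))),
                "beta": dict(zip(names, beta)),
            },
        )

    mu = expit(Xa @ beta)
    info = (Xa * (wa * mu * (1 - mu))[:, None]).T @ Xa
    bread = np.linalg.inv(info)
    use_robust = robust if robust is not None else weights is not None
    if use_robust:
        resid = wa * (ya - mu)
        meat = (Xa * (resid**2)[:, None]).T @ Xa
        cov = bread @ meat @ bread
    else:
        cov = bread
    ll = float(np.sum(wa * (ya * np.log(mu) + (1 - ya) * np.log1p(-mu))))
    return ModelFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        n_used=len(X),
        n_dropped=n_dropped,
        converged=converged,
        n_iter=it,
        weights_desc="none" if weights is None else "ipw",
        loglike=ll,
    )


def scale_covariates(design: pd.DataFrame) -> pd.DataFrame:
    """Rescale age to 10-year, weight to 10-kg and CD4 to 100-cell units.

    Applied once before fitting so that reported odds ratios correspond to
    clinically interpretable differences.  The frame is flagged and a second
    application raises instead of silently rescaling again.
    """
    missing = [c for c in SCALE_DIVISORS if c not in design.columns]
    if missing:
        raise SchemaError(f"scale_covariates: missing column(s) {missing}")
    if design.attrs.get(_SCALED_FLAG):
        raise SchemaError("covariates are already scaled; refusing to rescale")
    out = design.copy()
    for col, div in SCALE_DIVISORS.items():
        out[col] = out[col] / div
    out.attrs[_SCALED_FLAG] = True
    return out


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    """Rubin's-rules combination of M per-imputation estimates.

    ``total_variance = within + (1 + 1/M) * between``; degrees of freedom use
    the Barnard-Rubin small-sample adjustment when a complete-data df is given.
    """

    estimates: pd.Series          # pooled point estimates (q-bar)
    within: pd.Series             # mean within-imputation variance (W)
    between: pd.Series            # between-imputation variance (B)
    total: pd.Series              # total variance (T)
    df: pd.Series                 # per-coefficient degrees of freedom
    m: int
    alpha: float = 0.05
    dof_complete: float | None = None

    @property
    def se(self) -> pd.Series:
        return np.sqrt(self.total)

    def conf_int(self, alpha: float | None = None) -> pd.DataFrame:
        a = self.alpha if alpha is None else alpha
        tq = stats.t.ppf(1 - a / 2, np.clip(self.df, 1.0, None))
        return pd.DataFrame(
            {
                "ci_low": self.estimates - tq * self.se,
                "ci_high": self.estimates + tq * self.se,
            }
        )

    def odds_ratios(self, alpha: float | None = None) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "or": np.exp(self.estimates),
                "or_low": np.exp(ci["ci_low"]),
                "or_high": np.exp(ci["ci_high"]),
            }
        )


def rubin_pool(
    estimates,
    covariances,
    *,
    dof_complete: float | None = None,
    allow_single: bool = False,
    alpha: float = 0.05,
) -> PooledEstimate:
    """Pool M coefficient vectors and covariance matrices by Rubin's rules.

    Parameters
    ----------
    estimates : sequence of M coefficient vectors (Series or arrays).
    covariances : sequence of M covariance matrices, conformable.
    dof_complete : float, optional
        Complete-data residual degrees of freedom for the Barnard-Rubin
        adjustment; when omitted the classic large-sample df is used.
    allow_single : bool
        Permit M=1 (total variance collapses to the within-variance); off by
        default because a single imputation understates uncertainty.
    """
    est = [pd.Series(e) for e in estimates]
    m = len(est)
    if m < 2 and not allow_single:
        raise PoolingError(f"need at least 2 imputations to pool, got {m}")
    if len(covariances) != m:
        raise PoolingError("estimates and covariances must have equal length")
    index = est[0].index
    Q = np.vstack([e.reindex(index).to_numpy(float) for e in est])
    U = np.stack([np.diag(np.asarray(pd.DataFrame(c))) for c in covariances])
    if U.shape[1] != Q.shape[1]:
        raise PoolingError("covariance dimension does not match estimates")

    qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    T = W + (1 + 1 / m) * B

    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(T > 0, (1 + 1 / m) * B / T, 0.0)
        df_old = np.where(lam > 0, (m - 1) / lam**2, np.inf)
        if dof_complete is not None:
            nu = dof_complete
            df_obs = (nu + 1) / (nu + 3) * nu * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    df = np.where(np.isfinite(df), df, 1e9)

    mk = lambda v: pd.Series(v, index=index)
    return PooledEstimate(
        estimates=mk(qbar), within=mk(W), between=mk(B), total=mk(T),
        df=mk(df), m=m, alpha=alpha, dof_complete=dof_complete,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit survival curve with Greenwood variance.

    ``times`` are the distinct event times; at tied times deaths are counted
    before censorings (both are in the risk set at that time).
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray          # Greenwood variance of S at each event time
    n: int = 0

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.variance[idx])


@dataclass
class Estimate:
    """A scalar estimate with a Wald 95% interval (e.g. survival at 10 years)."""

    value: float
    se: float
    ci_low: float
    ci_high: float
    method: str = ""
    n: int | None = None

    def as_dict(self) -> dict:
        return {
            "value": self.value, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "method": self.method, "n": self.n,
        }


def km_survival(times, event_flags) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    ``event_flags`` is 1 for a death, 0 for censoring at ``times`` (for
    patients lost to follow-up this is their last clinic visit).
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(event_flags, dtype=int)
    if t.shape != d.shape:
        raise SchemaError("times and event flags must have equal length")
    if (t < 0).any() or not np.isfinite(t).all():
        raise SchemaError("times must be finite and non-negative")

    order = np.argsort(t, kind="stable")
    t, d = t[order], d[order]
    event_times = np.unique(t[d == 1])
    n = len(t)
    at_risk, events, surv, var = [], [], [], []
    s = 1.0
    green = 0.0
    for et in event_times:
        r = int(np.sum(t >= et))           # ties: deaths counted in the risk set
        di = int(np.sum((t == et) & (d == 1)))
        s *= 1 - di / r
        if r > di:
            green += di / (r * (r - di))
        else:
            green = np.inf
        at_risk.append(r)
        events.append(di)
        surv.append(s)
        var.append(s**2 * green if np.isfinite(green) else 0.0)
    return SurvivalCurve(
        times=np.asarray(event_times, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        events=np.asarray(events, dtype=int),
        survival=np.asarray(surv, dtype=float),
        variance=np.asarray(var, dtype=float),
        n=n,
    )


def _wald(value, se, method, n=None, alpha=0.05) -> Estimate:
    z = stats.norm.ppf(1 - alpha / 2)
    return Estimate(
        value=float(value), se=float(se),
        ci_low=float(np.clip(value - z * se, 0.0, 1.0)),
        ci_high=float(np.clip(value + z * se, 0.0, 1.0)),
        method=method, n=n,
    )


def survival_at_10(method_output, *, weights=None, at: float = 10.0) -> Estimate:
    """Survival (proportion alive) at 10 years for any of the methods.

    Dispatches on input type:

    - :class:`SurvivalCurve` -> ``S(10)`` with Greenwood-variance Wald CI
      (the Kaplan-Meier route);
    - an alive indicator plus ``weights`` -> IPW-weighted alive proportion
      among complete cases, with a design-based (Hajek) variance;
    - a list/tuple of M alive-indicator vectors -> Rubin-pooled proportion
      across completed imputation datasets.
    """
    if isinstance(method_output, SurvivalCurve):
        s = method_output.survival_at(at)
        return _wald(s, np.sqrt(method_output.variance_at(at)), "km",
                     n=method_output.n)
    if isinstance(method_output, (list, tuple)):
        props, variances = [], []
        for alive in method_output:
            a = np.asarray(alive, dtype=float)
            p = a.mean()
            props.append(pd.Series({"p": p}))
            variances.append(pd.DataFrame([[p * (1 - p) / len(a)]]))
        pooled = rubin_pool(props, variances)
        ci = pooled.conf_int()
        return Estimate(
            value=float(pooled.estimates["p"]), se=float(pooled.se["p"]),
            ci_low=float(max(ci["ci_low"]["p"], 0.0)),
            ci_high=float(min(ci["ci_high"]["p"], 1.0)),
            method="mice", n=len(np.asarray(method_output[0])),
        )
    alive = np.asarray(method_output, dtype=float)
    if weights is None:
        raise SchemaError("weights are required for the IPW survival estimate")
    w = np.asarray(weights, dtype=float)
    if w.shape != alive.shape:
        raise SchemaError("weights must align with the alive indicator")
    if w.sum() <= 0:
        raise EmptyDataError("zero total weight; weighted proportion undefined")
    p = float(np.sum(w * alive) / np.sum(w))
    # Hajek-ratio linearised variance for the weighted proportion
    var = float(np.sum(w**2 * (alive - p) ** 2) / np.sum(w) ** 2)
    return _wald(p, np.sqrt(var), "ipw", n=len(alive))
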