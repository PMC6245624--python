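"""Unit and oracle tests for the shared estimators: IRLS logistic regression,
covariate scaling, Rubin pooling and the Kaplan-Meier product-limit curve."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logit

import ltfimpute as lt
from ltfimpute.exceptions import FitError, PoolingError, SchemaError


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _two_by_two_frame(d0, a0, d1, a1, w1_dead=1.0):
    """Expand a 2x2 table (dead/alive by exposure) into rows with weights."""
    x = [0] * (d0 + a0) + [1] * (d1 + a1)
    y = [1] * d0 + [0] * a0 + [1] * d1 + [0] * a1
    w = [1.0] * (d0 + a0) + [w1_dead] * d1 + [1.0] * a1
    return pd.DataFrame({"x": x}), np.array(y, dtype=float), np.array(w)


def test_irls_matches_closed_form_on_all_small_2x2_tables():
    """On a saturated 2x2 the MLE has a closed form: intercept log(d0/a0),
    slope the log odds ratio.  Sweep every table with cells 1..4."""
    for d0, a0, d1, a1 in itertools.product(range(1, 5), repeat=4):
        X, y, _ = _two_by_two_frame(d0, a0, d1, a1)
        fit = lt.logistic_fit(X, y)
        expected_intercept = np.log(d0 / a0)
        expected_slope = np.log((d1 / a1) / (d0 / a0))
        assert abs(fit.params["intercept"] - expected_intercept) < 1e-8
        assert abs(fit.params["x"] - expected_slope) < 1e-8


def test_weighted_2x2_reproduces_tracing_example_odds_ratio():
    """Weighting the 20 complete-case male deaths by 4 fits male mortality at
    80% against 50% for women: OR (0.8/0.2)/(0.5/0.5) = 4."""
    X, y, w = _two_by_two_frame(50, 50, 20, 20, w1_dead=4.0)
    fit = lt.logistic_fit(X, y, weights=w)
    p_male = 1 / (1 + np.exp(-(fit.params["intercept"] + fit.params["x"])))
    assert p_male == pytest.approx(0.80, abs=1e-8)
    assert np.exp(fit.params["x"]) == pytest.approx(4.0, abs=1e-8)


def test_intercept_only_fit_is_logit_of_death_rate():
    y = np.array([1] * 3 + [0] * 7, dtype=float)
    fit = lt.logistic_fit(pd.DataFrame(index=range(10)), y)
    assert fit.params["intercept"] == pytest.approx(logit(0.3), abs=1e-10)


def test_irls_agrees_with_statsmodels_glm():
    """Independent cross-check of coefficients and covariance on a continuous
    design, unweighted and weighted with the sandwich."""
    import statsmodels.api as sm

    rng = np.random.default_rng(1)
    n = 300
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.binomial(1, 0.4, n)})
    eta = -0.5 + 0.8 * X["x1"] - 0.6 * X["x2"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    w = rng.uniform(0.5, 3.0, n)

    Xc = sm.add_constant(X)
    ref = sm.GLM(y, Xc, family=sm.families.Binomial()).fit()
    fit = lt.logistic_fit(X, y)
    np.testing.assert_allclose(fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-6)
    np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse.to_numpy(), atol=1e-6)

    ref_w = sm.GLM(y, Xc, family=sm.families.Binomial(), freq_weights=w).fit()
    fit_w = lt.logistic_fit(X, y, weights=w)
    np.testing.assert_allclose(fit_w.params.to_numpy(), ref_w.params.to_numpy(), atol=1e-6)


def test_sandwich_se_tracks_sampling_sd_of_weighted_estimator():
    """Design-based check of the robust covariance: over repeated draws with
    covariate-dependent missingness and 1/p weights, the mean sandwich SE
    should approximate the Monte-Carlo SD of the weighted coefficient."""
    rng = np.random.default_rng(5)
    n, reps = 800, 300
    betas, ses = [], []
    for _ in range(reps):
        x = rng.binomial(1, 0.5, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 1.0 * x)))).astype(float)
        p_obs = np.where(x == 1, 0.5, 0.9)        # MAR given x
        seen = rng.random(n) < p_obs
        X = pd.DataFrame({"x": x[seen]})
        fit = lt.logistic_fit(X, y[seen], weights=1.0 / p_obs[seen])
        betas.append(fit.params["x"])
        ses.append(fit.bse["x"])
    assert np.mean(ses) == pytest.approx(np.std(betas, ddof=1), rel=0.10)


def test_fit_errors_on_single_class_and_separation():
    with pytest.raises(FitError):
        lt.logistic_fit(pd.DataFrame({"x": [0, 1, 0, 1]}), [1, 1, 1, 1])
    # perfectly separated predictor
    X = pd.DataFrame({"x": [0.0, 0.1, 0.2, 1.0, 1.1, 1.2]})
    with pytest.raises(FitError):
        lt.logistic_fit(X, [0, 0, 0, 1, 1, 1])


def test_fit_drops_missing_rows_and_counts_them():
    X = pd.DataFrame({"x": [0, 1, np.nan, 0, 1, 0, 1, 1]})
    y = [0, 1, 1, np.nan, 0, 1, 1, 0]
    fit = lt.logistic_fit(X, y)
    assert fit.n_used == 6
    assert fit.n_dropped == 2


# ---------------------------------------------------------------------------
# covariate scaling
# ---------------------------------------------------------------------------

def test_scaling_reparameterizes_age_or_as_exp_10_beta(sim_model):
    """OR per 10 years equals exp(10 * beta-per-year)."""
    df = sim_model.truth
    raw = df[["age_years"]].copy()
    y = df["true_dead10"]
    beta_raw = lt.logistic_fit(raw, y).params["age_years"]
    scaled = lt.scale_covariates(df[list(lt.cohort.MODEL_COVARIATES)].copy())
    beta_scaled = lt.logistic_fit(scaled[["age_years"]], y).params["age_years"]
    assert np.exp(beta_scaled) == pytest.approx(np.exp(10 * beta_raw), rel=1e-6)


def test_scaling_guards():
    df = pd.DataFrame({"age_years": [30.0], "weight_kg": [60.0], "cd4": [100.0]})
    once = lt.scale_covariates(df)
    with pytest.raises(SchemaError):
        lt.scale_covariates(once)           # no silent double-scaling
    with pytest.raises(SchemaError):
        lt.scale_covariates(df.drop(columns=["cd4"]))


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def test_rubin_pool_hand_evaluated_formulas():
    """M=2 with estimates {0, 2} and variances {1, 1}: q-bar 1, W 1, B 2,
    T = 1 + 1.5*2 = 4, SE 2 (evaluated by hand from the pooling rules)."""
    pooled = lt.rubin_pool(
        [pd.Series({"b": 0.0}), pd.Series({"b": 2.0})],
        [pd.DataFrame([[1.0]], index=["b"], columns=["b"]),
         pd.DataFrame([[1.0]], index=["b"], columns=["b"])],
    )
    assert pooled.estimates["b"] == pytest.approx(1.0)
    assert pooled.within["b"] == pytest.approx(1.0)
    assert pooled.between["b"] == pytest.approx(2.0)
    assert pooled.total["b"] == pytest.approx(4.0)
    assert pooled.se["b"] == pytest.approx(2.0)


def test_rubin_pool_identical_estimates_and_permutation_invariance():
    rng = np.random.default_rng(0)
    ests = [pd.Series({"a": v, "c": -v}) for v in rng.normal(size=5)]
    covs = [pd.DataFrame(np.eye(2) * 0.5, index=["a", "c"], columns=["a", "c"])] * 5

    same = lt.rubin_pool([ests[0]] * 5, covs)
    assert (same.between == 0).all()
    assert (same.total == same.within).all()

    p1 = lt.rubin_pool(ests, covs)
    p2 = lt.rubin_pool(ests[::-1], covs)
    pd.testing.assert_series_equal(p1.total, p2.total)
    pd.testing.assert_series_equal(p1.estimates, p2.estimates)
    # pooled CI always contains the naive within-only CI
    assert (p1.total >= p1.within).all()


def test_rubin_pool_rejects_single_imputation_unless_flagged():
    e = [pd.Series({"b": 1.0})]
    c = [pd.DataFrame([[1.0]], index=["b"], columns=["b"])]
    with pytest.raises(PoolingError):
        lt.rubin_pool(e, c)
    single = lt.rubin_pool(e, c, allow_single=True)
    assert single.total["b"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def _km_oracle(times, events, t):
    """Brute-force product-limit: recompute each risk set by explicit
    enumeration, independent of the vectorised implementation."""
    s = 1.0
    for et in sorted({x for x, e in zip(times, events) if e == 1}):
        if et > t:
            break
        at_risk = sum(1 for x in times if x >= et)
        d = sum(1 for x, e in zip(times, events) if x == et and e == 1)
        s *= 1 - d / at_risk
    return s


def test_km_hand_cases():
    curve = lt.km_survival([1, 2, 3, 4], [1, 1, 0, 0])
    assert curve.survival_at(2.5) == pytest.approx(0.5)
    none = lt.km_survival([1, 2, 3], [0, 0, 0])
    assert none.survival_at(10) == 1.0
    with pytest.raises(SchemaError):
        lt.km_survival([-1, 2], [1, 0])


def test_km_exhaustive_small_cases_match_enumeration_oracle():
    """All event-flag configurations for n <= 8 distinct times, plus every
    tied-time configuration for n <= 4, equal the enumeration oracle."""
    for n in range(1, 9):
        times = list(range(1, n + 1))
        for flags in itertools.product([0, 1], repeat=n):
            curve = lt.km_survival(times, flags)
            for t in times:
                assert curve.survival_at(t) == pytest.approx(
                    _km_oracle(times, flags, t), abs=1e-12
                )
    for n in range(2, 5):
        for times in itertools.product([1, 2], repeat=n):
            for flags in itertools.product([0, 1], repeat=n):
                curve = lt.km_survival(list(times), flags)
                for t in (1, 2):
                    assert curve.survival_at(t) == pytest.approx(
                        _km_oracle(times, flags, t), abs=1e-12
                    )


def test_km_matches_lifelines_on_random_records():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(2)
    times = rng.uniform(0, 10, 50).round(2)
    events = rng.binomial(1, 0.6, 50)
    curve = lt.km_survival(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    for t, s in zip(curve.times, curve.survival):
        assert kmf.survival_function_at_times(t).iloc[0] == pytest.approx(s, abs=1e-10)


def test_km_greenwood_variance_no_censoring_is_binomial():
    """Without censoring Greenwood telescopes to S(1-S)/n."""
    times = [1, 2, 3, 4, 10, 10, 10, 10]
    events = [1, 1, 1, 0, 0, 0, 0, 0]  # censoring only at the end
    curve = lt.km_survival(times[:4] + times[4:], [1, 1, 1, 1] + [0] * 4)
    s = curve.survival_at(10)
    assert curve.variance_at(10) == pytest.approx(s * (1 - s) / 8, abs=1e-12)


# ---------------------------------------------------------------------------
# survival at 10 years
# ---------------------------------------------------------------------------

def test_survival_at_10_weighted_proportion_and_errors():
    alive = np.array([1.0, 1.0, 0.0, 0.0])
    est = lt.survival_at_10(alive, weights=np.array([1.0, 1.0, 1.0, 4.0]))
    assert est.value == pytest.approx(2 / 7)
    with pytest.raises(SchemaError):
        lt.survival_at_10(alive)           # IPW route requires weights


def test_survival_at_10_pooled_over_imputations():
    alive = [np.array([1, 1, 0, 1] * 25), np.array([1, 0, 0, 1] * 25)]
    est = lt.survival_at_10(alive)
    assert est.value == pytest.approx((0.75 + 0.5) / 2)
    assert est.ci_low < est.value < est.ci_high


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.tuples(st.floats(0, 20, allow_nan=False), st.integers(0, 1)),
        min_size=1,
        max_size=30,
    )
)
def test_km_curve_invariants(records):
    """Survival starts at 1, is non-increasing, and stays within [0, 1]."""
    times = [r[0] for r in records]
    events = [r[1] for r in records]
    curve = lt.km_survival(times, events)
    s = np.concatenate([[1.0], curve.survival])
    assert np.all(np.diff(s) <= 1e-12)
    assert np.all((curve.survival >= 0) & (curve.survival <= 1))
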