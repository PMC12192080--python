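"""Clock fitting, AIC, locus selection, cross-validation, nested F-test."""

import itertools
import math
import warnings

import numpy as np
import pytest
import scipy.stats

from pyroclock import (
    Cohort,
    GeneratorConfig,
    SITE_KEYS,
    age_filter,
    aic,
    builtin_clock,
    compare_nested,
    cross_validate,
    fit_ols,
    generate_training_cohort,
    m5_prime_select,
    standardized_coefficients,
)
from pyroclock.clock_build import _metrics
from pyroclock.errors import (
    FoldSizeError,
    InsufficientDataError,
    SingularDesignError,
)

from conftest import make_profile


def cohort_from_xy(X, y, sites):
    X = np.asarray(X, dtype=float)
    profiles = [
        make_profile(f"p{i}", int(age), dict(zip(sites, row)))
        for i, (age, row) in enumerate(zip(y, X))
    ]
    return Cohort(profiles)


# ---------------------------------------------------------------- age_filter

def test_age_filter_keeps_reproductive_range(full_range_cohort):
    kept = age_filter(full_range_cohort, 10, 50)
    assert len(kept) == 60
    assert all(10 <= p.age <= 50 for p in kept)
    assert age_filter(full_range_cohort, 0, 200).profiles == full_range_cohort.profiles
    with pytest.raises(ValueError):
        age_filter(full_range_cohort, 51, 50)
    with pytest.warns(UserWarning):
        age_filter(full_range_cohort, 0, 5)


# ------------------------------------------------------------------- fit_ols

def test_fit_ols_recovers_noiseless_line():
    m = np.arange(20, dtype=float)
    cohort = cohort_from_xy(m[:, None], 2 + 3 * m, ["ELOVL2_C5"])
    model = fit_ols(cohort, ["ELOVL2_C5"])
    assert model.intercept == pytest.approx(2.0, abs=1e-9)
    assert model.coefficients["ELOVL2_C5"] == pytest.approx(3.0, abs=1e-10)
    assert model.metrics.rmse == pytest.approx(0.0, abs=1e-9)


def test_fit_ols_matches_normal_equations_oracle(rng):
    """Coefficients agree with an independent normal-equations solve."""
    sites = ["KLF14_C1", "FHL2_C2", "ELOVL2_C5"]
    X = rng.uniform(5, 60, size=(20, 3))
    y = rng.integers(10, 80, size=20)
    model = fit_ols(cohort_from_xy(X, y, sites), sites)
    D = np.column_stack([np.ones(20), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y.astype(float))
    assert model.intercept == pytest.approx(beta[0], abs=1e-8)
    for j, s in enumerate(sites):
        assert model.coefficients[s] == pytest.approx(beta[j + 1], abs=1e-8)


def test_fit_ols_residuals_orthogonal_to_design(training_cohort):
    model = fit_ols(training_cohort, list(SITE_KEYS))
    X = np.array([[p.methylation[s] for s in SITE_KEYS] for p in training_cohort])
    y = np.array(training_cohort.ages(), dtype=float)
    yhat = model.intercept + X @ np.array([model.coefficients[s] for s in SITE_KEYS])
    resid = y - yhat
    scale = np.sum(np.abs(y))
    assert abs(resid.sum()) / scale < 1e-8
    for j in range(X.shape[1]):
        assert abs(resid @ X[:, j]) / (scale * np.abs(X[:, j]).max()) < 1e-8


def test_fit_ols_errors():
    sites = ["KLF14_C1", "FHL2_C2"]
    tiny = cohort_from_xy([[1, 2], [3, 4], [5, 6]], [10, 20, 30], sites)
    with pytest.raises(InsufficientDataError):
        fit_ols(tiny, sites)
    m = np.arange(10, dtype=float)
    collinear = cohort_from_xy(np.column_stack([m, 2 * m]), 10 + m, sites)
    with pytest.raises(SingularDesignError):
        fit_ols(collinear, sites)


# ---------------------------------------------------- standardized coefficients

def test_standardized_coefficients_are_scale_free(training_cohort):
    sites = list(SITE_KEYS)
    model = fit_ols(training_cohort, sites)
    std = standardized_coefficients(model, training_cohort)
    rescaled = Cohort(
        [
            make_profile(
                p.sample_id, p.age,
                {s: (v / 10 if s == "ELOVL2_C7" else v) for s, v in p.methylation.items()},
            )
            for p in training_cohort
        ]
    )
    model_r = fit_ols(rescaled, sites)
    std_r = standardized_coefficients(model_r, rescaled)
    assert std_r["ELOVL2_C7"] == pytest.approx(std["ELOVL2_C7"], rel=1e-9)


def test_single_predictor_standardized_coefficient_is_pearson_r(training_cohort):
    model = fit_ols(training_cohort, ["ELOVL2_C5"])
    std = standardized_coefficients(model, training_cohort)
    x = [p.methylation["ELOVL2_C5"] for p in training_cohort]
    r = scipy.stats.pearsonr(x, training_cohort.ages()).statistic
    assert std["ELOVL2_C5"] == pytest.approx(r, abs=1e-12)


def test_zero_variance_site_reported_as_nan(training_cohort):
    flat = Cohort(
        [
            make_profile(p.sample_id, p.age, {**p.methylation, "KLF14_C1": 5.0})
            for p in training_cohort
        ]
    )
    model = fit_ols(flat, ["ELOVL2_C5"])
    model.coefficients["KLF14_C1"] = 0.1  # inject a term over the flat site
    with pytest.warns(UserWarning, match="zero variance"):
        std = standardized_coefficients(model, flat)
    assert math.isnan(std["KLF14_C1"])


# ------------------------------------------------------------------------ aic

def test_aic_hand_arithmetic_and_monotonicity():
    assert aic(100.0, 60, 5) == pytest.approx(60 * math.log(100 / 60) + 12, abs=1e-12)
    assert aic(200.0, 60, 5) > aic(100.0, 60, 5)
    assert aic(100.0, 60, 4) == pytest.approx(aic(100.0, 60, 5) - 2, abs=1e-12)
    with pytest.warns(UserWarning):
        assert aic(0.0, 60, 5) == -math.inf


# ---------------------------------------------------------------- m5' selection

def test_m5_keeps_two_strong_orthogonal_predictors(rng):
    sites = ["ELOVL2_C5", "C1orf132_C1"]
    x1 = rng.uniform(10, 40, 60)
    x2 = rng.uniform(30, 90, 60)
    y = np.rint(1.0 * x1 + 0.5 * x2 + rng.normal(0, 1, 60)).astype(int)
    model = m5_prime_select(cohort_from_xy(np.column_stack([x1, x2]), y, sites), sites)
    assert set(model.sites) == set(sites)


def test_m5_drops_null_locus_and_matches_exhaustive_search():
    """One pure-noise site among three informative ones: the greedy pass
    removes exactly the noise site and lands on the global AIC optimum
    found by all-subsets enumeration."""
    rng = np.random.default_rng(0)
    sites = ["KLF14_C1", "FHL2_C2", "ELOVL2_C5", "TRIM59_C7"]
    n = 60
    x = rng.uniform(10, 50, size=(n, 4))
    y = np.rint(5 + 0.5 * x[:, 0] + 0.3 * x[:, 1] + 0.5 * x[:, 2]
                + rng.normal(0, 2, n)).astype(int)
    cohort = cohort_from_xy(x, y, sites)
    model, trace = m5_prime_select(cohort, sites, return_trace=True)
    assert "TRIM59_C7" not in model.sites
    # every accepted removal lowered the AIC
    for _, before, after in trace:
        assert after < before
    best = min(
        (
            fit_ols(cohort, list(sub)).metrics.aic
            for r in range(1, 5)
            for sub in itertools.combinations(sites, r)
        )
    )
    assert model.metrics.aic == pytest.approx(best, abs=1e-9)


def test_m5_null_locus_removal_rate_matches_f_threshold():
    """Dropping a truly-null predictor lowers the AIC iff its t-statistic
    satisfies t^2 < (n-p-1)(e^{2/n}-1); the observed removal rate over
    replicates must therefore exceed one half but cannot approach one."""
    truth = builtin_clock("Age_predict2")
    removed = 0
    reps = 40
    for seed in range(reps):
        cfg = GeneratorConfig(
            mode="model_faithful", decades=(10, 20, 30, 40, 50),
            n_per_decade=12, seed=seed, truth_model=truth, noise_sd_age=3.6,
        )
        cohort = generate_training_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = m5_prime_select(cohort, list(SITE_KEYS))
        removed += "TRIM59_C7" not in model.sites
    # per-attempt acceptance bound: P(F(1,53) < 1.80) ~ 0.81
    bound = scipy.stats.f.cdf(53 * (math.exp(2 / 60) - 1), 1, 53)
    assert 0.5 < removed / reps <= bound + 3 * math.sqrt(bound * (1 - bound) / reps)


# ------------------------------------------------------------- cross-validation

def test_cv_on_noiseless_linear_data_is_perfect():
    m = np.arange(30, dtype=float)
    cohort = cohort_from_xy(m[:, None], (4 + 2 * m).astype(int), ["ELOVL2_C5"])
    cv = cross_validate(cohort, ["ELOVL2_C5"], k=5, seed=0)
    assert cv.mae == pytest.approx(0.0, abs=1e-9)
    assert cv.rmse == pytest.approx(0.0, abs=1e-9)
    assert cv.correlation == pytest.approx(1.0, abs=1e-12)


def test_pooled_metric_arithmetic():
    """Pooled residuals (1, -2, 3) give MAE 2 and RMSE sqrt(14/3)."""
    y = np.array([11.0, 18.0, 33.0])
    yhat = np.array([10.0, 20.0, 30.0])
    m = _metrics(y, yhat, p=1, source="cross_validation")
    assert m.mae == pytest.approx(2.0, abs=1e-12)
    assert m.rmse == pytest.approx(math.sqrt(14 / 3), abs=1e-12)
    assert m.rmse >= m.mae


def test_loo_is_seed_independent(training_cohort):
    sites = ["ELOVL2_C5", "FHL2_C2"]
    a = cross_validate(training_cohort, sites, k=len(training_cohort), seed=1)
    b = cross_validate(training_cohort, sites, k=len(training_cohort), seed=999)
    assert a == b


def test_cv_fold_size_guard(training_cohort):
    with pytest.raises(ValueError):
        cross_validate(training_cohort, ["ELOVL2_C5"], k=1)
    small = Cohort(training_cohort.profiles[:8])
    with pytest.raises(FoldSizeError):
        cross_validate(small, list(SITE_KEYS), k=2, seed=0)


def test_cv_rmse_at_least_mae(training_cohort):
    for seed in range(5):
        cv = cross_validate(training_cohort, list(SITE_KEYS), k=10, seed=seed)
        assert cv.rmse >= cv.mae >= 0


# ----------------------------------------------------------------- nested ANOVA

def test_compare_nested_reduced_equals_full(training_cohort):
    full = fit_ols(training_cohort, list(SITE_KEYS))
    res = compare_nested(full, full, training_cohort)
    assert res.f_stat == 0.0 and res.p_value == 1.0
    assert res.rss_reduced == pytest.approx(res.rss_full)


def test_compare_nested_rejects_non_nested(training_cohort):
    a = fit_ols(training_cohort, ["ELOVL2_C5", "FHL2_C2"])
    b = fit_ols(training_cohort, ["ELOVL2_C7"])
    with pytest.raises(ValueError, match="not nested"):
        compare_nested(a, b, training_cohort)


def test_compare_nested_null_p_is_uniform(rng):
    """Dropping a coefficient-zero predictor yields a U(0,1) p-value."""
    sites = ["ELOVL2_C5", "TRIM59_C7"]
    pvals = []
    for _ in range(500):
        x = rng.uniform(5, 45, size=(60, 2))
        y = np.rint(10 + 1.0 * x[:, 0] + rng.normal(0, 3, 60)).astype(int)
        cohort = cohort_from_xy(x, y, sites)
        full = fit_ols(cohort, sites)
        reduced = fit_ols(cohort, ["ELOVL2_C5"])
        pvals.append(compare_nested(full, reduced, cohort).p_value)
    ks = scipy.stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_compare_nested_detects_informative_predictor(rng):
    sites = ["ELOVL2_C5", "ELOVL2_C7"]
    x = rng.uniform(5, 45, size=(60, 2))
    # second predictor worth one residual SD per its own SD
    y = np.rint(10 + 1.0 * x[:, 0] + (3.0 / np.std(x[:, 1])) * x[:, 1]
                + rng.normal(0, 3, 60)).astype(int)
    cohort = cohort_from_xy(x, y, sites)
    res = compare_nested(fit_ols(cohort, sites), fit_ols(cohort, sites[:1]), cohort)
    assert res.p_value < 0.001
    assert res.rss_reduced >= res.rss_full
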