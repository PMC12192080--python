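"""Fitting and selecting linear methylation-age clocks.

Ordinary least squares over percent methylation predictors, backward
elimination of uninformative loci in the style of the M5' attribute
screen (drop the predictor with the smallest absolute standardized
coefficient while the Akaike criterion improves), k-fold cross-validated
error metrics, and the nested-model F-test used to confirm that a dropped
locus did not carry signal.

AIC convention: ``n * ln(RSS/n) + 2 * (p + 1)`` with ``p`` the number of
predictors (+1 for the intercept).  Only AIC *differences* between nested
models on the same data are meaningful under this convention.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .cohort import Cohort, ClockModel, FitMetrics, MethylationProfile
from .errors import (
    FoldSizeError,
    InsufficientDataError,
    SingularDesignError,
)

__all__ = [
    "AnovaResult",
    "age_filter",
    "fit_ols",
    "standardized_coefficients",
    "aic",
    "m5_prime_select",
    "cross_validate",
    "compare_nested",
]

logger = logging.getLogger(__name__)


def age_filter(cohort: Cohort, min_age: int, max_age: int) -> Cohort:
    """Restrict a cohort to ``min_age <= age <= max_age``, keeping order.

    Used to drop the over-50 training samples whose methylation trends
    plateau or reverse and would degrade a linear clock aimed at a
    reproductive-age test population.
    """
    if min_age > max_age:
        raise ValueError(f"min_age {min_age} exceeds max_age {max_age}")
    kept = cohort.subset(lambda p: min_age <= p.age <= max_age)
    logger.info(
        "age_filter [%d, %d]: kept %d of %d samples", min_age, max_age, len(kept), len(cohort)
    )
    if len(kept) == 0:
        warnings.warn(
            f"age filter [{min_age}, {max_age}] removed every sample", stacklevel=2
        )
    return kept


def _complete_profiles(
    cohort: Cohort, sites: Sequence[str]
) -> list[MethylationProfile]:
    complete = [p for p in cohort if p.has_sites(sites)]
    dropped = len(cohort) - len(complete)
    if dropped:
        warnings.warn(
            f"{dropped} profile(s) with missing values at modeled sites excluded",
            stacklevel=3,
        )
    return complete


def _design(profiles: Sequence[MethylationProfile], sites: Sequence[str]):
    X = np.array([[p.methylation[s] for s in sites] for p in profiles], dtype=float)
    y = np.array([p.age for p in profiles], dtype=float)
    return X, y


def aic(rss: float, n: int, p: int) -> float:
    """Akaike criterion ``n * ln(rss/n) + 2 * (p + 1)`` for an OLS fit.

    ``p`` counts predictors (the intercept adds one parameter).  A zero
    RSS (perfect fit) yields ``-inf`` with a warning.
    """
    if n <= p + 1:
        raise InsufficientDataError(f"n={n} too small for p={p} predictors")
    if rss <= 0:
        warnings.warn("zero residual sum of squares; AIC is -inf", stacklevel=2)
        return float("-inf")
    return n * math.log(rss / n) + 2 * (p + 1)


def _metrics(
    y: np.ndarray, yhat: np.ndarray, p: int, source: str
) -> FitMetrics:
    """Pooled error metrics for observed ages ``y`` and predictions ``yhat``.

    RAE and RRSE normalize by the errors of the mean-only predictor, with
    the mean taken over the pooled observed ages.
    """
    n = len(y)
    e = y - yhat
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    ybar = float(np.mean(y))
    abs_base = float(np.sum(np.abs(y - ybar)))
    sq_base = float(np.sum((y - ybar) ** 2))
    sse = float(np.sum(e**2))
    rae = 100.0 * float(np.sum(np.abs(e))) / abs_base if abs_base > 0 else float("nan")
    rrse = 100.0 * math.sqrt(sse / sq_base) if sq_base > 0 else float("nan")
    r2 = 1.0 - sse / sq_base if sq_base > 0 else float("nan")
    r2_adj = (
        1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else float("nan")
    )
    if np.ptp(yhat) == 0 or np.ptp(y) == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(y, yhat)[0, 1])
    return FitMetrics(
        correlation=corr,
        mae=mae,
        rmse=rmse,
        rae=rae,
        rrse=rrse,
        r2=r2,
        r2_adj=r2_adj,
        aic=aic(sse, n, p) if n > p + 1 else float("nan"),
        n=n,
        p=p,
        source=source,
    )


def fit_ols(
    cohort: Cohort, sites: Sequence[str], name: str = "fitted_clock"
) -> ClockModel:
    """Ordinary least-squares clock over the given sites.

    Returns the model with classical coefficient standard errors and
    resubstitution metrics attached.  Profiles with a missing value at any
    modeled site are excluded with a warning.
    """
    sites = list(sites)
    profiles = _complete_profiles(cohort, sites)
    n, p = len(profiles), len(sites)
    if n <= p + 1:
        raise InsufficientDataError(
            f"need more than p+1={p + 1} samples to fit {p} predictors, got {n}"
        )
    X, y = _design(profiles, sites)
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # pinpoint dependent columns via pivoted QR on the centered design
        _, r, piv = scipy.linalg.qr(design, pivoting=True)
        bad = sorted(
            ["intercept" if j == 0 else sites[j - 1] for j in piv[rank:]]
        )
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    fit = sm.OLS(y, design).fit()
    coefficients = {s: float(b) for s, b in zip(sites, fit.params[1:])}
    coef_se = {"intercept": float(fit.bse[0])}
    coef_se.update({s: float(b) for s, b in zip(sites, fit.bse[1:])})
    model = ClockModel(
        name=name,
        intercept=float(fit.params[0]),
        coefficients=coefficients,
        coef_se=coef_se,
        metrics=_metrics(y, np.asarray(fit.fittedvalues), p, "resubstitution"),
    )
    return model


def standardized_coefficients(
    model: ClockModel, cohort: Cohort
) -> dict[str, float]:
    """Scale-free coefficients: ``b * sd(site) / sd(age)`` over the cohort.

    A zero-variance site has an undefined standardized coefficient and is
    reported as NaN with a warning.
    """
    profiles = _complete_profiles(cohort, model.sites)
    X, y = _design(profiles, model.sites)
    sd_age = float(np.std(y, ddof=1))
    out: dict[str, float] = {}
    for j, site in enumerate(model.sites):
        sd_site = float(np.std(X[:, j], ddof=1))
        if sd_site == 0 or sd_age == 0:
            warnings.warn(
                f"standardized coefficient undefined for {site} (zero variance)",
                stacklevel=2,
            )
            out[site] = float("nan")
        else:
            out[site] = model.coefficients[site] * sd_site / sd_age
    return out


def m5_prime_select(
    cohort: Cohort,
    sites: Sequence[str],
    name: str = "m5_selected",
    return_trace: bool = False,
):
    """Backward elimination of uninformative loci under the Akaike criterion.

    Iteratively fit OLS on the current site set, find the site with the
    smallest absolute standardized coefficient, and refit without it; the
    removal is kept when it lowers the AIC, otherwise selection stops.
    Ties in the standardized coefficient are broken by the lower
    post-removal AIC, then lexicographically by site key.

    With ``return_trace=True`` also returns the list of
    ``(removed_site, aic_before, aic_after)`` steps.
    """
    current = list(sites)
    model = fit_ols(cohort, current, name=name)
    trace: list[tuple[str, float, float]] = []
    while len(current) > 1:
        std = standardized_coefficients(model, cohort)
        smallest = min(abs(v) for v in std.values() if not math.isnan(v))
        candidates = sorted(
            s for s, v in std.items() if not math.isnan(v) and abs(v) == smallest
        )
        best_site, best_trial = None, None
        for site in candidates:
            trial = fit_ols(
                cohort, [s for s in current if s != site], name=name
            )
            if best_trial is None or trial.metrics.aic < best_trial.metrics.aic:
                best_site, best_trial = site, trial
        if best_trial.metrics.aic < model.metrics.aic:
            trace.append((best_site, model.metrics.aic, best_trial.metrics.aic))
            logger.info(
                "m5_prime_select: removed %s (AIC %.3f -> %.3f)",
                best_site,
                model.metrics.aic,
                best_trial.metrics.aic,
            )
            current.remove(best_site)
            model = best_trial
        else:
            logger.info(
                "m5_prime_select: stopping; removing %s would raise AIC "
                "%.3f -> %.3f",
                best_site,
                model.metrics.aic,
                best_trial.metrics.aic,
            )
            break
    if return_trace:
        return model, trace
    return model


def cross_validate(
    cohort: Cohort, sites: Sequence[str], k: int = 10, seed: int = 0
) -> FitMetrics:
    """k-fold cross-validated error metrics, pooled over held-out samples.

    Samples are permuted with the given seed and split into contiguous
    near-equal folds; each fold is predicted by a model fitted on the
    remainder, and the metrics are computed once over the pooled held-out
    predictions.  Leave-one-out (``k = n``) is seed-independent because
    every partition into singletons pools to the same prediction set.
    """
    sites = list(sites)
    profiles = _complete_profiles(cohort, sites)
    n, p = len(profiles), len(sites)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise InsufficientDataError(f"cannot make {k} folds from {n} samples")
    X, y = _design(profiles, sites)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    sizes = np.full(k, n // k, dtype=int)
    sizes[: n % k] += 1
    yhat = np.empty(n, dtype=float)
    start = 0
    for fold_size in sizes:
        test_idx = perm[start : start + fold_size]
        train_idx = np.setdiff1d(perm, test_idx)
        if len(train_idx) < p + 2:
            raise FoldSizeError(
                f"training remainder of {len(train_idx)} samples cannot support "
                f"{p} predictors; use a different number of folds"
            )
        design = sm.add_constant(X[train_idx], has_constant="add")
        beta, *_ = np.linalg.lstsq(design, y[train_idx], rcond=None)
        yhat[test_idx] = beta[0] + X[test_idx] @ beta[1:]
        start += fold_size
    return _metrics(y, yhat, p, "cross_validation")


@dataclass
class AnovaResult:
    """F-test of a reduced clock nested in a full clock."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    rss_full: float
    rss_reduced: float


def compare_nested(
    full: ClockModel, reduced: ClockModel, cohort: Cohort
) -> AnovaResult:
    """Extra-sum-of-squares F-test for dropping the sites absent from
    ``reduced``.

    A non-significant p-value means the dropped loci carried no detectable
    age signal beyond the retained ones.
    """
    full_sites = set(full.sites)
    reduced_sites = set(reduced.sites)
    if not reduced_sites <= full_sites:
        raise ValueError(
            f"models are not nested: {sorted(reduced_sites - full_sites)} "
            "only in the reduced model"
        )
    profiles = _complete_profiles(cohort, full.sites)
    n = len(profiles)
    p_full = len(full_sites)

    def _rss(sites: Sequence[str]) -> float:
        X, y = _design(profiles, list(sites))
        design = sm.add_constant(X, has_constant="add")
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        return float(resid @ resid)

    rss_full = _rss(full.sites)
    rss_reduced = _rss([s for s in full.sites if s in reduced_sites])
    delta_p = p_full - len(reduced_sites)
    df_den = n - p_full - 1
    if delta_p == 0:
        return AnovaResult(0.0, 0, df_den, 1.0, rss_full, rss_reduced)
    f_stat = ((rss_reduced - rss_full) / delta_p) / (rss_full / df_den)
    f_stat = max(f_stat, 0.0)
    p_value = float(scipy.stats.f.sf(f_stat, delta_p, df_den))
    return AnovaResult(f_stat, delta_p, df_den, p_value, rss_full, rss_reduced)
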