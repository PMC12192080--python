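"""Nonparametric cohort statistics for the infertility analyses.

Spearman rank correlation with a Fisher-z confidence interval, the
Kruskal-Wallis H test, the Mann-Whitney U test, the paired Wilcoxon
signed-rank test, and the grouped comparison report that contrasts
chronological age, predicted (epigenetic) age and the integer-year
acceleration delta across clinical strata: study groups I-IV, ART use,
BMI normal vs deviation, and AMH above vs below 1.2 ng/mL.

Rank-test p-values delegate to scipy with fixed, reproducible method
rules: exact enumeration for small tie-free samples, otherwise the normal
approximation with tie correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from .cohort import Cohort, GROUPS
from .clock_apply import PredictionRecord

__all__ = [
    "SpearmanResult",
    "TestResult",
    "StratumSummary",
    "PartitionReport",
    "GroupComparisonTable",
    "spearman_with_ci",
    "kruskal_wallis",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "build_group_report",
]

#: Clinical cutoffs: AMH below 1.2 ng/mL flags low ovarian reserve; BMI in
#: the closed band [18.5, 25] kg/m^2 counts as normal.
AMH_LOW_CUTOFF = 1.2
BMI_NORMAL_RANGE = (18.5, 25.0)


@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    group_ns: tuple[int, ...]
    df: int | None = None


def spearman_with_ci(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> SpearmanResult:
    """Spearman rho with a Fisher-z confidence interval.

    Rho uses average ranks for ties.  The CI applies the Fisher z
    transform with the Fieller-corrected standard error
    ``sqrt(1.06 / (n - 3))`` appropriate for rank correlations, then
    back-transforms.  The two-sided p-value uses the t approximation with
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4 for a confidence interval, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    rho = float(scipy.stats.spearmanr(x, y).statistic)
    if abs(rho) >= 1.0:
        p_value = 0.0
        ci_low = ci_high = rho
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p_value = 2.0 * float(scipy.stats.t.sf(abs(t), n - 2))
        z = math.atanh(rho)
        se = math.sqrt(1.06 / (n - 3))
        zcrit = float(scipy.stats.norm.ppf(0.5 + level / 2.0))
        ci_low = math.tanh(z - zcrit * se)
        ci_high = math.tanh(z + zcrit * se)
    return SpearmanResult(rho, ci_low, ci_high, p_value, n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across two or more groups (tie-corrected),
    with the chi-squared reference distribution on k - 1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    ns = tuple(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult("kruskal_wallis", 0.0, 1.0, ns, df=len(arrays) - 1)
    h, p = scipy.stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), float(p), ns, df=len(arrays) - 1)


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The p-value is exact when the smaller sample has at most 8 values and
    the pooled sample is tie-free; otherwise the normal approximation with
    tie correction (and continuity correction) is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # all observations tied: the test is vacuous
        return TestResult(
            "mann_whitney", len(a) * len(b) / 2.0, 1.0, (len(a), len(b))
        )
    exact = min(len(a), len(b)) <= 8 and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        "mann_whitney",
        float(res.statistic),
        min(1.0, float(res.pvalue)),
        (len(a), len(b)),
    )


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test of ``x`` vs ``y``.

    Zero differences are dropped (Wilcoxon convention); the statistic is
    ``W = min(W+, W-)`` over average ranks of the absolute differences.
    The p-value is exact for at most 15 effective pairs without tied
    absolute differences, otherwise the normal approximation with
    continuity and tie correction is used.  If every pair is tied the test
    is vacuous: p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n_eff = len(d)
    if n_eff == 0:
        warnings.warn("all paired differences are zero; test is vacuous", stacklevel=2)
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, (len(x),))
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    exact = n_eff <= 15 and not _has_ties(np.abs(d))
    res = scipy.stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=True,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return TestResult(
        "wilcoxon_signed_rank", w, min(1.0, float(res.pvalue)), (n_eff,)
    )


@dataclass
class StratumSummary:
    """Medians and the paired chronological-vs-predicted test for one stratum."""

    name: str
    n: int
    median_chronological: float
    median_predicted: float
    median_delta: float
    paired_p: float


@dataclass
class PartitionReport:
    """One way of partitioning the cohort (groups, ART, BMI, AMH)."""

    partition: str
    test_name: str
    strata: list[StratumSummary]
    p_chronological: float | None
    p_predicted: float | None
    p_delta: float | None


@dataclass
class GroupComparisonTable:
    """Comparative analysis of clinical strata by chronological age,
    predicted age, and EAA/EAD delta."""

    partitions: list[PartitionReport] = field(default_factory=list)

    def partition(self, name: str) -> PartitionReport:
        for p in self.partitions:
            if p.partition == name:
                return p
        raise KeyError(name)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _between_p(strata_values: list[np.ndarray], test: str) -> float | None:
    nonempty = [v for v in strata_values if len(v) > 0]
    if len(nonempty) < 2:
        return None
    if test == "kruskal_wallis":
        return kruskal_wallis(nonempty).p_value
    return mann_whitney(nonempty[0], nonempty[1]).p_value


def build_group_report(
    cohort: Cohort,
    predictions: Sequence[PredictionRecord],
    table5_sign: bool = False,
) -> GroupComparisonTable:
    """Build the clinical comparison table over four partitions.

    Within each stratum, chronological and predicted ages are compared by
    the paired Wilcoxon signed-rank test; across strata, chronological
    age, predicted age and the delta are compared by Kruskal-Wallis (the
    four study groups) or Mann-Whitney (binary partitions).  Empty strata
    are omitted with a warning.

    ``table5_sign=True`` flips the reported delta medians to the
    chronological-minus-predicted orientation used in some published
    tabulations; the tests are sign-invariant.
    """
    by_id = {r.sample_id: r for r in predictions}
    missing = [p.sample_id for p in cohort if p.sample_id not in by_id]
    if missing:
        raise ValueError(f"predictions missing for samples: {missing[:5]}")

    def partition_members(partition: str) -> list[tuple[str, list]]:
        if partition == "group":
            return [
                (g, [p for p in cohort if p.group == g]) for g in GROUPS
            ]
        if partition == "art":
            return [
                ("yes", [p for p in cohort if p.art_used is True]),
                ("no", [p for p in cohort if p.art_used is False]),
            ]
        if partition == "bmi":
            lo, hi = BMI_NORMAL_RANGE
            with_bmi = [p for p in cohort if p.bmi is not None]
            return [
                ("normal", [p for p in with_bmi if lo <= p.bmi <= hi]),
                ("deviation", [p for p in with_bmi if p.bmi < lo or p.bmi > hi]),
            ]
        if partition == "amh":
            with_amh = [p for p in cohort if p.amh is not None]
            return [
                (f">{AMH_LOW_CUTOFF}", [p for p in with_amh if p.amh >= AMH_LOW_CUTOFF]),
                (f"<{AMH_LOW_CUTOFF}", [p for p in with_amh if p.amh < AMH_LOW_CUTOFF]),
            ]
        raise KeyError(partition)

    table = GroupComparisonTable()
    plan = [
        ("group", "kruskal_wallis"),
        ("art", "mann_whitney"),
        ("bmi", "mann_whitney"),
        ("amh", "mann_whitney"),
    ]
    sign = -1.0 if table5_sign else 1.0
    for partition, test in plan:
        strata: list[StratumSummary] = []
        chron_v, pred_v, delta_v = [], [], []
        for name, members in partition_members(partition):
            if not members:
                warnings.warn(
                    f"stratum {partition}={name} is empty and was omitted",
                    stacklevel=2,
                )
                chron_v.append(np.array([]))
                pred_v.append(np.array([]))
                delta_v.append(np.array([]))
                continue
            recs = [by_id[p.sample_id] for p in members]
            chron = np.array([r.chronological for r in recs], dtype=float)
            pred = np.array([r.predicted for r in recs], dtype=float)
            delta = np.array([r.delta for r in recs], dtype=float)
            chron_v.append(chron)
            pred_v.append(pred)
            delta_v.append(delta)
            strata.append(
                StratumSummary(
                    name=name,
                    n=len(recs),
                    median_chronological=float(np.median(chron)),
                    median_predicted=float(np.median(pred)),
                    median_delta=sign * float(np.median(delta)),
                    paired_p=wilcoxon_signed_rank(chron, pred).p_value,
                )
            )
        table.partitions.append(
            PartitionReport(
                partition=partition,
                test_name=test,
                strata=strata,
                p_chronological=_between_p(chron_v, test),
                p_predicted=_between_p(pred_v, test),
                p_delta=_between_p(delta_v, test),
            )
        )
    return table
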