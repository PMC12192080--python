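"""Applying a methylation clock to samples and cohorts.

Provides the two published blood-panel clocks (``Age_predict1`` with all six
CpGs, ``Age_predict2`` with the uninformative *TRIM59* site dropped),
per-sample prediction, integer-year epigenetic age acceleration (EAA) /
deceleration (EAD) classification, and cohort-level accuracy summaries.

Sign convention: ``delta = predicted_rounded - chronological``, so a
positive delta means the sample looks epigenetically *older* than its
chronological age (EAA) and a negative delta younger (EAD).
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, ClockModel, FitMetrics, MethylationProfile
from .errors import InsufficientDataError, MissingSiteError

__all__ = [
    "PredictionRecord",
    "EvaluationSummary",
    "builtin_clock",
    "predict_age",
    "classify",
    "evaluate_cohort",
]

_BUILTIN: dict[str, dict] = {
    "Age_predict1": {
        "intercept": 24.4506,
        "coefficients": {
            "FHL2_C2": 0.1492,
            "KLF14_C1": 0.4488,
            "TRIM59_C7": 0.0114,
            "C1orf132_C1": -0.3771,
            "ELOVL2_C5": 0.3328,
            "ELOVL2_C7": 0.3259,
        },
        "coef_se": {
            "intercept": 5.727,
            "FHL2_C2": 0.0833,
            "KLF14_C1": 0.3094,
            "TRIM59_C7": 0.1432,
            "C1orf132_C1": 0.0514,
            "ELOVL2_C5": 0.2235,
            "ELOVL2_C7": 0.1148,
        },
        "metrics": FitMetrics(
            correlation=0.9674,
            mae=2.6158,
            rmse=3.5943,
            rae=21.42,
            rrse=25.17,
            r2=0.954,
            r2_adj=0.9488,
            aic=319.0,
            n=60,
            p=6,
            source="reported",
        ),
    },
    "Age_predict2": {
        "intercept": 24.3118,
        "coefficients": {
            "FHL2_C2": 0.1495,
            "KLF14_C1": 0.4492,
            "C1orf132_C1": -0.3755,
            "ELOVL2_C5": 0.3335,
            "ELOVL2_C7": 0.3303,
        },
        "coef_se": {
            "intercept": 5.4046,
            "FHL2_C2": 0.0825,
            "KLF14_C1": 0.3065,
            "C1orf132_C1": 0.047,
            "ELOVL2_C5": 0.2212,
            "ELOVL2_C7": 0.0996,
        },
        "metrics": FitMetrics(
            correlation=0.9675,
            mae=2.6039,
            rmse=3.5866,
            rae=21.33,
            rrse=25.12,
            r2=0.954,
            r2_adj=0.94975,
            aic=317.0,
            n=60,
            p=5,
            source="reported",
        ),
    },
}

BUILTIN_CLOCK_NAMES = tuple(_BUILTIN)


def builtin_clock(name: str) -> ClockModel:
    """Return one of the published clocks by name.

    ``metrics.source`` is ``"reported"`` for these models: the numbers are
    the published training summaries, not recomputed here.
    """
    try:
        spec = _BUILTIN[name]
    except KeyError:
        raise LookupError(
            f"unknown clock {name!r}; valid names: {', '.join(_BUILTIN)}"
        ) from None
    return ClockModel(
        name=name,
        intercept=spec["intercept"],
        coefficients=dict(spec["coefficients"]),
        coef_se=dict(spec["coef_se"]),
        metrics=copy.deepcopy(spec["metrics"]),
    )


def predict_age(model: ClockModel, profile: MethylationProfile) -> float:
    """Predicted (epigenetic) age in continuous years, without clipping."""
    total = model.intercept
    for site, coef in model.coefficients.items():
        value = profile.methylation.get(site)
        if value is None:
            raise MissingSiteError(
                f"sample {profile.sample_id}: no methylation value for {site}"
            )
        total += coef * value
    return total


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class PredictionRecord:
    """One sample's prediction and integer-year EAA/EAD call."""

    sample_id: str
    chronological: int
    predicted: float
    predicted_rounded: int
    delta: int
    status: str

    def __post_init__(self) -> None:
        expected = "EAA" if self.delta > 0 else "EAD" if self.delta < 0 else "concordant"
        if self.status != expected:
            raise ValueError(
                f"status {self.status!r} inconsistent with delta {self.delta}"
            )


def classify(
    predicted: float, chronological: int, sample_id: str = ""
) -> PredictionRecord:
    """Integerize a prediction and call EAA/EAD/concordant.

    The *prediction* is rounded half-away-from-zero to whole years before
    differencing, so a concordant call means the rounded predicted age sits
    exactly on the identity line.
    """
    if chronological < 0:
        raise ValueError("chronological age must be non-negative")
    rounded = _round_half_away(predicted)
    delta = rounded - chronological
    status = "EAA" if delta > 0 else "EAD" if delta < 0 else "concordant"
    return PredictionRecord(
        sample_id=sample_id,
        chronological=chronological,
        predicted=predicted,
        predicted_rounded=rounded,
        delta=delta,
        status=status,
    )


@dataclass
class EvaluationSummary:
    """Cohort-level accuracy and EAA/EAD composition.

    ``mad`` and ``rmse`` are computed about the identity line from the
    continuous predictions; ``see`` is the residual standard deviation
    (divisor n-2) about the auxiliary regression of predicted on
    chronological age, i.e. the scatter about the fitted trend line rather
    than the diagonal.
    """

    n: int
    mad: float
    see: float
    rmse: float
    frac_concordant: float
    frac_eaa: float
    frac_ead: float
    delta_min: int
    delta_max: int
    mean_chronological: float
    mean_predicted: float

    def to_dict(self) -> dict:
        from dataclasses import fields

        return {f.name: getattr(self, f.name) for f in fields(self)}


def evaluate_cohort(
    model: ClockModel, cohort: Cohort
) -> tuple[list[PredictionRecord], EvaluationSummary]:
    """Predict every sample and summarize accuracy and EAA/EAD fractions.

    Raises :class:`InsufficientDataError` below n = 3 (the auxiliary
    regression SEE needs n - 2 residual degrees of freedom).
    """
    if len(cohort) < 3:
        raise InsufficientDataError(
            f"need at least 3 samples to evaluate, got {len(cohort)}"
        )
    records = [
        classify(predict_age(model, p), p.age, sample_id=p.sample_id)
        for p in cohort
    ]
    chron = np.array([r.chronological for r in records], dtype=float)
    pred = np.array([r.predicted for r in records], dtype=float)
    err = pred - chron
    mad = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.ptp(chron) == 0:
        warnings.warn(
            "chronological age is constant; SEE about the regression line "
            "is undefined",
            stacklevel=2,
        )
        see = float("nan")
    else:
        slope, intercept = np.polyfit(chron, pred, 1)
        resid = pred - (intercept + slope * chron)
        see = float(np.sqrt(np.sum(resid**2) / (len(records) - 2)))
    n = len(records)
    n_eaa = sum(r.status == "EAA" for r in records)
    n_ead = sum(r.status == "EAD" for r in records)
    n_conc = n - n_eaa - n_ead
    summary = EvaluationSummary(
        n=n,
        mad=mad,
        see=see,
        rmse=rmse,
        frac_concordant=n_conc / n,
        frac_eaa=n_eaa / n,
        frac_ead=n_ead / n,
        delta_min=min(r.delta for r in records),
        delta_max=max(r.delta for r in records),
        mean_chronological=float(np.mean(chron)),
        mean_predicted=float(np.mean(pred)),
    )
    return records, summary
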