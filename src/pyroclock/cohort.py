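"""Core domain types: methylation profiles, cohorts, clock models, fit metrics.

A :class:`MethylationProfile` is one blood sample: chronological age in whole
years, percent methylation at the panel CpGs, and optional clinical fields
used by the infertility analyses (study group I-IV, AMH, BMI, ART history).
A :class:`Cohort` is an ordered collection of profiles sharing the same site
set.  A :class:`ClockModel` is a named linear age predictor over site keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Iterator, Mapping

from .errors import IntegrityError, SchemaError, ValidationError
from .sites import BUILTIN_SITES

__all__ = [
    "GROUPS",
    "MethylationProfile",
    "Cohort",
    "FitMetrics",
    "ClockModel",
]

#: Clinical study groups: I control, II infertility without ART,
#: III ART with pregnancy and delivery, IV ART without pregnancy.
GROUPS = ("I", "II", "III", "IV")


@dataclass
class MethylationProfile:
    """One sample's age, methylation panel and optional clinical fields.

    ``methylation`` maps site keys (``GENE_LABEL``) to percent values in
    [0, 100]; ``None`` marks an explicitly missing measurement.  Ages are
    whole years; fractional ages are rejected rather than rounded so that
    downstream integer age-acceleration arithmetic is never silently
    perturbed.
    """

    sample_id: str
    age: int
    methylation: dict[str, float | None]
    group: str | None = None
    amh: float | None = None
    bmi: float | None = None
    art_used: bool | None = None
    art_pregnancy: bool | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be a non-empty string")
        if isinstance(self.age, bool) or not isinstance(self.age, int):
            # numpy integers are fine; reject floats even when integral-valued
            try:
                import numbers

                if isinstance(self.age, numbers.Integral):
                    self.age = int(self.age)
                else:
                    raise ValidationError(
                        f"sample {self.sample_id}: age must be an integer number "
                        f"of years, got {self.age!r}"
                    )
            except ValidationError:
                raise
        if not 0 <= self.age <= 120:
            raise ValidationError(
                f"sample {self.sample_id}: age {self.age} outside [0, 120]"
            )
        for site, value in self.methylation.items():
            if value is None:
                continue
            value = float(value)
            if not 0.0 <= value <= 100.0:
                raise ValidationError(
                    f"sample {self.sample_id}: methylation {value} at {site} "
                    "outside [0, 100]"
                )
            self.methylation[site] = value
        if self.group is not None and self.group not in GROUPS:
            raise ValidationError(
                f"sample {self.sample_id}: group {self.group!r} not in {GROUPS}"
            )
        if self.amh is not None and not self.amh >= 0:
            raise ValidationError(
                f"sample {self.sample_id}: AMH {self.amh} must be >= 0 ng/mL"
            )
        if self.bmi is not None and not self.bmi > 0:
            raise ValidationError(
                f"sample {self.sample_id}: BMI {self.bmi} must be positive"
            )
        if self.group == "I" and self.art_used:
            raise ValidationError(
                f"sample {self.sample_id}: control group I excludes ART use"
            )

    @property
    def site_keys(self) -> frozenset[str]:
        return frozenset(self.methylation)

    def has_sites(self, sites: Iterable[str]) -> bool:
        """True if every requested site has a non-missing value."""
        return all(self.methylation.get(s) is not None for s in sites)

    @property
    def has_clinical(self) -> bool:
        return self.group is not None


@dataclass
class Cohort:
    """Ordered collection of profiles with unique ids and a shared site set."""

    profiles: list[MethylationProfile]
    label: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.profiles:
            if p.sample_id in seen:
                raise IntegrityError(f"duplicate sample_id {p.sample_id!r}")
            seen.add(p.sample_id)
        if self.profiles:
            ref = self.profiles[0].site_keys
            for p in self.profiles[1:]:
                if p.site_keys != ref:
                    raise IntegrityError(
                        f"sample {p.sample_id} covers sites {sorted(p.site_keys)} "
                        f"but the cohort covers {sorted(ref)}"
                    )

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[MethylationProfile]:
        return iter(self.profiles)

    def __getitem__(self, i: int) -> MethylationProfile:
        return self.profiles[i]

    @property
    def site_keys(self) -> tuple[str, ...]:
        if not self.profiles:
            return ()
        first = self.profiles[0].methylation
        return tuple(first)

    def ages(self) -> list[int]:
        return [p.age for p in self.profiles]

    def subset(self, predicate, label: str | None = None) -> "Cohort":
        """New cohort with the profiles satisfying ``predicate``, order kept."""
        return Cohort(
            [p for p in self.profiles if predicate(p)],
            label if label is not None else self.label,
        )


@dataclass
class FitMetrics:
    """Goodness-of-fit summary for an age predictor.

    ``mae``/``rmse`` are in years; ``rae``/``rrse`` are percentages relative
    to the mean-only predictor; ``source`` records whether the numbers come
    from resubstitution on the training data or pooled held-out
    cross-validation predictions.
    """

    correlation: float
    mae: float
    rmse: float
    rae: float
    rrse: float
    r2: float
    r2_adj: float
    aic: float
    n: int
    p: int
    source: str = "resubstitution"

    def __post_init__(self) -> None:
        if self.source not in ("resubstitution", "cross_validation", "reported"):
            raise ValidationError(f"unknown metrics source {self.source!r}")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitMetrics":
        return cls(**{f.name: d[f.name] for f in dc_fields(cls) if f.name in d})


@dataclass
class ClockModel:
    """Named linear age predictor: age = intercept + sum(coef * methylation%).

    Coefficients are in years per methylation percentage point.  ``coef_se``
    optionally carries classical OLS standard errors under the same site keys
    plus ``"intercept"``.
    """

    name: str
    intercept: float
    coefficients: dict[str, float]
    coef_se: dict[str, float] | None = None
    metrics: FitMetrics | None = None

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValidationError("a clock needs at least one coefficient")
        for key in self.coefficients:
            if key not in BUILTIN_SITES:
                raise SchemaError(
                    f"unknown site key {key!r}; known: {sorted(BUILTIN_SITES)}"
                )
        if self.coef_se is not None:
            for key in self.coef_se:
                if key != "intercept" and key not in BUILTIN_SITES:
                    raise SchemaError(f"unknown site key {key!r} in coef_se")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.coefficients)
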