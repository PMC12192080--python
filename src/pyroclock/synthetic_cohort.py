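"""Seeded synthetic cohorts with the statistical structure of the study design.

Two cohort kinds are generated:

* a *training* cohort spanning decade age groups 10-80, each CpG drawn from
  a normal around per-decade mean/SD anchors (the published subgroup
  summaries), truncated to the [0, 100] percent range.  Between anchor ages
  the mean and SD are interpolated linearly; outside the anchor range they
  are clamped.  The anchors encode the observed linear methylation trend up
  to age ~50 and the plateau/reversal beyond it.
* a *test* cohort of women of reproductive age (default 64 women split
  7/16/29/12 over clinical groups I-IV) with AMH and BMI drawn per group
  and an optional injected epigenetic-age offset per group: methylation is
  sampled from the anchors evaluated at ``age + shift`` so a known
  acceleration signal is embedded for power/recovery experiments.

In ``model_faithful`` mode the training ages are regenerated from a truth
clock applied to the drawn methylation plus Gaussian noise, which makes the
linear-model assumptions hold exactly — useful for coefficient-recovery and
locus-selection tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, ClockModel, GROUPS, MethylationProfile
from .errors import ConfigError
from .sites import SITE_KEYS

__all__ = [
    "DEFAULT_ANCHORS",
    "DecadeAnchors",
    "GeneratorConfig",
    "ClinicalConfig",
    "methylation_mean",
    "methylation_sd",
    "generate_training_cohort",
    "generate_test_cohort",
]

# (decade age, mean %, SD %) per site; the published per-decade subgroup
# summaries of the 94-sample training panel.
DecadeAnchors = dict[str, tuple[tuple[int, float, float], ...]]

DEFAULT_ANCHORS: DecadeAnchors = {
    "KLF14_C1": (
        (10, 2.17, 0.39),
        (20, 2.50, 0.52),
        (30, 4.92, 1.83),
        (40, 6.33, 1.92),
        (50, 5.00, 1.04),
        (60, 6.50, 1.24),
        (70, 7.58, 2.43),
        (80, 7.70, 2.21),
    ),
    "FHL2_C2": (
        (10, 17.7, 2.46),
        (20, 23.9, 2.50),
        (30, 27.5, 2.97),
        (40, 33.2, 6.19),
        (50, 45.8, 8.53),
        (60, 37.8, 4.45),
        (70, 45.8, 7.19),
        (80, 46.6, 5.10),
    ),
    "TRIM59_C7": (
        (10, 11.4, 1.62),
        (20, 17.9, 4.03),
        (30, 21.6, 4.08),
        (40, 26.8, 2.45),
        (50, 20.7, 2.77),
        (60, 23.5, 3.29),
        (70, 26.1, 10.4),
        (80, 30.1, 6.06),
    ),
    "C1orf132_C1": (
        (10, 82.2, 2.52),
        (20, 74.1, 6.05),
        (30, 66.7, 7.74),
        (40, 61.6, 10.0),
        (50, 40.4, 6.08),
        (60, 38.1, 6.04),
        (70, 28.7, 10.1),
        (80, 29.2, 7.15),
    ),
    "ELOVL2_C5": (
        (10, 8.08, 1.51),
        (20, 13.2, 1.47),
        (30, 20.2, 2.70),
        (40, 23.7, 4.27),
        (50, 25.0, 2.63),
        (60, 30.7, 3.23),
        (70, 37.6, 8.37),
        (80, 37.0, 5.25),
    ),
    "ELOVL2_C7": (
        (10, 30.1, 2.43),
        (20, 46.4, 2.50),
        (30, 59.8, 4.94),
        (40, 66.6, 6.96),
        (50, 66.2, 1.99),
        (60, 72.8, 3.16),
        (70, 75.6, 3.55),
        (80, 72.1, 2.81),
    ),
}

DECADES = (10, 20, 30, 40, 50, 60, 70, 80)


def _interp(anchors: tuple[tuple[int, float, float], ...], age: float, idx: int) -> float:
    """Piecewise-linear interpolation of anchor column ``idx`` (1=mean, 2=SD),
    clamped to the nearest anchor outside the anchor age range."""
    ages = [a[0] for a in anchors]
    vals = [a[idx] for a in anchors]
    return float(np.interp(age, ages, vals))


def methylation_mean(
    site: str, age: float, anchors: DecadeAnchors | None = None
) -> float:
    """Expected percent methylation at ``site`` for a given age.

    At an anchor age this returns the anchor mean exactly; between anchors
    it interpolates linearly; outside the anchor range it clamps to the
    nearest anchor.
    """
    anchors = anchors if anchors is not None else DEFAULT_ANCHORS
    if site not in anchors:
        raise KeyError(f"unknown site {site!r}")
    return _interp(anchors[site], age, 1)


def methylation_sd(
    site: str, age: float, anchors: DecadeAnchors | None = None
) -> float:
    """Interpolated per-decade SD of percent methylation at ``site``."""
    anchors = anchors if anchors is not None else DEFAULT_ANCHORS
    if site not in anchors:
        raise KeyError(f"unknown site {site!r}")
    return _interp(anchors[site], age, 2)


@dataclass
class GeneratorConfig:
    """Training-cohort generator settings.

    ``table2`` mode draws methylation around the decade anchors and keeps
    the design ages; ``model_faithful`` mode regenerates ages from
    ``truth_model`` applied to the drawn methylation plus N(0,
    ``noise_sd_age``) noise, rounded to whole years.  ``site_correlation``
    adds an equicorrelated shared residual factor across sites (default 0:
    sites independent given age, as the published summaries imply nothing
    further).
    """

    mode: str = "table2"
    anchors: DecadeAnchors = field(default_factory=lambda: DEFAULT_ANCHORS)
    n_per_decade: int = 12
    decades: tuple[int, ...] = DECADES
    age_placement: str = "at_anchor"
    seed: int = 0
    truth_model: ClockModel | None = None
    noise_sd_age: float = 3.6
    site_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("table2", "model_faithful"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.age_placement not in ("at_anchor", "uniform_in_decade"):
            raise ConfigError(f"unknown age_placement {self.age_placement!r}")
        if self.n_per_decade < 1:
            raise ConfigError("n_per_decade must be >= 1")
        if not self.decades:
            raise ConfigError("decades set must be non-empty")
        for d in self.decades:
            if d not in DECADES:
                raise ConfigError(f"decade {d} not one of {DECADES}")
        if not 0.0 <= self.site_correlation < 1.0:
            raise ConfigError("site_correlation must be in [0, 1)")
        for site, anch in self.anchors.items():
            ages = [a[0] for a in anch]
            if ages != sorted(ages):
                raise ConfigError(f"{site}: anchors must be sorted by age")
            if any(a[1] < 0 or a[2] < 0 for a in anch):
                raise ConfigError(f"{site}: anchor means/SDs must be >= 0")


@dataclass
class ClinicalConfig:
    """Test-cohort (women of reproductive age) generator settings.

    Defaults reproduce the study design: 64 women aged 24-39 split
    7/16/29/12 over groups I-IV with the published per-group AMH and BMI
    summaries.  ``eaa_shift`` injects a true epigenetic-age offset (years)
    per group by evaluating the methylation anchors at ``age + shift``.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"I": 7, "II": 16, "III": 29, "IV": 12}
    )
    age_range: tuple[int, int] = (24, 39)
    amh: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (5.2, 3.2),
            "II": (3.6, 4.1),
            "III": (2.1, 1.5),
            "IV": (3.4, 1.4),
        }
    )
    bmi: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "I": (21.0, 3.7),
            "II": (21.0, 1.5),
            "III": (22.0, 3.3),
            "IV": (22.0, 4.2),
        }
    )
    eaa_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be non-negative")
        if sum(self.group_sizes.values()) == 0:
            raise ConfigError("at least one group must be non-empty")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigError("age_range must be (low, high) with low <= high")


def _draw_methylation(
    rng: np.random.Generator,
    anchors: DecadeAnchors,
    age: float,
    site_correlation: float = 0.0,
    max_redraws: int = 1000,
) -> dict[str, float]:
    """One sample's site vector: truncated normal around the interpolated
    anchors, redrawn jointly until every site lands in [0, 100]."""
    sites = [s for s in SITE_KEYS if s in anchors]
    means = np.array([methylation_mean(s, age, anchors) for s in sites])
    sds = np.array([methylation_sd(s, age, anchors) for s in sites])
    rho = site_correlation
    for _ in range(max_redraws):
        eps = rng.standard_normal(len(sites))
        if rho > 0:
            shared = rng.standard_normal()
            eps = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
        values = means + sds * eps
        if np.all((values >= 0.0) & (values <= 100.0)):
            return dict(zip(sites, values.tolist()))
    # pathological anchors (mean far outside range): fall back to clipping
    return dict(zip(sites, np.clip(values, 0.0, 100.0).tolist()))


def generate_training_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a decade-structured training cohort.

    Identical configs (including seed) produce identical cohorts, down to
    the emitted CSV bytes.
    """
    rng = np.random.default_rng(config.seed)
    profiles: list[MethylationProfile] = []
    idx = 0
    for decade in sorted(config.decades):
        for _ in range(config.n_per_decade):
            idx += 1
            if config.age_placement == "at_anchor":
                age = decade
            else:
                age = int(rng.integers(decade - 4, decade + 6))
            methylation = _draw_methylation(
                rng, config.anchors, age, config.site_correlation
            )
            if config.mode == "model_faithful":
                truth = config.truth_model
                if truth is None:
                    raise ConfigError("model_faithful mode needs a truth_model")
                pred = truth.intercept + sum(
                    c * methylation[s] for s, c in truth.coefficients.items()
                )
                noisy = pred + rng.normal(0.0, config.noise_sd_age)
                age = int(np.clip(np.floor(abs(noisy) + 0.5) * np.sign(noisy), 1, 120))
            profiles.append(
                MethylationProfile(
                    sample_id=f"TR{idx:04d}", age=int(age), methylation=methylation
                )
            )
    return Cohort(profiles, label="synthetic_training")


def _draw_amh(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Gamma draw matched to the group mean/SD (AMH is positive, right-skewed)."""
    if sd <= 0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return float(rng.gamma(shape, scale))


def generate_test_cohort(
    config: ClinicalConfig,
    anchors: DecadeAnchors | None = None,
    seed: int = 0,
) -> Cohort:
    """Generate the reproductive-age test cohort with clinical fields.

    Group membership fixes the ART flags (I/II never used ART; III used ART
    and achieved pregnancy; IV used ART without pregnancy).  Methylation is
    drawn from the anchors evaluated at ``age + eaa_shift[group]``, so the
    injected epigenetic-age offset is recoverable by any clock calibrated
    on matched training data.
    """
    anchors = anchors if anchors is not None else DEFAULT_ANCHORS
    rng = np.random.default_rng(seed)
    profiles: list[MethylationProfile] = []
    idx = 0
    lo, hi = config.age_range
    for group in GROUPS:
        size = config.group_sizes.get(group, 0)
        shift = float(config.eaa_shift.get(group, 0.0))
        for _ in range(size):
            idx += 1
            age = int(rng.integers(lo, hi + 1))
            methylation = _draw_methylation(rng, anchors, age + shift)
            amh_mean, amh_sd = config.amh[group]
            bmi_mean, bmi_sd = config.bmi[group]
            bmi = max(14.0, float(rng.normal(bmi_mean, bmi_sd)))
            art_used = group in ("III", "IV")
            art_pregnancy = (
                True if group == "III" else False if group == "IV" else None
            )
            profiles.append(
                MethylationProfile(
                    sample_id=f"TS{idx:04d}",
                    age=age,
                    methylation=methylation,
                    group=group,
                    amh=_draw_amh(rng, amh_mean, amh_sd),
                    bmi=bmi,
                    art_used=art_used,
                    art_pregnancy=art_pregnancy,
                )
            )
    return Cohort(profiles, label="synthetic_test")
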