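# Methods

## The clock and its assumptions

The age predictor is ordinary least squares of chronological age (whole
years) on percent methylation at up to six CpG sites. The linearity
assumption is empirically reasonable only up to roughly age 50: beyond it
several panel sites plateau or reverse, so `age_filter` restricts fitting
to 10–50 by default in the pipeline. Predictions are not clipped; the
model is applied as the linear form it is.

Epigenetic age acceleration is integerized: the continuous prediction is
rounded half-away-from-zero and differenced against chronological age,
`delta = round(pred) − chron`. Rounding the *prediction* (rather than the
delta) makes `delta = 0` coincide with the rounded prediction sitting on
the identity line, which is how "correctly predicted" samples are usually
displayed. The sign convention is positive-when-older (EAA); reports can
flip the displayed delta medians (`table5_sign`) for comparison with
tabulations that print chronological minus predicted.

## Error metrics

* MAE / MAD: mean absolute error of continuous predictions about the
  identity line, in years.
* RMSE: root mean squared error about the identity line (the square root
  is always applied; RMSE ≥ MAE on every cohort, a property the test
  suite asserts).
* RAE / RRSE: absolute and root-squared error as a percentage of the
  mean-only predictor's error, with the mean taken over the pooled
  evaluated ages.
* SEE: residual standard deviation (divisor n−2) about the *auxiliary
  regression* of predicted on chronological age — the scatter about the
  fitted trend line, not the diagonal. This is the only definition under
  which a cohort's SEE can fall below its RMSE, and the standard reading
  of a calibration scatterplot's fitted line.
* Cross-validation: samples are permuted with a mandatory seed and split
  into contiguous near-equal folds; metrics are computed once over the
  pooled held-out predictions. Leave-one-out is therefore
  seed-independent. A fold layout whose training remainder cannot support
  p+2 samples is rejected.

## Locus selection

M5'-style backward elimination: fit, find the site with the smallest
absolute standardized coefficient `b·sd(site)/sd(age)`, refit without it,
keep the removal if `AIC = n·ln(RSS/n) + 2(p+1)` decreases, else stop.
Ties are broken by the lower post-removal AIC, then lexicographically.
The AIC convention matters only through differences between nested models
on the same data; absolute AIC values are not comparable across
conventions, so published absolute AIC figures are treated as indicative
only.

A structural property of any Akaike-penalty stop rule is worth knowing:
dropping a truly null predictor lowers this AIC iff its squared
t-statistic is below `(n−p−1)(e^{2/n}−1)` (≈1.80 at n=60, p=6, →2 as
n→∞), so a null locus survives elimination with probability ≈
P(χ²₁ > 2) ≈ 0.16 *even asymptotically*. Backward elimination under AIC
is not a consistent selector; the suite tests the attainable property
(removal rate above one half and compatible with the F-threshold bound)
rather than near-certain removal.

## The synthetic generator

The generator emulates the published study design, not raw biology:

* **Training mode `table2`** — per-decade anchors (age, mean, SD) for each
  site, defaulting to the published decade summaries of the 94-sample
  training panel. Between anchors, mean and SD are interpolated linearly;
  outside 10–80 they clamp. Draws are normal, truncated to [0, 100] by
  joint redraw (SDs are small relative to the range, so moments stay
  near-nominal). Ages sit at the decade anchor by default
  (`at_anchor`, reproducing the grouped design) or spread uniformly over
  [decade−4, decade+5]. `n_per_decade` is uniform (default 12, i.e. 96
  samples over eight decades; the original design had 10 in the 80s
  decade for 94 total — the difference is immaterial to every analysis
  here, which filters to ages ≤ 50).
* **Training mode `model_faithful`** — methylation drawn as above, then
  age regenerated as a truth clock applied to the drawn values plus
  N(0, `noise_sd_age`) noise, rounded to whole years and clipped to
  [1, 120]. Under this mode the linear-model assumptions hold exactly up
  to rounding, which is what coefficient-recovery and locus-selection
  tests need. Because ages are integerized, recovery of truth
  coefficients is statistical (≈1/√n), not exact. The default
  `noise_sd_age` of 3.6 years mirrors the residual scale of the published
  training fit.
* **Test cohort** — 64 women aged 24–39 split 7/16/29/12 over clinical
  groups I–IV (control; infertility without ART; ART with delivery; ART
  without pregnancy), matching the published design. AMH is drawn from a
  gamma matched to each group's mean/SD (positive, right-skewed), BMI
  from a normal floored at 14 kg/m²; ART flags follow group membership.
  `eaa_shift` injects a known epigenetic-age offset per group by
  evaluating the methylation anchors at `age + shift`.

Sites are independent given age (an equicorrelation knob, default 0, is
exposed for sensitivity work); there is no batch structure, assay noise
model, or bisulfite-conversion failure mode. Consequently, passing tests
demonstrate that the *pipeline* behaves correctly on data with the study's
first- and second-moment structure — they do not validate the clock on
real blood samples.

Two consequences of the piecewise-linear anchor map deserve emphasis,
because tests compare simulations against closed-form expectations derived
from it rather than against idealized values:

* a globally linear clock fitted on decade-anchored training data carries
  an age-dependent calibration bias between anchors, about +1 year on
  average over ages 24–39 for the default anchors (the worked example's
  EAA excess);
* an injected offset of +3 anchor-years maps to `E[g(a+3) − g(a)] ≈ 2.5`
  predicted years over that band (local anchor slope ≈ 0.7–1.06 of the
  global slope), where `g(a)` is the clock applied to the anchor means at
  age `a`. Recovery tests therefore check the simulated group difference
  against this exact expectation within Monte-Carlo error, plus a
  one-year band around the nominal offset.

In anchor-driven (`table2`) data every site, including *TRIM59*, carries
genuine age signal, so backward elimination frequently retains all six
loci there; the *TRIM59*-removal behavior is specific to data generated
under a truth clock with no *TRIM59* term.

## Statistics

Rank tests delegate to scipy behind a fixed, reproducible method policy:
Mann–Whitney p-values are exact when the smaller sample has ≤ 8
observations and the pooled sample is tie-free, otherwise normal
approximation with tie and continuity correction; Wilcoxon signed-rank
drops zero differences, reports `W = min(W⁺, W⁻)` on average ranks, exact
for ≤ 15 effective tie-free pairs, otherwise corrected normal
approximation; Kruskal–Wallis uses the tie-corrected H against χ²(k−1).
Degenerate inputs (all observations tied, all paired differences zero)
return p = 1 as vacuous tests rather than erroring.

The Spearman CI uses the Fisher z transform with the Fieller-corrected
standard error `sqrt(1.06/(n−3))`, chosen over a bootstrap for
determinism; simulated coverage at n=100 is ~95%.

The clinical comparison table partitions the cohort four ways — groups
I–IV (Kruskal–Wallis), ART yes/no, BMI normal/deviation, AMH above/below
1.2 ng/mL (Mann–Whitney) — with per-stratum medians and a paired Wilcoxon
of chronological vs predicted age within each stratum. BMI is "normal" on
the closed interval [18.5, 25]; AMH exactly 1.2 goes to the high stratum
(low is defined strictly below the cutoff). No multiple-testing
correction is applied, mirroring the analysis the table reproduces.

## Numerical and design choices

* Ages are integers end to end; fractional input ages are rejected, not
  rounded.
* Site keys are `GENE_LABEL` strings because *ELOVL2* contributes two
  CpGs.
* Missing methylation is representable (empty CSV cell); profiles missing
  a modeled site are excluded from fitting/prediction with a warning.
* Clock JSON round-trips bit-exactly (floats serialized at full repr
  precision); cohort CSV writes are byte-deterministic.
* Rank-deficient designs raise an error naming the collinear columns
  (pivoted QR); zero-variance sites yield NaN standardized coefficients
  with a warning; zero RSS yields −inf AIC with a warning.
* Per-stage seeds in the CLI pipeline are derived by hashing
  `(seed, stage)` so adding a stage never shifts the other streams.

## Problem sizes

Simulation-based tests use study-scale designs (n = 60 training, 64 test)
where the claim is about the design, and larger sizes only where the claim
is asymptotic: 2000/decade for generator moment checks, 5000 samples for
coefficient recovery, 500/group for offset recovery, 400–1000 replicates
for selection frequency, null-uniformity, type-I error and CI coverage.

## Known limitations

* No real-data validation: the source cohorts' per-sample methylation is
  not publicly deposited, so all quantitative checks run on matched
  synthetic data.
* The generator's between-site independence given age understates the
  correlation structure of real panels; CV error estimates on synthetic
  data are accordingly mildly optimistic.
* Post-50 non-monotone methylation is represented only through the
  anchors; the generator does not decide between plateau and reversal.
* The published test-set error trio (RMSE below MAD) cannot arise from a
  single residual definition; this package reports standard definitions
  (RMSE ≥ MAD always) plus the regression-line SEE, and makes no attempt
  to reverse-engineer the printed combination.
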