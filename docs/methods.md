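# Methods

## Measurement model

A thermal-latency assay reads the time until paw (plantar test) or tail
(tail-flick test) withdrawal from a radiant heat stimulus, capped at a
per-assay cutoff (15 s plantar at 50% intensity, 4 s tail-flick at 40%) to
prevent tissue damage; a reading at the cutoff is right-censored.  Baseline
latency per animal is the mean of three repeats taken 5 min apart after
discarding repeats more than one sample standard deviation from the mean of
all three (inclusive boundary, single pass — the rule is not iterated).
Analgesic effect is the percent of maximal possible effect,

    %MPE(t) = 100 · (post(t) − pre) / (cutoff − pre),

clamped to [0, 100]: readings faster than baseline (hyperalgesic direction)
score 0 rather than negative, because the score is interpreted as block
intensity.  Animals whose trimmed baseline is at or above the cutoff have no
denominator — their neuropathy saturates the assay — and are excluded with an
explicit reason before any scoring.  Fasting glucose classifies animals as
diabetic (> 23 mmol/L) or non-diabetic (< 8 mmol/L); the gap [8, 23] maps to
an explicit "indeterminate" status excluded from both arms rather than being
silently assigned.

## Sampling design

One analgesia meter serves a group, so a group of *n* ≤ 9 mice shares a
1.5-min slot grid over a 270-min horizon (180 grid points), partitioned into
twenty 13.5-min windows of nine slots.  Each mouse is measured exactly once
per window; with n < 9 the block design is incomplete.  Slot assignment
fixes a seeded random base order and advances every mouse's slot by two
positions per window (mod 9).  A step of two — rather than the naive step of
one — guarantees consecutive measurements of the same animal are at least
two slot spacings (3 min) apart even across the window-wrap, for every window
size.  The grid is interpreted per treatment-condition arm; whether a real
study shares one grid across arms does not affect the per-arm analysis.
`validate_schedule` checks collisions, off-grid times, and missing or
duplicated mouse-window pairs, reporting violations as data rather than
exceptions.

## Block kinetics and duration

Group kinetics are summarized as mean ± sample SD of %MPE per half-open
window (a value at exactly t = 13.5 k min belongs to window k); empty windows
are reported with n = 0 and skipped by the fits.

Two descriptions of the trajectory are computed:

* **Cubic fit.**  An unweighted OLS cubic of window means on window
  midpoints (unweighted because only the means define the published
  trajectory).  The solve uses centred/scaled time for conditioning and maps
  coefficients back exactly by polynomial composition; it matches an exact
  rational normal-equation solve to well below 1e-8.  R² = 1 − SSres/SStot,
  defined as 0 with a warning when the response has zero variance, so
  0 ≤ R² ≤ 1 always.  Landmarks come from the analytic roots of the
  derivative quadratic, classified by the second derivative, with global
  extrema taken over the closed domain: the global maximum is the **onset
  peak**, an interior local minimum the **partial release**.  Per-segment
  cubic fits over user-chosen sub-domains (`fit_mode: multi-segment`)
  accommodate trajectories with several release marks that a single cubic
  cannot carry.

* **Interval-means path.**  The window means themselves, thresholded
  directly.

The **sensory block duration** is the time from injection until the
trajectory falls below the diminished-block threshold (default 15% MPE; a
value exactly at the threshold counts as diminished) and does not re-exceed
it before the end of the horizon; if it never settles below, the duration is
**censored above the horizon**.  On the cubic path the crossing is the last
real root of (fit − threshold) after the onset peak, found analytically.  On
the means path:

1. scanning forward from the global peak, the block counts as diminished at
   the first window below threshold confirmed by the following window (or by
   the end of the horizon), and a re-exceedance counts as a genuine re-block
   only when sustained over two consecutive windows — a single noisy window
   cannot flip the call in either direction;
2. the crossing time is interpolated linearly between the bracketing window
   means and refined by a three-parameter logistic decay
   A / (1 + exp((t − m)/s)) fitted by weighted least squares to all windows
   of the terminal descent — each window weighted by its own standard error
   (SD/√n, floored at one %MPE point) — clamped to within one window of the
   bracket (plain interpolation is the fallback when the fit fails).

The logistic refinement and its weighting exist because window means are
heteroscedastic: a mouse whose baseline sits near the cutoff has a small
%MPE denominator and contributes near-random scores, so a crossing read off
two adjacent means alone is fragile and unweighted pooling lets such an
animal's spikes flatten the fitted tail.  Weighted pooling of the whole
descent recovers generator durations of 60–160 min to within half a window
(±6.75 min) in ≥ 90% of noisy replicates at 0.5-s observation noise, and to
within ~2 min noise-free.

The pipeline's headline duration uses the interval-means path
(`fit_mode: piecewise`, the default).  The single global cubic is retained as
the descriptive model (onset/release landmarks, R²) and can be selected for
the duration (`fit_mode: cubic`), but a rise-plateau-fall trajectory is not
cubic: in calibration runs its crossings were off by 3–20 min noise-free and
it frequently fails to descend below threshold inside the domain at all.

## Discrimination statistics

%MPE scores pooled over the horizon feed ROC curves: thresholds sweep the
distinct scores with ties grouped, so the trapezoidal AUC equals the
tie-corrected Mann–Whitney concordance probability.  Two model pairs are
built per study: "LA" models discriminate condition within a fixed
anesthetic, "condition" models discriminate anesthetic within a fixed
condition; the positive class is the one expected to show deeper/longer
block (the neuropathic condition, or the extended-release formulation).
Scores are aggregated per window mean by default (20 scores per arm);
per-measurement and per-mouse aggregation are selectable.  The AUC standard
error uses the Hanley–McNeil closed form (Q1 = A/(2−A), Q2 = 2A²/(1+A)),
with a stratified bootstrap as a pluggable alternative — no distributional
assumption beyond independence either way.  Two areas from disjoint arms are
contrasted with χ² = (A₁ − A₂)²/(SE₁² + SE₂²) on 1 df; a correlated-AUC
(DeLong-style) comparison is out of scope because the compared models come
from independent samples.  Cohort covariates use the classical
pooled-variance two-sample t-test by default (groups are balanced by design,
making the Welch distinction minor); Welch is available.  All p-values are
two-sided and are labelled with two significance tiers (significant at
p < 0.05, notably significant at p < 0.1) rather than truncated.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the pharmacokinetics.  Cohorts: per-condition truncated-normal baselines
(control 6.4 ± 2.8 s, neuropathic 11.9 ± 3.4 s), glucose (7.6 ± 0.9 vs
24.6 ± 5.4 mmol/L) and weight (28.5 ± 2.2 vs 21.3 ± 2.4 g); baselines are
capped at the 15-s cutoff and capped draws are kept, not resampled, so the
exclusion filter is exercised at realistic rates (roughly a third of
neuropathic animals).  A saturated animal reads the cutoff in all three
baseline repeats.  Within-mouse repeat spread defaults to 0.4 s.

True block intensity g(t) ∈ [0, 1] of the baseline→cutoff gap is piecewise
cosine-eased: rise from 0 to the peak at `onset_min`, optional partial
release (`release_dip`) with optional rebound back to the peak, then a decay
whose pace is calibrated so g(`duration_min`) = 0.15 exactly.  Observed
latency is baseline + g·(cutoff − baseline) + Gaussian noise (default SD
0.5 s — chosen for test power; the underlying studies publish no
within-mouse variance over time), clamped to [0, cutoff] with the censored
flag set when the clamp binds at the cutoff.  Default arm profiles: single
release at 106 min (control/BH), 117.1 min (neuropathic/BH) and 118 min
(control/LB); the neuropathic/LB arm dips to intensity 0.565 at 92.8 min,
rebounds, and crosses 0.15 only at 320 min — past the horizon, so its
duration must be reported censored.  All randomness flows through one seeded
generator; identical seeds give byte-identical studies.

What passing tests on this generator do **not** show about real data: no
within-mouse autocorrelation or habituation to the stimulus, no
between-mouse variation in block shape within an arm (all mice in an arm
share one g), additive Gaussian noise rather than the skewed latency noise
of real assays, and no tail-flick time courses (only tail-flick baselines).

## Defaults that matter

| parameter | default | unit | why |
|---|---|---|---|
| plantar cutoff / tail-flick cutoff | 15 / 4 | s | censoring ceilings of the assays |
| diminished-block threshold | 15 | %MPE | standard criterion for block release |
| window / slot spacing / horizon | 13.5 / 1.5 / 270 | min | the 180-point interleaved grid |
| mice per arm | 6 | — | typical group size for this design |
| glucose thresholds | > 23, < 8 | mmol/L | diabetic / non-diabetic inclusion rules |
| fit_mode | piecewise | — | robust duration; cubic kept as descriptive model |
| roc_aggregation | window-mean | — | one score per design window (20 per arm) |
| t_test_variant | pooled | — | balanced groups; Welch optional |
| observation noise | 0.5 | s | generator test-power choice, not a fitted value |

## Numerical conventions

Floats in reports are serialized at six significant digits (round-half-even)
so repeated runs are byte-identical and diffable; NaN serializes as null.
Baseline trimming compares |v − mean| ≤ SD + 1e-9 to keep the boundary
inclusive under floating point.  Degenerate statistics (both SDs zero with
unequal means; two zero-SE AUCs that differ) report p at the smallest
positive double with a warning rather than zero, keeping p ∈ (0, 1].

## Known limitations

The duration estimator assumes a single terminal descent after the last
sustained re-block; trajectories that oscillate around the threshold in
more than two sustained episodes are resolved by the run-rule but the
logistic refinement then fits only the final descent.  Arms with several
excluded animals can drop to 2–3 informative mice, where window means are
noisy and duration estimates degrade (the neuropathic arms of the real
design are the hard case; their published descriptive fits explain only
~25–29% of variance).  AUC standard errors from 20 window means are large;
the χ² contrast has low power at these sizes.  The schedule generator does
not interleave the four arms against each other (each arm gets its own
grid), and no optimal-design search is attempted.
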