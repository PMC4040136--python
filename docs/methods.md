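# Methods

## The EF score

One imaged field is an 8-bit RGB raster of an elastin-stained (Weigert /
Elastica-van-Gieson) lung section.  The score chain is:

1. **Grayscale.** Weighted luminance with configurable weights, default
   Rec. 601 (0.299, 0.587, 0.114), rounded half-up to integer intensities.
   Luminance is preferred to a single channel because all three stain
   classes (fiber, collagen, background) order monotonically in luminance;
   color deconvolution is deliberately out of scope.
2. **Fibrotic-lesion mask.** Pixels with intensity at or below the first
   (lighter) threshold.  Dark is foreground: fibrotic tissue is darker than
   background on these stains.
3. **Elastic-fiber mask.** Pixels at or below the second (darker) threshold
   *and* inside the fibrotic mask.  Containment is enforced so the score is
   a true fraction; both masks derive from the same grayscale transform.
4. **Score.** `100 × |EF mask| / |fibrotic mask|`, in percent.  An empty
   fibrotic mask is an error ("no fibrotic lesion detected"), and such
   fields are excluded from patient means with a logged warning rather than
   being scored 0%.

Per patient, the EF score is the **unweighted mean over imaged fields** (not
a pixel-pooled ratio), so each field contributes equally regardless of its
lesion area; per-lobe means are taken over that lobe's fields only.  This
matches how a reader averages "the proportion in each image".

**Thresholds.** Manual threshold choices are not reproducible, so the
default is automated: Otsu's method on the full histogram for the lesion
mask, and Otsu restricted to within-lesion pixels for the fiber mask.  Fixed
intensity values (0–255, `ef ≤ fibrotic`) can be supplied instead; equality
of the two thresholds makes the masks coincide (score 100%).  Otsu on a
constant image raises a degenerate-histogram error.

Monotonicity holds by construction: the score is nondecreasing in the fiber
threshold and nonincreasing in the lesion threshold (new lesion pixels
admitted by a higher lesion threshold are lighter than the fiber threshold,
so they enlarge only the denominator).

## Synthetic fields

Real stained sections are not publicly available, so the generator emulates
what the quantifier sees, with exact ground truth:

- **Fibrotic region**: a single simply-connected blob attached to the bottom
  image edge (a stylized subpleural lesion).  Its upper boundary is a
  moving-average-smoothed random profile scaled so the region covers the
  requested image fraction (default 0.5).
- **Fibers**: random-walk polylines with bounded turning angle (±0.35 rad
  per unit step) and fixed thickness (default 2 px), stamped with a disk
  footprint, clipped to the fibrotic region.  Fibers are added until the
  fiber area reaches the target fraction of the lesion; each fiber adds well
  under 2% of the lesion area, so the realized fraction lands within the
  0.02 tolerance or, if the fiber budget runs out short of it, the generator
  raises "target fraction unattainable".  `ef_fraction` 0 and 1 are exact
  special cases (no fibers / lesion fully painted).
- **Colors and noise**: background (235, 228, 225), collagen (186, 96, 110),
  fiber (45, 32, 48) — luminances ≈ 230, 125, 38, enforced ordered — with
  i.i.d. Gaussian pixel noise (default sd 8) added after painting, clipped
  to [0, 255].  At sd 8 the class separations (≈ 43 and 52 gray levels to
  the midway thresholds) are > 5 sd, so fixed midway thresholds make
  essentially no pixel errors; the noise exercises robustness without
  destroying separability by design.
- **Determinism**: one `numpy` generator seeded from the spec reproduces the
  image bit for bit; the stored realized fraction equals the ratio recounted
  from the emitted masks exactly.

What this does *not* emulate: stain variability, uneven illumination, folds
and bubbles, out-of-focus regions, true elastin morphology, or multiple
lesions per field.  Passing recovery tests therefore demonstrates the
correctness of the measurement chain, not robustness to real-slide
artifacts.

## Synthetic cohorts

Two groups (default 6 vs 28 patients, labeled IPPFE / IPF).  Continuous
clinical variables are normals truncated by rejection at physiologic bounds
that live in the packaged `default_config.yaml` (percentages in [0, 100],
BMI ≥ 10, etc.); `sd = 0` degenerates to a constant.  Defaults mirror a
small fibroelastosis-vs-UIP case-control profile (e.g. BMI 17.9 ± 0.9 vs
24.3 ± 2.8; FVC %pred 62.7 ± 10.9 vs 88.6 ± 21.9; EF score 28.5 ± 3.3 vs
12.1 ± 4.4 percent).  Categoricals are drawn from per-group probabilities.
Survival is exponential with group medians (defaults 40 vs 68 months,
matching the groups' observation periods) under independent exponential
censoring calibrated so `P(censored) = censoring_rate` (default 0.5).
Groups of fewer than two patients are rejected (downstream variances would
be undefined).

## Semiquantitative scores and agreement

Extent of fibrosis is banded per lobe as none / 1–10 / 11–25 / 26–50 /
51–75 / 76–100 percent (scores 0–5) and summed over the five lobes to 0–25.
Band assignment uses the printed lower bounds as cut-points: a percent
scores the highest band whose lower bound it reaches, any nonzero
involvement scores at least 1, and 0 is reserved for exactly 0%.  Severity
items use a 0–3 scale; binary findings are presence flags.

Weighted kappa follows the standard disagreement-weight form,
`κ = 1 − Σw·observed / Σw·expected`, with `w_ij = |i−j|/(k−1)` (linear,
default) or `(i−j)²/(k−1)²` (quadratic); expected proportions come from the
product of the raters' marginals.  Linear weighting is the default as the
conservative common choice for ordinal clinical scales; both are exposed.
With two categories both weightings reduce to unweighted Cohen's kappa.
Two constant raters have zero expected disagreement and raise an
"agreement undefined" error.  Consensus replays the observers'
reconciliation: agreements stand, disagreements go to a rule
(`take_lower`, `take_higher`, `take_mean_round_half_up`, or any callable),
and every resolution is logged.

## Statistical conventions

All tests are two-sided at α = 0.05, with no multiple-testing correction —
each table row is nominal, and reports state this.  Specific choices, made
to match how classic clinical-statistics software builds such tables:

- **Student (pooled) t, not Welch**, both from raw samples and from printed
  mean ± SD / n summaries; the two routes agree exactly on moment-matched
  samples.  Zero-variance degeneracies: equal means → p = 1; unequal → p = 0
  with a warning.
- **Fisher's exact two-sided p is the small-p-values sum** (all tables with
  the observed margins whose hypergeometric probability does not exceed the
  observed one), not the doubled one-tail.  A zero margin yields p = 1 with
  a degeneracy warning.
- **Pearson chi-square without continuity correction**, df = (r−1)(c−1);
  a zero expected count is an error.  2×2 categorical comparisons route to
  Fisher when any expected count is below 5, otherwise chi-square.
- **Mann-Whitney U** uses midranks; the exact null distribution when
  `n_x·n_y ≤ 400` and there are no ties, otherwise the normal approximation
  with tie and continuity corrections.  A fully tied pooled sample returns
  U at its null mean with p = 1.
- **Kaplan-Meier / log-rank** with the deaths-before-censorings tie
  convention; the log-rank is undefined (error) with no events.
- Reports round p-values to 3 decimals and percents to 1 decimal.

## Problem sizes in tests and the acceptance script

Synthetic fields are 256×256 (recovery checks) or 192×192 (replicated
cohort experiments), one field per synthetic patient, 100 replicates for
the group-separation experiment and 2,000 simulations for the t-test
calibration — sizes chosen so the whole battery runs on a laptop in about
a minute while keeping the Monte-Carlo standard errors far below the
margins being tested (e.g. rejection-rate SE ≈ 0.005 at 2,000 reps).

## Known limitations

- The threshold chain assumes three luminance-ordered classes; it has no
  stain normalization, color deconvolution, artifact detection, or
  whole-slide tiling.
- Synthetic fibers are geometric polylines, not elastin morphology; the
  generator is a test harness, not a histology simulator.
- The cohort generator draws variables independently within groups; real
  clinical covariates correlate.
- Recomputing p-values from printed summaries inherits the rounding of
  those summaries; small discrepancies from values computed on raw data are
  expected and are flagged, not resolved.
- No regression or proportional-hazards modelling; confidence intervals
  beyond Greenwood's for the survival curve are out of scope.
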