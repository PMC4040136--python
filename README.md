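# efscore

Quantitative elastic-fiber scoring of elastin-stained lung histology, with
the small-cohort statistics needed to compare two patient groups.

In fibrotic lung disease, the balance of collagen and elastic fibers (EF)
inside a lesion carries diagnostic weight: idiopathic pleuroparenchymal
fibroelastosis (IPPFE) deposits dense subpleural elastosis, while the usual
interstitial pneumonia pattern of idiopathic pulmonary fibrosis (IPF) is
collagen-dominated and can look deceptively similar on routine stains.  On
Elastica-van-Gieson / Weigert-stained sections, elastic fibers are the
darkest structures, fibrotic collagen is intermediate, and background is
pale — which makes the fiber burden measurable by thresholding.

`efscore` is aimed at pathology-image analysts and clinical researchers who
need that measurement, plus the surrounding analysis, as reproducible code.

## The statistic

For one imaged field, convert to grayscale, binarize twice (dark-is-
foreground), and take the area fraction:

    EF score = 100 x |{x : I(x) <= t_EF}| / |{x : I(x) <= t_fib}|   (percent)

where `t_EF < t_fib` so the fiber mask is contained in the fibrotic-lesion
mask.  Thresholds default to Otsu's method (for the lesion) and Otsu
restricted to within-lesion pixels (for the fibers), with fixed-value
override.  A patient's EF score is the unweighted mean over all their imaged
fields, optionally stratified by lung lobe.

Around the image chain the package provides:

- `efscore.synthdata` — synthetic EVG-like fields with pixel-exact
  ground-truth masks, and synthetic two-group cohort/survival tables;
- `efscore.semiquant` — 0–3 severity scales, per-lobe 0–5 fibrosis-extent
  bands summed to a 0–25 total, two-observer consensus, and Cohen's
  weighted kappa (linear or quadratic weights);
- `efscore.cohortstats` — Fisher's exact test (two-sided, small-p-values
  sum), Pearson chi-square without continuity correction, pooled-variance
  Student t from raw samples or printed mean ± SD summaries, Mann-Whitney U
  (exact for small tie-free samples), Pearson/Spearman correlation,
  Kaplan-Meier and the log-rank test;
- `efscore.pipeline` plus an `efscore` CLI — a reproducible end-to-end run
  emitting CSV tables, a markdown report, and a machine-readable JSON.

## Worked example

Scoring a synthetic field with known truth (`examples/01_score_synthetic_field.py`):

```
fibrotic pixels : 32742
fiber pixels    : 9349
measured EF score: 28.6%
ground truth     : 28.6%
```

The field was generated with a target fiber fraction of 28.5%; the chain
recovers the painted fraction to within rounding at the default noise level.

Recomputing published-style table rows from printed inputs
(`examples/02_published_table_statistics.py`):

```
fine crackles 3/6 vs 27/28                              fisher_exact     p = 0.012
pneumothorax 4/6 vs 1/28                                fisher_exact     p = 0.002
smoking current/ex/never 0/3/3 vs 13/13/2               chi_square       p = 0.011
FVC %pred 62.7+/-10.9 (n=6) vs 88.6+/-21.9 (n=28)       student_t_pooled p = 0.009
BMI 17.9+/-0.9 vs 24.3+/-2.8                            student_t_pooled p = 0.000
```

Counts and mean ± SD with group sizes are sufficient inputs: no raw data are
needed to verify a clinical table's p-values.  The other examples cover
cohort simulation, inter-rater agreement, and the full pipeline.

## Command line

```sh
efscore synth-images --out fields/ --count 4 --ef-fraction 0.285 --seed 1
efscore score --images fields/ --manifest manifest.csv --threshold-mode otsu --out scores.csv
efscore synth-cohort --out cohort/ --n-a 6 --n-b 28 --seed 1
efscore report --config pipeline.yaml
```

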