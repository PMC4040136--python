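"""Two-observer ordinal scoring: consensus and weighted-kappa agreement.

Two observers score consolidation severity (0-3) on ten cases; disagreements
are reconciled by a rule, and chance-corrected agreement is summarized by
Cohen's weighted kappa.
"""

from efscore import RaterPair, consensus, weighted_kappa
from efscore.semiquant import extent_band_to_score, total_extent_score, LOBES

pair = RaterPair(
    ratings_a=(0, 1, 2, 0, 1, 3, 2, 2, 1, 0),
    ratings_b=(0, 2, 2, 1, 1, 3, 2, 1, 1, 0),
    n_categories=4,
)

for weighting in ("linear", "quadratic"):
    res = weighted_kappa(pair, weighting)
    print(f"{weighting:10s} kappa = {res.kappa:.2f}")

print("consensus  :", consensus(pair, "take_mean_round_half_up"))

# Per-lobe fibrosis extent: percent involvement -> 0-5 band, summed to 0-25.
involvement = {"right_upper": 40, "right_middle": 8, "right_lower": 12,
               "left_upper": 55, "left_lower": 0}
extent = {lobe: extent_band_to_score(p) for lobe, p in involvement.items()}
print("extent bands:", [extent[l] for l in LOBES], "-> total", total_extent_score(extent))
# Kappa near 0.7 is substantial agreement; the total extent score condenses
# five lobes into one 0-25 burden number.
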