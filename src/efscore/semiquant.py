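"""Semiquantitative HRCT / pathology scoring and inter-rater agreement.

Fibrosis extent is scored per lung lobe on a 0-5 band of percent
involvement (none / 1-10 / 11-25 / 26-50 / 51-75 / 76-100) and summed over
the five lobes to a 0-25 total.  Severity findings (reticulation,
ground-glass, consolidation, collagen deposition, organizing pneumonia,
cellularity, emphysema) use a 0-3 scale (none / mild / moderate / severe);
binary findings (honeycombing, pleural thickening, pleuritis, lymphoid
hyperplasia) are presence flags.  Two-observer reads are reconciled by a
consensus rule and their agreement summarized by Cohen's weighted kappa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "LOBES",
    "ScoreSet",
    "RaterPair",
    "KappaResult",
    "total_extent_score",
    "extent_band_to_score",
    "weighted_kappa",
    "consensus",
    "CONSENSUS_RULES",
]

logger = logging.getLogger(__name__)

LOBES = ("right_upper", "right_middle", "right_lower", "left_upper", "left_lower")

SEVERITY_ITEMS = (
    "reticulation",
    "ground_glass",
    "consolidation",
    "emphysema",
    "collagen_deposition",
    "organizing_pneumonia",
    "cellularity",
)

PRESENCE_ITEMS = (
    "honeycombing_hrct",
    "pleural_thickening",
    "microscopic_honeycombing",
    "lymphoid_hyperplasia",
    "pleuritis",
)

# printed lower bounds of the percent-involvement bands for extent scores 1..5
# (1-10, 11-25, 26-50, 51-75, 76-100)
_BAND_LOWER = (1.0, 11.0, 26.0, 51.0, 76.0)


@dataclass(frozen=True)
class ScoreSet:
    """All semiquantitative scores for one patient (one rater or consensus)."""

    patient_id: str
    extent: Mapping[str, int]
    severity: Mapping[str, int] = field(default_factory=dict)
    presence: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_extent(self.extent)
        for item, score in self.severity.items():
            if score not in (0, 1, 2, 3):
                raise ValueError(f"severity {item}={score} outside 0-3")

    @property
    def total_extent(self) -> int:
        return total_extent_score(self.extent)


@dataclass(frozen=True)
class RaterPair:
    """Two observers' ratings of the same items on a shared ordinal scale."""

    ratings_a: tuple[int, ...]
    ratings_b: tuple[int, ...]
    n_categories: int

    def __post_init__(self) -> None:
        if len(self.ratings_a) != len(self.ratings_b):
            raise ValueError("rating vectors differ in length")
        if len(self.ratings_a) < 2:
            raise ValueError("need at least two rated items")
        k = self.n_categories
        if k < 2:
            raise ValueError("need at least two categories on the scale")
        for v in (*self.ratings_a, *self.ratings_b):
            if not 0 <= v <= k - 1:
                raise ValueError(f"rating {v} outside [0, {k - 1}]")


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weighting: Literal["linear", "quadratic"]


def _validate_extent(extent: Mapping[str, int]) -> None:
    if set(extent) != set(LOBES):
        missing = set(LOBES) - set(extent)
        extra = set(extent) - set(LOBES)
        raise ValueError(
            f"extent must score each of the five lobes exactly once "
            f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
        )
    for lobe, score in extent.items():
        if score not in (0, 1, 2, 3, 4, 5):
            raise ValueError(f"extent score {score} for {lobe} outside 0-5")


def total_extent_score(extent: Mapping[str, int]) -> int:
    """Sum of the five per-lobe extent scores; ranges over 0-25."""
    _validate_extent(extent)
    return int(sum(extent.values()))


def extent_band_to_score(percent_extent: float) -> int:
    """Map a percent involvement to its 0-5 extent band.

    The bands are the closed integer ranges 1-10, 11-25, 26-50, 51-75 and
    76-100; a percent is assigned the highest band whose printed lower bound
    it reaches (so 10.5% stays in band 1, 11% enters band 2).  0 maps to band
    0 only for exactly 0% — any nonzero involvement scores at least 1.
    """
    if not 0 <= percent_extent <= 100:
        raise ValueError("percent extent must lie in [0, 100]")
    if percent_extent == 0:
        return 0
    band = sum(percent_extent >= lower for lower in _BAND_LOWER)
    return max(1, band)


def weighted_kappa(
    pair: RaterPair, weighting: Literal["linear", "quadratic"] = "linear"
) -> KappaResult:
    """Cohen's weighted kappa for two raters on a k-category ordinal scale.

    Disagreement weights are w_ij = |i-j|/(k-1) (linear) or (i-j)^2/(k-1)^2
    (quadratic); kappa = 1 - sum(w * observed) / sum(w * expected) with
    expected cell proportions from the product of the raters' marginals.
    Linear weighting is the default, the conservative common choice for
    ordinal clinical scales.
    """
    k = pair.n_categories
    a = np.asarray(pair.ratings_a)
    b = np.asarray(pair.ratings_b)
    if len(set(a) | set(b)) < 2:
        raise ValueError("agreement undefined: both raters used a single category")

    observed = np.zeros((k, k))
    np.add.at(observed, (a, b), 1.0)
    observed /= observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))

    i, j = np.indices((k, k))
    if weighting == "linear":
        w = np.abs(i - j) / (k - 1)
    elif weighting == "quadratic":
        w = (i - j) ** 2 / (k - 1) ** 2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    exp_disagreement = float((w * expected).sum())
    if exp_disagreement == 0:
        raise ValueError("agreement undefined: zero expected disagreement")
    kappa = 1.0 - float((w * observed).sum()) / exp_disagreement
    return KappaResult(kappa, weighting)


def _take_lower(a: int, b: int) -> int:
    return min(a, b)


def _take_higher(a: int, b: int) -> int:
    return max(a, b)


def _take_mean_round_half_up(a: int, b: int) -> int:
    return math.floor((a + b) / 2 + 0.5)


CONSENSUS_RULES: dict[str, Callable[[int, int], int]] = {
    "take_lower": _take_lower,
    "take_higher": _take_higher,
    "take_mean_round_half_up": _take_mean_round_half_up,
}


def consensus(
    pair: RaterPair, resolver: str | Callable[[int, int], int] = "take_mean_round_half_up"
) -> tuple[int, ...]:
    """Reconcile two raters into one vector.

    Where the observers agree that value stands; disagreements go to the
    resolver — a named rule from :data:`CONSENSUS_RULES` or any callable
    ``(a, b) -> int`` (e.g. an interactive prompt standing in for the
    discussion between observers).  Every resolver decision is logged.
    """
    rule = CONSENSUS_RULES[resolver] if isinstance(resolver, str) else resolver
    out = []
    for idx, (a, b) in enumerate(zip(pair.ratings_a, pair.ratings_b)):
        if a == b:
            out.append(a)
        else:
            value = rule(a, b)
            if not 0 <= value <= pair.n_categories - 1:
                raise ValueError(f"resolver returned {value}, outside the scale")
            logger.info("consensus at item %d: raters %d vs %d -> %d", idx, a, b, value)
            out.append(value)
    return tuple(out)
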