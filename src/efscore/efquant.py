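"""Elastic-fiber quantification from elastin-stained section images.

The chain is: RGB field -> grayscale (configurable luminance weights) ->
fibrotic-lesion mask (first, lighter threshold) -> elastic-fiber mask
(second, darker threshold, constrained to lie inside the fibrotic mask) ->
EF score = 100 x fiber pixels / fibrotic pixels.  Dark is foreground
throughout: elastin stains nearly black, fibrotic collagen darker than the
pale background.  Per-patient scores are unweighted means over that
patient's imaged fields, optionally stratified by lung lobe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.filters import threshold_otsu

from efscore.config import default_grayscale_weights

__all__ = [
    "ThresholdConfig",
    "EfScoreResult",
    "PatientAggregate",
    "DegenerateHistogramError",
    "EmptyFibroticMaskError",
    "to_gray",
    "segment_fibrotic",
    "segment_ef",
    "ef_score",
    "score_image",
    "patient_ef_score",
    "load_rgb_image",
    "score_manifest",
]

logger = logging.getLogger(__name__)

Lobe = Literal["upper", "lower", "unspecified"]


class DegenerateHistogramError(ValueError):
    """Otsu thresholding requested on a constant image."""


class EmptyFibroticMaskError(ValueError):
    """EF score requested but no fibrotic lesion was detected."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Binarization settings for the two-threshold chain.

    In ``otsu`` mode the fibrotic threshold is Otsu's on the full grayscale
    histogram and the fiber threshold is Otsu's restricted to pixels inside
    the fibrotic mask.  In ``fixed`` mode the two intensities are given
    explicitly and the fiber threshold must be the darker of the two.
    """

    mode: Literal["otsu", "fixed"] = "otsu"
    fibrotic_threshold: int | None = None
    ef_threshold: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "fixed":
            if self.fibrotic_threshold is None or self.ef_threshold is None:
                raise ValueError("fixed mode requires both thresholds")
            for t in (self.fibrotic_threshold, self.ef_threshold):
                if not 0 <= t <= 255:
                    raise ValueError("thresholds must lie in [0, 255]")
            if self.ef_threshold > self.fibrotic_threshold:
                raise ValueError(
                    "ef_threshold must not be lighter than fibrotic_threshold"
                )


@dataclass(frozen=True)
class EfScoreResult:
    """Pixel counts and EF score (percent) for one field."""

    n_fibrotic_pixels: int
    n_ef_pixels: int
    ef_score: float


@dataclass(frozen=True)
class PatientAggregate:
    """Per-patient EF summary.

    ``patient_ef_score`` is the unweighted mean of per-image scores (not a
    pixel-pooled ratio); ``lobe_scores`` holds the mean over each lobe's
    images.
    """

    patient_id: str
    images: tuple[tuple[EfScoreResult, str], ...]
    patient_ef_score: float
    lobe_scores: dict[str, float] = field(default_factory=dict)


def to_gray(
    image: np.ndarray, weights: Sequence[float] | None = None
) -> np.ndarray:
    """Convert an (H, W, 3) uint8 RGB image to grayscale.

    Per-pixel weighted luminance, rounded half-up to integer intensities.
    Default weights are Rec. 601 (0.299, 0.587, 0.114).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    w = np.asarray(weights if weights is not None else default_grayscale_weights(), float)
    if w.shape != (3,):
        raise ValueError("need exactly three grayscale weights")
    lum = img.astype(np.float64) @ w
    return np.clip(np.floor(lum + 0.5), 0, 255).astype(np.uint8)


def _resolve_threshold(
    gray: np.ndarray, cfg: ThresholdConfig, fixed: int | None, within: np.ndarray | None
) -> float:
    if cfg.mode == "fixed":
        return float(fixed)  # type: ignore[arg-type]
    values = gray if within is None else gray[within]
    if values.size == 0 or values.min() == values.max():
        raise DegenerateHistogramError(
            "degenerate histogram: cannot compute an Otsu threshold on a "
            "constant (or empty) intensity sample"
        )
    return float(threshold_otsu(values))


def segment_fibrotic(gray: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    """Binarize the fibrotic lesion: pixels at or below the first threshold."""
    t = _resolve_threshold(gray, cfg, cfg.fibrotic_threshold, within=None)
    return gray <= t


def segment_ef(
    gray: np.ndarray, fibrotic: np.ndarray, cfg: ThresholdConfig
) -> np.ndarray:
    """Binarize elastic fibers: darker threshold, constrained to the lesion.

    Containment in the fibrotic mask is enforced so the downstream ratio is a
    true fraction.
    """
    if fibrotic.shape != gray.shape:
        raise ValueError("fibrotic mask shape does not match image")
    t = _resolve_threshold(gray, cfg, cfg.ef_threshold, within=fibrotic)
    return (gray <= t) & fibrotic


def ef_score(ef: np.ndarray, fibrotic: np.ndarray) -> EfScoreResult:
    """EF score: percentage of fibrotic-lesion pixels occupied by fiber."""
    if ef.shape != fibrotic.shape:
        raise ValueError("mask shapes differ")
    if np.any(ef & ~fibrotic):
        raise ValueError("ef mask must be contained in the fibrotic mask")
    n_fib = int(fibrotic.sum())
    if n_fib == 0:
        raise EmptyFibroticMaskError("no fibrotic lesion detected; score undefined")
    n_ef = int(ef.sum())
    return EfScoreResult(n_fib, n_ef, 100.0 * n_ef / n_fib)


def score_image(
    image: np.ndarray,
    cfg: ThresholdConfig | None = None,
    weights: Sequence[float] | None = None,
) -> tuple[EfScoreResult, np.ndarray, np.ndarray]:
    """Run the full chain on one RGB field; returns (result, fibrotic, ef)."""
    cfg = cfg or ThresholdConfig()
    gray = to_gray(image, weights)
    fibrotic = segment_fibrotic(gray, cfg)
    ef = segment_ef(gray, fibrotic, cfg)
    return ef_score(ef, fibrotic), fibrotic, ef


def patient_ef_score(
    patient_id: str, results: Iterable[tuple[EfScoreResult, str]]
) -> PatientAggregate:
    """Aggregate per-image results into a per-patient EF score.

    The patient score is the unweighted mean of image-level scores; lobe
    means are computed over that lobe's images only.  Images whose fibrotic
    mask was empty never reach this function (scoring them raises), so every
    entry contributes.
    """
    entries = tuple(results)
    if not entries:
        raise ValueError("need at least one scored image per patient")
    scores = np.array([r.ef_score for r, _ in entries])
    lobes = [lobe for _, lobe in entries]
    lobe_scores = {
        lobe: float(scores[[l == lobe for l in lobes]].mean())
        for lobe in dict.fromkeys(lobes)
    }
    return PatientAggregate(patient_id, entries, float(scores.mean()), lobe_scores)


def load_rgb_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF field as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def score_manifest(
    image_dir: str | Path,
    manifest: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
    weights: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, list[PatientAggregate]]:
    """Score every image listed in a manifest and aggregate per patient.

    ``manifest`` needs columns ``image`` (filename relative to ``image_dir``),
    ``patient_id`` and ``lobe`` ({upper, lower, unspecified}).  Images with an
    empty fibrotic mask are excluded from the patient mean with a warning.
    Returns the per-image score table (columns patient_id, image_id, lobe,
    n_fibrotic, n_ef, ef_score_percent) and the per-patient aggregates.
    """
    cfg = cfg or ThresholdConfig()
    image_dir = Path(image_dir)
    rows = []
    per_patient: dict[str, list[tuple[EfScoreResult, str]]] = {}
    for rec in manifest.itertuples(index=False):
        img = load_rgb_image(image_dir / rec.image)
        lobe = getattr(rec, "lobe", "unspecified") or "unspecified"
        try:
            result, _, _ = score_image(img, cfg, weights)
        except EmptyFibroticMaskError:
            logger.warning(
                "image %s of patient %s has no fibrotic pixels; excluded "
                "from the patient mean",
                rec.image,
                rec.patient_id,
            )
            continue
        per_patient.setdefault(str(rec.patient_id), []).append((result, lobe))
        rows.append(
            {
                "patient_id": rec.patient_id,
                "image_id": rec.image,
                "lobe": lobe,
                "n_fibrotic": result.n_fibrotic_pixels,
                "n_ef": result.n_ef_pixels,
                "ef_score_percent": result.ef_score,
            }
        )
    aggregates = [
        patient_ef_score(pid, entries) for pid, entries in per_patient.items()
    ]
    return pd.DataFrame(rows), aggregates
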