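"""Synthetic EVG-like histology images and two-group cohort tables.

Real elastin-stained sections of fibrotic lung are not publicly deposited, so
every downstream stage of the package is exercised against synthetic data
with pixel-exact ground truth.  ``generate_evg_image`` paints a subpleural
fibrotic blob (collagen color) on a pale background and lays curvilinear dark
fibers inside it until a target elastic-fiber area fraction is reached;
``generate_cohort`` draws two-group clinical tables (truncated normals,
categoricals, exponential survival with independent censoring) with the
distributional structure of a small fibrosis case-control study.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from efscore.config import default_truncation_bounds

__all__ = [
    "SyntheticImageSpec",
    "SyntheticCohortSpec",
    "GroundTruth",
    "EfTargetUnattainableError",
    "generate_evg_image",
    "generate_cohort",
    "write_image_bundle",
    "DEFAULT_CONTINUOUS",
    "DEFAULT_CATEGORICAL",
]

# EVG palette: elastic fibers stain blue-black, collagen red, background pale.
_BACKGROUND = (235, 228, 225)
_COLLAGEN = (186, 96, 110)
_FIBER = (45, 32, 48)

_REC601 = (0.299, 0.587, 0.114)


class EfTargetUnattainableError(RuntimeError):
    """Raised when the requested fiber area fraction cannot be reached."""


def _luminance(rgb: Sequence[float]) -> float:
    return sum(w * c for w, c in zip(_REC601, rgb))


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one synthetic elastin-stained field.

    ``fibrotic_fraction`` is the fraction of the image covered by the
    fibrotic-lesion blob; ``ef_fraction`` the target fraction of fibrotic
    pixels occupied by elastic fiber.  ``fiber_count`` is the fiber budget:
    fibers are added one at a time until the target fraction is reached, and
    exceeding the budget raises :class:`EfTargetUnattainableError`.
    Fiber < collagen < background in luminance, so the two-threshold
    segmentation chain is well posed.
    """

    width: int = 512
    height: int = 512
    fibrotic_fraction: float = 0.5
    ef_fraction: float = 0.285
    fiber_count: int = 50_000
    fiber_thickness: int = 2
    background_color: tuple[int, int, int] = _BACKGROUND
    collagen_color: tuple[int, int, int] = _COLLAGEN
    fiber_color: tuple[int, int, int] = _FIBER
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        if not 0 < self.fibrotic_fraction <= 1:
            raise ValueError("fibrotic_fraction must lie in (0, 1]")
        if not 0 <= self.ef_fraction <= 1:
            raise ValueError("ef_fraction must lie in [0, 1]")
        if self.fiber_count < 0:
            raise ValueError("fiber_count must be >= 0")
        if self.fiber_thickness < 1:
            raise ValueError("fiber_thickness must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lf = _luminance(self.fiber_color)
        lc = _luminance(self.collagen_color)
        lb = _luminance(self.background_color)
        if not lf < lc < lb:
            raise ValueError(
                "colors must be ordered fiber < collagen < background in luminance"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Pixel-exact masks behind a generated image."""

    fibrotic_mask: np.ndarray
    ef_mask: np.ndarray
    realized_ef_fraction: float

    def __post_init__(self) -> None:
        if self.ef_mask.shape != self.fibrotic_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.ef_mask & ~self.fibrotic_mask):
            raise ValueError("ef_mask must be contained in fibrotic_mask")


def _subpleural_region(spec: SyntheticImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Single simply-connected blob adjacent to the bottom image edge.

    The blob is a band whose upper boundary is a smoothed random profile;
    every column touches the bottom edge, so the region is connected and has
    no holes (a stylized subpleural lesion).
    """
    h, w = spec.height, spec.width
    if spec.fibrotic_fraction >= 1.0:
        return np.ones((h, w), dtype=bool)
    target_area = max(w, int(round(spec.fibrotic_fraction * w * h)))
    profile = rng.standard_normal(w + 1)
    # moving-average smoothing; window scales with width
    win = max(3, w // 8)
    kernel = np.ones(win) / win
    smooth = np.convolve(np.concatenate([profile] * 3), kernel, mode="same")[w : 2 * w]
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    base = spec.fibrotic_fraction * h
    depth = base * (1.0 + 0.3 * smooth)
    depth = np.clip(np.round(depth), 1, h).astype(int)
    # one correction pass so the realized area is close to the target
    delta = int(round((target_area - depth.sum()) / w))
    depth = np.clip(depth + delta, 1, h)
    rows = np.arange(h)[:, None]
    return rows >= (h - depth[None, :])


def _disk_offsets(thickness: int) -> np.ndarray:
    r = thickness / 2.0
    span = int(np.ceil(r))
    dy, dx = np.mgrid[-span : span + 1, -span : span + 1]
    keep = dy * dy + dx * dx <= r * r + 1e-9
    return np.stack([dy[keep], dx[keep]], axis=1)


def _draw_fiber(
    spec: SyntheticImageSpec,
    rng: np.random.Generator,
    fibrotic: np.ndarray,
    offsets: np.ndarray,
    n_steps: int,
) -> np.ndarray:
    """Pixels of one random smooth polyline of the given thickness.

    Random walk with bounded turning angle, started at a random fibrotic
    pixel; the footprint is clipped to the fibrotic region by the caller.
    """
    h, w = fibrotic.shape
    fib_idx = np.flatnonzero(fibrotic)
    start = fib_idx[rng.integers(len(fib_idx))]
    y, x = divmod(start, w)
    angle = rng.uniform(0, 2 * np.pi)
    turns = rng.uniform(-0.35, 0.35, size=n_steps)
    ys = np.empty(n_steps + 1)
    xs = np.empty(n_steps + 1)
    ys[0], xs[0] = y, x
    for i in range(n_steps):
        angle += turns[i]
        ys[i + 1] = ys[i] + np.sin(angle)
        xs[i + 1] = xs[i] + np.cos(angle)
    pts = np.stack([np.round(ys), np.round(xs)], axis=1).astype(int)
    thick = pts[:, None, :] + offsets[None, :, :]
    thick = thick.reshape(-1, 2)
    np.clip(thick[:, 0], 0, h - 1, out=thick[:, 0])
    np.clip(thick[:, 1], 0, w - 1, out=thick[:, 1])
    mask = np.zeros((h, w), dtype=bool)
    mask[thick[:, 0], thick[:, 1]] = True
    return mask


def generate_evg_image(spec: SyntheticImageSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate one synthetic EVG-stained field with ground-truth masks.

    Returns an ``(H, W, 3)`` uint8 RGB image and the :class:`GroundTruth`
    carrying the fibrotic and elastic-fiber masks plus the realized fiber
    fraction (recomputed exactly from the emitted masks).  Identical spec and
    seed reproduce the image bit for bit.

    Raises
    ------
    EfTargetUnattainableError
        If the fiber budget is exhausted more than 0.02 below the target
        fraction.
    """
    rng = np.random.default_rng(spec.seed)
    fibrotic = _subpleural_region(spec, rng)
    n_fib = int(fibrotic.sum())

    ef = np.zeros_like(fibrotic)
    if spec.ef_fraction >= 1.0:
        ef = fibrotic.copy()
    elif spec.ef_fraction > 0:
        target_px = int(round(spec.ef_fraction * n_fib))
        tol_px = 0.02 * n_fib
        offsets = _disk_offsets(spec.fiber_thickness)
        n_steps = max(15, min(spec.height, spec.width) // 6)
        drawn = 0
        n_ef = 0
        while n_ef < target_px:
            if drawn >= spec.fiber_count:
                if target_px - n_ef > tol_px:
                    raise EfTargetUnattainableError(
                        f"target fraction unattainable: reached "
                        f"{n_ef / n_fib:.4f} of {spec.ef_fraction:.4f} after "
                        f"{drawn} fibers"
                    )
                break
            fiber = _draw_fiber(spec, rng, fibrotic, offsets, n_steps)
            ef |= fiber & fibrotic
            n_ef = int(ef.sum())
            drawn += 1

    realized = float(ef.sum()) / n_fib
    image = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    image[:] = spec.background_color
    image[fibrotic] = spec.collagen_color
    image[ef] = spec.fiber_color
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)
    return image, GroundTruth(fibrotic, ef, realized)


def write_image_bundle(
    out_dir: str | Path,
    stem: str,
    image: np.ndarray,
    truth: GroundTruth,
    spec: SyntheticImageSpec,
) -> dict[str, Path]:
    """Write image (RGB PNG), masks (0/255 PNG) and a JSON parameter sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{stem}.png",
        "fibrotic_mask": out / f"{stem}_fibrotic_mask.png",
        "ef_mask": out / f"{stem}_ef_mask.png",
        "params": out / f"{stem}_params.json",
    }
    Image.fromarray(image, mode="RGB").save(paths["image"])
    for key, mask in (("fibrotic_mask", truth.fibrotic_mask), ("ef_mask", truth.ef_mask)):
        Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(paths[key])
    params = dataclasses.asdict(spec)
    params["realized_ef_fraction"] = truth.realized_ef_fraction
    paths["params"].write_text(json.dumps(params, indent=2, sort_keys=True))
    return paths


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

# (mean_a, sd_a, mean_b, sd_b) per continuous variable; group A is the small
# fibroelastosis-like group, group B the larger UIP-like group.
DEFAULT_CONTINUOUS: dict[str, tuple[float, float, float, float]] = {
    "age_yr": (69.2, 3.9, 61.4, 9.9),
    "bmi": (17.9, 0.9, 24.3, 2.8),
    "pack_years": (29.3, 33.1, 66.8, 97.4),
    "fvc_pct_pred": (62.7, 10.9, 88.6, 21.9),
    "dlco_pct_pred": (77.9, 13.4, 89.0, 26.1),
    "bal_lymphocytes_pct": (6.0, 4.5, 5.2, 7.0),
    "bal_neutrophils_pct": (2.5, 3.3, 0.6, 0.8),
    "bal_eosinophils_pct": (1.7, 2.0, 0.4, 0.6),
}

# categories, probabilities for group A, probabilities for group B
DEFAULT_CATEGORICAL: dict[str, tuple[tuple[str, ...], tuple[float, ...], tuple[float, ...]]] = {
    "sex": (("male", "female"), (5 / 6, 1 / 6), (26 / 28, 2 / 28)),
    "smoking": (("current", "ex", "never"), (0.0, 0.5, 0.5), (13 / 28, 13 / 28, 2 / 28)),
    "fine_crackles": (("yes", "no"), (0.5, 0.5), (27 / 28, 1 / 28)),
    "pneumothorax": (("yes", "no"), (4 / 6, 2 / 6), (1 / 28, 27 / 28)),
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Two-group cohort generator parameters.

    Continuous variables are truncated normals (bounds from the packaged
    config unless overridden), categoricals are drawn from per-group
    probabilities, EF scores are truncated normals in percent, and survival
    times are exponential with the stated medians under independent
    exponential censoring calibrated to ``censoring_rate``.
    """

    n_group_a: int = 6
    n_group_b: int = 28
    group_a: str = "IPPFE"
    group_b: str = "IPF"
    continuous: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS)
    )
    categorical: Mapping[
        str, tuple[tuple[str, ...], tuple[float, ...], tuple[float, ...]]
    ] = field(default_factory=lambda: dict(DEFAULT_CATEGORICAL))
    ef_mean_a: float = 28.5
    ef_sd_a: float = 3.3
    ef_mean_b: float = 12.1
    ef_sd_b: float = 4.4
    survival_median_a: float = 40.0
    survival_median_b: float = 68.0
    censoring_rate: float = 0.5
    bounds: Mapping[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("need at least 2 patients per group")
        for name, (_, sd_a, _, sd_b) in self.continuous.items():
            if sd_a < 0 or sd_b < 0:
                raise ValueError(f"negative sd for {name}")
        if self.ef_sd_a < 0 or self.ef_sd_b < 0:
            raise ValueError("negative EF score sd")
        for name, (cats, pa, pb) in self.categorical.items():
            for probs in (pa, pb):
                if len(probs) != len(cats):
                    raise ValueError(f"probability length mismatch for {name}")
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ValueError(f"probabilities for {name} must sum to 1")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.survival_median_a <= 0 or self.survival_median_b <= 0:
            raise ValueError("survival medians must be positive")


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    n: int,
    bounds: tuple[float, float] | None,
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    x = rng.normal(mean, sd, size=n)
    if bounds is None:
        return x
    lo, hi = bounds
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a two-group cohort table and its survival table.

    Returns ``(cohort, survival)``: one row per synthetic patient each.  The
    cohort frame carries ``patient_id``, ``group``, every continuous and
    categorical variable, and ``ef_score_pct``; the survival frame carries
    ``time_months`` and the death indicator ``event``.
    """
    rng = np.random.default_rng(spec.seed)
    bounds = dict(default_truncation_bounds())
    if spec.bounds:
        bounds.update(spec.bounds)

    groups = [(spec.group_a, spec.n_group_a), (spec.group_b, spec.n_group_b)]
    rows: dict[str, list] = {"patient_id": [], "group": []}
    pid = 0
    for label, n in groups:
        for _ in range(n):
            pid += 1
            rows["patient_id"].append(f"P{pid:03d}")
            rows["group"].append(label)
    cohort = pd.DataFrame(rows)
    is_a = (cohort["group"] == spec.group_a).to_numpy()

    for name, (ma, sa, mb, sb) in spec.continuous.items():
        col = np.empty(len(cohort))
        col[is_a] = _truncated_normal(rng, ma, sa, spec.n_group_a, bounds.get(name))
        col[~is_a] = _truncated_normal(rng, mb, sb, spec.n_group_b, bounds.get(name))
        cohort[name] = col

    for name, (cats, pa, pb) in spec.categorical.items():
        col = np.empty(len(cohort), dtype=object)
        col[is_a] = rng.choice(cats, size=spec.n_group_a, p=pa)
        col[~is_a] = rng.choice(cats, size=spec.n_group_b, p=pb)
        cohort[name] = col

    ef = np.empty(len(cohort))
    ef_bounds = bounds.get("ef_score_pct", (0.0, 100.0))
    ef[is_a] = _truncated_normal(rng, spec.ef_mean_a, spec.ef_sd_a, spec.n_group_a, ef_bounds)
    ef[~is_a] = _truncated_normal(rng, spec.ef_mean_b, spec.ef_sd_b, spec.n_group_b, ef_bounds)
    cohort["ef_score_pct"] = ef

    scale = np.where(is_a, spec.survival_median_a, spec.survival_median_b) / np.log(2)
    event_time = rng.exponential(scale)
    if spec.censoring_rate > 0:
        # independent exponential censoring: P(C < T) = rc/(rc+rt)
        cens_scale = scale * (1 - spec.censoring_rate) / spec.censoring_rate
        cens_time = rng.exponential(cens_scale)
    else:
        cens_time = np.full(len(cohort), np.inf)
    time = np.minimum(event_time, cens_time)
    survival = pd.DataFrame(
        {
            "patient_id": cohort["patient_id"],
            "group": cohort["group"],
            "time_months": time,
            "event": event_time <= cens_time,
        }
    )
    return cohort, survival
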