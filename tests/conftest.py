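import numpy as np
import pytest

from efscore.efquant import ThresholdConfig
from efscore.synthdata import SyntheticImageSpec, generate_evg_image

REC601 = (0.299, 0.587, 0.114)


def luminance(rgb):
    return sum(w * c for w, c in zip(REC601, rgb))


def midway_thresholds(spec: SyntheticImageSpec) -> ThresholdConfig:
    """Fixed thresholds halfway between the generator's three color luminances."""
    lf = luminance(spec.fiber_color)
    lc = luminance(spec.collagen_color)
    lb = luminance(spec.background_color)
    return ThresholdConfig(
        mode="fixed",
        fibrotic_threshold=int((lc + lb) / 2),
        ef_threshold=int((lf + lc) / 2),
    )


@pytest.fixture(scope="session")
def noiseless_field():
    """A noise-free synthetic field whose masks the chain must recover exactly."""
    spec = SyntheticImageSpec(
        width=256, height=256, fibrotic_fraction=0.5, ef_fraction=0.2,
        noise_sd=0.0, seed=3,
    )
    image, truth = generate_evg_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noisy_field():
    """A synthetic field at the default noise level (sd 8)."""
    spec = SyntheticImageSpec(
        width=256, height=256, fibrotic_fraction=0.5, ef_fraction=0.285,
        noise_sd=8.0, seed=5,
    )
    image, truth = generate_evg_image(spec)
    return spec, image, truth
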