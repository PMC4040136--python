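"""Packaged defaults (truncation bounds, grayscale weights, rounding rules)."""

from __future__ import annotations

import functools
from importlib import resources
from typing import Any

import yaml


@functools.lru_cache(maxsize=1)
def load_defaults() -> dict[str, Any]:
    """Load the packaged default configuration."""
    text = resources.files("efscore").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def default_truncation_bounds() -> dict[str, tuple[float, float]]:
    raw = load_defaults()["truncation_bounds"]
    return {k: (float(lo), float(hi)) for k, (lo, hi) in raw.items()}


def default_grayscale_weights() -> tuple[float, float, float]:
    r, g, b = load_defaults()["grayscale_weights"]
    return (float(r), float(g), float(b))
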