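"""Shared fixtures and scene-construction helpers."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from dirtcore.imagefmt import RootImage
from dirtcore.pipeline import PipelineConfig
from dirtcore.segmentation import BinaryMask, classify_components, label_components


def image_from_mask(mask: np.ndarray, fg: float = 0.9) -> RootImage:
    return RootImage(pixels=np.where(mask, fg, 0.0), source_id="synthetic")


def scene_from_mask(mask: np.ndarray, config: PipelineConfig | None = None):
    """Label and classify a boolean mask directly (no threshold/opening)."""
    mask = np.asarray(mask, dtype=bool)
    img = image_from_mask(mask)
    comps = label_components(BinaryMask(mask=mask, threshold_used=0.5))
    return classify_components(comps, img, config or PipelineConfig())


def random_blob(rng: np.random.Generator, shape=(64, 64), smooth=3.0, quantile=0.8) -> np.ndarray:
    """A random smooth blob mask; guaranteed non-empty."""
    noise = ndimage.gaussian_filter(rng.random(shape), smooth)
    mask = noise > np.quantile(noise, quantile)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return PipelineConfig()
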