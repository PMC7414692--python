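"""Exposure standardization of raw micrographs.

Micrographs of the same specimen type arrive under widely varying exposure;
the regression features must see a stable intensity distribution. The chain
here is median-filter denoising, then contrast-limited adaptive histogram
equalization (CLAHE), then an optional gamma correction. CLAHE equalizes
intensities tile-by-tile with a clip on histogram peaks, which brings under-
and well-exposed images of the same tissue to nearly the same local contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import exposure

from .io import AnnotatedImage

# Rec. 709 luminance weights.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the standardization chain.

    Attributes
    ----------
    clahe_clip : float
        CLAHE clip limit, normalized to [0, 1] as in
        :func:`skimage.exposure.equalize_adapthist`; higher gives more
        contrast.
    clahe_tile : int
        CLAHE tile edge in pixels (>= 2).
    median_radius : int
        Radius of the square median-filter footprint, in pixels.
    gamma : float
        Gamma correction exponent applied last; 1.0 disables it.
    """

    clahe_clip: float = 0.01
    clahe_tile: int = 16
    median_radius: int = 2
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.clahe_clip <= 0 or self.median_radius <= 0 or self.gamma <= 0:
            raise ValueError("all preprocessing parameters must be strictly positive")
        if self.clahe_tile < 2:
            raise ValueError("clahe_tile must be >= 2")


def to_grayscale(image: AnnotatedImage) -> AnnotatedImage:
    """Convert an RGB image to grayscale by Rec. 709 luminance.

    Already-gray inputs pass through unchanged; annotations are carried
    through untouched.
    """
    if image.n_channels == 1:
        return image
    if image.n_channels != 3:
        raise ValueError(f"expected 1 or 3 channels, got {image.n_channels}")
    gray = image.pixels @ _LUMA
    return AnnotatedImage(pixels=gray, annotations=list(image.annotations), id=image.id)


def standardize(image: AnnotatedImage, cfg: PreprocessConfig | None = None) -> AnnotatedImage:
    """Denoise and contrast-standardize a grayscale image.

    Median filter (square footprint of radius ``cfg.median_radius``), then
    CLAHE (tile ``cfg.clahe_tile``, clip ``cfg.clahe_clip``), then gamma.
    Output is in [0, 1]; annotations are unchanged; the chain is
    deterministic. A perfectly flat image skips CLAHE (equalizing a flat
    field is undefined) and passes through unchanged.
    """
    cfg = cfg or PreprocessConfig()
    if image.n_channels != 1:
        raise ValueError("standardize expects a single-channel image; run to_grayscale first")
    if min(image.height, image.width) < cfg.clahe_tile:
        raise ValueError(
            f"image {image.height}x{image.width} smaller than one CLAHE tile "
            f"({cfg.clahe_tile} px); use a smaller clahe_tile"
        )
    arr = ndimage.median_filter(
        image.pixels, size=2 * cfg.median_radius + 1, mode="reflect"
    )
    if np.ptp(arr) > 1e-12:
        arr = exposure.equalize_adapthist(
            np.clip(arr, 0.0, 1.0),
            kernel_size=cfg.clahe_tile,
            clip_limit=cfg.clahe_clip,
        )
    if cfg.gamma != 1.0:
        arr = np.power(arr, cfg.gamma)
    arr = np.clip(arr, 0.0, 1.0)
    return AnnotatedImage(pixels=arr, annotations=list(image.annotations), id=image.id)


def preprocess(image: AnnotatedImage, cfg: PreprocessConfig | None = None) -> AnnotatedImage:
    """Full chain: grayscale conversion followed by :func:`standardize`.

    Applied identically at train and predict time so the feature
    distribution matches.
    """
    return standardize(to_grayscale(image), cfg)


def config_from_dict(d: dict) -> PreprocessConfig:
    """Build a config from a ``preprocess:`` config block."""
    return replace(PreprocessConfig(), **d)
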