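"""Dense upright SIFT descriptors, one per pixel.

Each pixel of a preprocessed grayscale image is described by the canonical
128-dimensional SIFT descriptor of the square patch centered on it: image
gradients by central differences, gradient magnitudes Gaussian-weighted
(sigma = patch_size / 2) and accumulated into a 4x4 grid of spatial bins x 8
orientation bins with bilinear spatial and linear (circular) orientation
interpolation, then L2-normalized, clamped at 0.2 and renormalized.

The descriptor is "upright": no keypoint detection, no scale selection, no
dominant-orientation assignment. Rotation invariance would discard the
boundary-orientation signal that distinguishes cell edges from interiors,
and scale is fixed by the patch size. The image is mirror-reflected at its
borders so edge pixels get full patches and the feature count equals the
pixel count exactly.

The descriptor of every pixel is computed simultaneously: accumulating
orientation-binned gradient magnitude into one spatial bin is a correlation
of the orientation map with a separable (triangular-weight x Gaussian)
kernel, so the whole map costs 8 x 4 row filters plus 32 x 4 column filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

N_ORIENT = 8
N_SPATIAL = 4  # 4x4 grid
DESCRIPTOR_DIM = N_SPATIAL * N_SPATIAL * N_ORIENT  # 128
CLAMP = 0.2

from .io import AnnotatedImage


@dataclass
class FeatureMap:
    """Per-pixel descriptor array of shape ``(H, W, 128)`` (float32)."""

    descriptors: np.ndarray
    patch_size: int

    def __post_init__(self) -> None:
        if self.descriptors.ndim != 3 or self.descriptors.shape[2] != DESCRIPTOR_DIM:
            raise ValueError(
                f"descriptors must be (H, W, {DESCRIPTOR_DIM}), got {self.descriptors.shape}"
            )

    @property
    def height(self) -> int:
        return self.descriptors.shape[0]

    @property
    def width(self) -> int:
        return self.descriptors.shape[1]


def _bin_kernels(patch_size: int) -> np.ndarray:
    """1-D kernels combining the triangular bin weight with the Gaussian.

    Returns shape ``(4, patch_size)``: kernel ``i`` at tap ``k`` weights the
    pixel at offset ``d = k - patch_size/2`` for spatial bin ``i`` whose
    center sits at ``(i - 1.5) * patch_size/4`` from the patch center.
    """
    half = patch_size // 2
    bin_width = patch_size / N_SPATIAL
    sigma = patch_size / 2.0
    d = np.arange(-half, half)  # offsets covered by the patch
    gauss = np.exp(-(d.astype(np.float64) ** 2) / (2.0 * sigma**2))
    kernels = np.empty((N_SPATIAL, patch_size))
    for i in range(N_SPATIAL):
        center = (i - (N_SPATIAL - 1) / 2.0) * bin_width
        tri = np.maximum(0.0, 1.0 - np.abs(d - center) / bin_width)
        # the isotropic Gaussian factorizes per axis, so each 1-D kernel
        # carries the full 1-D marginal
        kernels[i] = tri * gauss
    return kernels


def _orientation_maps(padded: np.ndarray) -> np.ndarray:
    """Gradient magnitude linearly distributed over 8 orientation bins.

    Gradients by central differences; the angle ``atan2(gy, gx)`` (mod 2pi)
    is split between its two neighboring bins of width pi/4.
    """
    gy, gx = np.gradient(padded)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), 2.0 * np.pi)
    t = ang / (2.0 * np.pi / N_ORIENT)
    b0 = np.floor(t).astype(np.intp) % N_ORIENT
    frac = t - np.floor(t)
    maps = np.zeros((N_ORIENT,) + padded.shape)
    rows, cols = np.indices(padded.shape)
    np.add.at(maps, (b0, rows, cols), mag * (1.0 - frac))
    np.add.at(maps, ((b0 + 1) % N_ORIENT, rows, cols), mag * frac)
    return maps


def dense_sift(image: AnnotatedImage, patch_size: int = 16) -> FeatureMap:
    """Compute one upright SIFT descriptor per pixel.

    Parameters
    ----------
    image : AnnotatedImage
        Single-channel preprocessed image.
    patch_size : int
        Side of the square descriptor support, divisible by 4 and smaller
        than the image's shorter side. Default 16 px.

    Returns
    -------
    FeatureMap
        ``(H, W, 128)`` float32 array; descriptor layout is
        ``(row bin, column bin, orientation)`` flattened. All-zero-gradient
        patches (e.g. in a constant image) yield the zero descriptor.
    """
    if image.n_channels != 1:
        raise ValueError("dense_sift expects a single-channel image")
    if patch_size % 4 != 0:
        raise ValueError(f"patch_size must be divisible by 4, got {patch_size}")
    h, w = image.height, image.width
    if patch_size >= min(h, w):
        raise ValueError(
            f"patch_size {patch_size} must be smaller than min image side {min(h, w)}"
        )
    half = patch_size // 2
    pad = half + 1  # +1 so every patch pixel has a central-difference gradient
    padded = np.pad(image.pixels, pad, mode="reflect")
    omaps = _orientation_maps(padded)
    kernels = _bin_kernels(patch_size)

    # Correlate1d with a length-patch_size kernel centers it at tap half,
    # i.e. tap k addresses offset k - half in [-half, half): exactly the patch.
    desc = np.empty((N_SPATIAL, N_SPATIAL, N_ORIENT, h, w))
    for o in range(N_ORIENT):
        for i in range(N_SPATIAL):
            rowpass = ndimage.correlate1d(omaps[o], kernels[i], axis=0, mode="constant")
            for j in range(N_SPATIAL):
                full = ndimage.correlate1d(rowpass, kernels[j], axis=1, mode="constant")
                desc[i, j, o] = full[pad : pad + h, pad : pad + w]
    desc = desc.reshape(DESCRIPTOR_DIM, h, w).transpose(1, 2, 0)

    norms = np.linalg.norm(desc, axis=2, keepdims=True)
    nonzero = norms > 1e-12
    desc = np.where(nonzero, desc / np.where(nonzero, norms, 1.0), 0.0)
    desc = np.minimum(desc, CLAMP)
    norms = np.linalg.norm(desc, axis=2, keepdims=True)
    nonzero = norms > 1e-12
    desc = np.where(nonzero, desc / np.where(nonzero, norms, 1.0), 0.0)
    return FeatureMap(descriptors=desc.astype(np.float32), patch_size=patch_size)


def flatten_features(fm: FeatureMap) -> np.ndarray:
    """Flatten to ``(H * W, 128)`` in row-major pixel order.

    Row ``k`` is the descriptor of pixel ``(k // W, k % W)``; invertible by
    :func:`unflatten_features` given the image shape.
    """
    return fm.descriptors.reshape(-1, DESCRIPTOR_DIM)


def unflatten_features(mat: np.ndarray, height: int, width: int, patch_size: int) -> FeatureMap:
    """Inverse of :func:`flatten_features`."""
    if mat.shape != (height * width, DESCRIPTOR_DIM):
        raise ValueError(f"matrix shape {mat.shape} does not match {height}x{width}")
    return FeatureMap(
        descriptors=np.asarray(mat).reshape(height, width, DESCRIPTOR_DIM),
        patch_size=patch_size,
    )


def descriptors_at(fm: FeatureMap, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Gather descriptors at pixel positions ``(rows, cols)`` as ``(n, 128)``."""
    return fm.descriptors[np.asarray(rows), np.asarray(cols)]
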