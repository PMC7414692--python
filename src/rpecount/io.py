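"""Image, annotation, and density-map I/O.

Coordinate convention used throughout the package: 0-based, ``x`` is the
column index, ``y`` the row index, origin at the top-left, so an annotation
``(x, y)`` addresses ``pixels[y, x]``.

Formats: images are PNG or TIFF (8/16-bit, grayscale or RGB), intensities
rescaled to [0, 1] on read; annotations are CSV files with header ``x,y``,
one cell center per row; density maps are single-channel 32-bit float TIFF.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


class FormatError(ValueError):
    """Raised for unreadable or unsupported image/annotation files."""


@dataclass
class AnnotatedImage:
    """A micrograph with (possibly empty) point annotations of cell centers.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` grayscale or ``(H, W, 3)`` RGB array, float in [0, 1].
    annotations : list of (int, int)
        Ordered ``(x, y)`` cell centers; duplicates allowed. The length of
        this list is the ground-truth cell count for the image.
    id : str
        Identifier used in reports.
    """

    pixels: np.ndarray
    annotations: list[tuple[int, int]] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or 3-D, got shape {self.pixels.shape}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError(f"3-D pixels must have 3 channels, got {self.pixels.shape[2]}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        self.annotations = [(int(x), int(y)) for x, y in self.annotations]
        h, w = self.pixels.shape[:2]
        for x, y in self.annotations:
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(
                    f"annotation ({x}, {y}) outside image of width {w}, height {h}"
                )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def count(self) -> int:
        """Ground-truth cell count: the number of annotations."""
        return len(self.annotations)


@dataclass
class DensityMap:
    """Nonnegative scalar field (cells per pixel) whose integral is the count."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"density map must be 2-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")

    @property
    def total(self) -> float:
        """Integral of the density: the (real-valued) cell count."""
        return float(self.values.sum())


def read_image(path: str | Path) -> AnnotatedImage:
    """Read a PNG or TIFF micrograph; intensities rescaled to [0, 1].

    Rescaling divides by the dtype maximum (255 or 65535); RGB stays
    3-channel (grayscale conversion is :func:`rpecount.preprocess.to_grayscale`'s
    job). Annotations are left empty.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        raise FormatError(
            f"unsupported bit depth {arr.dtype} in {path}; expected 8- or 16-bit"
        )
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        raise FormatError(f"unsupported channel layout {arr.shape} in {path}")
    return AnnotatedImage(pixels=arr.astype(np.float64) / scale, id=path.stem)


def write_image(image: AnnotatedImage, path: str | Path) -> None:
    """Write pixels as 16-bit PNG or TIFF (rounded from the [0, 1] floats)."""
    path = Path(path)
    arr = np.clip(image.pixels, 0.0, 1.0)
    arr16 = np.round(arr * 65535.0).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr16)
    else:
        iio.imwrite(path, arr16)


def read_annotations(path: str | Path) -> list[tuple[int, int]]:
    """Read cell centers from a CSV with header ``x,y``.

    Order and duplicates are preserved (two cells may share a rounded
    center). Negative or non-numeric coordinates raise with the row number.
    """
    path = Path(path)
    points: list[tuple[int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip().lower() for c in header[:2]] != ["x", "y"]:
            raise FormatError(f"{path}: expected CSV header 'x,y', got {header}")
        for i, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                x, y = int(float(row[0])), int(float(row[1]))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: non-numeric coordinates on row {i}") from exc
            if x < 0 or y < 0:
                raise FormatError(f"{path}: negative coordinate on row {i}")
            points.append((x, y))
    return points


def write_annotations(points: list[tuple[int, int]], path: str | Path) -> None:
    """Write cell centers as CSV with header ``x,y``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for x, y in points:
            writer.writerow([int(x), int(y)])


def read_density(path: str | Path) -> DensityMap:
    """Read a density map from a float32 TIFF."""
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read density file {path}: {exc}") from exc
    return DensityMap(values=np.asarray(arr, dtype=np.float64))


def write_density(density: DensityMap, path: str | Path) -> None:
    """Write a density map as single-channel float32 TIFF.

    Read-back reproduces values to float32 precision; the nonnegativity
    invariant is enforced before writing (by :class:`DensityMap`).
    """
    if np.any(density.values < 0):  # defensive; DensityMap already enforces
        raise ValueError("density values must be nonnegative")
    tifffile.imwrite(Path(path), density.values.astype(np.float32))
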