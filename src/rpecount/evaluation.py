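"""Dataset splitting, crop augmentation, and counting-accuracy metrics.

The headline metric is the average error rate over M test images,

    AER = (1/M) * sum_t |F_t - s_t| / s_t * 100%,

where ``F_t`` is the model's (real-valued) count and ``s_t`` the annotated
ground truth, with accuracy ACC = 100% - AER. The spread is reported as the
population standard deviation of the per-image relative errors (x100), and
the conventional "95% CI" half-width as twice that std; a t-based CI of the
mean error is reported alongside under its own name, since +/- 2 std of
per-image errors is a dispersion band, not a standard CI of the mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotatedImage
from .models import CountModel, count
from .preprocess import PreprocessConfig


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test division.

    ``round_side`` selects which side the floor applies to: ``"test"``
    (test = floor(test_fraction * n), the 70/30 convention) or ``"train"``
    (train = floor((1 - test_fraction) * n), which for a 90/10 split of 85
    images yields 76 train / 9 test).
    """

    test_fraction: float
    seed: int = 0
    round_side: str = "test"

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.round_side not in ("test", "train"):
            raise ValueError("round_side must be 'test' or 'train'")


@dataclass
class EvalReport:
    """Per-image counts and the aggregate metrics, all in percent."""

    per_image: list[tuple[str, float, int, float]]  # (id, F, s*, rel err)
    aer: float
    acc: float
    std: float
    ci_halfwidth: float  # 2 * std, the dispersion band used in reporting
    ci_mean_t_halfwidth: float  # t-based 95% CI of the mean error
    M: int
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_image, columns=["id", "estimated", "true", "rel_error"]
        )

    def summary(self) -> dict:
        return {
            "M": self.M,
            "aer_percent": self.aer,
            "acc_percent": self.acc,
            "std_percent": self.std,
            "ci95_halfwidth_percent": self.ci_halfwidth,
            "ci95_mean_t_halfwidth_percent": self.ci_mean_t_halfwidth,
            **self.extra,
        }

    def save(self, csv_path: str | Path, json_path: str | Path) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def report_from_counts(
    ids: list[str], estimated: list[float], true: list[int]
) -> EvalReport:
    """Build the metric report from already-computed counts.

    Every ground-truth count must be positive (the relative error divides
    by it).
    """
    if not ids:
        raise ValueError("empty test set")
    if any(s <= 0 for s in true):
        raise ValueError(
            "every test image needs >= 1 annotation: the relative error divides by s*"
        )
    rel = np.abs(np.asarray(estimated, dtype=np.float64) - np.asarray(true)) / np.asarray(
        true, dtype=np.float64
    )
    aer = float(rel.mean() * 100.0)
    std = float(rel.std(ddof=0) * 100.0)  # population std
    m = len(ids)
    if m >= 2:
        sem = rel.std(ddof=1) / math.sqrt(m)
        t_half = float(stats.t.ppf(0.975, m - 1) * sem * 100.0)
    else:
        t_half = float("nan")
    return EvalReport(
        per_image=[(i, float(f), int(s), float(r)) for i, f, s, r in zip(ids, estimated, true, rel)],
        aer=aer,
        acc=100.0 - aer,
        std=std,
        ci_halfwidth=2.0 * std,
        ci_mean_t_halfwidth=t_half,
        M=m,
    )


def evaluate(
    model: CountModel,
    test_set: list[AnnotatedImage],
    preprocess_cfg: PreprocessConfig | None = None,
    patch_size: int | None = None,
) -> EvalReport:
    """Run the full counting pipeline on each test image and score it."""
    ids, est, true = [], [], []
    for img in test_set:
        if img.count == 0:
            raise ValueError(
                f"test image {img.id!r} has 0 annotations; AER divides by the true count"
            )
        ids.append(img.id)
        est.append(count(model, img, preprocess_cfg, patch_size))
        true.append(img.count)
    return report_from_counts(ids, est, true)


def split(
    dataset: list[AnnotatedImage], spec: SplitSpec
) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    """Random, disjoint, exhaustive train/test partition (seeded)."""
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 images to split")
    if spec.round_side == "test":
        n_test = math.floor(spec.test_fraction * n)
    else:
        n_test = n - math.floor((1.0 - spec.test_fraction) * n)
    if n_test == 0 or n_test == n:
        raise ValueError(f"split of {n} images at {spec.test_fraction} leaves one side empty")
    order = np.random.default_rng(spec.seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [dataset[i] for i in range(n) if i not in test_idx]
    test = [dataset[i] for i in range(n) if i in test_idx]
    return train, test


def augment_by_cropping(
    dataset: list[AnnotatedImage],
    min_cells: int,
    n_crops: int = 15,
    crop_fraction: float = 0.5,
    seed: int = 0,
    min_size: int = 16,
) -> list[AnnotatedImage]:
    """Enlarge a dataset with random sub-images of cell-rich originals.

    Each image with strictly more than ``min_cells`` annotations contributes
    ``n_crops`` crops of size ``(crop_fraction*H, crop_fraction*W)`` at
    uniformly random positions (crops may overlap). A crop inherits the
    annotations whose centers fall inside its window, re-indexed to crop
    coordinates. Originals are retained first, in order.
    """
    if not 0.0 < crop_fraction < 1.0:
        raise ValueError("crop_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = list(dataset)
    for img in dataset:
        if img.count <= min_cells:
            continue
        ch = int(crop_fraction * img.height)
        cw = int(crop_fraction * img.width)
        if min(ch, cw) < min_size:
            raise ValueError(
                f"crop {ch}x{cw} smaller than the feature patch size {min_size}"
            )
        for k in range(n_crops):
            top = int(rng.integers(0, img.height - ch + 1))
            left = int(rng.integers(0, img.width - cw + 1))
            pts = [
                (x - left, y - top)
                for x, y in img.annotations
                if left <= x < left + cw and top <= y < top + ch
            ]
            out.append(
                AnnotatedImage(
                    pixels=img.pixels[top : top + ch, left : left + cw].copy(),
                    annotations=pts,
                    id=f"{img.id}_crop{k}",
                )
            )
    return out
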