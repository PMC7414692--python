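"""End-to-end orchestration: images -> features + labels -> trained model.

This is the glue the CLI and the experiments share: it applies the
preprocessing chain, extracts dense SIFT, builds Gaussian-mixture labels
(resolving ``sigma="auto"`` against the training annotations once), trains
the requested model kind, and embeds the full pipeline configuration in the
model so that :func:`rpecount.models.count` is self-contained.
"""

from __future__ import annotations

from dataclasses import asdict

from .density import KernelSpec, auto_sigma, make_density
from .features import dense_sift
from .io import AnnotatedImage
from .models import (
    CountModel,
    MLPSpec,
    TrainConfig,
    train_lrr,
    train_mlp,
)
from .preprocess import PreprocessConfig, preprocess


def resolve_sigma(
    images: list[AnnotatedImage], sigma: float | str, factor: float = 0.25
) -> float:
    """Resolve ``"auto"`` to the data-driven kernel width, else pass through."""
    if sigma == "auto":
        return auto_sigma(images, factor=factor)
    return float(sigma)


def build_training_set(
    images: list[AnnotatedImage],
    preprocess_cfg: PreprocessConfig,
    patch_size: int,
    kernel: KernelSpec,
):
    """Per image: preprocessed dense-SIFT features paired with density labels."""
    pairs = []
    for img in images:
        prepped = preprocess(img, preprocess_cfg)
        fm = dense_sift(prepped, patch_size=patch_size)
        dm = make_density(img, kernel)
        pairs.append((fm, dm))
    return pairs


def train_pipeline(
    images: list[AnnotatedImage],
    kind: str = "mlp",
    preprocess_cfg: PreprocessConfig | None = None,
    patch_size: int = 16,
    sigma: float | str = "auto",
    truncate: float = 3.0,
    mlp_spec: MLPSpec | None = None,
    train_cfg: TrainConfig | None = None,
) -> CountModel:
    """Train a counting model of the given kind on annotated images.

    Returns a model whose ``meta`` records the preprocessing, feature and
    kernel configuration, so predictions on raw images need no extra
    arguments.
    """
    if kind not in ("mlp", "lrr"):
        raise ValueError(f"unknown model kind {kind!r}")
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    train_cfg = train_cfg or TrainConfig()
    sigma_val = resolve_sigma(images, sigma)
    kernel = KernelSpec(sigma=sigma_val, truncate=truncate)
    pairs = build_training_set(images, preprocess_cfg, patch_size, kernel)
    if kind == "mlp":
        model = train_mlp(pairs, mlp_spec, train_cfg)
    else:
        model = train_lrr(pairs, train_cfg)
    model.meta.update(
        {
            "preprocess": asdict(preprocess_cfg),
            "patch_size": patch_size,
            "sigma": sigma_val,
            "truncate": truncate,
        }
    )
    return model
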