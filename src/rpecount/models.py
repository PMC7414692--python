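"""Regressors from SIFT descriptors to density values.

Two model kinds share one interface:

* ``mlp`` — a fully connected network (default two hidden layers of 2000
  rectified-linear units, linear output) trained by mini-batch stochastic
  gradient descent with momentum on the mean squared error between predicted
  and target per-pixel density values. This is the primary model.
* ``lrr`` — linear ridge regression, the closed-form baseline: it solves
  ``min_w sum_j (w.f_j + b - s_j)^2 + lambda ||w||^2`` (intercept
  unpenalized) over the same sampled training pixels.

Training pixels are subsampled per image: most pixels of a micrograph carry
near-zero density, so each image contributes ``pixels_per_image`` samples of
which a configurable fraction is drawn from within the kernel support of an
annotation. Targets are multiplied by ``density_scale`` during training
(raw densities are O(1e-2) and their gradients stall SGD); predictions are
divided back, and negative outputs are clipped to zero since a density is
physically nonnegative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import Ridge

from .density import DensityMap
from .features import DESCRIPTOR_DIM, FeatureMap, dense_sift, flatten_features
from .io import AnnotatedImage
from .preprocess import PreprocessConfig, preprocess

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLPSpec:
    """Architecture: ReLU hidden layers, linear scalar output."""

    hidden_sizes: tuple[int, ...] = (2000, 2000)
    input_dim: int = DESCRIPTOR_DIM
    output_dim: int = 1

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) < 1 or any(s <= 0 for s in self.hidden_sizes):
            raise ValueError("hidden_sizes must be a nonempty list of positive ints")


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and sampling hyperparameters (shared by both model kinds)."""

    learning_rate: float = 3e-3
    batch_size: int = 512
    epochs: int = 50
    seed: int = 0
    pixels_per_image: int = 4096
    foreground_fraction: float = 0.5
    ridge_lambda: float = 1.0
    momentum: float = 0.9
    density_scale: float = 100.0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs, self.pixels_per_image) <= 0:
            raise ValueError("learning_rate, batch_size, epochs, pixels_per_image must be positive")
        if not 0.0 <= self.foreground_fraction <= 1.0:
            raise ValueError("foreground_fraction must be in [0, 1]")
        if self.ridge_lambda < 0 or self.density_scale <= 0:
            raise ValueError("ridge_lambda must be >= 0 and density_scale > 0")


@dataclass
class CountModel:
    """A trained descriptor-to-density regressor.

    ``params`` holds ``weights``/``biases`` lists for an MLP, or ``w``/``b``
    for ridge. ``density_scale`` records the target multiplier used in
    training so prediction can undo it. ``meta`` carries provenance (seed,
    loss history) plus the preprocessing/feature/kernel configuration needed
    to make :func:`count` self-contained.
    """

    kind: str
    params: dict
    density_scale: float
    spec: MLPSpec | None = None
    ridge_lambda: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        if self.kind == "mlp":
            return self.params["weights"][0].shape[0]
        return self.params["w"].shape[0]


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over sampled pixels — the training objective."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    target = np.asarray(target, dtype=np.float64).ravel()
    return float(np.mean((pred - target) ** 2))


def sample_pixels(
    fm: FeatureMap, dm: DensityMap, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``pixels_per_image`` (descriptor, raw density) training pairs.

    Foreground pixels (density > 0, i.e. within the kernel support of an
    annotation) are sampled at ``foreground_fraction``; the remainder is
    drawn from the background. No pool is ever sampled beyond its size
    (duplicating the handful of empty pixels of a confluent monolayer would
    bias the regression toward zero); a shortfall on one side is given to
    the other, so exactly ``pixels_per_image`` unique pixels are returned
    whenever the image has that many.
    """
    if fm.descriptors.shape[:2] != dm.values.shape:
        raise ValueError("feature map and density map shapes differ")
    flat_d = dm.values.ravel()
    fg = np.flatnonzero(flat_d > 1e-12)
    bg = np.flatnonzero(flat_d <= 1e-12)
    n = min(cfg.pixels_per_image, flat_d.size)
    n_fg = min(int(round(n * cfg.foreground_fraction)), fg.size)
    n_bg = min(n - n_fg, bg.size)
    n_fg = min(n - n_bg, fg.size)  # hand any background shortfall back
    idx_parts = []
    if n_fg:
        idx_parts.append(rng.choice(fg, size=n_fg, replace=False))
    if n_bg:
        idx_parts.append(rng.choice(bg, size=n_bg, replace=False))
    idx = np.concatenate(idx_parts)
    X = flatten_features(fm)[idx].astype(np.float64)
    y = flat_d[idx]
    return X, y


def _assemble(
    train_set: list[tuple[FeatureMap, DensityMap]], cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    if not train_set:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    xs, ys = [], []
    for fm, dm in train_set:
        X, y = sample_pixels(fm, dm, cfg, rng)
        xs.append(X)
        ys.append(y)
    return np.vstack(xs), np.concatenate(ys)


def _init_mlp(spec: MLPSpec, rng: np.random.Generator) -> dict:
    """He-style scaled-uniform initialization for ReLU layers."""
    sizes = [spec.input_dim, *spec.hidden_sizes, spec.output_dim]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return {"weights": weights, "biases": biases}


def _forward_mlp(params: dict, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass; returns scalar outputs and per-layer activations."""
    acts = [X]
    a = X
    n_layers = len(params["weights"])
    for i, (W, b) in enumerate(zip(params["weights"], params["biases"])):
        z = a @ W + b
        a = z if i == n_layers - 1 else np.maximum(z, 0.0)  # linear output layer
        acts.append(a)
    return a[:, 0], acts


def forward_raw(model: CountModel, X: np.ndarray) -> np.ndarray:
    """Raw (scaled, unclipped) model outputs for descriptor rows ``X``."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.input_dim:
        raise ValueError(f"descriptor dim {X.shape[1]} != model input dim {model.input_dim}")
    if model.kind == "mlp":
        out, _ = _forward_mlp(model.params, X)
        return out
    return X @ model.params["w"] + model.params["b"]


def train_mlp(
    train_set: list[tuple[FeatureMap, DensityMap]],
    spec: MLPSpec | None = None,
    cfg: TrainConfig | None = None,
) -> CountModel:
    """Train the MLP by SGD with momentum on sampled pixels.

    Reproducible given ``cfg.seed`` (initialization, pixel sampling, and
    batch shuffling all derive from it). The per-epoch mean loss is recorded
    in ``meta['loss_history']``; a NaN loss aborts with the offending epoch.
    """
    spec = spec or MLPSpec()
    cfg = cfg or TrainConfig()
    X, y_raw = _assemble(train_set, cfg)
    y = y_raw * cfg.density_scale
    rng = np.random.default_rng(cfg.seed + 1)
    params = _init_mlp(spec, rng)
    velocity = {
        "weights": [np.zeros_like(W) for W in params["weights"]],
        "biases": [np.zeros_like(b) for b in params["biases"]],
    }
    n = X.shape[0]
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = X[sel], y[sel]
            out, acts = _forward_mlp(params, xb)
            err = out - yb
            epoch_losses.append(float(np.mean(err**2)))
            # backprop of mean squared error
            grad = (2.0 / xb.shape[0]) * err[:, None]
            for i in range(len(params["weights"]) - 1, -1, -1):
                a_prev = acts[i]
                gW = a_prev.T @ grad
                gb = grad.sum(axis=0)
                if i > 0:
                    grad = (grad @ params["weights"][i].T) * (acts[i] > 0)
                velocity["weights"][i] = (
                    cfg.momentum * velocity["weights"][i] - cfg.learning_rate * gW
                )
                velocity["biases"][i] = (
                    cfg.momentum * velocity["biases"][i] - cfg.learning_rate * gb
                )
                params["weights"][i] += velocity["weights"][i]
                params["biases"][i] += velocity["biases"][i]
        mean_loss = float(np.mean(epoch_losses))
        if not np.isfinite(mean_loss):
            raise RuntimeError(
                f"training diverged: non-finite loss at epoch {epoch + 1}; "
                "reduce learning_rate"
            )
        history.append(mean_loss)
        log.info("epoch %d/%d: loss %.6f", epoch + 1, cfg.epochs, mean_loss)
    return CountModel(
        kind="mlp",
        params=params,
        density_scale=cfg.density_scale,
        spec=spec,
        meta={"seed": cfg.seed, "loss_history": history, "final_loss": history[-1],
              "train_config": asdict(cfg)},
    )


def train_lrr(
    train_set: list[tuple[FeatureMap, DensityMap]],
    cfg: TrainConfig | None = None,
) -> CountModel:
    """Fit the linear-ridge-regression baseline in closed form.

    The intercept is unpenalized. With ``ridge_lambda == 0`` a rank-deficient
    design raises rather than returning one of infinitely many solutions.
    """
    cfg = cfg or TrainConfig()
    X, y_raw = _assemble(train_set, cfg)
    y = y_raw * cfg.density_scale
    if cfg.ridge_lambda == 0.0:
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < X.shape[1]:
            raise ValueError(
                "design matrix is singular with ridge_lambda=0; set ridge_lambda > 0"
            )
    ridge = Ridge(alpha=cfg.ridge_lambda, fit_intercept=True)
    ridge.fit(X, y)
    resid = float(np.mean((ridge.predict(X) - y) ** 2))
    return CountModel(
        kind="lrr",
        params={"w": ridge.coef_.astype(np.float64), "b": float(ridge.intercept_)},
        density_scale=cfg.density_scale,
        ridge_lambda=cfg.ridge_lambda,
        meta={"seed": cfg.seed, "final_loss": resid, "train_config": asdict(cfg)},
    )


def predict_density(model: CountModel, fm: FeatureMap) -> DensityMap:
    """Per-pixel prediction, rescaled to raw density and clipped at zero."""
    X = flatten_features(fm)
    out = np.empty(X.shape[0])
    chunk = 65536
    for start in range(0, X.shape[0], chunk):
        out[start : start + chunk] = forward_raw(model, X[start : start + chunk])
    values = np.maximum(out / model.density_scale, 0.0).reshape(fm.height, fm.width)
    return DensityMap(values=values)


def training_loss(model: CountModel, fm: FeatureMap, dm: DensityMap) -> float:
    """The training objective evaluated over every pixel of one image.

    Mean over pixels of the squared difference between the raw model output
    and the density target scaled by ``density_scale``.
    """
    pred = forward_raw(model, flatten_features(fm))
    return mse_loss(pred, dm.values.ravel() * model.density_scale)


def count(
    model: CountModel,
    image: AnnotatedImage,
    preprocess_cfg: PreprocessConfig | None = None,
    patch_size: int | None = None,
) -> float:
    """Estimate the cell count of a raw image: preprocess, extract dense
    SIFT, predict the density, and integrate it. Not rounded — evaluation
    uses the real value."""
    if preprocess_cfg is None and "preprocess" in model.meta:
        preprocess_cfg = PreprocessConfig(**model.meta["preprocess"])
    if patch_size is None:
        patch_size = int(model.meta.get("patch_size", 16))
    prepped = preprocess(image, preprocess_cfg)
    fm = dense_sift(prepped, patch_size=patch_size)
    return predict_density(model, fm).total


def save_model(model: CountModel, path: str | Path) -> None:
    """Serialize to a single ``.npz`` archive (parameters + full config)."""
    arrays: dict[str, np.ndarray] = {}
    if model.kind == "mlp":
        for i, (W, b) in enumerate(zip(model.params["weights"], model.params["biases"])):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        arrays["n_layers"] = np.array(len(model.params["weights"]))
    else:
        arrays["w"] = model.params["w"]
        arrays["b"] = np.array(model.params["b"])
    header = {
        "kind": model.kind,
        "density_scale": model.density_scale,
        "ridge_lambda": model.ridge_lambda,
        "spec": asdict(model.spec) if model.spec else None,
        "meta": model.meta,
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(Path(path), **arrays)


def load_model(path: str | Path) -> CountModel:
    """Inverse of :func:`save_model`."""
    with np.load(Path(path)) as npz:
        header = json.loads(bytes(npz["header"]).decode())
        if header["kind"] == "mlp":
            n = int(npz["n_layers"])
            params = {
                "weights": [npz[f"W{i}"] for i in range(n)],
                "biases": [npz[f"b{i}"] for i in range(n)],
            }
        else:
            params = {"w": npz["w"], "b": float(npz["b"])}
    spec = header["spec"]
    if spec is not None:
        spec = MLPSpec(
            hidden_sizes=tuple(spec["hidden_sizes"]),
            input_dim=spec["input_dim"],
            output_dim=spec["output_dim"],
        )
    return CountModel(
        kind=header["kind"],
        params=params,
        density_scale=header["density_scale"],
        spec=spec,
        ridge_lambda=header["ridge_lambda"],
        meta=header["meta"],
    )
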