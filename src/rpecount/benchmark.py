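"""Reference experiments on the synthetic mosaic benchmark.

Two experiments exercise the whole pipeline end to end on generated data
with exact ground truth:

* :func:`run_counting_benchmark` — the headline parameter-recovery
  experiment: a dataset of confluent mosaics with varying cell counts and
  exposure gains is split into train/test, the MLP and the ridge baseline
  are trained on identical features and labels, and both are scored with
  AER/ACC on the held-out images.
* :func:`run_exposure_experiment` — the preprocessing claim: standardizing
  exposure should (a) collapse the intensity gap between renderings of the
  same mosaic at different gains and (b) let a model trained only on
  well-exposed frames count under-exposed frames with little accuracy loss.

Problem sizes default to a desk-scale setting (50 images of 128 x 128 px,
40-60 cells, hidden layers [200, 200]) chosen so the full benchmark runs in
a few minutes on one CPU; all sizes are parameters.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluation import SplitSpec, evaluate, split
from .models import MLPSpec, TrainConfig
from .pipeline import train_pipeline
from .preprocess import PreprocessConfig, standardize
from .synthetic import MosaicSpec, generate_dataset, generate_mosaic

#: Feature patch used by the benchmark experiments. At the emulated cell
#: scale (~19 px wall spacing) a descriptor support of 32 px spans more than
#: one wall, which is what lets per-pixel features encode local density.
BENCH_PATCH_SIZE = 32


def run_counting_benchmark(
    seed: int = 1,
    n_images: int = 50,
    image_size: int = 128,
    count_range: tuple[int, int] = (40, 60),
    gain_range: tuple[float, float] = (0.4, 1.0),
    test_fraction: float = 0.2,
    hidden_sizes: tuple[int, ...] = (200, 200),
    patch_size: int = BENCH_PATCH_SIZE,
    kinds: tuple[str, ...] = ("mlp", "lrr"),
) -> dict:
    """Train and score both model kinds on one synthetic dataset.

    Returns a dict with the train/test sizes, the resolved kernel sigma,
    and an :class:`~rpecount.evaluation.EvalReport` per model kind.
    """
    template = MosaicSpec(height=image_size, width=image_size)
    data = generate_dataset(template, n_images, count_range, gain_range, seed=seed)
    train_set, test_set = split(data, SplitSpec(test_fraction=test_fraction, seed=seed + 1))
    cfg = TrainConfig(seed=seed + 2)
    pre = PreprocessConfig()
    out: dict = {
        "n_train": len(train_set),
        "n_test": len(test_set),
        "reports": {},
        "models": {},
    }
    for kind in kinds:
        model = train_pipeline(
            train_set,
            kind=kind,
            preprocess_cfg=pre,
            patch_size=patch_size,
            mlp_spec=MLPSpec(hidden_sizes=tuple(hidden_sizes)),
            train_cfg=cfg,
        )
        out["models"][kind] = model
        out["reports"][kind] = evaluate(model, test_set)
        out.setdefault("sigma", model.meta["sigma"])
    return out


def run_exposure_experiment(
    seed: int = 1,
    n_train: int = 30,
    n_test: int = 10,
    image_size: int = 128,
    count_range: tuple[int, int] = (40, 60),
    well_gain: tuple[float, float] = (0.8, 1.0),
    under_gain: tuple[float, float] = (0.35, 0.55),
    patch_size: int = BENCH_PATCH_SIZE,
    kind: str = "lrr",
) -> dict:
    """Quantify how exposure standardization protects counting accuracy.

    Trains one model on well-exposed mosaics only, then evaluates it on a
    well-exposed and an under-exposed test set with matched cell counts.
    Also reports the mean-intensity gap between low- and high-gain
    renderings of one identical mosaic, before and after standardization.
    """
    pre = PreprocessConfig()
    template = MosaicSpec(height=image_size, width=image_size)

    # gap between identical geometry at two gains
    probe = replace(template, n_cells=int(np.mean(count_range)), seed=seed + 7)
    hi = generate_mosaic(replace(probe, exposure_gain=1.0))
    lo = generate_mosaic(replace(probe, exposure_gain=under_gain[0]))
    gap_before = abs(float(hi.pixels.mean()) - float(lo.pixels.mean()))
    gap_after = abs(
        float(standardize(hi, pre).pixels.mean()) - float(standardize(lo, pre).pixels.mean())
    )

    train_set = generate_dataset(template, n_train, count_range, well_gain, seed=seed + 10)
    test_well = generate_dataset(template, n_test, count_range, well_gain, seed=seed + 11)
    rng = np.random.default_rng(seed + 12)
    test_under = []
    for i, img in enumerate(test_well):
        gain = float(rng.uniform(*under_gain))
        dark = generate_mosaic(
            replace(template, n_cells=img.count, exposure_gain=gain,
                    seed=int(rng.integers(0, 2**31 - 1)))
        )
        dark.id = f"under_{i:03d}"
        test_under.append(dark)

    model = train_pipeline(
        train_set, kind=kind, preprocess_cfg=pre, patch_size=patch_size,
        train_cfg=TrainConfig(seed=seed + 13),
    )
    rep_well = evaluate(model, test_well)
    rep_under = evaluate(model, test_under)
    return {
        "gap_before": gap_before,
        "gap_after": gap_after,
        "gap_shrink_factor": gap_before / gap_after if gap_after > 0 else float("inf"),
        "report_well": rep_well,
        "report_under": rep_under,
        "acc_drop_pp": rep_well.acc - rep_under.acc,
    }
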