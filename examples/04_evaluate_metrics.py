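"""Score a trained model with the counting metrics.

The average error rate AER is the mean over test images of the relative
count error |F - s*| / s* (in percent); accuracy is ACC = 100% - AER. The
report also carries the population std of per-image errors, the 2-std
dispersion band conventionally printed as "95% CI", and a t-based CI of
the mean error under its own name.
"""

from rpecount import (
    MosaicSpec,
    SplitSpec,
    TrainConfig,
    evaluate,
    generate_dataset,
    split,
    train_pipeline,
)

data = generate_dataset(
    MosaicSpec(height=128, width=128), n_images=20,
    count_range=(40, 60), gain_range=(0.4, 1.0), seed=11,
)
train_set, test_set = split(data, SplitSpec(test_fraction=0.25, seed=1))
model = train_pipeline(train_set, kind="lrr", patch_size=32, train_cfg=TrainConfig(seed=1))

report = evaluate(model, test_set)
print(f"M = {report.M} test images")
print(f"AER {report.aer:.2f}%   ACC {report.acc:.2f}%")
print(f"std {report.std:.2f}%   CI halfwidth (2 std) {report.ci_halfwidth:.2f}%")
print(f"t-based 95% CI of the mean error: +/- {report.ci_mean_t_halfwidth:.2f}%")
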