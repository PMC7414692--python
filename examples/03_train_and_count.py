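"""Train a counting model and count cells in unseen images.

A small dataset of synthetic mosaics is split into train/test; the ridge
baseline is trained on dense-SIFT descriptors regressed onto density
labels (swap kind="mlp" for the neural model), and counts on held-out
images are the integrals of the predicted density maps. Runs in about a
minute on one CPU.
"""

from rpecount import (
    MosaicSpec,
    SplitSpec,
    TrainConfig,
    count,
    generate_dataset,
    split,
    train_pipeline,
)

data = generate_dataset(
    MosaicSpec(height=128, width=128), n_images=20,
    count_range=(40, 60), gain_range=(0.4, 1.0), seed=11,
)
train_set, test_set = split(data, SplitSpec(test_fraction=0.25, seed=1))

model = train_pipeline(
    train_set, kind="lrr", patch_size=32, train_cfg=TrainConfig(seed=1)
)
print(f"trained on {len(train_set)} images; kernel sigma {model.meta['sigma']:.2f} px")

for img in test_set:
    est = count(model, img)
    print(f"{img.id}: estimated {est:6.1f}   true {img.count}")
# estimates are real-valued density integrals; round only for display
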