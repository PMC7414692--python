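# rpecount

Counting retinal pigment epithelium (RPE) cells in fluorescence
micrographs by density-map regression — no segmentation, no detection, and
no convolutional network, so a handful of annotated images is enough to
train a model.

RPE health is quantified by cell density and morphology in
phalloidin-stained confocal images of cell culture (ARPE-19) or
RPE/choroid flat-mounts, where counting by hand is slow and
boundary-based segmentation struggles with blurry, curvy walls.
`rpecount` instead estimates a *density map* whose integral is the count:

1. **Standardize exposure** — median denoise, contrast-limited adaptive
   histogram equalization (CLAHE), optional gamma — so under- and
   well-exposed acquisitions yield the same feature statistics.
2. **Describe every pixel** with an upright dense SIFT descriptor
   (4×4 spatial × 8 orientation bins = 128 values per pixel); descriptors
   need no training, which is what keeps the data requirement small.
3. **Build labels** from point annotations: one normalized 2-D Gaussian
   per annotated center, so `sum(label) = count` exactly.
4. **Regress** descriptors onto density values, minimizing the mean
   squared error `J(θ) = (1/N) Σ_k ‖F(U_k; θ) − s_k‖²` with a small fully
   connected network (two ReLU hidden layers, linear output) trained by
   SGD with momentum — or with closed-form linear ridge regression (LRR)
   as a baseline.
5. **Count** an unseen image as the integral of its predicted density,
   and score test sets with the average error rate
   `AER = (1/M) Σ_t |F_t − s*_t| / s*_t × 100%` and `ACC = 100% − AER`.

A synthetic generator renders confluent epithelial mosaics (jittered
hexagonal lattice, bright Voronoi walls, variable exposure gain, read
noise) with exact ground truth, so the entire pipeline is testable without
any image downloads.

## Worked example

```python
from rpecount import (MosaicSpec, SplitSpec, TrainConfig, count,
                      evaluate, generate_dataset, split, train_pipeline)

data = generate_dataset(MosaicSpec(height=128, width=128), n_images=20,
                        count_range=(40, 60), gain_range=(0.4, 1.0), seed=11)
train_set, test_set = split(data, SplitSpec(test_fraction=0.25, seed=1))
model = train_pipeline(train_set, kind="lrr", patch_size=32,
                       train_cfg=TrainConfig(seed=1))
report = evaluate(model, test_set)
print(f"AER {report.aer:.2f}%  ACC {report.acc:.2f}%")
for img_id, est, true, _ in report.per_image[:2]:
    print(f"{img_id}: estimated {est:.1f}  true {true}")
```

prints

```
AER 5.27%  ACC 94.73%
synth_001: estimated 54.5  true 52
synth_007: estimated 54.7  true 57
```

i.e. on held-out mosaics the integral of the predicted density lands
within about 5% of the true cell count on average. The `examples/`
directory holds one short script per capability (generation, labels,
training, metrics, the full MLP-vs-LRR benchmark).

The same workflow is available from a shell:

```sh
rpecount synth    --config config.yaml   # dataset: PNGs + CSVs + manifest
rpecount train    --config config.yaml   # model archive (.npz)
rpecount count    --config config.yaml image1.png image2.png
rpecount evaluate --config config.yaml   # per-image CSV + JSON summary
```

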