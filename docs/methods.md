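# Methods

## The counting model

`rpecount` counts cells without detecting them. Every pixel of a
standardized grayscale micrograph is mapped to a nonnegative density value
(cells per pixel) and the count of a region is the integral of the density
over it. The supervision signal is built from point annotations: one
normalized discrete 2-D Gaussian per annotated cell center, summed into a
label map `s` with `sum(s) = number of annotations` exactly. A regressor
`F(·; θ)` maps the 128-dimensional dense-SIFT descriptor of each pixel to
its density value and is trained to minimize the mean squared error

    J(θ) = (1/N) Σ_k ‖F(U_k; θ) − s_k‖²

over the training images, realized as the mean per-pixel squared error over
pixels sampled from each image (equivalent to a sum up to a learning-rate
rescaling; the mean keeps the rate independent of the sample count). Two
regressors share this interface: a fully connected network with ReLU hidden
layers and a linear scalar output, trained by mini-batch SGD with momentum,
and closed-form linear ridge regression (LRR) with an unpenalized
intercept, used as the baseline the network must beat.

The method's assumptions: cells tile the field (confluent monolayer), the
boundary stain dominates local gradient structure, and annotation points
lie inside their cells. Nothing assumes convex or even closed cell
outlines, which is why the approach tolerates blurry, curvy walls that
defeat segmentation.

## Pipeline stages and parameters

**Exposure standardization** (`preprocess`). Median filter, then CLAHE,
then gamma. Defaults: `median_radius=2` (5×5 footprint), `clahe_tile=16`
px, `clahe_clip=0.01` (normalized clip limit as in scikit-image),
`gamma=1.0`. The tile must be larger than a typical cell interior:
equalizing a tile that lies wholly inside one dark interior stretches the
noise floor to full range, and under-exposed images (lower signal-to-noise)
then produce spurious gradient texture that inflates counts. With a 16 px
tile every tile straddles a wall at the cell scales the package targets,
and measured counting accuracy on under-exposed frames is within ~1
percentage point of well-exposed frames (the exposure experiment below).
The chain is deterministic and applied identically at train and predict
time; a perfectly flat image passes through unchanged.

**Dense upright SIFT** (`features`). One descriptor per pixel: central
difference gradients on the mirror-reflected image, gradient magnitudes
Gaussian-weighted (σ = patch/2) into 4×4 spatial × 8 orientation bins with
bilinear spatial and circular-linear orientation interpolation, L2
normalization, clamp at 0.2, renormalization. No keypoint detection, scale
selection, or orientation assignment: rotation invariance would discard
the wall-orientation signal, and scale is fixed by `patch_size`. The whole
map is computed with separable correlations (the triangular bin weight ×
Gaussian factorizes per axis), so a 128×128 image takes well under a
second. `patch_size` defaults to 16 px and must be divisible by 4; the
benchmark experiments use 32 px because a descriptor should span more than
one wall-to-wall distance (~19 px in the synthetic mosaics) to carry local
density information — with a 16 px patch the ridge baseline's error
roughly triples at that scale.

**Density labels** (`density_labels` via `make_density`). Kernel std
`sigma` defaults to `"auto"`: 0.25 × the median nearest-neighbor distance
between annotated centers of the training set, which keeps the central
mass of each Gaussian inside its cell at any magnification. Kernels are
truncated at `truncate=3` σ and renormalized over their in-bounds support
when they overhang the border, so mass conservation is exact (±1e-6) for
every annotation layout — this identity is what makes the count-as-integral
readout unbiased.

**Training** (`models`). Pixels are subsampled per image
(`pixels_per_image=4096` by default; at the 128² benchmark scale 1024
samples left a visible shrinkage bias in the ridge fit). A
`foreground_fraction` (default 0.5) of samples is drawn from pixels inside
a kernel support (density > 0), the rest from the background; no pool is
ever sampled beyond its size — duplicating the few empty pixels of a
confluent field would bias the regression toward zero. Targets are scaled
by `density_scale=100` during training because raw densities are O(1e-2)
and their gradients stall SGD; predictions are divided back and clipped at
zero (densities are physically nonnegative, and negative background
predictions must not reduce counts). The MLP defaults: hidden sizes
[2000, 2000] (the architecture the method was designed around; the
benchmark uses [200, 200], which trains in minutes on one CPU at no
measured accuracy cost at that problem size), He-style scaled-uniform
initialization, SGD with momentum 0.9, `learning_rate=3e-3`,
`batch_size=512`, `epochs=50`. The learning rate was set on training-loss
evidence: at 1e-3 the network's training MSE after 50 epochs barely
undercut the closed-form ridge solution, i.e. the optimizer — not the
model class — was the bottleneck; 3e-3 converges well inside the stability
region. Both trainers are bit-reproducible given their seed. The ridge
penalty `ridge_lambda` defaults to 1.0; λ=0 with a rank-deficient design
raises rather than silently picking one of many solutions.

**Evaluation** (`evaluation`). AER is the mean per-image relative count
error × 100, ACC = 100 − AER, dispersion is the *population* std of the
per-image errors, and the conventional "95% CI" band is ±2 std of those
errors. That band is a dispersion interval, not a standard CI of the mean,
so a t-based 95% CI of the mean error is reported alongside under its own
name. Splits use floor rounding on the test side by default; a
`round_side="train"` switch covers the convention where the floor applies
to the training side (e.g. 85 images at 90/10 → 76/9). Crop augmentation
adds `n_crops` random sub-windows (default crop fraction 0.5, overlap
allowed) of every image whose annotation count exceeds a threshold, with
annotations inherited by position.

## The synthetic generator

`synthetic.generate_mosaic` emulates a phalloidin-stained confluent
epithelium: centers on a hexagonal lattice (spacing chosen so `n_cells`
tile the frame) with uniform jitter up to `jitter`·spacing/2 per axis
(default 0.35), walls rendered where the distances to the two nearest
centers differ by less than `boundary_width` (default 2.5 px), wall/interior
intensities 0.85/0.15, a multiplicative exposure gain, and additive
Gaussian read noise (σ = 0.02) clipped to [0, 1]. Ground truth is exact by
construction. What it does **not** emulate: a confocal point-spread
function, intensity mottle inside cells, multinucleation or pathology,
out-of-focus tissue, or staining artifacts. Passing the benchmark therefore
shows that the pipeline recovers counts from wall-texture statistics under
varying exposure and density — it does not certify accuracy on any
particular real tissue, for which the stated published accuracies on
annotated micrographs remain the reference point.

## Benchmark problem sizes

The end-to-end experiments run at a desk scale chosen so the whole suite
completes in minutes on a single CPU: 50 mosaics of 128×128 px with 40-60
cells and exposure gain uniform in [0.4, 1.0], split 40 train / 10 test,
MLP hidden [200, 200], feature patch 32 px. The exposure experiment trains
on 30 well-exposed mosaics (gain 0.8-1.0) and compares test accuracy on
well-exposed versus under-exposed (gain 0.35-0.55) sets with matched
counts; it also measures the mean-intensity gap between renderings of one
identical mosaic at gain 1.0 and 0.35 before and after standardization.
All sizes are function parameters, not constants.

## Numerical choices and degenerate inputs

- Descriptor normalization treats norms below 1e-12 as zero, so constant
  patches give the zero descriptor rather than NaN.
- Kernel placement rounds sub-pixel annotations to the nearest pixel
  (annotation files are integer pixels).
- `split` errors when a side would be empty; `evaluate` errors on a test
  image with zero annotations (AER divides by the true count).
- A mosaic whose walls would cover more than half the frame (cells too
  dense for the wall width) is rejected at generation.
- Training aborts with the offending epoch on a non-finite loss instead of
  returning a silently broken model.
- Counts are real-valued density integrals; rounding happens only in the
  CLI display column.

## Known limitations

- Per-pixel prediction at full resolution is memory-bound for very large
  frames (an H×W×128 float32 feature map is ~134 MB at 512²); prediction
  chunks pixels, but feature maps are materialized per image.
- The descriptor is gain-invariant by construction, so residual exposure
  sensitivity enters only through noise amplification in preprocessing;
  extremely under-exposed frames (signal comparable to read noise) remain
  out of reach.
- Counts of non-confluent fields (sparse cells on empty background) are
  supported by the sampler but not exercised by the benchmark.
- `sigma="auto"` needs at least one training image with two annotations;
  single-cell images require an explicit sigma.
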