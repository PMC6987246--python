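# Methods

`dwiqc` detects acquisition artifacts in diffusion MRI (dMRI) at the level of
2D slices and aggregates the detections into volume-level quality flags. This
note documents the models, the synthetic-data generator that stands in for a
manually labeled corpus, the numerical choices, and the limits of what the
synthetic benchmarks demonstrate.

## Problem setting

A dMRI acquisition is a 4D image: a 3D voxel grid times a gradient axis, one
3D "gradient volume" per diffusion weighting. Artifacts enter during
acquisition and are conventionally screened by eye, view by view: Nyquist
(N/2) ghosting, herringbone spikes, chemical shift and susceptibility
distortion are most apparent in **axial** slices; motion-induced signal
dropout and multiband/interleave banding cut across slices and are most
apparent in **sagittal** slices. `dwiqc` mirrors that protocol with two
independent binary slice classifiers — an axial detector and a sagittal
detector — each emitting P(artifactual) per slice.

## Slice extraction

Brain extent is located with an intensity bounding box: a voxel belongs to
the head mask when its mean-over-gradients intensity exceeds
`threshold_fraction` (default 0.1) of the robust maximum (99th percentile).
The robust maximum ignores isolated hot voxels; the default fraction sits
well above the Rayleigh background of magnitude images and well below
parenchyma. Retention rules, with the anatomical axes read from the NIfTI
affine:

* **sagittal**: indices within the left-right extent, excluding `margin`
  (default 5) slices counted inward from each brain edge, boundary slices
  inclusive;
* **axial**: indices from the inferior extent boundary (everything below —
  neck, background — is excluded) up to `top_margin` (default 5) slices below
  the superior boundary.

Every retained slice is normalized to zero mean and unit **population**
standard deviation; constant slices map to all-zero images rather than
dividing by zero. Normalization is idempotent and invariant to affine
intensity rescaling, so it is safe to apply defensively at every entry point.

## Synthetic data generator

No public labeled QC corpus exists at this granularity, so the package ships
a generator whose outputs are labeled by construction.

**Phantom.** An ellipsoidal head: brain parenchyma (intensity 0.70) with a
deep white-matter blob (0.50) and a CSF-like ventricle (1.00), wrapped in a
~2-voxel fat rim (1.20), on a default 64×64×36 grid with 4 gradients.
Gradient 0 is the unattenuated (b=0-like) volume; the other gradients
attenuate tissue — not the fat rim — by factors drawn uniformly from
[0.55, 0.80]. Two realism terms prevent the phantom from being pathologically
clean: a correlated intra-brain texture field (Gaussian-smoothed white noise,
σ=2 px, 10% amplitude — a stand-in for parenchymal/gyral texture) and a very
smooth multiplicative bias field (10% — a stand-in for coil sensitivity).
Without them, any visible artifact is trivially separable from the sterile
background by local-pattern statistics, which misrepresents how texture
baselines behave on real data. Rician noise (σ=0.03 by default) is applied
per gradient as |(I+n₁) + i·n₂| with iid Gaussian n₁, n₂; background voxels
are therefore Rayleigh with mean σ√(π/2), which the tests verify against the
closed form. A small per-volume geometry jitter (±4% on the semi-axes) keeps
volumes from being pixel-identical anatomies.

**Artifact injectors.** Each artifact is produced by the minimal k-space or
image-domain mechanism that yields its phenotype; every injector is the
*exact* identity at zero severity and modifies only its affected
(slice, gradient) set:

| type | mechanism | severity range |
|---|---|---|
| ghosting | even/odd phase-encode lines of the slice's 2D k-space scaled by (1±α); equivalent to adding α·(half-FOV-shifted copy) | α ∈ [0.1, 0.5] |
| herringbone | conjugate spike pair added to k-space at ±k₀ → cosine stripe pattern | amplitude 2–10 × p95(|k|) |
| chemical shift | fat-rim component translated `shift_px` voxels along the frequency-encode axis and re-added with a weight | 2–5 px, weight 0.3–0.8 |
| susceptibility | Gaussian-bump displacement field along the phase-encode axis, linear interpolation (smooth fields, no ringing) | 2–6 px peak, σ 4–8 px |
| motion dropout | whole axial slices scaled by (1−a) → dark bands across every sagittal slice | a ∈ [0.4, 1.0] |
| multiband interleave | every `period`-th axial slice scaled by (1−m) → venetian-blind banding sagittally | m ∈ [0.2, 0.6], period 3–6 |

The herringbone severity is referenced to the 95th percentile of the slice's
k-space magnitude: a reference above the noise floor, so the configured range
produces stripes of image amplitude ≈0.03–0.17 against tissue ≈0.7 — visible
without saturating. (Referencing the *median* |k|, which is the noise floor,
yields stripes several times below the noise and no observable phenotype.)

**Labels.** A slice is labeled artifactual in the view where its artifact
class manifests: the affected axial slices for the four axial classes; all
retained sagittal slices of affected gradients for the two sagittal classes
(dropout and banding cross every sagittal slice). The dataset writer re-runs
the retention rules on the *written* volume when building the manifest, so
manifest rows match exactly what a consumer extracting the files will see,
even when an artifact perturbs the intensity bounding box. Magnitude images
are clipped at zero before writing. Given (PhantomSpec, menu, seed) the
dataset — including the manifest bytes — is fully reproducible.

## Detectors

Both detectors share one interface: a convolutional backbone and a trainable
head of one 256-unit fully connected layer, dropout (rate 0.5), and a
two-way softmax. Training uses RMSprop with cross-entropy loss; default 20
epochs, batch size 32. The default learning rate of 2×10⁻⁴ is the
transfer-learning rate for head-only retraining over a frozen backbone.
Layers, backprop and RMSprop are implemented in-package in double-precision
numpy (`dwiqc.nn`), which keeps training deterministic bit-for-bit given the
seeds.

* `vgg16_imagenet`: the standard 13-conv-layer VGG16 feature stack,
  forward-only and frozen, loading ImageNet weights from a user-supplied
  `.npz`; inputs are padded to square, resized to 224×224 and
  channel-replicated (padding rather than anisotropic resizing preserves
  artifact geometry). Only the head trains: 512·256 + 256 + 256·2 + 2 =
  131,842 parameters over the average-pooled 512-dim final conv features.
  Without a weights file, model construction fails with an error pointing to
  the scratch backbone.
* `compact_scratch` (default): three 3×3 conv blocks (8/16/32 channels, each
  with ReLU and 2×2 max pooling) feeding the head from the *flattened* 8×8×32
  final conv map. Flattening rather than global average pooling is
  deliberate: ghost replicas and rim displacements are spatially localized,
  and pooling them away leaves the scratch model unable to fit the artifact
  class. Scratch training moves all ~540k parameters from random init, which
  needs a larger step than head-only retraining; `TrainConfig.for_scratch()`
  sets 10⁻³.

`extract_features` returns the average-pooled final-conv vector (32-dim
compact, 512-dim VGG16) regardless of head type, for the feature→PCA→SVM
pipeline.

Class imbalance (artifactual slices are rare) is handled either by
inverse-frequency loss weights (default) or by `balanced` mode, which tops up
the minority class with augmented copies to parity — preferable when the
absolute number of artifact examples is small, since it also adds geometric
diversity.

A predicted probability ≥ 0.5 labels a slice artifactual — ties flag, because
in QC a false positive costs one extra look while a false negative lets a
corrupted volume through.

**Cross-validation.** `cross_validate` shuffles slices into k folds (default
5) with fold sizes differing by at most one; augmentation applies to training
folds only. The default slice-level protocol permits slices of one volume to
appear in both train and test folds (the returned summary says so
explicitly); `subject_level=True` assigns whole volumes to folds instead. The
standing end-to-end benchmark uses a volume-level holdout for exactly this
reason.

## Augmentation

One augmented copy applies a single affine transform — translation (≤10% of
the frame), rotation (≤15°), zoom (0.9–1.1), shear (≤10°) — plus an optional
horizontal flip, parameters drawn uniformly; vertical flips are off by
default (axial brain slices are roughly left-right symmetric but not
up-down). Out-of-frame pixels take the nearest edge value so augmentation
cannot introduce sharp dark borders that mimic artifacts. Ranges are mild by
design: augmentation must not turn a clean slice into an artifact look-alike.
Labels are copied unchanged, so class marginals are conserved exactly.
Default multiplier 2 (originals plus one augmented copy each).

## Texture baselines

* **Gabor bank (32 features)**: 4 scales × 4 orientations, frequencies
  0.06·2ˢ cycles/px (0.06–0.48, all kernels smaller than a 64-px slice),
  bandwidth 1. Kernels are made zero-mean, and the image is edge-padded
  before convolution, so a constant image yields an exactly-zero response;
  features are the mean and standard deviation of each response magnitude,
  scale-major. 16 filters × 2 statistics = 32.
* **Zernike moments (9 features)**: magnitudes |Z_nm| for all n ≤ 4,
  m ≥ 0, n−m even, computed over the inscribed disk by direct projection on
  the radial polynomials; magnitudes are rotation invariant. A config switch
  (`full_set=False`) restricts to the single (4, 2) moment for the
  alternative reading of "order 4, repetition 2".
* **Uniform LBP (10 features)**: P=8, R=1 code histogram on the slice
  quantized to 256 gray levels (LBP's native domain; on continuous floats
  every sub-noise fluctuation flips neighbor comparisons). Min-max
  quantization makes the histogram exactly invariant to affine gray-level
  changes.

Each feature family feeds a random forest (100 trees, seeded). Two hybrid
baselines: the Gabor features into a 256-unit FC network with dropout and
softmax trained with the same RMSprop/cross-entropy recipe (inputs
standardized on the training set), and backbone CNN features into PCA
retaining the smallest component count with ≥98% cumulative explained
variance, then an RBF SVM. The PCA is fitted on training features only;
test data are projected with the stored axes. Forest/SVM hyperparameters
are library defaults — the baselines are comparison points, not tuned
competitors.

## Reporting and workload arithmetic

Slice reports carry (volume, view, gradient, slice, probability, label),
ordered deterministically. A *volume* is one 3D gradient image. A volume is
flagged in a view when its artifactual-slice count reaches the slice-count
threshold T (count ≥ T, so T=1 means "any artifactual slice flags the
volume"). Raising T can only unflag, so flagged sets are nested and recall
is non-increasing in T — a property the tests check on random reports.
Precision/recall/accuracy are evaluated in exact rational arithmetic;
zero-denominator cases return an explicit undefined marker (`None`), never a
silent 0 or 1.

The workload estimator converts an operating point into analyst effort: with
recall r and precision p over a corpus holding `n_artifactual` bad volumes,
the flagged list is expected to contain r·n_artifactual true positives and
therefore r·n_artifactual/p entries; inspecting only that list is a
100·(1 − flagged/n_total)% reduction. On a corpus of 4163 gradient volumes
with 557 axial-artifactual and 138 sagittal-artifactual volumes, the axial
detector's T=3 operating point (p=0.94, r=0.98) gives an 86.05% reduction and
the sagittal T=10 point (p=0.97, r=0.95) gives 96.75% — reproduced to two
decimals by `estimate_inspection_reduction` and recomputed by the acceptance
script.

## Standing benchmarks and their problem sizes

Sizes are chosen so both benchmarks run routinely on one CPU core.

* **End-to-end** (`dwiqc.benchmarks.end_to_end_benchmark`): 60 synthetic
  volumes (30 artifactual, all six types in the menu), volume-level 75/25
  split, per view ≤1200 clean training slices plus all artifactual ones,
  balanced by augmented oversampling (≈2,400 training slices), compact
  backbone, 10 epochs. Reported: held-out slice accuracy per view and the
  Spearman correlation between ghost severity (α ∈ {0.1 … 0.5}) and the mean
  predicted artifact probability on fixed mid-brain slices.
* **Baseline ordering** (`baseline_ordering_benchmark`): 400 clean vs 400
  artifactual (herringbone/ghosting) slices, independent per-slice
  injections, half held out; reports recall per feature scheme.

## What passing these benchmarks does and does not show

The generator reproduces the *mechanisms* of six artifact classes but not
the full variability of clinical data: anatomy is ellipsoidal, noise is
stationary, artifacts arrive one per volume, and severity ranges are the
documented ones. Accuracies on this substrate say the pipeline is wired
correctly end to end — labels align with injections, detectors learn the
phenotypes, thresholds behave monotonically — not that any particular
accuracy will transfer to scanner data. Axial slice-level recall in the
end-to-end benchmark is modest (the axial corpus holds only ~15 artifactual
volumes, a handful per artifact type), which is the expected behavior of a
scratch-trained CNN at that sample size, and is reported as measured rather
than hidden by the class-imbalanced accuracy.

## Known limitations

* No pulse-sequence simulation: no EPI readout timing, eddy currents or
  field maps; susceptibility is a geometric warp without intensity pile-up
  conservation.
* Gradient direction/b-value metadata is carried opaquely; b=0 and weighted
  volumes are sliced and classified identically.
* The VGG16 path is forward-complete but requires externally supplied
  weights; all shipped benchmarks use the compact backbone.
* Binary labels only; the reports do not attribute artifact types.
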