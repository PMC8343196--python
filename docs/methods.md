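# Methods

`seednet` implements a complete workflow for classifying crop-seed varieties
from near-infrared hyperspectral images when labeled samples are scarce:
cube calibration and seed segmentation, per-seed spectrum extraction,
three one-dimensional deep architectures trained on a sample-rich source
crop, a freeze-and-fine-tune transfer procedure for small target crops, and
four classical chemometric baselines for comparison. Because no public seed
dataset accompanies the workflow, a seeded synthetic generator supplies
spectra and scenes with the statistical structure the method assumes; this
note records the model, the defaults, and what the synthetic experiments do
and do not demonstrate.

## From cube to spectrum

A scan is an H x W x B reflectance cube. Raw counts are corrected with
white/dark references, `R = (I_raw - I_dark) / (I_white - I_dark)`, applied
per voxel; voxels where the references coincide (dead detector elements)
yield 0 with a logged warning rather than an exception, so one bad pixel
cannot abort a batch run. Bands outside the usable window — 975–1646 nm by
convention for this sensor class, where head and tail bands are
noise-dominated — are discarded; the interval is closed on both ends.

Seeds are located on the band image with the strongest foreground/background
contrast, scored as Otsu inter-class variance (deterministic, no tuning).
Segmentation is Otsu thresholding, morphological opening (disk radius 1 by
default; closing available but off), 8-connected labeling, and an area
filter (20 px default). Labels are renumbered in raster-scan order of each
component's first pixel so results are reproducible across runs. Touching
seeds are out of scope (no watershed); scenes are assumed sparse.

Every pixel spectrum of an ROI is passed through the per-pixel transform
*before* averaging — by default wavelet shrinkage (db4, level 3, soft
universal threshold sigma·sqrt(2 ln n), sigma from the finest-level
MAD/0.6745). The ordering matters: the mean of denoised pixels is not the
denoised mean, and the extraction API therefore takes the transform as an
argument instead of post-processing mean spectra. The wavelet family and
level are conventional for NIR reflectance, not sacred; both are config
fields and results should be reported with them.

## Dataset bookkeeping

Stratified splits use integer ratios: 3:1:1 for the sample-rich source
regime and 1:2:2 for sample-limited targets (validation and test double the
training set to make test estimates stable when training data are tiny).
Per class of size n, train and validation take `round(n*a/(a+b+c))` and
`round(n*b/(a+b+c))` (half away from zero) and test takes the exact
remainder, so the three counts always sum to n. This rounding rule is
load-bearing: it reproduces the canonical subset totals exactly (e.g. class
sizes 2697/2848/2849/2026 at 3:1:1 give 6252/2084/2084, and 250-per-variety
targets at 1:2:2 give 50/100/100 per class).

Training-size sweeps keep `max(1, round(fraction * n_train_class))` indices
per class as the *prefix of one seeded per-class permutation*, so for a
fixed seed the 10 % subset is contained in the 20 % subset: accuracy curves
over fractions are monotone in information, not confounded by resampling.

Class ids are assigned in alphabetical order of class names so confusion
matrices are comparable across runs.

## The three architectures

All consume an (N, 1, B) batch of raw reflectance spectra (deep models get
no scaling; see baselines below) and emit class probabilities. They are
implemented in a compact NumPy engine (`seednet.nn`) with explicit
forward/backward passes — 1D convolution via im2col GEMM (stride 1, 'same'
padding, odd kernels), batch normalization, ELU (alpha 1), max/average
pooling, dense layers, residual and inception containers — in float32,
fully deterministic under a seeded generator. Gradients are verified
against central finite differences in the test suite.

* **VGG family**: two V blocks (two 1x3 convs, each followed by BN+ELU;
  16 then 32 filters), a 2/2 max pool after each block, flatten, a 64-unit
  dense layer with BN+ELU (Fc1), and the class output layer (Fc2) with
  softmax. Flatten width is `32 * floor(floor(B/2)/2)` (1600 at B = 200).
* **RES family**: a 32-filter 1x7 stem (BN, ELU, 2/2 max pool), four
  residual blocks with filters 32-64-128-256 (conv-BN-ELU-conv-BN plus a
  skip; a 1x1 projection on the skip path where channel counts change —
  the standard resolution of the silent mismatch a doubling schedule
  creates), a global average pool over the spectral axis, one dense output
  layer.
* **INCEPTION family**: a 16-filter 1x3 stem (as above), four inception
  blocks with base filters 16-32-64-128 and a 2/2 max pool between
  consecutive blocks. Each block runs four parallel branches — 1x1 conv;
  1x1 bottleneck (f/2) then 1x3; 1x1 bottleneck then 1x5; 3-wide stride-1
  max pool then 1x1 conv — each conv followed by BN+ELU, concatenated
  channel-wise (output 4f channels). The bottleneck width and the 1x1 conv
  on the pooling branch follow GoogLeNet convention; both are genuine
  design choices where only the filter-doubling schedule is pinned.

Unstated details fixed for determinism and simplicity: 'same' padding
everywhere (required for the residual addition to type-check), pool size
2/stride 2, global average pooling as the "average over the spectral
dimension", BN before ELU after every dense layer, He-uniform fan-in
initialization from the model seed, argmax decisions with ties to the lower
class id. The RES/INCEPTION tail registers its post-pool reshape under the
layer name `flatten` so the transfer freeze boundary has one uniform name
in all three families.

**Training protocol.** Softmax cross-entropy, SGD with momentum 0.9,
learning rate 0.001, batch 128, 400 epochs by default; after each epoch the
validation accuracy is scored and the best epoch's weights (earliest on
ties) are restored before test evaluation. A `learning_rate = 0` run is a
dry run: no parameter *or* normalization-statistic update, so the model is
left bit-identical — the optimizer sanity oracle. Training aborts with a
diagnostic on non-finite loss. An optional patience field stops training
after that many epochs without validation improvement (useful for tiny
fine-tuning sets; off by default).

## Transfer procedure

A `TransferPlan` names a source checkpoint, the target class count, the
freeze boundary (default `flatten`), layers to reinitialize, and the
fine-tune protocol (batch 3, learning rate 1e-4, momentum 0.9, 400 epochs
by default — a gentler regime matched to tens of samples). `transplant`
rebuilds the architecture at the target width and copies every source
weight that fits bit-exactly; when class counts differ only the final dense
layer is freshly initialized (Fc1 keeps source weights), and when they
match the entire model — output layer included — is carried over, which
maximizes transferred information for same-cardinality tasks. A flag can
force output reinitialization for ablations. `finetune` freezes every
layer before the boundary, *including batch-norm statistics* (a frozen
layer that kept adapting its normalization would not be frozen in any
useful sense), and trains the dense head. The freeze contract is bit-exact
and audited in the tests and the acceptance script.

Transfer can hurt when source and target share no feature structure
(negative transfer); the harness reports that outcome rather than hiding
it, and the generator can construct uncorrelated domain pairs
(`shared_structure = 0`) to demonstrate it.

## Baselines

All four classical models are selected on validation accuracy — one
criterion for every method, including PLS-DA, where a residual-based
criterion would otherwise make selection rules heterogeneous. Spectra are
standardized per band (fit on the training subset only) for the baselines
because SVM-RBF and MLP are scale-sensitive; the deep models consume raw
reflectance. Whether to standardize classical inputs is genuinely open;
the choice is recorded in every `BaselineResult`.

* LDA: project on 1..20 discriminant axes (capped at min(20, C-1, B)),
  classify by nearest class centroid in the projection; shrinkage fallback
  on singular within-class scatter, logged.
* PLS-DA: one-hot PLS regression with 1..20 latent variables (rank-capped),
  class = argmax of the predicted response.
* SVM: RBF kernel over exactly C in {10, 100, 1000, 10000} x gamma in
  {0.1, 0.01, 0.001, 0.0001} (16 fits, all logged); scikit-learn's pairwise
  multi-class scheme; ties prefer smaller C then larger gamma.
* MLP: eight width ladders, prefix-truncated to 1..4 hidden layers
  (32 structures; 24 with depths 1..3 for small targets — deeper nets are
  pointless at tens of samples), SGD at the deep-model settings with early
  stopping patience 50; non-converging structures are recorded and skipped.

"Prefix truncation" reads "simplified as depth decreases" as keeping the
widest layers; a suffix reading is config-selectable.

## Synthetic data: what it emulates

A spectrum is a smooth reflectance baseline minus class-modulated Gaussian
absorption features, plus per-sample baseline drift, smooth correlated
noise, and white noise. Defaults: 200 uniform bands over 975–1646 nm;
absorption centers 1119.45, 1206.92, 1307.97 and 1469.95 nm (carbohydrate
C–H overtones and protein/amide bands — the constituents crop seeds share),
width 25 nm, base depth 0.12.

Class structure: per-class amplitude deltas (uniform +-50 % of base depth,
scaled by `effect_scale`), with only small class offsets/slopes. Nuisance
structure: per-sample offset/slope/curvature drift (sd 0.03/0.02/0.015) —
the additive scatter variation of NIR reflectance, which this pipeline
deliberately leaves uncorrected (no SNV/MSC) — plus smooth correlated noise
(sd 0.01, Gaussian kernel 8 bands) and white noise (sd 0.005). The drift
dominating the class offsets is what makes the sample-limited regime real:
a network trained from scratch on a handful of samples cannot separate
drift from signal, while a source-trained feature extractor that has
learned to read absorption depths transfers. These scales were calibrated
once against that qualitative regime (source-scale training reaches ~0.95+
accuracy; from-scratch training at 5 samples/class clearly degrades) and
then frozen.

`generate_domain_pair` builds "related but different" domains: the target
reuses a fraction (`shared_structure`, default 0.8) of the source's
absorption centers, draws the rest afresh (>= 40 nm apart), and gets its
own class effects. At `shared_structure = 0` the class-difference profiles
of the two domains decorrelate (median |r| < 0.3 over seeds) — the
negative-transfer stress test. `separable_config` is the opposite extreme:
effect scale 2.0 with small noise, a zero-overlap benchmark on which any
competent classifier should approach 100 %.

Scenes place non-overlapping random ellipses (axes 5–9 px) on a dark plate
(background reflectance 0.08), fill each with pixel spectra from its class,
and embed everything into raw/white/dark cubes (constant references 4000
and 120 counts) such that calibration recovers the intended reflectances to
machine precision. Placement uses rejection sampling with bounded retries
and fails loudly when the scene is overcrowded.

What passing synthetic tests does **not** show: performance on real seeds.
The generator has no instrument line-shape, stray light, temperature drift,
seed-morphology or surface-texture effects, and its class differences are
by construction aligned with the absorption dictionary. Synthetic results
validate the machinery (contracts, protocols, relative comparisons), not
field accuracy.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run reduced-scale versions chosen
as the package's own desk-scale defaults: the separability benchmark uses
4 classes x 600 samples (400 in the acceptance script) at 200 bands with
per-architecture epoch budgets of 15 (VGG), 25-30 (RES) and 18-20
(INCEPTION) — the deeper residual network converges slowest; the transfer
experiment uses a 4-class source (100/class), a 3-class target (250/class,
1:2:2 split), training fractions 0.1 and 0.2, fine-tune/scratch budgets of
100 epochs, and medians over 5 seeds; the scene test uses the default
20-seed 96x128 scene. The full-scale protocol (400 epochs, batch 128, thousands of
samples) is the library default for real use.

## Known limitations

* The engine is CPU/NumPy: fine at desk scale, not for thousands of epochs
  on tens of thousands of spectra.
* No data augmentation, learning-rate schedules, or spectral-spatial (2D/3D)
  networks; no domain-adaptation losses (MMD, adversarial) — transfer is
  transplant + freeze + fine-tune only.
* Segmentation assumes non-touching seeds on a dark background.
* t-SNE uses the exact solver below 500 samples (keeps duplicate inputs
  coincident) and Barnes-Hut above; perplexity defaults to 30 with 1000
  iterations.
* Scatter correction, derivative spectra and outlier removal are
  intentionally absent from the preprocessing chain.
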