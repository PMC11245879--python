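# Methods

## Problem setting

The package classifies each pixel of a hyperspectral microscopy cube
(H×W×B, one B-band spectrum per pixel) into background, high-functioning
cell, or low-functioning cell (codes 0/1/2). Ground-truth labels come from a
per-field functional assay, so they are scarce: a handful of labeled pixels
per class per field is the realistic regime, and the pipeline's two
distinctive pieces — spatial-spectral neighbor (SSN) augmentation and a
parameter-lean separable CNN — both exist to make that regime workable.

## Preprocessing

Screening operates on 8-bit images on the 0–255 scale.

* **Brightness exclusion** drops an image iff its mean HSV value strictly
  exceeds 240 (the boundary value is kept); over-bright fields wash cell
  boundaries into the background.
* **Mean-V normalization** rescales multiplicatively toward a target mean of
  130, clipping to [0, 255] and re-applying the scale up to 5 times because
  clipping eats part of the gain; it stops as soon as the mean is within ±1
  of target. Images whose clipped dynamic range cannot reach the target
  (e.g. almost-everywhere-dark frames) converge as close as the range
  allows. All-zero images are rejected as degenerate.
* **Resize** is bilinear with half-pixel center alignment and edge clamping
  (output pixel i samples input coordinate (i+0.5)·scale−0.5). This
  convention is pinned explicitly — rather than delegated to an image
  library's default — so the operator can be verified against a
  closed-form nested-loop oracle, and so constants are preserved exactly.
* **Median denoising** uses a 3×3 window (configurable, odd ≥ 3) with
  edge-replicate padding; **histogram equalization** is the classic 8-bit
  CDF map round((cdf−cdf_min)/(N−cdf_min)·255); **contrast** is either
  linear stretch about the image mean (gain ≥ 0; gain 0 collapses to the
  mean) or a gamma curve 255·(x/255)^g with g > 0.

Hyperspectral cubes bypass the HSV steps entirely; they enter the pipeline
as calibrated intensity arrays.

## Spatial-spectral combined distance and SSN augmentation

For pixel x with ws×ws spatial window S(x) (ws odd; edge-replicated at cube
borders), the combined distance between two pixels is defined as

    SSCD(x_i, x_j) = ‖ mean-spectrum(S(x_i)) − mean-spectrum(S(x_j)) ‖₂ .

Averaging before differencing makes the distance a true pseudometric
(non-negative, symmetric, zero on identical windows, triangle inequality),
reduces to plain spectral distance at ws = 1, and suppresses per-pixel noise
by a factor ws — which is exactly why window size helps on noisy tasks.

The SSNs of a labeled pixel are the k in-window candidates (the ws×ws window
minus the center; clipped at cube borders) with the smallest SSCD between
their own windows and the center's window. Ordering ties break by row-major
position, so selection is deterministic and independent of enumeration
order. Augmentation grafts each labeled pixel's label onto its SSNs; when
several sources claim one position the smallest-distance claim wins, and
originals (distance 0) always beat augmented claims. The window-pool design
couples the useful SSN count to ws: ws = 1 has an empty pool and ws = 3 at
most 8 candidates, so small-window grid rows are structurally degenerate —
requesting more neighbors than the pool holds returns the whole pool rather
than failing, keeping the full grid runnable.

In split-based protocols, augmented samples whose position falls in the
held-out set are dropped before training: an augmented sample carries a
held-out pixel's *features*, and evaluating on pixels whose features entered
training would flatter the score.

## Separable convolutional classifier

Input samples are ws×ws×B patches with the B spectral bands as channels.
The depthwise operator is implemented as written in its index form — a
sliding elementwise-product-and-sum, i.e. cross-correlation without kernel
flip — with valid padding, so a K×K kernel shrinks each spatial axis by
K−1. The pointwise operator is a per-pixel E×C linear map. Both are plain
numpy (einsum over stride-tricks window views) and are tested against
four-nested-loop oracles of the defining formulas at ≤ 1e-6 relative error.

Default architecture: two separable blocks (K = 3, E = 16 then 32, ReLU,
bias on the pointwise step), global average pooling, and a dense softmax
head to 3 classes. Each block's kernel is clipped to the remaining spatial
extent of the patch, so ws = 3 gets one 3×3 block plus a pointwise block and
ws = 1 degenerates to an all-pointwise network on the single-pixel spectrum;
this is what keeps the whole WS grid trainable with one architecture family.

Training: mini-batch SGD with momentum 0.9, learning rate 0.01, batch 32,
30 epochs by default, on cross-entropy weighted by inverse class frequency
(normalized to mean 1) because background dominates the pixel population.
Inputs are standardized per band using training-set statistics stored in the
model. Initialization is He-style scaled to each factor's fan-in. One master
seed drives initialization and shuffling, and the whole loop is numpy-only,
so loss histories are bitwise-reproducible; a non-finite loss raises a
training error rather than returning silently.

Whole-cube prediction replicate-pads the cube by ws//2 so every pixel owns a
full patch, and returns both the argmax label mask and the softmax score
maps (rows sum to 1) for threshold-free metrics.

## Metrics

One-vs-rest per class: Acc = (TP+TN)/(TP+TN+FP+FN), Sen = TP/(TP+FN),
Spe = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN),
F1 = 2·PPV·Sen/(PPV+Sen); AUC by the rank (Mann-Whitney) method, which
equals all-pairs counting with ties at ½ and is invariant under monotone
score transforms. A zero denominator flags the metric undefined (NaN) and
excludes it from the macro average — never substituted by 0, which would
silently bias small-class summaries.

Two accuracy notions are reported and must not be conflated: per-class
one-vs-rest accuracy (macro-averaged over classes) and `overall_accuracy`,
the plain multi-class fraction-correct. For 3 classes they are related by
macro-OvR-Acc = 1 − (2/3)·error-rate, so the macro version is always the
more flattering number; grid search and learning curves report the
fraction-correct.

## Evaluation protocols

**Grid search** sweeps WS ∈ {1,3,5,7,9,11,13} × SSN ∈ {2,4,…,16}. Labeled
pixels are split once, stratified 50/50 by the master seed; every cell
augments the same training half with its own (ws, k), retrains from the same
seed, and is scored on the held-out half (fraction-correct). Failed cells
record NaN instead of aborting the sweep; the best cell breaks ties toward
the smallest ws, then the smallest k.

**Learning curve.** A "sample" is one labeled image. Each replicate
generates max(size) training cubes and a disjoint test set from the task
parameters (fresh cell layout and noise per cube), labels 1 pixel per class
per training image, retrains at every budget, and scores on ≈360 held-out
pixels (8 test images × 15 pixels/class). The 1-pixel budget keeps the
20→100 range inside the learning regime instead of saturating at the first
budget, and the test-set size keeps measurement granularity (~1/360) well
below the accuracy differences of interest. Mean ± SD over ≥ 5 replicates is
reported; an adapter protocol (`fit(x, y, seed)` / `predict(x)`) lets any
external classifier run under the identical protocol.

## Synthetic data

`synthgen` emulates the structure the classifier actually consumes:
non-overlapping elliptical cells (random semi-axes, orientation, position;
bounded rejection sampling, with a placement error if the field cannot hold
the requested cells) on a background, each pixel's spectrum equal to its
class signature plus i.i.d. N(0, σ²) per band, optionally Gaussian-blurred
spatially (signal and noise together, as optics would). Default signatures
over B = 8 bands: flat dim background (40), and two opposite spectral ramps
(60→140 and 140→60) for the cell classes, so classes differ in spectral
shape rather than brightness. Noise is left unclipped to keep its
distribution exactly Gaussian; heavy-noise cubes may therefore contain
negative intensities.

Task difficulty is parameterized by spectral separability — minimum pairwise
signature distance over noise SD (∞ when noiseless): presets easy = 20,
medium = 4, hard = 1.5. Zero-noise cubes are exactly classifiable from
single-pixel spectra and anchor the end-to-end tests: the exact-recovery
check runs at ws = 1 deliberately, because with larger windows boundary
pixels mix classes in their patches and exactness would depend on incidental
cell geometry rather than on the pipeline.

What the generator does **not** model: fibroblast-like cell morphology,
wavelength-dependent noise, autofluorescence spectra, optical vignetting,
focus drift, or any coupling between a cell's shape and its class. Passing
tests therefore demonstrate correctness of the pipeline's mechanics and its
behavior under controlled separability/label-scarcity conditions — not
performance on real stem-cell imagery. Band count and wavelength range of
real instruments are not modeled either; defaults (B = 8, no wavelengths)
are echoed in every output so downstream users can see what was assumed.

Problem sizes in the shipped tests and in `scripts/acceptance.py` (cubes
24–80 px on a side, 5-seed replicates, 15–30 epoch training runs) were
chosen as the smallest sizes at which each property is statistically
resolvable; all of them scale up by passing larger `SynthParams`.

## Numerical and design notes

* Coordinates are row-major, 0-based (row, col); windows use half-open
  index ranges internally; all tie-breaks are row-major.
* Cube containers: ENVI header+raw (BIP/BIL/BSQ read, BIP write, dtype
  preserved — so integer data round-trips bitwise and float data exactly)
  and a compressed npz archive for dependency-light fixtures.
* The depthwise/pointwise pair is deliberately not fused or replaced by a
  library convolution: the operators in this exact index form *are* the
  model, and the tests compare them against independent loop oracles.
* Known limitations: training is single-threaded numpy and sized for
  patch-scale inputs, not megapixel rasters; the mean-then-Euclidean SSCD
  discards within-window spatial arrangement (two windows with equal means
  are indistinguishable); augmentation assumes local label smoothness and
  will propagate errors across a class boundary if a labeled pixel sits on
  one — the smallest-distance conflict rule mitigates but cannot eliminate
  this.
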