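# Methods

## Network

The segmentation backbone is a two-level nested U. Outer level: six
encoder stages (2× ceil-mode max-pooling between them) and five decoder
stages, each decoder stage consuming the channel concatenation of the
bilinearly upsampled deeper feature and the encoder skip. Inner level:
every stage is a residual U-block RSU-*L* (*L* ∈ {4…7}) — an input
convolution forming the residual branch, an *L*-level conv encoder
(first level `out_ch → mid_ch`, then `mid_ch → mid_ch`), a dilated
(rate-2) bottom convolution, and a mirrored decoder on concatenated
(skip, deeper) features whose last level maps `2·mid_ch → out_ch`; the
block output adds the decoder result to the residual branch. The three
deepest stages are the dilated RSU-4F variant (rates 1/2/4/8, mirrored;
no resampling), which therefore accepts any spatial size. Plain stages
accept any size too because pooling uses ceiling semantics and
upsampling targets the exact skip size; the canonical input is a
multiple of 32.

Stage table (height, in, mid, out): encoder 7(3,32,64), 6(64,32,128),
5(128,64,256), 4(256,128,512), 4F(512,256,512), 4F(512,256,512);
decoder 4F(1024,256,512), 4(1024,128,256), 5(512,64,128), 6(256,32,64),
7(128,16,64). Each decoder stage and the deepest encoder stage emits a
side output (3×3 conv → 2 class channels, bilinear upsample to input
size); a 1×1 convolution fuses the six concatenated side maps. The head
is two-class with softmax; grayscale inputs are replicated to three
channels.

### Squeeze-and-excitation residual branches

The `seu2net` variant recalibrates the residual branch (the input-conv
output, which is also the feature "after the first convolutional
block" — the two descriptions coincide for this wiring) of each of the
eight non-dilated stages: global average pooling to a per-channel
descriptor, affine → ReLU → affine → logistic to gates in (0,1), output
`gates ⊙ x + x`. Two weight layouts:

* `shared_group` (default): one (group 16 → bottleneck 4 → 16) affine
  pair with biases, shared across consecutive channel groups —
  148 parameters per block regardless of width. This layout is the only
  one consistent with the published constant per-block overhead
  (8 × 148 = 1,184 total) across residual widths of 64–512; a
  conventional width-dependent bottleneck cannot produce it. The
  sharing is therefore an inference from the printed accounting, not a
  described mechanism, and the per-channel alternative is provided.
* `per_channel`: the conventional C → C/r → C bottleneck (default
  r = 16; the reduced-width test configuration uses r = 4 because its
  widths are not multiples of 16).

### Parameter accounting

`count_parameters` reports per-stage and total counts of persistent
arrays: trainable weights/biases **plus batch-norm running statistics**
(two length-C buffers per BN). The buffer-inclusive convention is what
the published totals for this model family use — with it the default
two-class head reproduces 44,052,518 / 44,053,702 exactly (BN buffer
channels across the net sum to 14,400, hence +28,800 over the
44,023,718 trainable count), and the variant difference equals the pure
SE overhead since SE units carry no buffers. Trainable-only counts are
reported alongside. The mult-add figure is informational only: one
multiply-accumulate per conv weight application at the stated input
size; published FLOPs figures are tool- and convention-dependent and
are not an acceptance quantity.

## Losses

Predictions enter the losses as probability maps (softmax over the
two class channels; validated to sum to 1 within 1e-4).

* Cross-entropy: mean over pixels of −log p(true class), log clamped at
  1e-12.
* Dice loss: `1 − (2 Σ p₁t + ε)/(Σ p₁ + Σ t + ε)` on soft foreground
  probabilities, ε = 1e-6 guarding empty masks. The factor 2 follows
  the standard Sørensen–Dice definition; written without it a perfect
  match would score ½, inconsistent with Dice coefficients ≈ 0.95 being
  reported as near-perfect, so the conventional form is implemented.
* BCE: per-pixel binary cross-entropy on the foreground probability.
* Mixture: 0.7·CE + 0.3·Dice (the default training objective); the
  four modes `mixture`/`ce`/`dice`/`bce` are selectable to mirror the
  loss-ablation arms.

Deep supervision is on by default — the selected loss is summed,
equally weighted, over the fused map and all six side outputs, the
usual convention in this architecture family (whether the original
experiments supervised the side outputs is unstated; a `fused_only`
flag restricts to the fused map, which is always what evaluation uses).

## Metrics

Confusion counts (per-class intersect/pred/label pixel areas) are
accumulated globally over the evaluation split — the area-based
vocabulary of the metric definitions — not averaged per image (a
per-image path exists for diagnostics via single-pair accumulation).
IoU = TP/(TP+FP+FN) and Dice = 2TP/(pred₁+label₁) use the lesion
foreground; accuracy is overall pixel accuracy Σ_c intersect_c / total
(the standard reading of the area-based definition); kappa is
(Acc − P_e)/(1 − P_e) with P_e = Σ_c pred_c·label_c / total². Exact
identities used as test oracles: Dice = 2·IoU/(1+IoU), and kappa = 0
for any constant prediction. Edge case: with no foreground in either
prediction or truth over the accumulation, IoU and Dice are defined
as 1. Argmax ties resolve to class 0 (background).

## Training procedure

Momentum SGD (coefficient 0.9, Nesterov flag on, weight decay 0 —
the latter two coefficients are standard defaults, configurable) with
the cosine schedule η_t = η_min + ½(η_max−η_min)(1+cos(π·t_c/T)) at
η_max = 0.0015, η_min = 0, T = 5400 iterations. "Training runs" are
read as iterations (consistent with the 900-step checkpoint cadence
against 9000 total); since 9000 > 5400 the default schedule warm-restarts
(t_c = t mod T), with a clamped mode (t_c = min(t, T)) available.
Batch size 4, checkpoint every 900 iterations (10 checkpoints over the
full recipe), no data augmentation, evaluation uses the last
checkpoint. Non-finite outputs abort with a divergence diagnostic.
Splits are 8:1:1 train/val/test at the **volume** level (floor
allocation to val/test, remainder to train), so adjacent slices of one
patient cannot leak across splits.

## Numerical backend

The networks run on an in-package reverse-mode autodiff engine over
NumPy arrays: broadcasting arithmetic, GEMM-based same-padded dilated
convolution (strided im2col views), 2×2 ceil-mode max pooling,
half-pixel-center bilinear resampling implemented as dense 1-D
interpolation matrices (transposed exactly in the backward pass), batch
normalization (batch statistics in training, running statistics —
momentum 0.1, eps 1e-5 — at evaluation), and momentum SGD. Every op's
gradient is verified against central finite differences in float64;
training runs in float32. Blocks are tested in evaluation mode where
determinism matters, and all randomness (init, shuffling, phantoms)
flows from explicit `numpy.random.default_rng` seeds.

## Synthetic phantom

The generator emulates the statistical structure the pipeline assumes
of contrast abdominal CT: an ellipsoidal liver of N(60, 10²) HU voxels
on a −1000 HU background, spherical lesions of N(0, 15²) HU (darker
than liver, as hypodense lesions are), additive N(0, 5²) HU noise
everywhere, values rounded to integer HU in the CT range [−1024, 3071].
Default geometry 96×96×24 voxels at (0.7, 0.7, 5.0) mm spacing (a
512×512 export path exists for integration tests); three lesions with
radii drawn from [3, 6] voxels, placed by rejection sampling so each
sphere lies entirely inside the liver and spheres are pairwise disjoint
(≥ 2 voxel gap) — hence connected-component counts equal the requested
lesion count. Label volumes follow either the binary convention
(lesion = 1) or the three-class convention (liver = 1, lesion = 2;
preprocessing retains only the lesion class). What the phantom does
*not* model: anatomy (organ shape, neighbouring organs, vasculature),
partial-volume effects, scanner reconstruction texture, lesion shape
irregularity, and intensity overlap between lesion and liver
distributions beyond their Gaussian tails. Tests passing on phantoms
therefore demonstrate that the pipeline's mechanics (shapes, label
rules, losses, optimization) are correct and that the network can fit
high-contrast structure — not that clinical-grade accuracy transfers to
real CT.

## Scale of the bundled experiments

The published experiments run at 512×512 on GPU with private clinical
data; the bundled configurations are chosen to exercise the identical
code paths at CPU scale. The smoke setup trains the reduced-width
eleven-stage configuration (channels cut 8×, per-channel SE) on the
eight phantom slices richest in lesion at 96×96 for 200 iterations —
about two minutes on one core — and its pass thresholds (training loss
halves; train-set Dice ≥ 0.8) were fixed after five pre-runs of exactly
that configuration (observed: loss drop 80–89%, Dice 0.86–0.96).
Full-size models are built (for the structural audit) but not trained
in the test suite.

## Known limitations

* No GPU path and no multi-threaded conv; full-size 512×512 training is
  out of reach of the NumPy backend at realistic time budgets.
* Binary task only (background/lesion); multi-class heads would need
  metric generalization.
* Bilinear resampling uses the half-pixel-center convention throughout;
  frameworks with align-corners semantics will differ at the pixel
  level.
* The phantom's simplifications listed above; no augmentation pipeline.
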