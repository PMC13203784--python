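# Methods

## The model

`hybridseg` implements a hybrid residual CNN–Transformer U-Net for binary
(lesion vs. background) segmentation of 2-D breast images. The network
has four parts:

**Encoder.** Four stages, each two residual blocks followed by 2×2 max
pooling. A residual block is Conv3×3 → BatchNorm → ReLU → Conv3×3 →
BatchNorm, added to a skip path and passed through a final ReLU:

    Y = ReLU(BN(Conv(X)))        Z = BN(Conv(Y))
    S = X                        if C_in = C_out
    S = BN(Conv1×1(X))           otherwise
    out = ReLU(Z + S)

The main convolutions carry no bias (batch norm supplies the affine
terms). Channel widths start at `base_channels` (default 32) and double
per stage: 32 → 64 → 128 → 256, while a 256×256 input is pooled to
128 → 64 → 32 → 16 pixels. A convolution with C_in inputs, C_out outputs
and kernel k holds C_out·C_in·k² weights plus C_out biases when biased;
the 1×1 output head over 32 channels therefore holds exactly 33
parameters.

**Transformer bottleneck.** Two further residual blocks double the width
to 512 channels at 16×16. The map is flattened row-major into N = 256
tokens of dimension 512, a learnable positional embedding
P ∈ R^{1×N×C} is added, and the tokens pass through L = 4 pre-norm
Transformer encoder blocks:

    z'  = z  + MHSA(LN(z))
    z'' = z' + FFN(LN(z'))

MHSA is scaled dot-product attention, softmax(QKᵀ/√d_k)V per head, with
H = 8 heads of d_k = 64, concatenated and linearly re-projected. The FFN
expands by the MLP ratio (default 4.0) with a GELU nonlinearity. Tokens
are reshaped back to a 512×16×16 map. `use_transformer=False` bypasses
tokenization entirely, giving the plain residual U-Net used as the
ablation baseline through the identical code path.

**Decoder.** Four blocks of kernel-2 stride-2 transposed convolution,
concatenation with the matching encoder skip (bilinear resampling aligns
the grids if an odd input size makes them differ), and two residual
blocks: 512 → 256 → 128 → 64 → 32 channels back to full resolution.

**Head.** A 1×1 convolution to one channel and a sigmoid,
P(x,y) = 1/(1+exp(−z(x,y))). Masks are produced by thresholding at 0.5;
the tie at exactly 0.5 is assigned to foreground, making the documented
threshold inclusive.

## Objective

Training minimises binary cross-entropy plus Dice loss:

    L_BCE  = −(1/N) Σ [ y_i log p_i + (1−y_i) log(1−p_i) ]
    Dice   = (2 Σ y_i p_i + ε) / (Σ p_i + Σ y_i + ε)
    L      = L_BCE + (1 − Dice)

ε defaults to 1e-6 and sits in both numerator and denominator, so an
empty prediction against an empty reference scores Dice 1. Probabilities
are clamped to [1e-7, 1−1e-7] before the logarithms. The `bce` variant
drops the Dice term.

## Numerical core

The network, losses and optimizer run on a compact reverse-mode
automatic-differentiation engine written on NumPy
(`hybridseg.autodiff`). Dense primitives — im2col convolution,
transposed convolution, max pooling, batch/layer normalisation, softmax,
bilinear resampling — carry hand-written vector–Jacobian products so the
heavy lifting stays inside BLAS; elementwise ops support full
broadcasting. Every primitive is verified against central finite
differences in float64 (`tests/test_autodiff.py`); model computation is
float32. Initialisation is Kaiming-normal for convolutions, Xavier for
dense projections, N(0, 0.02) for positional embeddings, all drawn from
a caller-supplied seeded generator, so construction and evaluation are
bit-reproducible. Evaluation mode uses stored batch-norm running
statistics.

## Training protocol

Adam (library-standard betas 0.9/0.999, eps 1e-8) at learning rate 1e-4,
batch size 4, up to 50 epochs. Validation Dice is measured after every
epoch and drives all three controllers:

* **Plateau schedule** — learning rate ×0.5 after 5 epochs without
  improvement (an improvement must exceed 1e-5 to count);
* **Early stopping** — halt after 12 epochs without improvement;
* **Checkpointing** — the best-validation-Dice state is kept and
  returned; the last epoch is saved alongside it.

Gradients are clipped to a global L2 norm of 5.0 before each step.
Mixed precision is exposed as a flag but inert: all computation here is
full-precision CPU NumPy.

**Warm-start sequential transfer.** A new phase loads the previous best
checkpoint non-strictly: parameters (and batch-norm buffers) whose
hierarchical name AND shape match are overwritten, everything else keeps
its fresh initialisation, and the load report lists matched, missing and
shape-mismatched names. A missing checkpoint is the defined
train-from-scratch branch; a corrupt file is an I/O error. Phases share
loss and hyperparameters. No forgetting mitigation (EWC, rehearsal,
distillation) is applied — plain sequential fine-tuning is the method;
re-evaluating earlier phases afterwards is available as a diagnostic.

## Data handling

Images are resized bilinearly to 256×256 (configurable), scaled to
[0, 1], grayscale replicated to three channels; masks are resized
nearest-neighbour and stay binary. RGB-coded annotations (red =
malignant, green = benign, black = background) collapse to a single
foreground class via a dominant-channel rule (>127 in red or green);
grayscale masks binarize at >127.

Splitting is patient-level 70/15/15: patients are shuffled with the
seed, assigned by flooring cumulative ratios with remainders to train
(20 patients give exactly 14/3/3), and every image follows its patient,
so no patient appears in two splits.

Two augmentation sets exist behind `AugmentationConfig` because the two
published descriptions differ: the default draws horizontal/vertical
flips, continuous rotations within ±15°, and multiplicative intensity
jitter in [0.9, 1.1]; the alternative (`right_angle_rotations=True`)
swaps the continuous rotations for 0/90/180/270° turns and adds uniform
scale jitter in [0.9, 1.1] with reflection padding/cropping. Geometric
transforms are applied identically to image and mask (the mask
nearest-neighbour and re-binarised); intensity jitter touches only the
image.

## Evaluation

Overlap metrics (hard-mask Dice, IoU = Dice/(2−Dice), pixel accuracy,
foreground F1 — which equals hard Dice) are computed per image and then
averaged; 95% confidence intervals come from a percentile bootstrap with
1000 resamples of the per-image scores, deterministic under the seed.
The percentile method was chosen over BCa as the simplest estimator
consistent with the resampling protocol. Confusion statistics are pooled
over all pixels of a split and reported one-vs-rest for background and
foreground with macro (unweighted) and support-weighted averages.
ROC-AUC uses the rank (Mann–Whitney) formulation with ties counted ½;
full splits are subsampled to at most 1e5 pixels with a seeded generator
(exact mode available). Published protocols that average "per foreground
object" are ambiguous about object identity; this package averages per
image, and reports pooled pixel statistics separately.

## Synthetic phantoms

The generator (`hybridseg.phantoms`) emulates the statistical character
of four imaging modalities: ultrasound (dark elliptical lesions,
multiplicative gamma-distributed speckle of shape 4 — a standard
approximation — and mild depth shading), histology (20–80 small dark
nuclei on a pale textured background), mammography (bright soft-edged
mass on a smooth gradient), and MRI (hyperintense region on Gaussian
noise). The mask is rasterised from the generating geometry *before*
noise, so registration is exact. Lesion radii default to 7–19% of the
image side (18–48 px at 256). All images of one synthetic patient share
a jittered base geometry, which makes patient-level splitting a real
leakage test. Images and masks are written as 8-bit PNGs (masks 0/255).

Phantoms carry learnable signal — a reduced hybrid model (base 8, 64 px
input, 2 Transformer layers) reaches train Dice ≥ 0.95 on 8 phantoms
within 200 Adam steps — but they are not photorealistic: they lack
acquisition artifacts, annotation noise, anatomical context and
inter-observer variability, so passing tests demonstrate correctness of
the machinery, not clinical performance.

## Problem sizes

The test suite and the acceptance script run reduced configurations
chosen as the smallest sizes that still exercise every code path: 32–64
px inputs with base widths 4–8 for training runs, the full 256-px
default configuration for single forward-pass shape checks, 500
Monte-Carlo replicates for bootstrap coverage, and a 20-patient
end-to-end experiment (8 epochs at 64 px). Full-scale training of the
default 28.7M-parameter model is out of scope for this CPU-only
implementation.

## Known limitations

* CPU-only and NumPy-bound: full-scale (256 px, base 32) training is
  impractical; the full model is exercised in inference only.
* Parameter totals of the default configuration (28.7M total, 12.7M in
  the Transformer) follow from the textual architecture description;
  published per-block totals that cannot be reconciled with any standard
  convention are treated as non-normative.
* Binary segmentation only; multi-class mask colour codes collapse to
  foreground.
* Bootstrap CIs quantify per-image score variability within a split,
  not between training runs.
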