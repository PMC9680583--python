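# Methods

## The problem

MRI-only radiotherapy planning needs electron-density information that MRI
does not carry.  A translation model maps T1-weighted MRI to a synthetic CT
(sCT) in Hounsfield Units, from which dose can be calculated.  Because
tightly registered MRI/CT training pairs are scarce, the models here train
**unpaired**: MRI and CT slices from different subjects and anatomical
positions are fed together, and structural correspondence is enforced by
the objective rather than by the data.

## Models

All three model kinds share one resnet encoder–decoder generator (7×7 input
convolution, two stride-2 downsampling convolutions, a stack of residual
blocks, a mirrored decoder, tanh output so images live in (−1, 1)), one
patch discriminator (three stride-2 convolutions, a 1-channel convolution
and a sigmoid, giving a grid of per-patch realness scores in (0, 1)), and
least-squares adversarial losses:

* generator term `mean (1 − D(G(x)))²`, discriminator term
  `mean [(1 − D(real))² + D(fake)²] / 2`.

**cyclegan** uses two generator/discriminator pairs and constrains content
with L1 cycle-consistency (`‖G_B(G_A(mri)) − mri‖₁` and the reverse) and L1
identity terms (`‖G_A(ct) − ct‖₁`, `‖G_B(mri) − mri‖₁`), weighted α = 10
and β = 5:

    L_G = L_adv_A + L_adv_B + α (L_cyc_MRI + L_cyc_CT)
          + β (L_id_CT + L_id_MRI)

**cut** is one-directional: a single generator/discriminator pair with two
patchwise contrastive (PatchNCE) terms replacing the cycles,
`L_G = L_adv + λ₁ NCE(MRI, sCT) + λ₂ NCE(CT, G(CT))`, λ₁ = λ₂ = 1.  The
second term is an identity-style regulariser in the CT domain: feeding a CT
through the generator should change nothing, so its features must match.

**cyclecut** combines both: the full cycleGAN objective plus four PatchNCE
terms, one per generator application in the two cycles — (MRI, sCT) and
(sMRI, cycle-CT) through the forward generator's encoder and heads, (CT,
sMRI) and (sCT, cycle-MRI) through the reverse generator's — each with unit
weight η₁…η₄ = 1 so all terms sit at comparable magnitude.

### PatchNCE

For each selected encoder layer *l*, feature vectors are read at S_l
spatial locations sampled uniformly without replacement (the same location
record is reused for the input and output stacks, so positives align by
construction), passed through a per-layer two-layer MLP head, and
L2-normalised.  For a query vector ẑ from the output and keys z from the
input, the per-location loss is the temperature-scaled cross-entropy

    −log [ exp(ẑ·z⁺/τ) / (exp(ẑ·z⁺/τ) + Σ_n exp(ẑ·z_n/τ)) ],  τ = 0.07,

with negatives drawn only from the other sampled locations of the *same*
image.  The per-layer value is the **mean** over locations (so the
magnitude is independent of S_l; a raw-sum variant sits behind the
`nce_reduction` switch) and layers are summed.  Feature vectors are
L2-normalised before the dot products — with τ = 0.07 the logits are then
bounded by ±1/τ, which keeps the softmax well-conditioned.

Selected encoder layers default to {input image, first convolution, each
downsampling convolution, middle residual block}.  The projection heads use
a leaky-ReLU hidden layer initialised with a small positive bias: a ReLU
encoder genuinely produces all-zero feature vectors at some locations, and
this choice guarantees a nonzero pre-normalisation embedding everywhere
(an epsilon guard keeps the normalisation NaN-free regardless).

## Training protocol

Adam (β₁ = 0.5, β₂ = 0.999), batch size 1, learning rate 2·10⁻⁴ constant
for the first half of training and decaying linearly to zero over the
second half (defaults: 200 epochs, decay from epoch 100).  Stored slices
are augmented per step: pad to 286² with the background value −1, random
crop to 256², rotate uniformly within ±5°, horizontal flip with
probability ½.  Each epoch shuffles the MRI and CT pools independently and
pairs them positionally; the epoch length is the larger pool, the smaller
pool cycling.  Each step performs one generator update (projection heads
included) followed by one update per discriminator, generators first, with
no image-history buffer.  Loss terms whose weight is zero are neither
computed nor reported.

Every random choice — shuffling, augmentation, patch sampling — derives
from the config seed through hierarchical seed sequences keyed by (epoch,
step), so a run is reproducible bit-for-bit and a checkpoint resume
continues the interrupted run exactly (checkpoints store weights, Adam
moments and step counters in one self-describing file).

## Preprocessing

CT and MRI volumes are assumed rigidly aligned at 1×1×1 mm (the phantom
generator emits them that way).  The chain is: body mask from CT
(threshold −400 HU, largest 3D connected component, slice-wise hole
filling), mask application (−1024 HU outside for CT, 0 for MRI), histogram
matching of each MRI to a reference scan (piecewise-linear map through 256
matched quantiles, rank-preserving), normalisation to [−1, 1], axial
slicing to a fixed stored size (240² at full scale) with empty-mask slices
dropped.

Normalisation bounds: MRI uses each volume's own (min, max) — after
histogram matching all scans share a comparable scale, so this is stable.
CT-domain images use the fixed window (−1024, 3071) HU rather than
per-image bounds: generator outputs must be invertible to HU for MAE to
mean anything, and a fixed window is the only self-consistent inverse.
At inference each axial slice is padded to the generator's divisibility
requirement (multiple of 2^downsamples), translated, cropped back,
denormalised with the CT window and masked to −1024 HU outside the body.

## Evaluation

Image metrics are computed inside the body mask (the ROI recorded in every
report): MAE in HU; PSNR = 10 log₁₀(Q²/MSE) with Q the maximum HU of the
two volumes over the ROI; SSIM in its single-statistic global form (one
mean, variance and covariance per image, C₁ = (0.01 Q)², C₂ = (0.03 Q)²).
A windowed SSIM exists behind no flag here deliberately — the global form
is the contract, and the tests pin it against an independent literal
transcription.

Gamma analysis is the standard global 3D index: for each reference voxel
the minimum over evaluated voxels within a search radius (3 × DTA) of
√(distance²/DTA² + dose-difference²/(dd·D_rx)²), dose differences
normalised to the prescription (50 Gy).  A voxel passes at γ ≤ 1; rates are
reported on the 2%/2 mm and 3%/3 mm criteria crossed with dose thresholds
of 10–90% of prescription.  No sub-voxel interpolation is used by default:
the grids are 1 mm, finer than both DTA criteria.  The search visits
offsets in order of increasing distance and stops when the distance term
alone exceeds every running minimum, which makes the radius-limited result
exact wherever γ ≤ radius/DTA (the tests verify equality with an
exhaustive-search oracle in that zone).  The index is directional; no
symmetry is assumed or used.

Group comparisons between per-subject metric values use the classical
two-tailed paired t-test; inputs with zero-variance differences are
rejected as degenerate rather than returning an unstable statistic.

## The phantom generator

Phantoms emulate head anatomy: an outer soft-tissue ellipsoid, a bone
skull shell, a brain compartment, 1–3 CSF ventricle blobs and an optional
tumor blob, with per-subject jitter of the ellipsoid axes (fraction 0.08 by
default).  Tissue intensities are Gaussian per tissue around table means;
the default table (air −1024, soft tissue 40, bone 1000, CSF 10, tumor
50 HU; MRI 0/300/100/150/400 a.u.) reproduces the T1 contrast inversion at
bone, which the generator enforces as an invariant.  CT and MRI derive from
the same label field, so the pair is voxelwise aligned with a known
cross-modality mapping — the ground truth every training and evaluation
test leans on.

A second, explicitly non-realistic table (`monotone_tissue_table`) orders
tissues identically in both modalities, making the MRI→CT mapping a fixed
monotone intensity transform.  The learnability tests use it because a
small model trained briefly can only be expected to recover a
representable, unambiguous mapping; the contrast-inversion invariant is
relaxed for this table by explicit flag.

What the phantoms do **not** emulate: bias fields, registration error,
scanner-dependent contrast, partial-volume effects at interfaces, real
cranial geometry.  Passing tests therefore demonstrate that the
optimisation and evaluation machinery is correct and that the models can
learn a known mapping from unpaired data at desk scale — not clinical-grade
translation accuracy.

The dose surrogate is a synthetic analytic stand-in for a treatment
planning system: seven attenuated Gaussian photon beams (gantry angles 30°,
90°, 140°, 180°, 220°, 275°, 330° in the axial plane), attenuation through
the water-equivalent path length derived from relative density
(HU + 1024)/1024, normalised to the prescription at the grid centre.  When
comparing CT- and sCT-based doses the sCT dose reuses the CT dose's
normalisation factor — the same delivery through different anatomy —
otherwise renormalisation would cancel exactly the HU-driven differences
the comparison exists to expose.

## Numerical engine

The networks run on a compact reverse-mode autodiff engine over numpy
arrays, sized for the small 2D configurations this package trains on CPU.
Convolution is evaluated as an im2col assembled tap-by-tap with
row-contiguous copies followed by a single GEMM; its adjoint scatters
through strided views, so strides are exact.  Instance normalisation is a
fused primitive with the standard closed-form backward.  Decoder
upsampling is nearest-neighbour resize + 3×3 convolution rather than
transposed convolution (no checkerboard artifacts, simpler exact adjoint).
Training tensors are float32; the pure metric/loss paths run in float64.
Every primitive's gradient is pinned against central finite differences in
the test suite, and the loss graph is dtype-stable (a float64 leak anywhere
would silently break checkpoint-resume bit-equivalence, which the tests
also pin).

## Problem sizes

The shipped tests and the acceptance script run a scaled-down protocol
chosen as the smallest configuration at which unpaired learning is
demonstrable: 3 subjects of 16×64×64 voxels (2 train, 1 held out), 64²
slices, 16-filter networks with one residual block, 32 patches per layer,
and ≈ 320 unpaired steps.  Under these conditions the combined model's
held-out MAE drops by well over half from random initialisation; the
full-scale protocol defaults (240² slices, 64 filters, 9 residual blocks,
200 epochs) remain the config defaults and scale the same code.

## Known limitations

* 2D axial slices only; through-plane continuity of the sCT is not
  enforced.
* One MRI sequence as input; no multi-sequence or 3D variants.
* The gamma module compares supplied dose grids; it does not plan or
  calculate clinical dose.
* The sigmoid discriminator combined with least-squares targets is kept as
  specified for this model family's protocol even though LSGAN is often
  used without the output sigmoid; targets 1/0 lie inside the sigmoid
  range, so the losses are well-defined.
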