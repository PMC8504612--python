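# Methods

This note documents the models, conventions and numerical choices behind
`lungwarp`, and what the bundled synthetic experiments do and do not
demonstrate.

## Registration model

The map between a fixed image `If` and a moving image `Im` on a common voxel
grid is `φ(p) = p + s(p)`, with `s` a dense displacement field *in voxel
units on the fixed grid*. Voxel units are used because the network head
feeds the warp layer directly; physical spacing enters only when landmark
errors are converted to millimetres. The warped image is
`(Im∘φ)(p) = Im(p + s(p))`, sampled trilinearly with sample coordinates
clamped to the volume border (clamping avoids injecting zeros that would
corrupt correlation windows near the boundary). Masks are warped with
nearest-neighbor sampling; fractional parts of exactly 0.5 round half-up per
axis so mask warps are bit-reproducible.

Inputs are assumed affinely pre-aligned; the package performs no affine
pre-registration and no lung segmentation (masks are inputs).

## Loss

`L_total = L_sim + β·R_jac + α·R_der`.

**Similarity.** `L_sim = 1 − NCC`, where NCC is the *mean* over voxels of
the squared windowed normalized cross-correlation: within a centered cubic
window (default edge 11 voxels) both images are mean-subtracted and the
squared covariance is divided by the product of the two sums of squares plus
a stabilizing `ε` (default 1e-5, denominator only). Windows are clipped at
the volume border, i.e. statistics use the in-bounds voxel count. Averaging
(rather than summing) the per-voxel correlations keeps `L_sim` in [0, 1]
at every resolution, so `1 − NCC` is well-scaled. Note the correlation is
squared, so a perfectly anticorrelated window scores as similar as a
perfectly correlated one; this follows the printed definition of the
similarity term.

**Folding penalty.** `R_jac = Σ_p (|det J(p)| − det J(p))` with
`J(p) = I + ∂s/∂p`, the Jacobian of the *full* map. The determinant of the
displacement's own gradient would be 0 for the identity map, which is
inconsistent with treating "all determinants positive" as the non-folding
condition, so the identity term is included; a zero field then yields
det = 1 everywhere and `R_jac = 0`. The penalty is exactly `2·Σ|det|` over
folding voxels and is subgradient-compatible (`sign(0) := 0`). Voxels with
determinant exactly 0 are *counted* as folding but contribute zero penalty;
both behaviors are kept as defined.

**Smoothness.** `R_der = Σ_p ‖∇s(p)‖²_F` over all nine partials.

**Finite differences.** All spatial derivatives use forward differences
with a backward fallback at the last index of each axis, identically in the
determinant map, the penalty, and the test oracles. Affine fields therefore
have exact derivatives everywhere, which the analytic test cases exploit.

**Ω is the full cropped volume**, not the lung mask; nothing in the loss
restricts the domain.

**Weights.** Defaults are α = 1, β = 1e-5, window 11. β trades accuracy
against invertibility: small β (1e-5..1e-4) gives the best similarity but
tolerates folding voxels; larger β (1e-3..1e-2) suppresses folding entirely
at some cost in accuracy. Because `R_jac` and `R_der` are sums over voxels,
their magnitude is extensive in the volume; the default α = 1 is tied to the
full-resolution grid (224×144×192). For the desk-scale experiments bundled
here the smoothness weight is set per-voxel, α = 1/|Ω| (e.g. 1/32768 at
32³), which keeps the smoothness pressure comparable to the bounded
similarity term at any fixture size. The printed sum forms are kept as the
public definitions; the per-voxel α is a run configuration, not a change to
the formulas.

## Thin-plate-spline augmentation

`f(x) = a₁ + a₂x + a₃y + a₄z + Σᵢ wᵢ U(|mᵢ − x|)`, `U(r) = r² log r`, one
coefficient set per output axis, fitted by the bordered system
`Kw + Pa = V`, `Pᵀw = 0` solved densely in one shot for all three axes.
Choices:

* `U(0) := 0`, the continuous limit of `r² log r` (needed on K's diagonal);
* natural logarithm — the kernel's span is invariant to the log base (a
  constant factor is absorbed by `w`), so the choice is cosmetic but fixed;
* control coordinates are normalized to [0,1]³, so the perturbation
  half-range h is a fraction of each axis extent (h = 0.1 displaces control
  points by up to 10%); this reading makes the 0.02–0.1 range a sensible
  "avoid overstretching" cap;
* the solution is accepted when the interpolation residual is below 1e-8;
  otherwise one retry with a 1e-10 ridge on K is attempted and logged, and
  failure raises with a condition-number diagnostic (duplicate or coplanar
  control points).

Augmentation draws a random TPS per (h, replicate) — lattice 5³ by default,
i.i.d. uniform(−h, h) per coordinate — and warps *both* members of a pair
with the same draw, so simulated pairs remain intrapatient-like. Per-record
seeds are `base_seed + record_index`, so any single simulated scan is
reproducible in isolation. Manifest totals include the originals:
`2 · n_pairs · (1 + replicates · |h values|)`; with the default 25×4 scheme,
30 pairs yield 6060 scans and 6 pairs yield 1212.

Backward warping evaluates the TPS at every output voxel (chunked along x to
bound the distance-matrix size) and samples the input there — trilinear for
images, nearest for masks.

## Network

A three-level encoder-decoder. Encoder: three stride-2 3×3×3 convolutions
(spatial reduction (1/2)³ overall). Each tensor that is about to be
downsampled — the 2-channel input and the first two encoder outputs — also
feeds an inception module (parallel convolutions with kernels 1/3/5,
concatenated, reduced by a 1×1×1 convolution back to the input width) on its
skip path; the decoder upsamples three times (zero-insertion + 3×3×3
convolution, i.e. a stride-2 transposed convolution) and concatenates the
inception-processed skip at each level. Every block is conv → normalization
→ LeakyReLU (slope 0.2); the final 3-channel convolution is linear so
displacements of either sign are possible, and its weights are initialized
at scale 1e-5 so training starts near the identity map (a standard
stabilizing choice for displacement heads).

Normalization layers compute per-channel statistics over the spatial axes of
the current sample — exactly what batch normalization degenerates to at the
batch size of 1 used for training — with learnable scale and shift and no
running averages, so inference is deterministic and self-contained.

Exact per-layer widths of the original design are not recoverable; channel
counts are configuration (`enc_channels`, default (16, 32, 64);
`inception_branch_channels`, default 4). Desk-scale runs use (4, 8, 16) with
2-channel branches (~19k parameters). Parameter counts are therefore not an
equivalence claim.

The whole computational graph — convolutions, normalization, warp, losses —
runs on the package's reverse-mode autodiff engine (`lungwarp.autodiff`),
a tape-based tensor over float64 numpy arrays. Every operation's gradient
is checked against central finite differences in `tests/test_autodiff.py`,
and the box-filter NCC path is additionally checked against a windowed loop
oracle.

## Training

Adam (framework-default β₁ = 0.9, β₂ = 0.999), learning rate 1e-4, batch
size 1, 20 epochs by default; batch sizes above 1 accumulate gradients.
Pairs enter as (moving, fixed) channel order. Data order and initialization
derive from a single seed; two runs with the same seed produce identical
loss curves. Validation loss is computed forward-only (the predicted field
is detached, and no optimizer step occurs), and the checkpoint with the best
validation loss is retained — training loss is used when the manifest has no
validation split. A non-finite loss aborts with the offending pair named.

Desk-scale study conditions (used by the end-to-end tests): 20 synthetic
pairs at 32³ with h ∈ {0.02, 0.05}, network (4, 8, 16), NCC window 9
(scaled to the 32³ volume), α = 1/32768, learning rate 1e-3, 12 epochs —
about 1.5 minutes of CPU training per β setting. The larger learning rate
compensates for the short schedule at toy scale; the library defaults remain
the full-scale recipe.

## Evaluation

* **TRE**: each fixed-image landmark `x` is mapped to `x + s(x)` (the field
  interpolated trilinearly at the non-integer landmark position — the same
  direction in which the moving image is warped) and the residual to the
  corresponding moving-image landmark is converted to mm per axis via the
  fixed image's spacing. Mean and *population* (divide-by-n) standard
  deviation are reported. TRE is directional: swapping the landmark roles
  without inverting the field changes the result.
* **Dice**: `2|A∩B|/(|A|+|B|)` of the warped moving mask (nearest-neighbor
  warp) against the fixed mask; defined as 1 when both masks are empty
  (logged). Symmetric in its arguments.
* **Folding count**: voxels with `det J ≤ 0`, over the full grid (not
  restricted to the lung field), sharing the determinant map with `R_jac`.

Batch evaluation writes one row per pair plus a mean summary row, including
the unregistered ("initial") TRE/Dice baselines; unreadable pairs are
skipped with a logged warning and excluded from summaries.

## Synthetic fixtures

Phantoms are sums of Gaussian blobs inside an ellipsoidal "lung field" mask,
plus a soft shell term at the ellipsoid boundary that mimics a lung-wall
contour; intensities are scaled to [0, 1]. A pair is built by warping the
phantom (and its mask) with a random TPS draw, so `fixed` is *exactly* the
TPS warp of `moving` and the dense ground-truth field is available
analytically (the TPS evaluated per voxel, not a numerical inverse), making
parameter-recovery tests exact up to interpolation. Landmarks are placed at
high-intensity-gradient sites inside the mask (homogeneous-region landmarks
carry no registration signal) and their moving-image correspondences are
computed through the ground-truth transform; with unit spacing, initial TRE
grows monotonically with h.

What the fixtures do **not** emulate: CT noise and reconstruction artifacts,
airway/vessel topology, sliding motion at the pleural boundary, and
intensity changes with lung density across the respiratory cycle. Passing
the fixture suite demonstrates correctness of the machinery (losses, warps,
training dynamics, metrics), not clinical-grade registration accuracy;
headline results on real 4DCT benchmarks require full-resolution GPU
training on the public datasets and are outside this package's test
surface.

## Known limitations

* Pure-numpy training is CPU-bound; full-resolution (224×144×192) training
  is impractical here, though the code path is identical.
* The displacement field is predicted directly (no diffeomorphic
  integration), so invertibility is encouraged by `R_jac`, not guaranteed.
* The squared-correlation similarity is blind to contrast inversion by
  construction.
* Landmark files follow the 1-based text convention of common 4DCT
  distributions; other conventions need the `one_based=False` flag.
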