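# Methods

## Problem and approach

Enzymes deposited in the PDB are assigned a hierarchical Enzyme
Commission (EC) number whose first digit (1–6) names the broad reaction
class: oxidoreductase, transferase, hydrolase, lyase, isomerase, ligase.
`enzyvox` predicts this first-level class from structure alone. The
premise is that 3-D shape is more conserved than sequence, so a
representation that discards sequence and side chains — keeping only the
backbone's spatial trace — still carries class signal while being robust
to evolutionary relatedness.

A structure is rendered as an `l × l × l` binary occupancy cube (default
l = 32) and classified by a small two-layer 3-D convolutional network.

## Occupancy-grid representation

Given the ordered backbone atoms (N, Cα, C, O of each residue; first
model, all chains, heteroatoms excluded):

1. **Hole completion.** Consecutive atoms A_i, A_{i+1} are joined by `p`
   regularly spaced points ((p−k+1)·A_i + k·A_{i+1})/(p+1), k = 1…p, in
   the original Å coordinates. At l = 32 the ~1.5 Å atom spacing already
   exceeds the 2.67 Å voxel pitch, so p defaults to 0; denser grids use
   p = 5 (l = 64) and p = 9 (l = 96).
2. **Size adjustment.** Coordinates are centered on the backbone
   barycenter and scaled by the homothety ratio λ = ⌊l/2 − 1⌋ / R_max,
   with R_max = 40 Å by default. Every structure gets the *same* ratio:
   absolute size stays visible to the classifier, and material outside
   the R_max sphere is clipped.
3. **Orientation.** The cloud is rotated into its principal-component
   frame (covariance eigenvectors, variances non-increasing), removing
   the arbitrary deposited orientation. Each axis keeps a sign
   ambiguity; we fix it by requiring the third central moment of the
   projected coordinates to be non-negative, falling back (for clouds
   symmetric to within 1e−9) to making the largest-magnitude loading
   positive. The residual ambiguity for symmetric clouds is exactly what
   flip augmentation covers.
4. **Voxelization.** Points are shifted so the barycenter sits at
   (l/2, l/2, l/2) and mapped to the nearest voxel index (round half
   away from zero; flooring is available via config). Points that would
   land on the outermost voxel shell are dropped along with everything
   outside the captured sphere, so occupied indices always lie in
   [1, l−2]³ and the cube edge never truncates a neighborhood.
5. **Outlier removal.** A single pass clears occupied voxels with no
   occupied neighbor. "Neighbor" defaults to the full 26-voxel shell;
   6- and 18-connectivity are available. The pass is not iterated to a
   fixed point — a chain whose ends become isolated after one pass is
   left as-is.

Numerical notes: rounding ties at exact half-integers are resolved away
from zero; tests use noisy inputs so no coordinate sits within 1e−6 of a
boundary. PCA on clouds with (near-)degenerate covariance spectra — a
straight rod (two noise axes) or a planar ring (two equal axes) — has no
stable frame on the degenerate axes; the rotation-invariance guarantee
of the pipeline therefore applies to clouds with well-separated
principal variances, and degenerate inputs trigger a warning.

## Classifier

Valid-padded, channels-last:

    32³×1 → conv 32@9³ s2 → LeakyReLU(0.1) → dropout 0.2
          → conv 64@5³ s1 → LeakyReLU(0.1) → maxpool 2³ s2 → dropout 0.3
          → flatten 4096 → dense 128 → LeakyReLU(0.1) → dropout 0.4
          → dense 6 → softmax

Valid padding is the only scheme under which the flattened width is
4³·64 = 4096 and the parameter total is exactly 804,614 (23,360 +
256,064 + 524,416 + 774). The training core — im2col convolutions,
pooling, inverted dropout, Adam — is implemented directly on numpy in
`enzyvox/_layers.py`; gradients are exercised by finite-difference
tests, and all heavy products run through BLAS.

**Loss.** Class-weighted categorical cross-entropy
L = −Σ_x Σ_i w_i δ_{x,i} log p̂_{x,i}, with uniform weights (all 1) or
imbalance-adapted weights w_i = max_j(count_j) / count_i computed on the
training counts (largest class gets exactly 1). The public
`weighted_cross_entropy` returns the sum over samples as defined; the
training loop minimizes the per-batch mean so the learning rate is
independent of batch size. An L2 penalty of strength 0.001 applies to
conv/dense kernels only (not biases). Probabilities inside logarithms
are clamped at 1e−7.

**Optimization.** Adam with learning rate 1e−3, β₁ = 0.9, β₂ = 0.999
(framework-standard defaults; the method needs little tuning), batch
size 32. Dropout rates (0.2 / 0.3 / 0.4) follow the usual schedule for
volumetric nets of this size; the exact sites and rates are mild choices
exposed in `ArchitectureSpec`. Full-scale convergence takes on the order
of 200 epochs; scaled-down runs in this repository use 20.

**Augmentation.** During training each of the three axis-flip indicators
is drawn independently with probability p_flip = 0.2 per sample per
pass, so 1 − 0.8³ ≈ 48.8% of visits receive at least one flip. Flips are
the only rigid transformations that preserve the principal axes, hence
the only augmentation consistent with the oriented representation.

**Decision fusion.** At test time the model can be queried on the
flipped copies of a volume: strategy `none` (single volume), `flips`
(equal coefficients) or `weighted_flips` (coefficient 1/(δx+δy+δz+1)),
each fused by summed probability or by (weighted) majority vote with
deterministic tie-breaking (majority ties resolve by larger summed
probability, then lowest class index). Whether the identity volume
joins the 7 flipped ones is configurable; it is included by default
(n = 8) since its fusion coefficient is well-defined and maximal.

## Data protocol

Labels come from a two-column CSV; multi-label enzymes are rejected
with a warning. The split is unstratified uniform random: 80/20
train/test, then 20% of the training pool held out for validation
(64/16/20% overall, sizes rounded). A repeated-split cross-validation
driver (`cross_validate`) re-splits with fold-indexed seeds and reports
mean ± sample s.d.

## Synthetic data

The six fixture families — straight rod, helix, planar ring, volume-
filling globule spiral, ellipsoidal shell, two-lobed dumbbell — are
parametric curves emitting four backbone atoms per residue at ~1.5 Å
spacing, with per-sample shape jitter (±10% size and winding) and 0.3 Å
isotropic coordinate noise. Scale defaults to 30 Å, comfortably inside
the R_max = 40 Å capture sphere, comparable to the typical enzyme radius.
The families are chosen to be separable by coarse 3-D shape — the signal
a volumetric classifier uses — while sharing the backbone-trace format
of real inputs.

What the fixtures do *not* emulate: realistic secondary/tertiary
structure statistics, within-class shape diversity of real folds,
crystallographic artifacts (missing residues, altlocs beyond the
simplest case), or any sequence information. Passing the scaled-down
learning test therefore shows the pipeline is wired correctly and the
network can learn shape classes from the representation — it says
nothing about accuracy on real PDB data, which requires the full
63,558-enzyme snapshot and hours of GPU training and is explicitly out
of scope here.

## Scaled-down benchmark

The repository's stochastic end-to-end check trains the default network
for 20 epochs on 60 training / 30 held-out samples per class (l = 32,
fixed seed) and requires held-out accuracy ≥ 0.5, far above the 1/6
chance floor; in practice the families are learned almost perfectly
within a few epochs. These problem sizes keep a full run in the
minutes range on a single CPU core.

## Known limitations

- Single-channel binary occupancy only; no biochemical attribute
  channels (hydropathy, charge) and no batch-norm/PReLU variants.
- One-pass outlier removal and nearest-index rounding are conventions;
  both are exposed in the config.
- Precision/recall for classes absent from predictions/truth are
  reported as 0 with an explicit flag — a toy-run artifact, impossible
  at realistic sample sizes.
- The CPU training core is sized for small volumes; grid sizes 64/96
  are supported by the representation, but training defaults to 32.
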