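# Methods

This note records the models, the numerical choices, and the places
where the design was genuinely open, so that a maintainer can tell which
behaviour is essential and which is a replaceable convention.

## Cube representation

A cube is the local environment of one interfacial residue: a
24×24×24 grid of 0.8 Å voxels (19.2 Å per side) centred on the
residue's CA and oriented by a frame built from its backbone scaffold —
origin CA, e1 = unit(N−CA), e3 = unit(e1×(C−CA)), e2 = e3×e1. The frame
uses backbone atoms only, so it exists for glycine, and it co-rotates
with the structure; rigid-motion invariance of the voxel values is a
tested property (deviations are at float rounding level, far below the
1e-5 tolerance the tests assert). Collinear backbone atoms are an error;
residues missing a backbone atom are skipped with a warning.

**Atom channels.** Two one-hot schemes are supported. `full167`
enumerates every heavy atom of the 20 standard amino acids — backbone
N/CA/C/O plus side chain, no OXT, no hydrogens — which yields exactly
167 (residue, atom) pairs. The channel order is frozen (residues
alphabetical by 3-letter code, atoms in backbone-then-side-chain
topology order) and exportable as a TSV table so stored cubes remain
portable. `element4` uses the four chemical elements C, N, O, S;
selenomethionine is mapped to methionine (SE→SD). Other nonstandard
residues are rejected with an explicit error rather than silently
re-typed.

**Density kernel.** Each atom contributes a separable Gaussian of width
σ = 0.8 Å (one voxel), truncated at 2σ per axis and renormalized, with
the 1D factors integrated analytically over each voxel interval
(differences of the normal CDF). Renormalized truncation makes an
atom's total deposited mass exactly 1 unless its kernel window crosses
the cube boundary, in which case the escaping part is lost — so total
grid mass counts the atoms well inside the cube, a property the tests
check to 2%. Voxel ownership is half-open, lower-inclusive:
voxel i covers [−9.6 + 0.8·i, −9.6 + 0.8·(i+1)) Å. The kernel width and
cutoff are parameters; the invariance and mass tests do not depend on
the specific kernel.

**Mask.** For self-supervision, every atom (any residue, either
partner) whose centre lies strictly inside a sphere of radius r_c
(default 5 Å) is deleted; an atom at exactly r_c is kept. The sphere is
centred on one of the central residue's heavy atoms: policy `CA`, `CB`
(falling back to CA for glycine), or `random` — uniform over the
residue's heavy atoms, drawn from an explicit seed so training data are
reproducible. A fixed masked volume avoids leaking amino-acid-specific
size or shape into the task.

## Interface regions

Accessibility is computed with the Shrake–Rupley rolling-probe method
(probe 1.4 Å, ProtOr van der Waals radii, 500 sphere points) via
biotite, twice per residue: in the complex, and in the free partner
obtained by deleting the other partner's chains with no relaxation
(rigid-body assumption, consistent with extracting both bound and free
descriptions from one model). Relative ASA divides by the Tien et al.
(2013) theoretical maximum for the residue type. A residue counts as
buried upon binding when it loses more than δ = 0.1 Å² of raw ASA — a
guard against stochastic SASA noise, deliberately applied to raw area
rather than rASA so the tolerance does not scale with residue size. The
five-case decision table at θ = 25% rASA then assigns
INT/SUR/SUP/COR/RIM; it is verified exhaustively against an independent
brute-force implementation on the 101×101 rASA grid. Since regions
depend only on thresholded rASA, any consistent rolling-probe SASA
implementation gives the same labels away from the thresholds.

## Auxiliary descriptors

The encoded vector is `[t_jet, pc, cv, sr one-hot ×5, gemme]`, length 9.
Four scalars describe the wild-type residue; the substitution score is
mutation-specific. Conservation and substitution scores are parsed from
external tabular files (strict headers, conflicting duplicates are
errors); this package does not run alignment-based predictors. The
interface-propensity table is a bundled per-residue scale (hydrophobic
and aromatic residues favoured at interfaces) and is swappable — any
per-residue scalar works, since the value enters only as one feature
slot. Circular variance uses heavy atoms of other residues within a
12 Å cutoff (the cutoff is a convention; it is exposed as a parameter).
Ablation configurations `SR`, `SR-Tjet`, `SR-GEMME`, `All` zero the
inactive scalar slots but keep the vector length fixed, so heads remain
shape-compatible across configurations. `minmax_scale_aux` scales the
scalar slots to [0,1] with training-set bounds only. The 5-way one-hot
order is (INT, SUR, SUP, COR, RIM).

## Models

All three models share a convolutional trunk: a 1×1×1 "projector"
convolution reducing the per-voxel channel vector to 20, three 3×3×3
convolutions each followed by batch normalization and ReLU, and a block
average pool down to 3×3×3. Default filter widths are (32, 64, 128)
with strides (2, 2, 1) (24→12→6→6, pooled to 3). Stride-1 convolutions
throughout would cost ~8 GFLOP per sample forward on the 24³ grid;
early downsampling keeps the cost near 50 MFLOP with no change to the
architecture's structure, and all of these hyperparameters are exposed
in `TrunkConfig`. `TrunkConfig.desk()` (filters 12/16/24) is the
reduced configuration used by the tests and experiments.

* **Masked-residue model**: trunk → dense 200 → dense 20 → dense 20 →
  softmax over the 20 amino acids. Dropout 40/20/10% on the input and
  first two layers of the dense subnetwork. Loss: categorical
  cross-entropy with per-class weights inversely proportional to
  amino-acid frequency, normalized to mean 1 (zero frequency is an
  error). The 200-dim *embedding* of a cube is the post-activation
  output of the first dense layer.
* **Siamese ΔΔG model**: the same trunk plus dense 200 → dense 20 in
  each branch; both branches are literally the same layer objects
  applied to a stacked batch, so weight sharing is exact by
  construction (asserted by identity, not approximate equality). The
  20-dim branch outputs are merged by subtraction — wild-type minus
  mutant, a frozen convention — concatenated with the 9-dim auxiliary
  vector, and mapped by one linear unit to the scalar prediction.
  Because the head is linear and shared, identical cubes contribute
  exactly zero and the prediction is odd in the cube pair; both
  identities are tested. Loss: mean squared error. Fine-tuning can
  start from a pre-trained masked-residue model (trunk + first dense
  layer transferred; the rest fresh) or from random weights.
* **Embedding classifiers**: one hidden layer of size 20 over a 200-dim
  embedding (or the arithmetic mean of an interface's per-cube
  embeddings for interface-level tasks), softmax output, cross-entropy.

**Engine.** The layers are a hand-written numpy engine with manual
backprop — convolutions as one BLAS matmul per kernel offset, standard
batch-norm and inverted-dropout backward passes, Adam — verified
against central finite differences in float64. Training is seeded and
deterministic on one device.

**Batch-norm recalibration.** With full-batch training there are very
few optimizer steps per epoch, so the exponentially averaged running
statistics (momentum 0.1) stay contaminated by their initial values
while the activations evolve; eval-mode forwards would then normalize
with the wrong scale. After training (and before each validation
evaluation) the running statistics are re-estimated as a cumulative
moving average over the training data, leaving parameters untouched.

**Optimizers and schedules.** Library defaults follow the intended
use: Adam at 1e-4 for self-supervised pre-training, 1e-3 for ΔΔG
fine-tuning, batch size 64 (a convention; exposed). The desk-scale
experiments below use 1e-3 throughout, the standard choice for quickly
fitting tiny datasets.

## Dataset handling

The mutation-table reader accepts the SKEMPI v2.0 semicolon dialect and
keeps single-point mutations measured by a reliable technique with
positive wild-type and mutant Kd; every dropped row is logged with a
reason. ΔG = R·T·ln(Kd) with R = 1.9872e-3 kcal/(mol·K); rows without a
usable temperature default to 298 K. Replicate measurements of the same
(complex, mutation) are aggregated by median ΔΔG (configurable to
mean) — a stated policy, since public tables contain repeated
measurements from different laboratories. Splits are either
mutation-level k-fold or complex-level (whole complexes held out; the
no-leakage invariant is tested on every generated plan), both seeded
and serializable to JSON. Metrics are the sample Pearson correlation
and RMSE, overall and per stratum; strata with fewer than two points
are reported as undefined rather than dropped. Sequence-identity-based
training filters expect a precomputed identity matrix; alignment is out
of scope.

## Synthetic data

The generators are pure functions of (spec, seed) and intentionally
idealized — the geometry code and networks need consistent,
reproducible shapes, not physical realism.

* **Toy complex**: two chains of idealized residues (canonical backbone
  internal coordinates, side chains on a fixed zig-zag from CB) laid
  along x; the central contact patch of chain B faces chain A at a
  5.5 Å CA-plane separation, while non-patch residues are displaced
  30 Å laterally so that burial is confined to exactly the designed
  patch. This gives deterministic region labels and exact
  interface-recovery tests. Written as valid PDB and re-parsed
  losslessly.
* **Labeled cubes**: each amino-acid label plants a distinctive
  constellation — 6+label atoms on an ~8 Å shell with label-dependent
  angles, radius and element pattern, plus 0.25 Å jitter — around a
  central residue template, then the standard 5 Å random-centre mask is
  applied. The planted signal sits outside the mask's reach, so the
  task is learnable by design.
* **Synthetic ΔΔG pairs**: wild-type and mutant cubes share a random
  far environment and differ in the number of atoms within 4.5 Å of the
  centre; the target is α·(count difference) + β·(auxiliary scalar) +
  Gaussian noise, with α = 0.4, β = 1.0 recorded as ground truth. This
  is a parameter-recovery construction: a model that reads local
  density and the auxiliary slot can predict the target, and held-out
  correlation measures how well it does.

What passing these tests shows — and does not show. They demonstrate
that the representation is faithful (invariant, mass-conserving,
correctly masked), that the learning machinery optimizes and
generalizes on signals that are visible in cubes, and that the
evaluation arithmetic is right. They do not demonstrate predictive
accuracy on real mutation data: real interfaces have correlated,
physical environments, conformational variability, and measurement
noise that the generators deliberately do not emulate, and the
published-scale experiments (hundreds of thousands of cubes, thousands
of mutations, externally modelled conformers) are far beyond these
problem sizes.

## Experiment sizes

The two standing experiments are sized for a single CPU: the overfit
check trains the masked-residue model on 40 labeled cubes (element
channels, desk trunk, Adam 1e-3, full batch, early stop at 95% training
accuracy, cap 200 epochs); the recovery check trains the Siamese model
on 150 synthetic pairs (noise sd 0.3 kcal/mol) for 80 epochs — enough
to bring the training MSE within about twice the injected noise floor —
and evaluates Pearson correlation on 50 held-out pairs, passing at
≥0.8 at the suite's fixed seed. With only 50 held-out points the
correlation estimate itself carries sampling noise of roughly ±0.05
across data seeds. Both experiments complete in minutes and are
deterministic given their seed.

## Known limitations

* Two-partner decomposition only; no multi-chain-group interfaces.
* Single-point mutations; multi-point effects would need summing
  single-mutation predictions, a crude approximation by design.
* PDB input only (no mmCIF), heavy atoms only, no structure repair.
* The 167-channel ordering is this package's frozen convention; other
  software using the same encoding may order channels differently,
  which affects stored-cube portability, not semantics.
* The numpy engine is single-device and eager; it is meant for
  desk-scale training and inference, not large-scale pre-training.
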