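# Methods

## The screening model

The toolkit implements a staged virtual-screening funnel for a protein target
with a co-crystallized reference ligand. The stages are deliberately ordered
from cheap to expensive: graph-based deep-learning scores over the whole
library, a docking-energy cut over the survivors, and physics-based
(MD/metadynamics) acceptance over the final shortlist. Each stage is a pure
function from a candidate table to a smaller candidate table, so stage counts
are monotonically non-increasing; the run report asserts this and flags any
violation.

### Pocket definition and graphs

The binding pocket is defined geometrically: a residue belongs to the pocket
when the minimum distance between any of its heavy atoms and any ligand heavy
atom is at most a cutoff. Hydrogens are excluded from all distance
operations — cryo-EM structures typically lack them, and heavy-atom minimum
distance is the common convention. Cα or centroid distances were the obvious
alternatives; minimum heavy-atom distance is what makes a 0.5 nm residue
contact cutoff chemically meaningful, so all residue–residue and
residue–ligand distances use it consistently.

Cutoff defaults differ per stage: 0.6 nm for the classifier's pocket, 0.8 nm
for the regressor's, 1.0 nm for generic pocket reports. All public-API
cutoffs are accepted in nanometres and converted to the internal Angstrom
convention at exactly one point (`structio.nm_to_angstrom`); a single
conversion boundary is the cheapest defence against silent factor-of-ten
errors when sources mix nm and Å.

Pocket-graph node features are 30-dimensional residue embeddings formed by
summing chemical-group vectors over an explicit decomposition table (shared
backbone unit + side-chain fragments, e.g. LEU = backbone + methylene +
methine + 2×methyl). The group-vector table is pluggable: a pretrained
fragment-embedding table can be loaded from JSON, while the default provider
derives each vector deterministically from a SHA-256 hash of (seed, group
name). The fallback has no chemical content beyond the decomposition
structure itself; its purpose is reproducibility without shipping third-party
weights. Embedding linearity (residue vector = exact sum of group vectors)
is a tested invariant.

Ligand graphs come from RDKit: heavy atoms as nodes, covalent bonds as
edges, and a one-hot-like feature row per atom (10 element classes, degree
0–5, attached-H count 0–4, formal charge clipped to −1/0/+1, aromaticity).
The bin layout is part of the model schema fingerprint so a trained model
records, and later verifies, the featurization it was trained under.

### Scoring heads

Both scoring models share one architecture: each graph passes through two
graph-convolution layers (symmetrically normalized adjacency with self-loops,
D^{-1/2}(A+I)D^{-1/2}, ReLU activations), is pooled by concatenated global
mean and max pooling, and the two pooled embeddings feed a two-layer dense
combiner. The BC head applies a logistic squash, guaranteeing output in
[0, 1] by construction; the RG head is linear and predicts on the pKa scale,
pKa = −log10(Kx). Mean and max pooling are permutation-invariant, so node
relabelling cannot change a score — a tested invariant, since silent feature
misalignment is the classic failure mode of graph scoring pipelines.

The implementation is plain NumPy with hand-written reverse-mode gradients
and a full-batch Adam optimizer. Defaults: hidden width 16, combiner width
32, learning rate 0.01, 500 epochs. These are toy-scale choices: the
package's contract is the architecture and pipeline, not parity with any
externally trained weights, and at the 8-pair scale the suite trains at both
heads memorize their labels in seconds. A numerical-gradient check pins the
backward pass to the forward definition. Weight initialization is a pure
function of the model seed and the optimizer has no sampling, so identical
(model, data, config) reproduce bit-identical weights. Checkpoints
serialize to JSON with a schema fingerprint; loading under a different
feature schema raises instead of mis-scoring.

### The funnel rule

A record survives iff BC ≥ bc_min AND RG ≥ rg_min AND docking ≤ docking_max,
with inclusive comparisons — reference tables contain boundary-adjacent
values (RG 9.0076 against a 9.0 cutoff), so strictness is semantically
load-bearing. A missing required score disqualifies: conservative semantics,
because a funnel that passes unknowns inflates downstream stages. Default
cutoffs are BC ≥ 0.99, RG ≥ 9.0 (pKa, i.e. ≤ 1 nM predicted), docking ≤ −7
kcal/mol; all are config knobs, and impossible thresholds (e.g. bc_min
= 1.01) are deliberately legal as a way to express an empty stage.

### Trajectory statistics

RMSD per frame is computed after optional least-squares (Kabsch)
superposition; the fit selection may differ from the measured selection, and
ligand RMSD is intended to be measured after fitting on pocket atoms, which
isolates binding-mode drift from global tumbling. RMSF is the per-atom RMS
deviation from the time-mean position after superposing frames onto the
time-average structure (default; iterated once from a first-frame fit) or
the first frame — the two standard conventions. Hydrogen bonds use the
geometric criterion D–A ≤ 0.35 nm and D–H–A angle ≥ 150°; both are field
defaults, explicitly configurable, and recorded in every report. The
coordination-number CV uses the rational switching function with n = 6,
m = 12 (common metadynamics practice); for m = 2n it is evaluated in the
algebraically reduced form 1/(1 + (r/r₀)ⁿ), which is numerically smooth
through the removable singularity at r = r₀ (where the limit is n/m).

### Free-energy reconstruction and acceptance

The FES is the negated sum of deposited Gaussian hills on a uniform 1-D CV
grid, with the well-tempered factor γ/(γ−1) applied per hill when a bias
factor is present, and the minimum shifted to zero. 2-D CVs are out of
scope. Basins are interior strict local minima (plateaus resolved to their
leftmost grid point) with a barrier-limited depth; boundary minima are
reported with a flag so monotone profiles remain interpretable. The
candidate-acceptance rule accepts when the global minimum's CV location
exceeds a threshold (default 0.5 coordination-number units): "the bound
state is the most stable state". The threshold quantifies "significantly
greater than zero contacts", which is not a universal constant; it is
therefore an explicit parameter reported with every decision.

Free energies are kept in kJ/mol with a kcal/mol conversion (÷4.184) at the
interface.

## Synthetic data: what it emulates and what it does not

The fixtures module generates, deterministically from a seed:

* **toy complexes** — residue clusters (4 atoms each) placed at controlled
  radii around a compact ligand blob, with the anchor atom exactly at the
  design radius; pocket ground truth is recomputed by brute force on the
  emitted coordinates, so it stays exact under jitter (default 0.3 Å);
* **score tables** — rows constructed to pass or fail the funnel config at a
  requested rate, with the exact expected survivor list as a sidecar;
* **breathing trajectories** — atoms oscillating ±aᵢ along x over an even
  number of frames, whose RMSF is analytically aᵢ;
* **hills files** — Gaussian hills carving requested (center, depth) basins,
  with the deepest requested center becoming the global minimum.

These exercise the toolkit's geometric, statistical and bookkeeping
contracts exactly. They are not physical: no force field, no realistic
protein topology, no correlated dynamics, no solvent. Passing tests
therefore demonstrate correctness of the computations, not predictive power
on real complexes; predictive power lives in externally trained weights and
real trajectories, both of which the toolkit ingests but does not create.

Problem sizes in the test suite and acceptance script (50-residue complexes,
200-hill FES oracles, 100 random acceptance profiles, 8-pair/500-epoch
training runs) were chosen as the smallest scales at which each property is
non-trivially exercised; all run in seconds on one CPU.

## Numerical choices and degenerate inputs

* Distances: exhaustive pairwise scans via `scipy.spatial.distance.cdist`;
  pockets are small enough that spatial indexing would add complexity
  without measurable benefit.
* Superposition: `scipy.spatial.transform.Rotation.align_vectors` after
  centroid removal (proper rotations only).
* FES brute-force validation runs in extended precision (`np.longdouble`)
  against the vectorized float64 path; the relative discrepancy is at
  rounding level (~1e-16), far inside the 1e-10 gate.
* Empty hill lists yield a flat zero profile, not an error — a run that
  deposited nothing has a flat estimate. Empty pocket selections, empty
  training sets and non-positive affinities raise.
* Altloc handling keeps the highest-occupancy conformer; insertion codes
  ride along in the residue id map. Residues are reindexed 0..n−1
  internally with the original (chain, resid) always recoverable, mirroring
  the reindexed-vs-original id bookkeeping needed when reporting per-residue
  RMSF for a pocket extracted from a large structure.
* Score-table parsing accepts the Unicode minus sign (typeset tables) and
  treats NA/empty cells as missing, never zero.

## Known limitations

* No mmCIF and no binary trajectory formats (DCD/XTC); multi-model PDB and
  XYZ cover the analysis scales this toolkit targets.
* 1-D collective variables only.
* The deterministic embedding fallback carries no learned chemistry; results
  with it are structural tests, not predictions.
* Hydrogen-bond donors must come with hydrogen positions; there is no
  hydrogen inference for heavy-atom-only models.
* No docking, no MD engine, no enhanced-sampling engine: score tables,
  trajectories and hills files are inputs.
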