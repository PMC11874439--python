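# Methods

This note records the models implemented, the defaults chosen where the
design was open, and what the synthetic benchmarks do and do not demonstrate.

## Empirical scoring and minimization

The inter-molecular score is the AutoDock Vina functional form: five terms
(gauss1, gauss2, repulsion, hydrophobic, hydrogen bond) of the surface
distance, summed over heavy-atom pairs within an 8 Å center-to-center cutoff,
weighted with the published Vina weights (−0.035579, −0.005156, 0.840245,
−0.035069, −0.587439) and divided by (1 + 0.05846·N_rot). Hydrogens are
parsed but never enter pair lists or RMSDs. Atom interaction types use a
reduced 13-type vocabulary (hydrophobic/other carbon, donor/acceptor/both for
N and O, S, P, halogen, metal, H); carbon is hydrophobic iff bonded only to
carbon or hydrogen, and N/O donor status comes from explicit bonded
hydrogens — a receptor without explicit hydrogens therefore types its N/O as
plain acceptors, a documented simplification. van der Waals radii come from a
fixed built-in table (C 1.9, N 1.8, O 1.7, S 2.0, P 2.1, halogens 1.8–2.0,
metals 1.2 Å), covalent radii from the standard Cordero table.

The ligand's conformation-dependent internal energy uses the same five terms
over intra-ligand heavy-atom pairs whose shortest bond path crosses at least
one rotatable bond and spans ≥3 bonds (the 1-4 relationship and beyond). This
is an approximation of the Vina lineage's internal energy (which excludes
1-4) chosen so that every torsion move has an internal-energy consequence; it
only affects sampling, not reported scores.

Local minimization is BFGS (SciPy) with analytic gradients: over 6 rigid-body
variables (rotation-vector parametrization about the ligand centroid, exact
axis-angle derivative) in standard mode, or over torsion angles only in
covalent mode, where the objective adds the internal energy. Sub-gradients at
the piecewise-linear kinks are 0. Stopping: gradient ∞-norm < 1e−4 or 200
iterations. The returned pose never scores worse than the input (the start is
kept if the line search fails).

## Sampling

Each Monte Carlo chain repeats mutate → minimize → Metropolis accept at fixed
temperature 1.2 score units (Vina lineage). One mutation is drawn uniformly
from {translation ≤ 2 Å (cube-root radial law, uniform in the ball), rigid
rotation about the centroid, single torsion drawn over the full circle};
covalent mode draws torsion moves only. Defaults: 8 chains
("exhaustiveness"), 200 steps per chain, 9 output modes, 1 Å diversity
filter. Moves whose minimized pose leaves the search box are rejected, so box
containment is an invariant of the output. Per-chain generators derive from
(seed, chain index) through NumPy's SeedSequence, making every output —
including the SDF bytes — a pure function of the configuration and seed.

## Gridding

Atoms deposit exp(−2d²/r²) within their radius r, continued by the quadratic
tail (4/(e²r²))d² − (12/(e²r))d + 9/e² that reaches zero with zero slope at
1.5 r; density is evaluated analytically at voxel centers. The full channel
layout is 13 interaction types × {receptor, ligand} = 26 channels at 0.5 Å
resolution and 48³ points; training and testing use a compact 8-channel map
(4 chemically grouped types × 2 roles) at 1.0 Å and 12³ points so that a CPU
can train scorers in seconds. Ligand-origin atoms of covalent constructs keep
is_ligand=True and therefore land in ligand channels.

## CNN scorers

Both families end in global average pooling and two linear heads: two pose
logits (bad, good) whose softmax good-class probability is CNNscore, and one
affinity output (pK). `default2018` is a linear stack of five 3×3×3
convolutions with two interleaved 2× max poolings; `dense` is three densely
connected blocks of four convolutions each (twelve total), pooled between
blocks. Widths are desk-scale (base 2–8 filters); initialization is He-normal
and fully determined by the model seed.

Losses: two-class cross entropy for the pose task; for affinity, squared
error when the pose is good and max(0, pred − true)² when it is bad, so a
wrong geometry is only penalized for over-predicting affinity. Training is
minibatch SGD with momentum 0.9 and global gradient-norm clipping at 5 (an
oversized early step can silence every ReLU in a network this small);
optional augmentation applies one of the 24 proper cube rotations per grid
per epoch. The backend is a small NumPy layer library (im2col convolutions,
explicit backprop) written for this package and verified against finite
differences in the test suite.

## Knowledge distillation

The KD loss is Σ_teachers KL(softmax(t/T) ‖ softmax(s/T)) on the pose logits,
batch-averaged, with temperature T = 1 by default; the total loss adds the
supervised pose CE and hinged affinity losses, with the KD term weighted
(default 1; the fidelity benchmark uses 2). "KL divergence of pre-softmax
values" is read as: the loss consumes raw logits and applies the softmax
internally; a soft-target cross-entropy variant against the mean teacher
distribution is available via `kd_mode="soft_ce"`. Distillation supervises
the pose score only; affinity always trains against ground truth. Teacher
logits are precomputed once per run unless augmentation is on, in which case
teachers score the same rotated grid the student sees.

The fidelity benchmark trains five teachers (default2018, width 4, 20 epochs,
lr 0.01) on a "graded" synthetic set, then compares students (10 epochs)
trained with and without the KD term by their held-out KL to the ensemble
mean, as a median over five student seeds. Teachers are trained to
convergence while students are deliberately under-trained: that is the regime
knowledge distillation addresses, and the label-only control quantifies what
the KD term adds.

## Synthetic data

`generate_toy_complex` imprints a pocket around a ground-truth ligand pose:
each receptor atom sits at zero surface distance from a random ligand heavy
atom (carbon opposite apolar atoms, oxygen opposite polar ones), rejecting
placements that clash with the ligand or crowd earlier atoms; once the
contact shell saturates, outer layers at +3/+6 Å are filled. A cysteine-like
residue (chain A, residue 145, N/CA/CB/SG) on the rim provides the covalent
anchor. This makes the reference pose the sharp global optimum of the
empirical score — which is exactly what redocking recovery tests require —
and `generate_toy_covalent_complex` does the same around a ligand first bound
to the anchor. Ligand conformers come from named SMILES templates embedded
with RDKit ETKDG at a fixed seed.

Labeled grids for CNN training come in two regimes: `separable` (good poses
jittered ≤1 Å RMSD, bad poses displaced 3–5 Å — cleanly distinguishable, used
for capacity checks) and `graded` (displacement magnitudes on a 0–4.5 Å
continuum with labels from the actual RMSD — near-threshold poses are
genuinely ambiguous, so trained models emit calibrated probabilities and
ensemble soft labels carry distillable information). True affinities are
per-complex pK values drawn uniformly from [4, 8].

What passing on these fixtures shows: the machinery is correct — scoring
matches its formulas, the sampler finds constructed optima, CNNs can learn
the pose discrimination present in the grids, distillation transfers ensemble
behavior. What it does not show: performance on real protein-ligand
complexes, whose pockets are flexible, solvated, and not shape-perfect
imprints, and whose pose/affinity labels are far noisier. No claim about real
benchmark numbers is made or implied.

## Numerical and design choices

- Surface-distance terms are exact (no precomputed grids or smoothing); at
  coincident atom centers the distance derivative is defined as 0.
- altLoc records keep the highest occupancy (ties: first seen); insertion
  codes append to the residue number; waters are excluded by default.
- Receptor bonds are inferred by covalent-radius distance (d < r_i + r_j +
  0.45 Å) since PDB CONECT records are unreliable.
- Rotatable bonds: acyclic single bonds with a heavy substituent beyond the
  axis on both sides; the root fragment is the largest rigid fragment, or the
  fragment holding a forced root atom (covalent constructs root at the
  residue backbone, and torsions that would sweep the anchor atom itself are
  excluded so the anchor stays at its receptor coordinates).
- Covalent placement: the new-bond direction at the receptor atom is the
  normalized negative sum of unit vectors to its bonded neighbors after
  removing one hydrogen (fallback +x); the ligand is rigidly rotated so the
  covalent atom's mean neighbor direction points away from the receptor, and
  the free rotation about the new bond is chosen by a 12-point scan
  maximizing the minimum ligand-receptor heavy-atom distance (ties: first).
  Optional construct refinement runs RDKit UFF with receptor-origin atoms
  fixed, falling back to a bond-length-restoring translation.
- RMSD symmetry correction enumerates graph automorphisms (RDKit substructure
  self-matches) capped at 10⁴ with identity fallback and warning; poses are
  compared in a common frame without superposition. EF top-k is
  k = ceil(fraction·N) with ties at the cut broken by stable input order.
- CNN checkpoints are single .npz files (JSON spec + parameter arrays).
- Problem sizes in the acceptance script (50 oracle complexes, 100
  minimization starts, 20 redocks, 160/60 train/held-out grids, 5 teachers ×
  5 student seeds) are the package's desk-scale study conditions; they keep a
  full from-scratch verification in the minutes range on one CPU core.

## Known limitations

- The empirical score has no explicit desolvation, electrostatics, or metal
  coordination terms beyond the type pairings listed.
- Receptor flexibility is limited to the covalent anchor residue's side chain
  beyond the anchor atom.
- The CNN families reproduce layer counts and the two-task head, not the
  exact filter counts of any released model; no pretrained weights ship with
  the package, so CNN rescoring requires user-trained checkpoints
  (`minidock-train`, `minidock-distill`).
- `--cnn_scoring refinement` (CNN-gradient pose optimization) maps to rescore
  with a warning.
- Protonation assignment, conformer generation from SMILES (outside the
  fixture templates), PDBQT, and mmCIF are out of scope.
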