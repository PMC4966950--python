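# Methods

`crowdtraj` analyzes molecular-dynamics trajectories of proteins in
crowded environments: ordered folds, molten globules and intrinsically
disordered chains surrounded by protein or polymer crowders at cellular
concentrations (~80-400 g/L). This note documents the models and
procedures the package implements, the parameters that matter, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the design was open.

## Units and conventions

All coordinates are nm, times ps, masses amu, temperatures kelvin;
readers convert on ingest (PDB Å → nm). Residue indices are 0-based in
memory and 1-based in every emitted table. Only orthorhombic periodic
boxes are supported; triclinic input raises an explicit error, which keeps
the minimum-image convention exact (the displacement per axis is reduced
by the nearest multiple of the box edge). Whether analysis frames are
wrapped or whole-molecule is up to the caller: every contact routine
applies the minimum image itself, so both layouts give identical results
(tested), and `unwrap` reconstructs continuous center-of-mass paths for
diffusion, valid while consecutive-frame displacements stay below half a
box edge.

## Structural descriptors

* **Superposition / RMSD.** Kabsch superposition via SVD with the
  determinant sign guard, so the optimal transform is always a proper
  rotation — reflections would be unphysical for chiral molecules. RMSD
  series superpose every frame on the reference independently.
* **RMSF** is computed about the *iterated mean structure*: frames are
  superposed on the current mean, the mean is recomputed, and the loop
  runs to a 1e-8 nm fixed point (≤ 20 passes). Using frame 1 instead of
  the mean is the main alternative; the mean is standard and less noisy.
* **Radius of gyration** is mass-weighted by default.
* **SASA** is Shrake-Rupley with a deterministic Fibonacci sphere lattice,
  960 points by default (≤ 1% quadrature error against the analytic sphere
  and two-sphere-cap closed forms). Atomic radii are the Bondi set;
  unknown elements fall back to 0.17 nm with a warning (or raise in strict
  mode). Test points landing exactly on a neighbor's surface (degenerate
  coincident spheres) are assigned to the lower-index atom so the union
  area is counted once. The per-residue decomposition reports ALL,
  BB (N, CA, C, O, OXT), SIDE = ALL − BB, POL = side-chain O and N atoms,
  APOL = the remaining side-chain atoms. Polarity is defined purely by
  element, so histidine side-chain nitrogens count as polar. Backbone O/N
  are *not* in POL by default; callers who want an all-atom polar fraction
  can compute it from the same per-atom areas.
* **Secondary structure** is an internal helix/coil rule, not a STRIDE
  reimplementation: with a full backbone a residue qualifies when
  φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°]; with Cα-only input it qualifies
  when its i→i+3 Cα distance lies in the ideal-helix band
  [0.49, 0.56] nm. Either way a residue is labeled H only inside a run of
  ≥ 4 consecutive qualifying residues. This is deliberately a trend
  detector validated on fixtures (ideal helices score 100% over interior
  residues, freely jointed coils ≤ 5%); absolute assignments on real
  proteins will differ from STRIDE's energy-based criteria.

## Contacts and quinary interactions

A contact is a Cα pair within **0.8 nm**, evaluated per frame with the
minimum image. Occupancy is the fraction of frames in contact. Intra-chain
statistics exclude sequence neighbors |i−j| ≤ 2 (configurable), which
would otherwise dominate every count. A pair is **explored** when its
contact count is *strictly greater than 5 frames* — counted in stored
frames regardless of stride, so the statistic is stride-sensitive and the
stride is recorded in outputs. The inter-protein percentage is averaged
per frame as 100·inter/(inter+intra); frames with no contacts are skipped
and logged. Class composition over {H, P, C} weights each contacting
residue by its summed occupancy (contact-time weighting, not a binary
union). The class scheme is config-overridable and echoed in every
output; the default is C = {ASP, GLU, LYS, ARG, HIS},
P = {SER, THR, ASN, GLN, CYS, TYR, TRP},
H = {ALA, VAL, LEU, ILE, MET, PHE, PRO, GLY}; nonstandard residues report
as class U. Native-contact overlap computes the reference contact set from
a single reference structure at the same cutoff and reports the fraction
held above an occupancy threshold.

## GROMOS clustering

Greedy neighbor-count clustering on pairwise optimally-superposed RMSD:
the frame with most neighbors within the cutoff becomes a center, its
neighborhood is removed, repeat. Ties break to the lowest frame index,
which makes the partition deterministic. The pairwise stage uses the
quaternion characteristic-polynomial (QCP) formulation of the Kabsch
problem — the largest eigenvalue of the 4×4 key matrix is found by Newton
iteration from its upper bound (Ga+Gb)/2, vectorized over frame pairs and
evaluated in row blocks, so only the boolean adjacency matrix is ever
materialized. From an upper bound the Newton error at least halves per
step (repeated-root worst case); 24 iterations bound the squared-deviation
error by ~2⁻²⁴ relative, far below any physical cutoff margin. The result
is block-size independent and matches a naive per-pair Kabsch loop to
1e-14 (tested).

The **two-step protocol** first reduces each trajectory at 0.15 nm
(backbone selection), then pools the step-1 centers across environments —
each carrying its cluster population as weight — into a joint clustering
at 0.35 nm. Joint clusters report per-environment occupancy.
**Environment overlap** is Σ_k min(occ_a(k), occ_b(k)) ∈ [0, 1]; this
min-occupancy reading is one defensible operationalization of
"conformational overlap", so the shared-cluster count is emitted alongside
as an alternative. **Conformational changes** are label changes between
consecutive frames of a single-trajectory clustering at 0.15 nm (0.10 nm
is conventional for notably rigid folds); the mean time between changes is
the simulated span divided by the change count, undefined-and-flagged at
zero changes.

## Helix orientation

A helix axis is the first principal axis of its Cα positions, sign-fixed
toward the C-terminus; the residue range is frozen from the reference
structure even if the helix partially unfolds. Elevation/azimuth of a
target helix are measured in a molecular frame built from an axis vector
(z) and an in-plane reference (x = the reference's component ⊥ z,
y = z × x): elevation = 90° − angle(target, z) signed into [−90°, 90°],
azimuth = atan2(t·y, t·x) ∈ (−180°, 180°]. At the pole the azimuth is
undefined and reported as 0 with a degenerate flag. The frame convention
is a documented package choice (the literature frame it stands in for is
not fully specified anywhere we could reimplement it from); the
convention id travels with the outputs so alternative frames remain
pluggable. Recovery on planted geometries is ≤ 1° noiseless and ≤ 5° at
0.02 nm Cα noise (Monte-Carlo over 100 seeds).

## Diffusion

Center-of-mass MSD uses every stored frame as a time origin (maximal
averaging; origin decorrelation is not enforced, but origin counts per lag
are reported). The all-origin average is evaluated exactly with the FFT
autocorrelation identity, O(T log T). D = slope/6 by least squares over
the central 10-90% of the MSD window (the windows themselves — e.g.
10 ns for water-like solvents, 25 ns for proteins — are caller inputs).
Diagnostics: the log-log exponent of the curve in the fit window must be
within 0.2 of 1 (ballistic input, exponent 2, is flagged), and a negative
slope reports D = 0 with a flag. The finite-size correction for a cubic
periodic box is additive,

    D0 = D_pbc + kB·T·ξ / (6π·η·L),  ξ = 2.837297,

with η a required input (default: water at 300 K, 0.89e-3 Pa·s) because
the appropriate viscosity depends on the simulated solvent model; raw and
corrected values are always reported together. 1 nm²/ps = 1e6 µm²/s.

## Quasi-harmonic entropy

Fluctuations about the mean structure, after removing rigid-body motion by
superposition, define the mass-weighted covariance
C = ⟨M^½ Δx Δxᵀ M^½⟩. Its eigenvalues λ (amu·nm²) give mode frequencies
ω = √(kB·T/λ) and the quantum harmonic-oscillator entropy per mode

    S/kB = α/(e^α − 1) − ln(1 − e^(−α)),  α = ħω/kB·T,

summed over modes. Stiff modes contribute nothing (α → ∞), so the
estimate is dominated by soft collective modes. After superposition the
six smallest eigenvalues (residual rigid-body modes) are dropped, plus
anything below 1e-8 amu·nm² whose frequency would diverge. "Backbone"
means N, Cα, C, O (configurable). The analysis window defaults to the
full trajectory and is expressed as a fraction so the common practice of
analyzing only the equilibrated tail (e.g. the final half) scales to
desk-size fixtures. With fewer frames than 3N the covariance is rank
deficient and a warning says so; the planted-spectrum fixtures therefore
use n ≥ 10× dimension. Entropy differences between environments carry a
block-bootstrap uncertainty (contiguous blocks, both sides re-estimated).
Constants (kB, ħ, amu, unit bridges) live in one table; entropy is
reported in both J/(mol·K) and kB units.

## Synthetic data: what it emulates, what it does not

Each generator plants one statistical feature and stores the truth in a
JSON manifest beside the trajectory, so estimator tests never re-derive
it. All randomness flows through one seeded generator per call —
bit-reproducible, no global state.

* `gen_brownian`: free Brownian particles, per-axis step variance 2·D·dt,
  wrapped into the box. Defaults (100 particles, D = 1e-3 nm²/ps ≈ a
  small-protein diffusion scale, dt = 1 ps, 1e4 steps) give the Einstein
  estimator ~1% recovery error. No hydrodynamics, no interactions.
* `gen_gaussian_ensemble`: frames from a zero-mean Gaussian whose
  mass-weighted covariance has exactly the requested spectrum (random
  orthogonal mode mixing optional). Because the fluctuations are planted
  without rigid-body noise, the covariance check runs with superposition
  off; real trajectories keep it on.
* `build_helix` / `build_helix_pair`: ideal α-helical Cα traces (radius
  0.23 nm, rise 0.15 nm, twist 100°/residue → consecutive Cα ≈ 0.38 nm),
  the second helix rotated onto a planted (elevation, azimuth).
* `gen_random_coil`: freely jointed Cα chain, bond exactly 0.38 nm, each
  frame independent. Planted contacts are realized by conditional
  resampling of the intervening sub-chain until the pair sits within
  0.7 nm, so occupancy ≥ 0.95 holds by construction; overlapping planted
  intervals are rejected as infeasible. No excluded volume — estimators
  under test do not depend on polymer realism, and the ideal-chain
  Rg ~ √n law doubles as an analytic check.
* `gen_two_state`: a symmetric two-state Markov chain (switch probability
  1/dwell per frame) emitting conformer + isotropic Gaussian noise;
  validates clustering and change-time recovery. Real conformational
  kinetics are neither Markovian at the frame level nor two-state.
* `build_crowded_box`: Cα-bead chains (mean residue mass 110 amu) in a
  cubic box whose edge is solved analytically from the target g/L
  (amu → g, nm³ → L), so the achieved concentration equals the target by
  construction; placement uses random position/orientation with a 0.3 nm
  hard-sphere clash rejection and a retry budget. Frames beyond the first
  add rigid-chain Brownian motion plus small bead jitter — enough to give
  the full pipeline contacts, descriptors and diffusion to measure, but
  not a physical model of crowding forces.

Passing tests on these fixtures demonstrates that the estimators recover
known truth under their own model assumptions (Gaussian fluctuations,
Markov switching, free diffusion). They do not certify behavior on real
force-field trajectories, where anharmonicity, correlated solvent motion
and finite sampling enter.

## Pipeline and the disorder trend

`run_pipeline` executes descriptors, contacts, clustering, helix
orientation, diffusion, entropy and trend aggregation per environment,
writes CSV/JSON tables with fixed float formatting, and records a manifest
(parameters, input hashes, stage outputs). A failed stage is logged and
does not abort independent stages. Identical config + seed yields
byte-identical outputs. Intrinsic disorder (an external predictor output,
e.g. PONDR-FIT) is always an *input* percentage per protein, never
computed. The claim that crowding effects scale with disorder is
operationalized as a Spearman rank correlation of each effect column
against disorder, with a one-sided permutation p-value — exhaustive over
all orderings for ≤ 6 proteins (n = 3, ρ = 1 → p = 1/6), 10⁴ seeded
shuffles otherwise. Constant columns are flagged rather than correlated.

## Problem sizes used in validation

The paper-scale systems behind this kind of analysis are multi-microsecond
all-atom trajectories; the validation suite instead runs desk-scale
fixtures chosen so every tolerance is meaningful: 1e4-step Brownian
ensembles (diffusion), 1e5-frame 12-mode Gaussian ensembles (entropy,
2%), 1e4-frame two-state chains (change times, 15%), 200-frame coils
(contacts), 100-seed helix-pair Monte-Carlo (5°), and an 8-chain 192 g/L
box for the end-to-end run. These sizes are the package's validation
conditions, stated here so they can be reproduced exactly.

## Known limitations

No triclinic boxes, velocities or force-field topologies; no β-sheet/turn
classes; no rotational diffusion or Green-Kubo route; no anharmonic or
mutual-information entropy corrections; energy-decomposition analyses that
require force-field parameters are out of scope. The secondary-structure
rule and the helix-frame convention are package-defined stand-ins whose
absolute values should not be compared against STRIDE or other published
conventions without recalibration.
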