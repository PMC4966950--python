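# crowdtraj

Trajectory analysis of protein structure, contacts, thermodynamics and
kinetics under **macromolecular crowding**.

The interior of a cell holds up to ~400 g/L of macromolecules. That
density reshapes how proteins behave: excluded volume favors compact
states, while weak, transient *quinary* protein-protein contacts pull
disordered chains toward extended conformers, and the viscous environment
slows every motion. `crowdtraj` implements the analysis chain used to
quantify these effects in molecular-dynamics simulations of ordered,
molten-globule and intrinsically disordered proteins in crowded boxes —
and ships synthetic-trajectory generators with planted ground truth so
every estimator is validated without multi-microsecond production runs.

## What it computes

| Quantity | Definition |
|---|---|
| RMSD / Rg / RMSF / sampling maps | Kabsch superposition (proper rotations only); mass-weighted Rg; RMSF about the iterated mean structure; 2-D occupancy histograms |
| SASA | Shrake-Rupley with a 960-point Fibonacci lattice; per-residue ALL/BB/SIDE/POL/APOL split (POL = side-chain O and N) |
| Contacts | Cα pairs within 0.8 nm under the minimum image; occupancy maps, the strict "explored in > 5 frames" rule, inter-protein percentage, residue-class (H/P/C) composition, native-contact overlap, environment difference maps |
| Conformers | GROMOS greedy neighbor-count clustering on pairwise superposed RMSD (QCP-accelerated); two-step 0.15 nm → pooled 0.35 nm protocol with per-environment occupancy and min-occupancy overlap; conformational-change timing |
| Helix geometry | Helix axes as first principal axes of Cα subsets; relative elevation/azimuth in a documented molecular frame; orientation frequency maps |
| Diffusion | Center-of-mass MSD (all time origins, exact FFT evaluation), Einstein relation D = slope/6, and the cubic-box finite-size correction D₀ = D_pbc + k_B·T·ξ/(6πηL), ξ = 2.837297 |
| Entropy | Quasi-harmonic: mass-weighted covariance eigenvalues λ → ω = √(k_BT/λ) → quantum harmonic-oscillator entropy per mode, summed |
| Trend | Spearman rank correlation of per-protein crowding effects against intrinsic disorder (external input, e.g. PONDR-FIT), with permutation p-values |

Formulas, parameter defaults and numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

Build a dense box of Cα-bead chains at 192 g/L — a mid-range cellular
concentration — and run the main estimators:

```python
import crowdtraj as ct

spec = ct.CrowdedBoxSpec(
    chains=(ct.ChainSpec(30, "coil", 4), ct.ChainSpec(20, "helix", 4)),
    concentration=192.0, n_frames=40, seed=1)
traj, manifest = ct.build_crowded_box(spec)

chain0 = range(30)
others = range(30, traj.topology.n_residues)
pct = ct.interprotein_fraction(traj, chain0, others)
n_exp, frac = ct.explored_contacts(traj, chain0)
timing = ct.conformational_change_times(
    traj, cutoff=0.15, selection=traj.topology.calpha(molecule_id=0))
entropy = ct.backbone_entropy(traj, 300.0, window=(0.5, 1.0))
diff = ct.diffusion_table(
    traj, {"chains": [m.molecule_id for m in traj.topology.molecules]})
```

Output:

```
box edge: 5.75 nm, achieved: 192.0 g/L
chain 0: 30.3% of contacts are inter-protein; 119 explored intra pairs (31.5%)
conformational changes: 31 (mean 25 ps between changes)
backbone entropy: 1209 J/(mol K) (145.4 kB, 19 modes)
D_pbc = 714 um^2/s, D_corrected = 836 um^2/s (box 5.75 nm)
```

Reading this: the box edge is solved analytically from the total chain
mass so the achieved concentration equals the 192 g/L target exactly. In
this dense box roughly a third of the first chain's instantaneous Cα
contacts are with *other* chains (quinary contacts), and a third of its
eligible intra-chain pairs have been explored for more than 5 frames. The
clustering stage counts 31 changes of conformational cluster across the
40 stored frames; the quasi-harmonic entropy comes from the 19 soft modes
that survive rank and rigid-body filtering at this short window length
(the rank warning it prints is expected at desk scale); and the
finite-size correction adds ~120 µm²/s to the periodic-box diffusion
coefficient at this small box edge — both raw and corrected values are
always reported.

The same pipeline runs from the shell:

```sh
crowdtraj make-synthetic --out-dir demo --n-frames 40 --seed 1
crowdtraj run-all --config demo/config.yaml --out-dir results
```

which writes per-frame descriptor tables, contact maps and summaries,
cluster/change timing, helix orientations, the diffusion table, entropy
summaries and a run manifest — all as CSV/JSON with fixed formatting, so
the same config and seed reproduce byte-identical outputs.

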