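# Methods

Definitions, conventions and defaults for every pipeline stage. Units are
nanometres, degrees, picoseconds and kJ/mol throughout; file I/O converts
to/from the PDB's ångströms.

## Domain model

A trajectory is a two-chain topology plus a dense `(n_frames, n_atoms, 3)`
coordinate array; `Frame`/`Chain`/`Residue` objects are materialized on
demand. Multi-model PDB files are read and written through biotite, one
`MODEL` block per frame; input files must contain exactly two chain
identifiers, and molecules are assumed whole (a C(i)–N(i+1) peptide bond
longer than 0.25 nm raises an error rather than silently producing
garbage features).

## Features

The primary feature space is the inverse distance between the side-chain
mass centers of every inter-chain residue pair: chain lengths n₁ and n₂
give n₁·n₂ strictly positive components (144 for a 12+12 dimer), flattened
row-major over the chain-A index. Side-chain centers are mass-weighted
over side-chain heavy atoms; glycine (or any residue modeled without a
side chain) uses Cα. Inverse distances are invariant under global rotation
and translation, and the chain-swap symmetry corresponds to transposing
the n₁×n₂ grid.

Dihedral PCA features — (sin, cos) of every backbone φ (residues 2..n)
and ψ (residues 1..n−1) — are available as an alternative, giving 8(n−1)
components per equal-length chain pair.

## PCA and free-energy surfaces

PCA is a centered SVD; components are sorted by decreasing variance and
signs are fixed so each component's largest-magnitude loading is positive
(PCA signs are otherwise arbitrary — this is a reproducibility
convention). Frames are projected onto the first two components and binned
on an `nbins × nbins` (default 60) histogram;

    F = −kT · ln(count / count_max)

so the occupied minimum is exactly 0 (the `raw` convention,
−kT·ln(count), matches unnormalized literature surfaces up to a
constant). kT defaults to k_B·300 K = 2.494 kJ/mol with
k_B = 0.0083145 kJ/(mol·K). Empty bins are NaN. Only free-energy
*differences* are physically meaningful; `relative_depths` is invariant to
adding a constant to all minima and uses the deepest minimum as reference
unless an explicit index is given.

Minima and basins come from a persistence (watershed) flood: occupied bins
are absorbed in ascending F (ties broken lexicographically by bin index),
and a local minimum survives only if its prominence — the barrier height
to a deeper neighboring basin at the merge point — reaches the threshold
(default 0.5 kJ/mol). Every occupied bin drains to exactly one surviving
minimum; a constant surface has no minima by convention. Basins are
labeled A, B, C, … by ascending minimum free energy. Optional Gaussian
smoothing of the counts is applied before flooding when requested.

## Hydrogen bonds and secondary structure

Backbone N–H···O=C bonds use a geometric criterion by default:
N···O ≤ 0.35 nm **and** H–N–O angle ≤ 30° at the donor. Intra-chain pairs
i→i and i→i±1 are excluded; the first residue of a chain (ammonium
terminus) and proline never donate. When the amide hydrogen is absent from
the model it is reconstructed 0.098 nm from N along the in-plane bisector
pointing away from C(prev) and CA. The Kabsch–Sander electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with a
−0.5 kcal/mol threshold is available behind the same interface
(`hb_method="kabsch_sander"`).

Secondary structure uses simplified Kabsch–Sander pattern rules on those
bonds: α-helix from two consecutive i→i+4 turns (marking residues
i+1..i+4), β-bridges from the parallel pattern
(Hb(i−1,j) ∧ Hb(j,i+1)) ∨ (Hb(j−1,i) ∧ Hb(i,j+1)) or the anti-parallel
pattern (Hb(i,j) ∧ Hb(j,i)) ∨ (Hb(i−1,j+1) ∧ Hb(j−1,i+1)), where Hb(p,q)
means the C=O of p accepts from the N–H of q; intra-chain bridges require
|i−j| ≥ 3; helix takes precedence over strand; remaining isolated
3/4/5-turns are labeled T.

Inter-chain contacts: a chain-A/chain-B residue pair is in contact when
the minimum distance between their side-chain heavy atoms (Cα for
glycine) is ≤ 0.54 nm.

Per-frame reaction coordinates (`FrameMetrics`): Lhelix and Lsheet
(residues labeled H/E over both chains), NUMintraHB/NUMinterHB,
NUMcon (contact pairs), cos θ between the chains' Cα end-to-end vectors,
and the polarity-signed statistic NUMinterHB·cos θ.

## States and orientation classes

Regions are the 8 sign patterns of (NUMintraHB > 0, Lhelix > 0,
Lsheet > 0); six carry conventional numerals and the two helix-without-
intra-bond patterns are kept as X1/X2 so the labels partition all frames:

| NUMintraHB>0 | Lhelix>0 | Lsheet>0 | label |
|---|---|---|---|
| yes | yes | no  | VI |
| yes | yes | yes | V  |
| yes | no  | no  | IV |
| yes | no  | yes | III |
| no  | yes | no  | X1 |
| no  | yes | yes | X2 |
| no  | no  | yes | II |
| no  | no  | no  | I  |

Orientation classes: frames without inter-chain bonds are `noHB`; bonded
frames are binned by θ into [0,50), [50,90), [90,130), [130,180] — the
edge overlaps are resolved as half-open, lower-inclusive intervals.
Parallel sheets land in θ[0,50), anti-parallel in θ[130,180].

Window probability tables split frames into consecutive windows (default:
the number of frames spanning 100 ns at the trajectory's frame spacing),
keep a flagged partial final window, and report per-label occupancy;
every row sums to 1. Transition graphs count consecutive-frame label
transitions within contiguous segments; for ensembles demultiplexed from
replica exchange these edges measure state *accessibility*, not kinetics.

## Representative structures

Per basin, pairwise Cα RMSDs (Kabsch superposition: SVD of the
cross-covariance with a determinant guard against reflections) are
clustered with single linkage at a cutoff (default 0.2 nm). The
representative is the member of the largest cluster with the lowest mean
in-cluster RMSD; ties go to the cluster containing the earliest frame and
then to the lowest frame index. Basins larger than 150 frames are
subsampled on an even index grid before clustering to keep the cost
bounded.

## Synthetic generator

The generator emits two-chain frames from five ideal conformers — helix
pair, β-hairpin pair, parallel sheet, anti-parallel sheet, and a
disordered (polyproline-II-like) pair — driven by a discrete Markov chain
plus isotropic per-atom Gaussian noise. Backbones are built by NeRF chain
extension from ideal bond lengths/angles; side chains are a single Cβ
(none for glycine).

Design choices that matter for correctness:

- **Twist-free strands.** Strand torsions are (φ, ψ) = (−140°, 137.5°),
  the β-region combination with an exact two-fold screw for this ideal
  geometry (residual twist 0.012°/residue). Textbook values near
  (−139°, 135°) leave a per-residue twist, so rigid strand copies cannot
  pair into an H-bonded sheet along their whole length.
- **Sheet assembly and refinement.** The partner strand is placed by the
  sheet symmetry operation (translation along the carbonyl direction for
  parallel; a two-fold rotation about the sheet normal for anti-parallel)
  with the register phase chosen by maximizing detected strand residues
  and inter-chain bonds over a discrete scan; a deterministic Nelder–Mead
  rigid-body refinement then pulls every detected inter-chain bond to
  canonical geometry (N···O ≈ 0.29 nm, near-linear N–H···O) under a
  0.22 nm steric guard.
- **Redundant hairpin bridges.** The two-residue hairpin turn torsions
  ((57.9°, −107.8°), (−121.5°, 30.0°)) are numerically tuned so each
  hairpin forms two hydrogen-bonded bridge pairs. Redundancy is the
  robustness lever: at σ = 0.02 nm per-atom noise the H–N–O angle has
  ≈ 11° standard deviation (the short 0.098 nm N–H lever arm amplifies
  positional noise), capping single-bond survival at ≈ 0.85–0.92 per
  frame no matter how ideal the geometry.
- **Exchangeable sampling.** The reference five-state spec uses transition
  rows equal to the stationary distribution (helix 0.05, hairpin 0.30,
  parallel 0.10, anti-parallel 0.45, disordered 0.10), emulating a
  well-equilibrated ensemble whose recorded frames are decorrelated —
  the regime in which plain binomial standard errors for window
  probabilities are valid. Sticky chains are supported for transition-
  graph work.
- **Noise-free depth calibration.** The two-state spec used to check
  ΔF = kT·ln(p₁/p₂) runs at σ = 0: the identity between bin-count depths
  and state populations is exact only for point-mass states.

Same seed ⇒ bit-identical trajectories; ground truth (state index, label,
intended region) is emitted per frame.

## Charge accounting

Formal charges per chain sum side-chain group charges (Lys +1, Arg +1,
Asp −1, Glu −1, His 0 at physiological pH) plus termini (+1/−1). The
acidic scheme protonates Asp/Glu to neutral and His to +1, keeping the
C-terminus deprotonated. α-syn12 is +2 per chain at physiological pH
(4 Cl⁻ for the dimer) and +3 at acidic pH (6 Cl⁻).

## Defaults summary

| Parameter | Default | Unit |
|---|---|---|
| temperature | 300 | K |
| kT | 2.494 (k_B·T) | kJ/mol |
| FES bins per axis | 60 | — |
| minima prominence | 0.5 | kJ/mol |
| H-bond N···O cutoff | 0.35 | nm |
| H-bond H–N–O cutoff | 30 | degrees |
| contact cutoff | 0.54 | nm |
| probability window | frames spanning 100 ns | frames |
| clustering cutoff | 0.2 | nm |
| clustering sample cap | 150 | frames/basin |
| generator noise σ | 0.02 | nm |
| frame spacing | 2 | ps |

## Determinism and the config hash

Every report table begins with `# config_hash=<sha256[:16]>` over the
canonical JSON of the effective configuration (excluding the output
directory, which changes where the report goes, not what is computed).
Floats are written as `%.6g` with −0.0 canonicalized, so identical
configurations produce byte-identical files.
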