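"""Synthetic two-chain peptide trajectories with known ground truth.

The generator emulates the conformational repertoire of a small
aggregating dimer at 300 K: a helix pair, an intra-chain β-hairpin pair,
parallel and anti-parallel inter-chain β-sheets, and a disordered
(polyproline-II-like) pair. A discrete Markov chain over those conformers
plus isotropic per-atom Gaussian coordinate noise yields trajectories for
which every downstream pipeline stage has an exact reference answer.

Backbones are built from ideal bond lengths/angles and per-residue φ/ψ
torsions (NeRF chain extension); side chains are reduced to Cβ except for
glycine. Sheet dimers are assembled by rigid-fitting the second chain
onto in-register targets offset by the inter-strand spacing; the pleat
phase and face are picked deterministically by maximizing the number of
detected inter-backbone hydrogen bonds, so the requested sheet topology
is realized for any chain length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .core import AA_1TO3, ALPHA_SYN12, Chain, Frame, Residue, Trajectory, TrajectoryMetadata, Topology, _frame_coords

# ideal backbone geometry (nm / degrees)
_B_N_CA, _B_CA_C, _B_C_N = 0.1458, 0.1525, 0.1329
_B_C_O, _B_N_H = 0.1231, 0.098
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA = 111.2, 116.2, 121.7
_ANG_CA_C_O = 120.8
_OMEGA = 180.0

#: canonical backbone torsions per conformer element; the strand values are
#: the β-region combination with an exact two-fold screw (no net twist), so
#: ideal strands pair into flat sheets along their whole length
PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-140.0, 137.5),
    "ppii": (-75.0, 145.0),
}
#: two-residue turn connecting the strands of a β-hairpin. The torsions
#: are numerically tuned so the hairpin forms two hydrogen-bonded bridge
#: pairs per chain at canonical geometry (N···O ≈ 0.27–0.30 nm, N–H···O
#: within ~20° of linear); the redundancy keeps the β-bridge signal stable
#: under the generator's coordinate noise.
HAIRPIN_TURN = ((57.9, -107.8), (-121.5, 30.0))

#: inter-strand Cα spacing of an ideal β-sheet, nm
SHEET_SPACING = 0.50

CONFORMER_KINDS = ("helix_pair", "hairpin_pair", "parallel_sheet",
                   "antiparallel_sheet", "disordered")

#: conformational region (truth table over NUMintraHB/Lhelix/Lsheet signs)
#: each generator state is designed to occupy
INTENDED_REGION = {
    "helix_pair": "VI",
    "hairpin_pair": "III",
    "parallel_sheet": "II",
    "antiparallel_sheet": "II",
    "disordered": "I",
}

_DEFAULT_SEPARATION = {
    "helix_pair": 1.5,
    "hairpin_pair": 1.8,
    "parallel_sheet": SHEET_SPACING,
    "antiparallel_sheet": SHEET_SPACING,
    "disordered": 2.5,
}


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom d with given c-d bond, b-c-d angle, a-b-c-d torsion."""
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(theta),
                  bond * np.sin(theta) * np.cos(phi),
                  bond * np.sin(theta) * np.sin(phi)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from backbone N, CA, C (L-configuration)."""
    b = (ca - n) * 10.0      # work in Å: the cross term is not scale-free
    cv = (c - ca) * 10.0
    a = np.cross(b, cv)
    cb = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cv
    return ca + cb / 10.0


def build_chain(sequence: str, phi_psi: list[tuple[float, float]],
                chain_id: str = "A") -> Chain:
    """Build one peptide chain from per-residue (φ, ψ) torsions.

    φ of the first residue is ignored (undefined); ψ of the last residue
    only orients its carbonyl. Side chains are a single Cβ (none for Gly);
    the amide hydrogen is placed for residues 2..n.
    """
    n = len(sequence)
    if n < 4:
        raise ValueError("sequence must have at least 4 residues")
    if len(phi_psi) != n:
        raise ValueError("need one (phi, psi) pair per residue")
    seq3 = []
    for letter in sequence.upper():
        if letter not in AA_1TO3:
            raise ValueError(f"unknown residue letter {letter!r}")
        seq3.append(AA_1TO3[letter])

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _ANG_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(n - 1):
        psi_i = phi_psi[i][1]
        N[i + 1] = _place(N[i], CA[i], C[i], _B_C_N, _ANG_CA_C_N, psi_i)
        CA[i + 1] = _place(CA[i], C[i], N[i + 1], _B_N_CA, _ANG_C_N_CA, _OMEGA)
        C[i + 1] = _place(C[i], N[i + 1], CA[i + 1], _B_CA_C, _ANG_N_CA_C,
                          phi_psi[i + 1][0])

    residues = []
    for i in range(n):
        atoms: dict[str, np.ndarray] = {"N": N[i]}
        if i > 0:
            u = _unit(C[i - 1] - N[i]) + _unit(CA[i] - N[i])
            atoms["H"] = N[i] - _B_N_H * _unit(u)
        atoms["CA"] = CA[i]
        if seq3[i] != "GLY":
            atoms["CB"] = _cbeta(N[i], CA[i], C[i])
        atoms["C"] = C[i]
        atoms["O"] = _place(N[i], CA[i], C[i], _B_C_O, _ANG_CA_C_O,
                            phi_psi[i][1] + 180.0)
        residues.append(Residue(seq3[i], i + 1, atoms))
    return Chain(chain_id, residues)


# ---------------------------------------------------------------------------
# Conformer specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConformerSpec:
    """One ideal dimer conformation the generator can emit."""

    kind: str
    separation: float | None = None   # inter-chain distance, nm
    register: int = 0                 # pairing offset for sheets
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in CONFORMER_KINDS:
            raise ValueError(f"unknown conformer kind {self.kind!r}; "
                             f"choose from {CONFORMER_KINDS}")
        sep = self.separation if self.separation is not None else _DEFAULT_SEPARATION[self.kind]
        if sep <= 0.3:
            raise ValueError("chain separation must exceed 0.3 nm")

    @property
    def effective_separation(self) -> float:
        return self.separation if self.separation is not None else _DEFAULT_SEPARATION[self.kind]

    @property
    def label(self) -> str:
        return self.name or self.kind

    @property
    def intended_region(self) -> str:
        return INTENDED_REGION[self.kind]


def _chain_phi_psi(kind: str, n: int) -> list[tuple[float, float]]:
    if kind == "helix_pair":
        return [PHI_PSI["helix"]] * n
    if kind == "disordered":
        return [PHI_PSI["ppii"]] * n
    if kind in ("parallel_sheet", "antiparallel_sheet"):
        return [PHI_PSI["strand"]] * n
    if kind == "hairpin_pair":
        n_first = (n - 2 + 1) // 2
        n_second = n - 2 - n_first
        return ([PHI_PSI["strand"]] * n_first + list(HAIRPIN_TURN)
                + [PHI_PSI["strand"]] * n_second)
    raise ValueError(kind)


def _chain_coords(chain: Chain) -> tuple[np.ndarray, list[tuple[int, str]]]:
    layout = [(i, name) for i, res in enumerate(chain.residues) for name in res.atoms]
    coords = np.array([chain.residues[i].atoms[name] for i, name in layout])
    return coords, layout


def _apply(chain: Chain, rot: np.ndarray, trans: np.ndarray, chain_id: str) -> Chain:
    residues = [
        Residue(r.name, r.index, {a: rot @ xyz + trans for a, xyz in r.atoms.items()})
        for r in chain.residues
    ]
    return Chain(chain_id, residues)


def _kabsch_transform(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation/translation superposing ``mobile`` onto ``target`` (least squares)."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    u, s, vt = np.linalg.svd((mobile - mc).T @ (target - tc))
    d = np.sign(np.linalg.det((u @ vt).T))
    corr = np.diag([1.0, 1.0, d])
    rot = (u @ corr @ vt).T
    return rot, tc - rot @ mc


def _perp_unit(e: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to e."""
    basis = np.eye(3)
    w = basis[np.argmin(np.abs(e @ basis.T))]
    return _unit(w - (w @ e) * e)


def _strand_frame(chain: Chain) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, np.ndarray]:
    """Strand axis, H-bond direction u (from the carbonyls), sheet normal w,
    per-residue rise and Cα centroid of an ideal strand."""
    ca = np.array([r.atoms["CA"] for r in chain.residues])
    c = chain.residues[0].atoms["C"]
    o = chain.residues[0].atoms["O"]
    axis = _unit(ca[-1] - ca[0])
    co = o - c
    u = _unit(co - (co @ axis) * axis)
    w = _unit(np.cross(axis, u))
    rise = np.linalg.norm(ca[-1] - ca[0]) / (len(ca) - 1)
    return axis, u, w, rise, ca.mean(axis=0)


def _sheet_dimer(sequence: str, spec: ConformerSpec) -> Frame:
    """Place two ideal strands as an H-bonded (anti)parallel sheet.

    The parallel sheet translates the partner along the carbonyl direction;
    the anti-parallel sheet applies the sheet dyad — a two-fold rotation
    about the sheet normal through the midpoint between the strands. The
    residual phase along the strand axis (which controls the hydrogen-bond
    register) is chosen deterministically among sub-rise shifts by
    maximizing strand residues, then inter-chain bonds.
    """
    from .annotation import DEFAULT_CONFIG, assign_secondary_structure, detect_backbone_hbonds

    n = len(sequence)
    if abs(spec.register) >= n - 1:
        raise ValueError(f"register {spec.register} out of range for length {n}")
    anti = spec.kind == "antiparallel_sheet"
    chain_a = build_chain(sequence, _chain_phi_psi(spec.kind, n), "A")
    chain_b0 = build_chain(sequence, _chain_phi_psi(spec.kind, n), "B")
    axis, u, w, rise, centroid = _strand_frame(chain_a)
    sep = spec.effective_separation

    def score(frame: Frame) -> tuple[int, int]:
        _, _, lsheet = assign_secondary_structure(frame, DEFAULT_CONFIG)
        n_inter = sum(hb.is_inter
                      for hb in detect_backbone_hbonds(frame, DEFAULT_CONFIG))
        return lsheet, n_inter

    best: tuple[tuple[int, int], Frame] | None = None
    if anti:
        rot = Rotation.from_rotvec(np.pi * w).as_matrix()
        for phase in spec.register * rise + rise * np.arange(16) / 8.0:
            pivot = centroid + 0.5 * sep * u + phase * axis
            chain_b = _apply(chain_b0, rot, pivot - rot @ pivot, "B")
            frame = Frame([chain_a, chain_b])
            s = score(frame)
            if best is None or s > best[0]:
                best = (s, frame)
    else:
        for side in (1.0, -1.0):
            for shift in spec.register * rise + rise * np.arange(-2, 3) / 4.0:
                chain_b = _apply(chain_b0, np.eye(3),
                                 side * sep * u + shift * axis, "B")
                frame = Frame([chain_a, chain_b])
                s = score(frame)
                if best is None or s > best[0]:
                    best = (s, frame)
    refined = _refine_sheet(best[1])
    return refined if score(refined) >= best[0] else best[1]


#: target hydrogen-bond N···O distance of an ideal sheet, nm
_HB_TARGET_NO = 0.29


def _refine_sheet(frame: Frame) -> Frame:
    """Polish a scanned sheet dimer by rigid-body refinement of chain B.

    The discrete phase scan realizes the right bond topology but leaves the
    hydrogen bonds near the edges of the detection criterion. This stage
    keeps that topology fixed and moves the second chain as a rigid body to
    put every inter-chain bond at canonical geometry (N···O near
    0.29 nm, N–H···O near linear), so the ideal conformers stay robustly
    classifiable under coordinate noise. Deterministic (Nelder–Mead from
    the scanned placement).
    """
    from scipy.optimize import minimize
    from scipy.spatial.distance import cdist

    from .annotation import detect_backbone_hbonds

    chain_a, chain_b = frame.chains
    intended = [(hb.donor, hb.acceptor)
                for hb in detect_backbone_hbonds(frame) if hb.is_inter]
    if not intended:
        return frame

    coords_a, _ = _chain_coords(chain_a)
    coords_b, layout_b = _chain_coords(chain_b)
    center_b = coords_b.mean(axis=0)
    atoms_a = {(r.index, name): xyz for r in chain_a.residues
               for name, xyz in r.atoms.items()}
    index_b = {(chain_b.residues[i].index, name): k
               for k, (i, name) in enumerate(layout_b)}

    # per intended bond: fixed donor-side (N, H) or acceptor-side (O)
    # positions from chain A, and row indices into the moving B array
    bonds = []
    for (dc, dr, _), (ac, ar, _) in intended:
        if dc == chain_a.id:
            bonds.append(("donor_fixed", atoms_a[(dr, "N")], atoms_a[(dr, "H")],
                          index_b[(ar, "O")]))
        else:
            bonds.append(("acceptor_fixed", index_b[(dr, "N")],
                          index_b[(dr, "H")], atoms_a[(ar, "O")]))

    def objective(p: np.ndarray) -> float:
        rot = Rotation.from_rotvec(p[:3]).as_matrix()
        moved = (coords_b - center_b) @ rot.T + center_b + p[3:]
        total = 0.0
        for tag, x1, x2, x3 in bonds:
            if tag == "donor_fixed":
                n_pos, h_pos, o_pos = x1, x2, moved[x3]
            else:
                n_pos, h_pos, o_pos = moved[x1], moved[x2], x3
            no = o_pos - n_pos
            d = np.linalg.norm(no)
            nh = _unit(h_pos - n_pos)
            ang = np.arccos(np.clip(nh @ (no / d), -1.0, 1.0))
            total += ((d - _HB_TARGET_NO) / 0.02) ** 2
            total += (ang / np.radians(10.0)) ** 2
        dmin = cdist(coords_a, moved).min()
        if dmin < 0.22:                       # steric guard
            total += 1e4 * (0.22 - dmin) ** 2
        return total

    res = minimize(objective, np.zeros(6), method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    rot = Rotation.from_rotvec(res.x[:3]).as_matrix()
    chain_b_ref = _apply(chain_b, rot, center_b + res.x[3:] - rot @ center_b,
                         chain_b.id)
    return Frame([chain_a, chain_b_ref])


def build_ideal_dimer(spec: ConformerSpec, sequence: str = ALPHA_SYN12) -> Frame:
    """Construct the ideal two-chain conformation described by ``spec``."""
    n = len(sequence)
    if n < 4:
        raise ValueError("sequence must have at least 4 residues")
    if spec.kind in ("parallel_sheet", "antiparallel_sheet"):
        return _sheet_dimer(sequence, spec)

    chain_a = build_chain(sequence, _chain_phi_psi(spec.kind, n), "A")
    ca = np.array([r.atoms["CA"] for r in chain_a.residues])
    axis = _unit(ca[-1] - ca[0])
    normal = _perp_unit(axis)
    sep = spec.effective_separation
    centroid = ca.mean(axis=0)

    if spec.kind == "helix_pair":
        rot = np.eye(3)
    elif spec.kind == "hairpin_pair":
        # flip the partner hairpin so the two face each other
        rot = Rotation.from_rotvec(np.pi * axis).as_matrix()
    else:  # disordered: skew the partner so the pair has no defined polarity
        rot = Rotation.from_rotvec(0.5 * np.pi * normal).as_matrix()
    trans = centroid + sep * normal - rot @ centroid
    chain_b = _apply(build_chain(sequence, _chain_phi_psi(spec.kind, n), "B"),
                     rot, trans, "B")
    return Frame([chain_a, chain_b])


# ---------------------------------------------------------------------------
# Markov-chain trajectory generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkovSpec:
    """A discrete-state generator: conformers, transition matrix, noise."""

    states: tuple[ConformerSpec, ...]
    transition: np.ndarray
    n_frames: int
    seed: int
    noise_sigma: float = 0.02      # nm, isotropic per-atom Gaussian
    frame_spacing_ps: float = 2.0
    initial: np.ndarray | None = None   # defaults to the stationary distribution

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        s = len(self.states)
        if t.shape != (s, s):
            raise ValueError(f"transition matrix must be {s}x{s}")
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        object.__setattr__(self, "transition", t)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["transition"] = np.asarray(self.transition).tolist()
        if self.initial is not None:
            d["initial"] = np.asarray(self.initial).tolist()
        return d


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution π of a row-stochastic matrix (π P = π)."""
    t = np.asarray(transition, dtype=float)
    w, v = np.linalg.eig(t.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def markov_trajectory(spec: MarkovSpec, sequence: str = ALPHA_SYN12,
                      ) -> tuple[Trajectory, "pd.DataFrame"]:
    """Sample a trajectory from a Markov chain over ideal conformers.

    Returns the trajectory and a ground-truth table with one row per frame
    (state index, state label, intended region label). The same seed always
    yields bit-identical output.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n_states = len(spec.states)
    frames = [build_ideal_dimer(s, sequence) for s in spec.states]
    topology = Topology.from_frame(frames[0])
    ideal = np.stack([_frame_coords(fr, topology) for fr in frames])

    pi0 = (np.asarray(spec.initial, dtype=float) if spec.initial is not None
           else stationary_distribution(spec.transition))
    cum = np.cumsum(spec.transition, axis=1)
    seq = np.empty(spec.n_frames, dtype=int)
    seq[0] = int(np.searchsorted(np.cumsum(pi0), rng.random()))
    u = rng.random(spec.n_frames - 1)
    for k in range(1, spec.n_frames):
        seq[k] = int(np.searchsorted(cum[seq[k - 1]], u[k - 1]))

    coords = ideal[seq]
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    meta = TrajectoryMetadata(temperature=300.0,
                              frame_spacing_ps=spec.frame_spacing_ps)
    traj = Trajectory(topology, coords, metadata=meta)
    truth = pd.DataFrame({
        "frame": np.arange(spec.n_frames),
        "state": seq,
        "label": [spec.states[s].label for s in seq],
        "region": [spec.states[s].intended_region for s in seq],
    })
    return traj, truth


# ---------------------------------------------------------------------------
# Canonical study conditions
# ---------------------------------------------------------------------------

#: stationary populations of the five-state reference ensemble: dominated by
#: anti-parallel sheet (the deepest basin of the real dimer), with substantial
#: hairpin (intra-β) weight, minor parallel-sheet and disordered states, and a
#: small residual helix population.
FIVE_STATE_POPULATIONS = {
    "helix_pair": 0.05,
    "hairpin_pair": 0.30,
    "parallel_sheet": 0.10,
    "antiparallel_sheet": 0.45,
    "disordered": 0.10,
}


def five_state_spec(n_frames: int = 10_000, seed: int = 0,
                    noise_sigma: float = 0.02) -> MarkovSpec:
    """The package's reference five-state generator.

    Transition-matrix rows equal the stationary distribution (exchangeable
    sampling), emulating a well-equilibrated replica-exchange ensemble in
    which recorded frames are decorrelated.
    """
    kinds = list(FIVE_STATE_POPULATIONS)
    pi = np.array([FIVE_STATE_POPULATIONS[k] for k in kinds])
    return MarkovSpec(
        states=tuple(ConformerSpec(k) for k in kinds),
        transition=np.tile(pi, (len(kinds), 1)),
        n_frames=n_frames,
        seed=seed,
        noise_sigma=noise_sigma,
    )


def two_state_spec(n_frames: int = 100_000, seed: int = 0,
                   p: float = 0.7) -> MarkovSpec:
    """Two-state generator used to calibrate free-energy depth differences.

    Noise-free by design: the identity ΔF = kT·ln(p₁/p₂) between basin
    depths and state populations is exact only for point-mass states.
    """
    pi = np.array([p, 1.0 - p])
    return MarkovSpec(
        states=(ConformerSpec("antiparallel_sheet"), ConformerSpec("helix_pair")),
        transition=np.tile(pi, (2, 1)),
        n_frames=n_frames,
        seed=seed,
        noise_sigma=0.0,
    )
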