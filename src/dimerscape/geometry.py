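"""Geometric featurization of dimer frames.

The central feature space is the vector of inverse distances between the
inter-chain side-chain centers of mass: for chain lengths ``n1`` and
``n2`` a frame maps to ``n1 * n2`` strictly positive numbers (144 for a
pair of 12-mers) that completely specify the inter-molecular arrangement
while being invariant under global rotation and translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import BACKBONE_ATOMS, ELEMENT_MASSES, Frame, Residue, Topology, Trajectory, element_of

#: atoms never counted as side chain (backbone + terminal variants)
_NON_SIDECHAIN = set(BACKBONE_ATOMS) | {"OXT", "H1", "H2", "H3"}

#: maximum plausible intra-chain C(i)–N(i+1) peptide-bond length; anything
#: longer indicates a broken (e.g. PBC-wrapped) molecule.
MAX_PEPTIDE_BOND_NM = 0.25

#: side-chain centers closer than this are treated as non-physical overlap
MIN_CENTER_DISTANCE_NM = 1e-6


# ---------------------------------------------------------------------------
# Side-chain centers
# ---------------------------------------------------------------------------


def _sidechain_atoms(residue: Residue) -> list[str]:
    return [
        name for name in residue.atoms
        if name not in _NON_SIDECHAIN and element_of(name) != "H"
    ]


def sidechain_center(residue: Residue) -> np.ndarray:
    """Mass-weighted center of the side-chain heavy atoms (nm).

    Glycine — and, as a fallback, any residue whose side chain is absent
    from the model — uses its Cα position as proxy.
    """
    names = _sidechain_atoms(residue)
    if residue.name == "GLY" or not names:
        if "CA" not in residue.atoms:
            raise ValueError(
                f"residue {residue.name}{residue.index} has neither side-chain "
                "atoms nor a CA atom")
        return residue.atoms["CA"].copy()
    masses = np.array([ELEMENT_MASSES[element_of(n)] for n in names])
    coords = np.array([residue.atoms[n] for n in names])
    return masses @ coords / masses.sum()


class SidechainIndex:
    """Per-topology atom indices and masses for vectorized center computation."""

    def __init__(self, topology: Topology) -> None:
        self.groups: list[list[tuple[np.ndarray, np.ndarray]]] = []
        for ch in topology.chains:
            chain_groups = []
            for res in ch.residues:
                side = [
                    (off, ELEMENT_MASSES[element_of(name)])
                    for name, off in zip(res.atom_names, res.atom_offsets)
                    if name not in _NON_SIDECHAIN and element_of(name) != "H"
                ]
                if res.name == "GLY" or not side:
                    ca = res.offset_of("CA")
                    if ca is None:
                        raise ValueError(
                            f"residue {res.name}{res.index} has neither "
                            "side-chain atoms nor a CA atom")
                    side = [(ca, 1.0)]
                idx = np.array([s[0] for s in side], dtype=int)
                w = np.array([s[1] for s in side], dtype=float)
                chain_groups.append((idx, w / w.sum()))
            self.groups.append(chain_groups)

    def centers(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Side-chain centers for coords of shape (..., n_atoms, 3).

        Returns two arrays of shape (..., n_res_chain, 3).
        """
        out = []
        for chain_groups in self.groups:
            cen = np.stack(
                [np.tensordot(coords[..., idx, :], w, axes=([-2], [0]))
                 for idx, w in chain_groups],
                axis=-2,
            )
            out.append(cen)
        return out[0], out[1]


# ---------------------------------------------------------------------------
# Whole-molecule guard
# ---------------------------------------------------------------------------


def check_chain_continuity(frame: Frame) -> None:
    """Raise if any intra-chain peptide bond exceeds the plausible maximum.

    Input models are assumed whole (no periodic-boundary wrapping); a
    stretched C(i)–N(i+1) distance is the fingerprint of a broken molecule.
    """
    for ch in frame.chains:
        for a, b in zip(ch.residues, ch.residues[1:]):
            if "C" in a.atoms and "N" in b.atoms:
                d = float(np.linalg.norm(b.atoms["N"] - a.atoms["C"]))
                if d > MAX_PEPTIDE_BOND_NM:
                    raise ValueError(
                        f"chain {ch.id}: peptide bond {a.name}{a.index}-"
                        f"{b.name}{b.index} is {d:.3f} nm (> "
                        f"{MAX_PEPTIDE_BOND_NM} nm); molecule appears broken")


# ---------------------------------------------------------------------------
# Inverse-distance features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureVector:
    """Flattened row-major grid of inter-chain inverse distances (nm⁻¹)."""

    values: np.ndarray
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.values.shape != (self.n1 * self.n2,):
            raise ValueError("feature length must equal n1 * n2")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("inverse distances must be finite and positive")

    def as_grid(self) -> np.ndarray:
        return self.values.reshape(self.n1, self.n2)

    @property
    def labels(self) -> list[str]:
        return [f"invd_{i + 1}_{j + 1}"
                for i in range(self.n1) for j in range(self.n2)]


def inverse_distance_vector(frame: Frame, check_continuity: bool = True) -> FeatureVector:
    """Inverse distances between all inter-chain side-chain center pairs.

    Component ``(i, j)`` is ``1 / ||c_i^A - c_j^B||``, flattened row-major
    over chain-A residue index.
    """
    if check_continuity:
        check_chain_continuity(frame)
    ca_chain, cb_chain = frame.chains
    centers_a = np.array([sidechain_center(r) for r in ca_chain.residues])
    centers_b = np.array([sidechain_center(r) for r in cb_chain.residues])
    d = cdist(centers_a, centers_b)
    if d.min() < MIN_CENTER_DISTANCE_NM:
        raise ValueError("coincident side-chain centers (distance < 1e-6 nm)")
    return FeatureVector(1.0 / d.ravel(), len(centers_a), len(centers_b))


def feature_matrix(traj: Trajectory) -> tuple[np.ndarray, tuple[int, int]]:
    """Inverse-distance features for every frame, shape (n_frames, n1*n2)."""
    index = SidechainIndex(traj.topology)
    centers_a, centers_b = index.centers(traj.coords)
    diff = centers_a[:, :, None, :] - centers_b[:, None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=-1))
    if d.min() < MIN_CENTER_DISTANCE_NM:
        raise ValueError("coincident side-chain centers (distance < 1e-6 nm)")
    n1, n2 = d.shape[1], d.shape[2]
    # continuity guard, vectorized over frames
    for chain in traj.topology.chains:
        c_idx = [r.offset_of("C") for r in chain.residues[:-1]]
        n_idx = [r.offset_of("N") for r in chain.residues[1:]]
        keep = [(c, n) for c, n in zip(c_idx, n_idx) if c is not None and n is not None]
        if keep:
            ci = np.array([k[0] for k in keep])
            ni = np.array([k[1] for k in keep])
            bond = np.linalg.norm(traj.coords[:, ni, :] - traj.coords[:, ci, :], axis=-1)
            if bond.max() > MAX_PEPTIDE_BOND_NM:
                f, b = np.unravel_index(np.argmax(bond), bond.shape)
                raise ValueError(
                    f"frame {f}, chain {chain.id}: peptide bond after residue "
                    f"{b + 1} is {bond[f, b]:.3f} nm; molecule appears broken")
    return (1.0 / d).reshape(len(traj), n1 * n2), (n1, n2)


# ---------------------------------------------------------------------------
# End-to-end orientation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrientationState:
    """End-to-end vectors of both chains and the angle between them."""

    e1: np.ndarray
    e2: np.ndarray
    cos_theta: float

    @property
    def theta_deg(self) -> float:
        return float(np.degrees(np.arccos(np.clip(self.cos_theta, -1.0, 1.0))))


def _end_to_end(chain_residues) -> np.ndarray:
    first, last = chain_residues[0], chain_residues[-1]
    if "CA" not in first.atoms or "CA" not in last.atoms:
        raise ValueError("end-to-end vector needs CA atoms on both terminal residues")
    e = last.atoms["CA"] - first.atoms["CA"]
    if np.linalg.norm(e) < 1e-9:
        raise ValueError("zero-length end-to-end vector")
    return e


def orientation(frame: Frame) -> OrientationState:
    """Angle between the two chains' Cα end-to-end vectors.

    θ near 0° marks a parallel arrangement, θ near 180° an anti-parallel one.
    """
    e1 = _end_to_end(frame.chains[0].residues)
    e2 = _end_to_end(frame.chains[1].residues)
    cos = float(e1 @ e2 / (np.linalg.norm(e1) * np.linalg.norm(e2)))
    return OrientationState(e1, e2, float(np.clip(cos, -1.0, 1.0)))


def orientation_series(traj: Trajectory) -> np.ndarray:
    """cos θ for every frame (vectorized)."""
    cos_list = []
    vecs = []
    for ch in traj.topology.chains:
        a = ch.residues[0].offset_of("CA")
        b = ch.residues[-1].offset_of("CA")
        if a is None or b is None:
            raise ValueError("end-to-end vector needs CA atoms on terminal residues")
        vecs.append(traj.coords[:, b, :] - traj.coords[:, a, :])
    e1, e2 = vecs
    n1 = np.linalg.norm(e1, axis=1)
    n2 = np.linalg.norm(e2, axis=1)
    if np.any(n1 < 1e-9) or np.any(n2 < 1e-9):
        raise ValueError("zero-length end-to-end vector")
    return np.clip(np.sum(e1 * e2, axis=1) / (n1 * n2), -1.0, 1.0)


# ---------------------------------------------------------------------------
# Kabsch superposition RMSD
# ---------------------------------------------------------------------------


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum RMSD (nm) between two point sets over rigid-body superposition.

    Uses the Kabsch algorithm (SVD of the cross-covariance with a
    determinant correction against improper rotations).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (N, 3); got {a.shape} and {b.shape}")
    if a.shape[0] < 3:
        raise ValueError("need at least three points for superposition")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, s, vt = np.linalg.svd(a.T @ b)
    sign = np.sign(np.linalg.det(u @ vt))
    s[-1] *= sign
    # RMSD² = (|a|² + |b|² − 2 Σ singular values) / N
    msd = (np.sum(a * a) + np.sum(b * b) - 2.0 * np.sum(s)) / a.shape[0]
    return float(np.sqrt(max(msd, 0.0)))
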