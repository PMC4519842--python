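"""Per-frame structural annotation.

Backbone hydrogen bonds (N-H···O=C) are detected with a geometric
criterion — donor–acceptor distance and hydrogen–donor–acceptor angle —
or, alternatively, with the Kabsch–Sander electrostatic energy. Secondary
structure follows simplified Kabsch–Sander pattern rules on those bonds:
α-helix from consecutive i→i+4 turns, strand from parallel/anti-parallel
bridge patterns (intra- or inter-chain), turn from isolated 3/4/5-turns.

The per-frame reaction coordinates collected in :class:`FrameMetrics`
(Lhelix, Lsheet, NUMintraHB, NUMinterHB, NUMcon, cos θ and the
orientation-signed inter-bond count) are the coordinates on which the
discrete conformational states of the dimer are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Frame, Topology, Trajectory, element_of
from .geometry import orientation, orientation_series

_KS_COUPLING = 0.084 * 332.0   # kcal·Å/mol, Kabsch–Sander electrostatic prefactor
_NH_BOND_NM = 0.098            # amide N-H bond length used for reconstruction


@dataclass(frozen=True)
class AnnotationConfig:
    """Cutoffs for hydrogen bonds and side-chain contacts.

    ``hb_method`` selects between the geometric criterion (donor–acceptor
    distance ≤ ``hb_distance_cutoff`` nm and H–donor–acceptor angle ≤
    ``hb_angle_cutoff`` degrees) and the Kabsch–Sander energy criterion
    (E ≤ ``ks_energy_cutoff`` kcal/mol).
    """

    hb_distance_cutoff: float = 0.35    # nm, N···O
    hb_angle_cutoff: float = 30.0       # degrees, angle(H, N, O) at the donor
    hb_method: str = "geometric"        # or "kabsch_sander"
    ks_energy_cutoff: float = -0.5      # kcal/mol
    contact_cutoff: float = 0.54        # nm, min side-chain heavy-atom distance

    def __post_init__(self) -> None:
        if self.hb_method not in ("geometric", "kabsch_sander"):
            raise ValueError(f"unknown hb_method {self.hb_method!r}")
        if self.hb_distance_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


DEFAULT_CONFIG = AnnotationConfig()


@dataclass(frozen=True)
class HBond:
    """A backbone N-H···O=C hydrogen bond."""

    donor: tuple[str, int, str]      # (chain id, residue index, "N")
    acceptor: tuple[str, int, str]   # (chain id, residue index, "O")
    hydrogen: str = "H"
    is_inter: bool = False
    # global residue positions (chain A residues first), used by pattern rules
    donor_pos: int = -1
    acceptor_pos: int = -1


@dataclass(frozen=True)
class FrameMetrics:
    """The scalar reaction coordinates of one frame."""

    Lhelix: int
    Lsheet: int
    NUMintraHB: int
    NUMinterHB: int
    NUMcon: int
    cos_theta: float

    @property
    def theta_deg(self) -> float:
        return float(np.degrees(np.arccos(np.clip(self.cos_theta, -1.0, 1.0))))

    @property
    def signed_interHB(self) -> float:
        return self.NUMinterHB * self.cos_theta


@dataclass
class HBProbabilityMap:
    """Residue-pair hydrogen-bond occupancy over a frame window."""

    matrix: np.ndarray
    kind: str                      # "intra" or "inter"
    window: tuple[int, int]        # [start, stop) frame range

    def __post_init__(self) -> None:
        if self.kind not in ("intra", "inter"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("occupancies must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Backbone index: per-topology atom bookkeeping
# ---------------------------------------------------------------------------


class BackboneIndex:
    """Flat per-residue backbone atom indices for a two-chain topology."""

    def __init__(self, topology: Topology) -> None:
        chain_ids, res_index, res_name = [], [], []
        idx = {a: [] for a in ("N", "H", "CA", "C", "O")}
        chain_of, prev_in_chain = [], []
        g = 0
        for ci, ch in enumerate(topology.chains):
            for k, res in enumerate(ch.residues):
                chain_ids.append(ch.id)
                res_index.append(res.index)
                res_name.append(res.name)
                chain_of.append(ci)
                prev_in_chain.append(g - 1 if k > 0 else -1)
                for a in idx:
                    off = res.offset_of(a)
                    idx[a].append(off if off is not None else -1)
                g += 1
        self.n_res = g
        self.chain_id = chain_ids
        self.res_index = np.array(res_index)
        self.res_name = res_name
        self.chain_of = np.array(chain_of)
        self.prev = np.array(prev_in_chain)
        self.idx = {a: np.array(v) for a, v in idx.items()}
        self.chain_lengths = tuple(len(ch.residues) for ch in topology.chains)
        # side-chain heavy atoms (Gly → CA proxy) for contact counting
        self.side_atoms: list[np.ndarray] = []
        for ch in topology.chains:
            for res in ch.residues:
                side = [off for name, off in zip(res.atom_names, res.atom_offsets)
                        if name not in ("N", "H", "CA", "C", "O", "OXT", "H1", "H2", "H3")
                        and element_of(name) != "H"]
                if res.name == "GLY" or not side:
                    ca = res.offset_of("CA")
                    side = [ca] if ca is not None else []
                self.side_atoms.append(np.array(side, dtype=int))

    def same_chain(self, i: int, j: int) -> bool:
        return self.chain_of[i] == self.chain_of[j]


def _gather(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """coords rows at idx; rows with idx == -1 become NaN."""
    out = np.full((len(idx), 3), np.nan)
    ok = idx >= 0
    out[ok] = coords[idx[ok]]
    return out


def _backbone_coords(coords: np.ndarray, bb: BackboneIndex) -> dict[str, np.ndarray]:
    """Per-residue backbone coordinates with amide H reconstructed if absent.

    The amide hydrogen is placed 0.098 nm from N along the in-plane
    bisector pointing away from both C(prev) and CA — the standard
    geometric reconstruction for PDB models lacking hydrogens. The first
    residue of each chain (ammonium terminus) gets no amide H and is never
    used as a donor.
    """
    arr = {a: _gather(coords, bb.idx[a]) for a in ("N", "H", "CA", "C", "O")}
    h = arr["H"]
    missing = ~np.isfinite(h[:, 0])
    for i in np.flatnonzero(missing):
        p = bb.prev[i]
        if p < 0:
            continue
        n, ca = arr["N"][i], arr["CA"][i]
        c_prev = arr["C"][p]
        if not (np.all(np.isfinite(n)) and np.all(np.isfinite(ca))
                and np.all(np.isfinite(c_prev))):
            continue
        u = (c_prev - n) / np.linalg.norm(c_prev - n) + (ca - n) / np.linalg.norm(ca - n)
        h[i] = n - _NH_BOND_NM * u / np.linalg.norm(u)
    return arr


# ---------------------------------------------------------------------------
# Hydrogen-bond detection
# ---------------------------------------------------------------------------


def _hbond_matrix(arr: dict[str, np.ndarray], bb: BackboneIndex,
                  config: AnnotationConfig) -> np.ndarray:
    """Boolean matrix M[d, a]: N-H of residue d donates to C=O of residue a.

    Intra-chain pairs d == a and d == a ± 1 are excluded; the first residue
    of a chain and prolines never donate.
    """
    n, h, c, o = arr["N"], arr["H"], arr["C"], arr["O"]
    donor_ok = (np.isfinite(n[:, 0]) & np.isfinite(h[:, 0]) & (bb.prev >= 0)
                & np.array([name != "PRO" for name in bb.res_name]))
    acceptor_ok = np.isfinite(o[:, 0]) & np.isfinite(c[:, 0])

    valid = donor_ok[:, None] & acceptor_ok[None, :]
    same = bb.chain_of[:, None] == bb.chain_of[None, :]
    pos = np.arange(bb.n_res)
    near = np.abs(pos[:, None] - pos[None, :]) <= 1
    valid &= ~(same & near)

    if config.hb_method == "geometric":
        d_no = np.linalg.norm(n[:, None, :] - o[None, :, :], axis=-1)
        with np.errstate(invalid="ignore"):
            hit = valid & (d_no <= config.hb_distance_cutoff)
            if hit.any():
                nh = h - n
                nh /= np.linalg.norm(nh, axis=-1, keepdims=True)
                no = o[None, :, :] - n[:, None, :]
                no = no / np.maximum(d_no[..., None], 1e-12)
                cos_angle = np.einsum("dk,dak->da", np.nan_to_num(nh), np.nan_to_num(no))
                cos_cut = np.cos(np.radians(config.hb_angle_cutoff))
                hit &= cos_angle >= cos_cut
        return hit
    # Kabsch–Sander electrostatic energy, distances in Å
    def dist(a, b):
        return 10.0 * np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = _KS_COUPLING * (1.0 / dist(n, o) + 1.0 / dist(h, c)
                            - 1.0 / dist(h, o) - 1.0 / dist(n, c))
        hit = valid & (e <= config.ks_energy_cutoff)
    return hit


def _bonds_from_matrix(m: np.ndarray, bb: BackboneIndex) -> list[HBond]:
    bonds = []
    for d, a in zip(*np.nonzero(m)):
        bonds.append(HBond(
            donor=(bb.chain_id[d], int(bb.res_index[d]), "N"),
            acceptor=(bb.chain_id[a], int(bb.res_index[a]), "O"),
            is_inter=not bb.same_chain(d, a),
            donor_pos=int(d), acceptor_pos=int(a),
        ))
    return bonds


def detect_backbone_hbonds(frame: Frame,
                           config: AnnotationConfig = DEFAULT_CONFIG) -> list[HBond]:
    """All backbone N-H···O=C hydrogen bonds of a frame."""
    from .core import Topology, _frame_coords
    topology = Topology.from_frame(frame)
    coords = _frame_coords(frame, topology)
    bb = BackboneIndex(topology)
    arr = _backbone_coords(coords, bb)
    return _bonds_from_matrix(_hbond_matrix(arr, bb, config), bb)


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------


def _ss_labels(m: np.ndarray, bb: BackboneIndex) -> list[str]:
    """Per-residue {H, E, T, C} labels from the donor→acceptor bond matrix."""
    n = bb.n_res
    # Hb(i, j): C=O of i accepts from N-H of j
    def hb(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and bool(m[j, i])

    def same(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and bb.same_chain(i, j)

    labels = ["C"] * n

    # α-helix: two consecutive 4-turns make residues i+1..i+4 helical
    turn = {k: set() for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n):
            if same(i, i + k) and hb(i, i + k):
                turn[k].add(i)
    # turns at i-1 and i make residues i+1 .. i+4 helical
    helical = set()
    for i in turn[4]:
        if i - 1 in turn[4]:
            helical.update(range(i + 1, i + 5))
    for i in helical:
        labels[i] = "H"

    # β-bridges: derive candidate pairs from observed bonds, then test patterns
    bonds = list(zip(*np.nonzero(m)))   # (donor, acceptor)
    candidates = set()
    for d, a in bonds:
        p, q = int(a), int(d)           # Hb(p, q)
        for i, j in ((p, q), (q, p), (p + 1, q - 1), (q - 1, p + 1),
                     (p + 1, q), (q - 1, p), (q, p + 1), (p, q - 1)):
            if 0 <= i < n and 0 <= j < n and i != j:
                candidates.add((min(i, j), max(i, j)))

    def bridge(i: int, j: int) -> bool:
        if same(i, j) and abs(i - j) < 3:
            return False
        im1, ip1 = (i - 1 if same(i, i - 1) else -9), (i + 1 if same(i, i + 1) else -9)
        jm1, jp1 = (j - 1 if same(j, j - 1) else -9), (j + 1 if same(j, j + 1) else -9)
        para = (hb(im1, j) and hb(j, ip1)) or (hb(jm1, i) and hb(i, jp1))
        anti = (hb(i, j) and hb(j, i)) or (hb(im1, jp1) and hb(jm1, ip1))
        return para or anti

    for i, j in candidates:
        if bridge(i, j):
            for k in (i, j):
                if labels[k] != "H":     # helix takes precedence over strand
                    labels[k] = "E"

    # isolated turns
    for k in (3, 4, 5):
        for i in turn[k]:
            for r in range(i + 1, i + k):
                if labels[r] == "C":
                    labels[r] = "T"
    return labels


def assign_secondary_structure(frame: Frame,
                               config: AnnotationConfig = DEFAULT_CONFIG,
                               ) -> tuple[list[list[str]], int, int]:
    """Per-residue secondary-structure labels plus (Lhelix, Lsheet).

    Returns one label list per chain; Lhelix/Lsheet count H/E residues over
    both chains.
    """
    from .core import Topology, _frame_coords
    topology = Topology.from_frame(frame)
    coords = _frame_coords(frame, topology)
    bb = BackboneIndex(topology)
    arr = _backbone_coords(coords, bb)
    labels = _ss_labels(_hbond_matrix(arr, bb, config), bb)
    n1 = bb.chain_lengths[0]
    per_chain = [labels[:n1], labels[n1:]]
    return per_chain, labels.count("H"), labels.count("E")


# ---------------------------------------------------------------------------
# Inter-chain side-chain contacts
# ---------------------------------------------------------------------------


def _contact_count(coords: np.ndarray, bb: BackboneIndex,
                   cutoff: float) -> tuple[list[tuple[int, int]], int]:
    n1, n2 = bb.chain_lengths
    pairs = []
    for i in range(n1):
        ai = bb.side_atoms[i]
        if len(ai) == 0:
            continue
        pa = coords[ai]
        for j in range(n2):
            aj = bb.side_atoms[n1 + j]
            if len(aj) == 0:
                continue
            pb = coords[aj]
            d2 = np.sum((pa[:, None, :] - pb[None, :, :]) ** 2, axis=-1)
            if d2.min() <= cutoff * cutoff:
                pairs.append((i + 1, j + 1))
    return pairs, len(pairs)


def interchain_contacts(frame: Frame, cutoff: float = DEFAULT_CONFIG.contact_cutoff,
                        ) -> tuple[list[tuple[int, int]], int]:
    """Residue pairs (1-based, chain A × chain B) whose side chains touch.

    A contact is a minimum side-chain heavy-atom distance ≤ ``cutoff``;
    glycine participates through its Cα proxy.
    """
    from .core import Topology, _frame_coords
    topology = Topology.from_frame(frame)
    coords = _frame_coords(frame, topology)
    bb = BackboneIndex(topology)
    return _contact_count(coords, bb, cutoff)


# ---------------------------------------------------------------------------
# Frame metrics
# ---------------------------------------------------------------------------


def frame_metrics(frame: Frame,
                  config: AnnotationConfig = DEFAULT_CONFIG) -> FrameMetrics:
    """Assemble all scalar reaction coordinates for one frame."""
    from .core import Topology, _frame_coords
    topology = Topology.from_frame(frame)
    coords = _frame_coords(frame, topology)
    bb = BackboneIndex(topology)
    arr = _backbone_coords(coords, bb)
    m = _hbond_matrix(arr, bb, config)
    labels = _ss_labels(m, bb)
    inter = ~(bb.chain_of[:, None] == bb.chain_of[None, :])
    num_inter = int(np.count_nonzero(m & inter))
    num_intra = int(np.count_nonzero(m) - num_inter)
    _, numcon = _contact_count(coords, bb, config.contact_cutoff)
    cos = orientation(frame).cos_theta
    return FrameMetrics(labels.count("H"), labels.count("E"),
                        num_intra, num_inter, numcon, cos)


def trajectory_metrics(traj: Trajectory,
                       config: AnnotationConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Frame metrics for a whole trajectory (vectorized bookkeeping).

    Returns a DataFrame with one row per frame and columns ``Lhelix``,
    ``Lsheet``, ``NUMintraHB``, ``NUMinterHB``, ``NUMcon``, ``cos_theta``,
    ``theta_deg`` and ``signed_interHB``.
    """
    bb = BackboneIndex(traj.topology)
    cos = orientation_series(traj)
    inter_mask = ~(bb.chain_of[:, None] == bb.chain_of[None, :])
    rows = []
    for f in range(len(traj)):
        coords = traj.coords[f]
        arr = _backbone_coords(coords, bb)
        m = _hbond_matrix(arr, bb, config)
        labels = _ss_labels(m, bb)
        num_inter = int(np.count_nonzero(m & inter_mask))
        num_intra = int(np.count_nonzero(m) - num_inter)
        _, numcon = _contact_count(coords, bb, config.contact_cutoff)
        rows.append((labels.count("H"), labels.count("E"),
                     num_intra, num_inter, numcon, cos[f]))
    df = pd.DataFrame(rows, columns=["Lhelix", "Lsheet", "NUMintraHB",
                                     "NUMinterHB", "NUMcon", "cos_theta"])
    df["theta_deg"] = np.degrees(np.arccos(np.clip(df["cos_theta"], -1, 1)))
    df["signed_interHB"] = df["NUMinterHB"] * df["cos_theta"]
    return df


# ---------------------------------------------------------------------------
# Hydrogen-bond probability maps
# ---------------------------------------------------------------------------


def hb_probability_maps(traj: Trajectory,
                        window: tuple[int, int] | None = None,
                        config: AnnotationConfig = DEFAULT_CONFIG,
                        ) -> tuple[HBProbabilityMap, HBProbabilityMap]:
    """Intra- and inter-chain hydrogen-bond occupancy maps over a window.

    The intra map entry (i, j) is the fraction of window frames in which
    either chain has a backbone bond donated by residue i to residue j
    (direction kept). The inter map entry (i, j) counts bonds between
    chain-A residue i and chain-B residue j in either direction
    (symmetrized). Indices are 0-based residue positions within a chain.
    """
    start, stop = window if window is not None else (0, len(traj))
    if not 0 <= start < stop <= len(traj):
        raise ValueError(f"empty or out-of-range window {window}")
    bb = BackboneIndex(traj.topology)
    n1, n2 = bb.chain_lengths
    n = max(n1, n2)
    intra = np.zeros((n, n))
    inter = np.zeros((n1, n2))
    for f in range(start, stop):
        arr = _backbone_coords(traj.coords[f], bb)
        m = _hbond_matrix(arr, bb, config)
        seen_intra, seen_inter = set(), set()
        for d, a in zip(*np.nonzero(m)):
            if bb.same_chain(d, a):
                dp = d - (0 if bb.chain_of[d] == 0 else n1)
                ap = a - (0 if bb.chain_of[a] == 0 else n1)
                seen_intra.add((dp, ap))
            else:
                ia = (d if bb.chain_of[d] == 0 else a)
                ib = (a if bb.chain_of[d] == 0 else d)
                seen_inter.add((ia, ib - n1))
        for key in seen_intra:
            intra[key] += 1
        for key in seen_inter:
            inter[key] += 1
    nf = stop - start
    return (HBProbabilityMap(intra / nf, "intra", (start, stop)),
            HBProbabilityMap(inter / nf, "inter", (start, stop)))


def ss_propensity(traj: Trajectory,
                  config: AnnotationConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-residue secondary-structure propensities over a trajectory.

    One row per (chain, residue), columns = fraction of frames labeled
    H/E/T/C.
    """
    bb = BackboneIndex(traj.topology)
    counts = np.zeros((bb.n_res, 4))
    order = {"H": 0, "E": 1, "T": 2, "C": 3}
    for f in range(len(traj)):
        arr = _backbone_coords(traj.coords[f], bb)
        labels = _ss_labels(_hbond_matrix(arr, bb, config), bb)
        for r, lab in enumerate(labels):
            counts[r, order[lab]] += 1
    frac = counts / len(traj)
    return pd.DataFrame({
        "chain": bb.chain_id,
        "residue": bb.res_index,
        "name": bb.res_name,
        "H": frac[:, 0], "E": frac[:, 1], "T": frac[:, 2], "C": frac[:, 3],
    })
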