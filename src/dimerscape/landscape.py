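"""Free-energy landscapes over collective coordinates.

The pipeline projects inverse-distance features (or sin/cos-transformed
backbone dihedrals, dPCA) onto their leading principal components and
converts the 2-D occupancy histogram into a free-energy surface
F = −kT·ln(P). Only free-energy *differences* are physically meaningful,
so the surface is max-normalized by default (the occupied minimum is 0)
with the raw −kT·ln(counts) convention available for comparison with
unnormalized literature values.

Basins are extracted with a persistence (watershed) flood: occupied bins
are absorbed in order of increasing F, and a local minimum survives only
if its prominence — the barrier to a deeper neighbor basin — exceeds a
threshold. Every occupied bin drains to exactly one surviving minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import squareform

from .core import Trajectory
from .geometry import kabsch_rmsd

#: Boltzmann constant, kJ/(mol·K)
KB_KJ_PER_MOL_K = 0.0083145


def thermal_energy(temperature: float = 300.0) -> float:
    """kT in kJ/mol at the given temperature (2.494 kJ/mol at 300 K)."""
    return KB_KJ_PER_MOL_K * temperature


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PCAModel:
    """Principal components of a feature covariance.

    ``components`` rows are orthonormal and sorted by decreasing explained
    variance; signs are fixed so each component's largest-magnitude loading
    is positive (a reproducibility convention — PCA signs are arbitrary).
    """

    mean: np.ndarray
    components: np.ndarray        # (k, n_features)
    eigenvalues: np.ndarray       # variances along components, non-increasing
    variance_fractions: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(x: np.ndarray) -> PCAModel:
    """Fit a PCA model (centered covariance eigendecomposition via SVD)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 frames and 2 features")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    mean = x.mean(axis=0)
    xc = x - mean
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s ** 2 / (x.shape[0] - 1)
    if eig.sum() <= 0:
        raise ValueError("rank-0 input: all frames are identical")
    # deterministic sign: largest-magnitude loading positive
    flip = np.array([np.sign(row[np.argmax(np.abs(row))]) or 1.0 for row in vt])
    vt = vt * flip[:, None]
    return PCAModel(mean=mean, components=vt, eigenvalues=eig,
                    variance_fractions=eig / eig.sum())


def project(model: PCAModel, x: np.ndarray, k: int = 2) -> np.ndarray:
    """Scores of ``x`` on the first ``k`` principal components."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.mean.shape[0]:
        raise ValueError(f"feature dimension mismatch: model expects "
                         f"{model.mean.shape[0]}, got {x.shape}")
    if not 1 <= k <= model.n_components:
        raise ValueError(f"k must be in [1, {model.n_components}], got {k}")
    return (x - model.mean) @ model.components[:k].T


def dpca_features(traj: Trajectory) -> np.ndarray:
    """(sin, cos) transforms of all backbone φ/ψ dihedrals, per frame.

    φ is defined for residues 2..n and ψ for residues 1..n−1 of each chain;
    each angle contributes a (sin, cos) pair, giving 8(n−1) features for a
    pair of equal-length chains.
    """
    feats = []
    for ch in traj.topology.chains:
        n_idx = [r.offset_of("N") for r in ch.residues]
        ca_idx = [r.offset_of("CA") for r in ch.residues]
        c_idx = [r.offset_of("C") for r in ch.residues]
        if any(i is None for i in n_idx + ca_idx + c_idx):
            raise ValueError(f"chain {ch.id}: incomplete backbone (N/CA/C needed)")
        co = traj.coords
        # φ_i: C(i−1), N(i), CA(i), C(i) for i = 2..n
        phi = _dihedrals(co[:, c_idx[:-1]], co[:, n_idx[1:]],
                         co[:, ca_idx[1:]], co[:, c_idx[1:]])
        # ψ_i: N(i), CA(i), C(i), N(i+1) for i = 1..n−1
        psi = _dihedrals(co[:, n_idx[:-1]], co[:, ca_idx[:-1]],
                         co[:, c_idx[:-1]], co[:, n_idx[1:]])
        ang = np.concatenate([phi, psi], axis=1)
        feats.append(np.sin(ang))
        feats.append(np.cos(ang))
    return np.concatenate(feats, axis=1)


def _dihedrals(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angles (radians) for stacked point quadruples."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2u)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.arctan2(y, x)


# ---------------------------------------------------------------------------
# Free-energy surface
# ---------------------------------------------------------------------------


@dataclass
class FESGrid:
    """A 2-D binned free-energy surface in kJ/mol.

    ``F`` is NaN on empty bins. With the default max-normalized convention
    the occupied minimum is exactly 0; the ``raw`` convention stores
    −kT·ln(counts), matching unnormalized literature surfaces up to a
    constant.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray
    counts: np.ndarray
    kT: float
    convention: str = "normalized"

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def bin_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bin indices of score pairs (values on the top edge fall inward)."""
        ix = np.clip(np.searchsorted(self.x_edges, x, side="right") - 1,
                     0, len(self.x_edges) - 2)
        iy = np.clip(np.searchsorted(self.y_edges, y, side="right") - 1,
                     0, len(self.y_edges) - 2)
        return ix, iy


def fes_from_projection(x: np.ndarray, y: np.ndarray, nbins: int = 60,
                        kT: float = thermal_energy(300.0),
                        convention: str = "normalized") -> FESGrid:
    """Free-energy surface F = −kT·ln(count/count_max) on an nbins² grid."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("score vectors must have equal length")
    if nbins < 5:
        raise ValueError("nbins must be at least 5")
    if convention not in ("normalized", "raw"):
        raise ValueError(f"unknown convention {convention!r}")
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=nbins)
    if np.count_nonzero(counts) == 1:
        warnings.warn("degenerate surface: all frames fall into a single bin",
                      stacklevel=2)
    f = np.full_like(counts, np.nan)
    occ = counts > 0
    ref = counts.max() if convention == "normalized" else 1.0
    f[occ] = -kT * np.log(counts[occ] / ref)
    return FESGrid(x_edges, y_edges, f, counts.astype(int), kT, convention)


# ---------------------------------------------------------------------------
# Minima, basins, relative depths
# ---------------------------------------------------------------------------


@dataclass
class Basin:
    """A surviving free-energy minimum and its catchment."""

    label: str
    minimum_bin: tuple[int, int]
    minimum_F: float
    relative_depth: float
    bins: list[tuple[int, int]]


@dataclass
class BasinDecomposition:
    basins: list[Basin]
    bin_labels: np.ndarray     # int basin index per bin, −1 where empty
    grid: FESGrid

    def frame_labels(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Basin label per frame from its projected scores."""
        ix, iy = self.grid.bin_of(np.asarray(x), np.asarray(y))
        idx = self.bin_labels[ix, iy]
        labels = np.array([b.label for b in self.basins] + ["?"])
        return labels[np.where(idx >= 0, idx, len(self.basins))]


_NEIGHBORS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def _flood(grid: FESGrid, prominence: float,
           smooth_sigma: float | None) -> tuple[list[dict], np.ndarray]:
    """Persistence flood over occupied bins (8-connected).

    Returns surviving components (each with its minimum bin/value) and the
    per-bin component assignment. Components whose prominence at a merge
    is below the threshold are absorbed into the deeper neighbor.
    """
    f = grid.F.copy()
    occ = grid.occupied
    if smooth_sigma:
        c = gaussian_filter(grid.counts.astype(float), smooth_sigma)
        f = np.full_like(f, np.nan)
        f[c > 0] = -grid.kT * np.log(c[c > 0] / c.max())
        occ = occ & (c > 0)
    bins = np.argwhere(occ)
    if len(bins) == 0:
        return [], np.full(f.shape, -1, dtype=int)
    values = f[occ]
    if np.ptp(values) == 0:
        # flat surface: no minima by convention
        return [], np.full(f.shape, -1, dtype=int)

    order = np.lexsort((bins[:, 1], bins[:, 0], values))
    comp_of = np.full(f.shape, -1, dtype=int)
    parent: list[int] = []
    comps: list[dict] = []

    def find(c: int) -> int:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for k in order:
        i, j = bins[k]
        level = f[i, j]
        neigh = set()
        for di, dj in _NEIGHBORS:
            a, b = i + di, j + dj
            if 0 <= a < f.shape[0] and 0 <= b < f.shape[1] and comp_of[a, b] >= 0:
                neigh.add(find(comp_of[a, b]))
        if not neigh:
            comps.append({"min_bin": (int(i), int(j)), "min_F": float(level)})
            parent.append(len(comps) - 1)
            comp_of[i, j] = len(comps) - 1
            continue
        target = min(neigh, key=lambda c: (comps[c]["min_F"],) + comps[c]["min_bin"])
        comp_of[i, j] = target
        for c in neigh - {target}:
            if level - comps[c]["min_F"] < prominence:
                parent[c] = target   # too shallow: merge into the deeper basin

    survivors = sorted({find(c) for c in range(len(comps))},
                       key=lambda c: (comps[c]["min_F"],) + comps[c]["min_bin"])
    remap = {c: r for r, c in enumerate(survivors)}
    assign = np.full(f.shape, -1, dtype=int)
    for k in order:
        i, j = bins[k]
        assign[i, j] = remap[find(comp_of[i, j])]
    return [comps[c] for c in survivors], assign


def find_minima(grid: FESGrid, prominence: float = 0.5,
                smooth_sigma: float | None = None,
                ) -> list[tuple[tuple[int, int], float]]:
    """Local FES minima with prominence ≥ threshold, sorted by F ascending.

    A constant surface reports no minima (flat-surface rule).
    """
    comps, _ = _flood(grid, prominence, smooth_sigma)
    return [(c["min_bin"], c["min_F"]) for c in comps]


def relative_depths(minima_F, reference_index: int | None = None) -> np.ndarray:
    """Depths of minima relative to a reference minimum.

    ``reference_index=None`` uses the deepest minimum; the result is
    invariant to adding any constant to all minima.
    """
    f = np.asarray(minima_F, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one minimum")
    ref = int(np.argmin(f)) if reference_index is None else reference_index
    return f - f[ref]


def assign_basins(grid: FESGrid, prominence: float = 0.5,
                  smooth_sigma: float | None = None,
                  reference_index: int | None = None) -> BasinDecomposition:
    """Partition all occupied bins into basins draining to surviving minima.

    Basin labels are A, B, C, … in order of ascending minimum free energy.
    Ties at plateau bins go to the neighbor with lower F, then to the
    lower basin label.
    """
    comps, bin_labels = _flood(grid, prominence, smooth_sigma)
    if not comps:
        raise ValueError("surface has no minima (flat or empty)")
    minima_f = np.array([c["min_F"] for c in comps])
    depths = relative_depths(minima_f, reference_index)
    basins = []
    for idx, comp in enumerate(comps):
        member_bins = [tuple(b) for b in np.argwhere(bin_labels == idx)]
        label = _basin_name(idx)
        basins.append(Basin(label, comp["min_bin"], comp["min_F"],
                            float(depths[idx]), member_bins))
    return BasinDecomposition(basins, bin_labels, grid)


def _basin_name(i: int) -> str:
    name = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        name = chr(ord("A") + r) + name
    return name


# ---------------------------------------------------------------------------
# Representative structures
# ---------------------------------------------------------------------------


def representative_structure(traj: Trajectory, frame_indices,
                             cutoff: float = 0.2) -> int:
    """Representative frame of a basin via single-linkage RMSD clustering.

    Pairwise Cα Kabsch RMSDs are clustered with single linkage at the
    given cutoff (nm); the representative is the member of the largest
    cluster minimizing mean RMSD to its cluster (ties: lowest frame index).
    """
    frame_indices = np.asarray(list(frame_indices), dtype=int)
    if frame_indices.size == 0:
        raise ValueError("need at least one member frame")
    if frame_indices.size == 1:
        return int(frame_indices[0])

    ca_idx = [r.offset_of("CA")
              for ch in traj.topology.chains for r in ch.residues]
    if any(i is None for i in ca_idx):
        raise ValueError("all residues need CA atoms for RMSD clustering")
    ca = traj.coords[np.ix_(frame_indices, np.array(ca_idx))]

    k = len(frame_indices)
    dist = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            dist[a, b] = dist[b, a] = kabsch_rmsd(ca[a], ca[b])
    clusters = fcluster(linkage(squareform(dist, checks=False), method="single"),
                        t=cutoff, criterion="distance")
    sizes = np.bincount(clusters)
    best_size = sizes.max()
    tied = np.flatnonzero(sizes == best_size)
    # tie rule: the cluster containing the earliest frame
    winner = min(tied, key=lambda c: frame_indices[clusters == c].min())
    members = np.flatnonzero(clusters == winner)
    mean_rmsd = dist[np.ix_(members, members)].mean(axis=1)
    # ties resolved toward the lowest original frame index
    order = np.lexsort((frame_indices[members], mean_rmsd))
    return int(frame_indices[members[order[0]]])
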