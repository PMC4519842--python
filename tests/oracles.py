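"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and textbook formulas,
deliberately sharing no code with the package: hydrogen-bond detection by
explicit pair enumeration, contact counting by nested loops, RMSD by the
Horn quaternion method (the package uses Kabsch/SVD), and single-linkage
clustering by naive agglomeration (the package uses scipy).
"""

from __future__ import annotations

import numpy as np

_NH = 0.098  # nm, amide N-H bond length for reconstruction


def _unit(v):
    return v / np.linalg.norm(v)


def _amide_h(residues, i):
    """Amide H of residue i (given atom if present, else reconstructed)."""
    res = residues[i]
    if "H" in res.atoms:
        return res.atoms["H"]
    if i == 0:
        return None
    prev = residues[i - 1]
    if "C" not in prev.atoms or "N" not in res.atoms or "CA" not in res.atoms:
        return None
    n, ca, c_prev = res.atoms["N"], res.atoms["CA"], prev.atoms["C"]
    u = _unit(c_prev - n) + _unit(ca - n)
    return n - _NH * _unit(u)


def oracle_hbonds(frame, distance_cutoff=0.35, angle_cutoff=30.0):
    """All backbone N-H···O=C bonds by explicit donor x acceptor enumeration.

    Returns a set of ((donor_chain, donor_res_index), (acc_chain, acc_res_index)).
    """
    bonds = set()
    for dch in frame.chains:
        for di, dres in enumerate(dch.residues):
            if di == 0 or dres.name == "PRO":
                continue  # no amide H: ammonium terminus / proline
            h = _amide_h(dch.residues, di)
            if h is None or "N" not in dres.atoms:
                continue
            n = dres.atoms["N"]
            for ach in frame.chains:
                for ai, ares in enumerate(ach.residues):
                    if "O" not in ares.atoms or "C" not in ares.atoms:
                        continue
                    if ach.id == dch.id and abs(di - ai) <= 1:
                        continue
                    o = ares.atoms["O"]
                    d = float(np.linalg.norm(o - n))
                    if d > distance_cutoff:
                        continue
                    cos_a = float(_unit(h - n) @ _unit(o - n))
                    ang = float(np.degrees(np.arccos(np.clip(cos_a, -1.0, 1.0))))
                    if ang <= angle_cutoff:
                        bonds.add(((dch.id, dres.index), (ach.id, ares.index)))
    return bonds


_BACKBONE_LIKE = {"N", "H", "CA", "C", "O", "OXT", "H1", "H2", "H3"}


def _side_heavy(res):
    pts = [xyz for name, xyz in res.atoms.items()
           if name not in _BACKBONE_LIKE and not name.strip().lstrip("0123456789").startswith("H")]
    if res.name == "GLY" or not pts:
        pts = [res.atoms["CA"]] if "CA" in res.atoms else []
    return pts


def oracle_contacts(frame, cutoff=0.54):
    """Inter-chain side-chain contact pairs (1-based positions), brute force."""
    a, b = frame.chains
    pairs = []
    for i, ra in enumerate(a.residues):
        pa = _side_heavy(ra)
        for j, rb in enumerate(b.residues):
            pb = _side_heavy(rb)
            if not pa or not pb:
                continue
            dmin = min(float(np.linalg.norm(x - y)) for x in pa for y in pb)
            if dmin <= cutoff:
                pairs.append((i + 1, j + 1))
    return pairs


def oracle_quaternion_rmsd(coords_a, coords_b):
    """Minimum superposition RMSD by the Horn quaternion method."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy,       szx - sxz,       sxy - syx],
        [syz - szy,       sxx - syy - szz, sxy + syx,       szx + sxz],
        [szx - sxz,       sxy + syx,       syy - sxx - szz, syz + szy],
        [sxy - syx,       szx + sxz,       syz + szy,       szz - sxx - syy],
    ])
    lam = float(np.linalg.eigvalsh(k)[-1])
    msd = (np.sum(a * a) + np.sum(b * b) - 2.0 * lam) / a.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def oracle_single_linkage(dist, cutoff):
    """Naive agglomerative single-linkage partition at a distance cutoff.

    Returns a set of frozensets of item indices.
    """
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        if best[0] > cutoff:
            break
        _, a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    return {frozenset(c) for c in clusters}


def oracle_representative(dist, frame_indices, cutoff):
    """Representative frame per the documented rule, from the oracle partition.

    Largest cluster (ties: the one containing the earliest frame), then the
    member with the lowest mean in-cluster distance (ties: lowest frame index).
    """
    frame_indices = np.asarray(frame_indices)
    parts = sorted(oracle_single_linkage(dist, cutoff),
                   key=lambda c: (-len(c), min(frame_indices[i] for i in c)))
    members = sorted(parts[0])
    means = [np.mean([dist[i, j] for j in members]) for i in members]
    order = sorted(range(len(members)),
                   key=lambda k: (means[k], frame_indices[members[k]]))
    return int(frame_indices[members[order[0]]])
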