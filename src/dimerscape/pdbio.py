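"""Multi-model PDB reading and writing (biotite-backed).

One ``MODEL``/``ENDMDL`` block per frame; coordinates are converted
between the PDB's ångströms and the package's internal nanometres.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import biotite.structure as struc
import numpy as np
from biotite.structure.io.pdb import PDBFile

from .core import (
    Topology, TopologyChain, TopologyResidue, Trajectory, TrajectoryMetadata,
    element_of,
)

_REQUIRED_BACKBONE = ("N", "CA", "C", "O")


def read_multimodel_pdb(path: str | Path,
                        metadata: TrajectoryMetadata | None = None) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Every ``MODEL`` becomes one frame (a file without MODEL records yields a
    single frame). The file must contain exactly two chain identifiers.
    Residues missing backbone atoms are flagged with a warning; amide
    hydrogens are *not* reconstructed here (the hydrogen-bond detector does
    that on demand).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure()
    except Exception as exc:  # biotite reports the offending line
        raise ValueError(f"could not parse PDB file {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    chain_ids = list(dict.fromkeys(stack.chain_id))
    if len(chain_ids) != 2:
        raise ValueError(
            f"expected exactly two chains, found {len(chain_ids)}: {chain_ids}"
        )

    chains: list[TopologyChain] = []
    for cid in chain_ids:
        mask = stack.chain_id == cid
        atom_idx = np.flatnonzero(mask)
        res_ids = stack.res_id[atom_idx]
        residues: list[TopologyResidue] = []
        # group consecutive atoms by residue id (standard PDB ordering)
        boundaries = np.flatnonzero(np.diff(res_ids) != 0)
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries + 1, [len(atom_idx)]))
        for s, e in zip(starts, ends):
            sel = atom_idx[s:e]
            names = tuple(stack.atom_name[sel])
            res = TopologyResidue(
                name=str(stack.res_name[sel[0]]),
                index=int(stack.res_id[sel[0]]),
                atom_names=names,
                atom_offsets=tuple(int(i) for i in sel),
            )
            missing = [a for a in _REQUIRED_BACKBONE if a not in names]
            if missing:
                warnings.warn(
                    f"residue {res.name}{res.index} of chain {cid} is missing "
                    f"backbone atoms {missing}", stacklevel=2)
            residues.append(res)
        chains.append(TopologyChain(cid, tuple(residues)))

    topology = Topology(tuple(chains), n_atoms=stack.array_length())
    coords = np.asarray(stack.coord, dtype=float) / 10.0   # Å → nm
    if metadata is None:
        metadata = TrajectoryMetadata()
    return Trajectory(topology, coords, metadata=metadata)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a standard multi-model PDB file."""
    if traj.n_frames < 1:
        raise ValueError("cannot write an empty trajectory")
    n_atoms = traj.topology.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    chain_id = np.empty(n_atoms, dtype="U4")
    res_id = np.empty(n_atoms, dtype=int)
    res_name = np.empty(n_atoms, dtype="U5")
    atom_name = np.empty(n_atoms, dtype="U6")
    element = np.empty(n_atoms, dtype="U2")
    for ch in traj.topology.chains:
        for res in ch.residues:
            for name, off in zip(res.atom_names, res.atom_offsets):
                chain_id[off] = ch.id
                res_id[off] = res.index
                res_name[off] = res.name
                atom_name[off] = name
                element[off] = element_of(name)
    stack.chain_id = chain_id
    stack.res_id = res_id
    stack.res_name = res_name
    stack.atom_name = atom_name
    stack.element = element
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    stack.coord = np.asarray(traj.coords, dtype=np.float32) * 10.0   # nm → Å

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
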