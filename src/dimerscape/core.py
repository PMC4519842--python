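"""Domain model for two-chain peptide trajectories.

Coordinates are stored in nanometres throughout the package; file I/O
converts from/to the ångström convention of the PDB format.

A :class:`Trajectory` keeps a single topology plus a dense
``(n_frames, n_atoms, 3)`` coordinate array, so that long synthetic
trajectories stay cheap; :class:`Frame`/:class:`Chain`/:class:`Residue`
objects are materialized on demand as lightweight views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

# Average atomic masses (u) of the elements occurring in peptides.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "SE": 78.971,
}

BACKBONE_ATOMS = ("N", "H", "CA", "C", "O")

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

#: N-terminal 12 residues of human α-synuclein, the package's reference case.
ALPHA_SYN12 = "MDVFMKGLSKAK"


def element_of(atom_name: str) -> str:
    """Guess the element from a PDB atom name (e.g. ``CA`` → C, ``OD1`` → O)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if stripped[:2].upper() in ("SE",):
        return "SE"
    return stripped[0].upper()


# ---------------------------------------------------------------------------
# Residue / Chain / Frame
# ---------------------------------------------------------------------------


@dataclass
class Residue:
    """One amino-acid residue: 3-letter name, 1-based index, atom → xyz (nm)."""

    name: str
    index: int
    atoms: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        for atom, xyz in self.atoms.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"atom {atom!r} of residue {self.name}{self.index}: "
                                 "coordinates must be a finite 3-vector")
            self.atoms[atom] = arr

    @property
    def one_letter(self) -> str:
        return AA_3TO1.get(self.name, "X")

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C", "O"))


@dataclass
class Chain:
    """An ordered peptide chain with a single-character identifier."""

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("a chain needs at least one residue")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"residue indices of chain {self.id!r} must be "
                             f"strictly increasing, got {idx}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class Frame:
    """A single recorded conformation of the two-chain system."""

    chains: list[Chain]
    time: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        if len(self.chains) != 2:
            found = [c.id for c in self.chains]
            raise ValueError(f"a Frame holds exactly two chains, got {found}")
        if self.time < 0:
            raise ValueError("frame time must be non-negative")


@dataclass(frozen=True)
class TrajectoryMetadata:
    """Run conditions attached to a trajectory."""

    ph_mode: str | None = None            # "physiological" | "acidic" | None
    temperature: float = 300.0            # K
    frame_spacing_ps: float = 2.0

    def __post_init__(self) -> None:
        if self.ph_mode not in (None, "physiological", "acidic"):
            raise ValueError(f"unknown pH mode {self.ph_mode!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


# ---------------------------------------------------------------------------
# Topology + columnar Trajectory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TopologyResidue:
    name: str
    index: int
    atom_names: tuple[str, ...]
    atom_offsets: tuple[int, ...]   # indices into the flat atom axis

    def offset_of(self, atom: str) -> int | None:
        try:
            return self.atom_offsets[self.atom_names.index(atom)]
        except ValueError:
            return None


@dataclass(frozen=True)
class TopologyChain:
    id: str
    residues: tuple[TopologyResidue, ...]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(AA_3TO1.get(r.name, "X") for r in self.residues)


@dataclass(frozen=True)
class Topology:
    chains: tuple[TopologyChain, ...]
    n_atoms: int

    def __post_init__(self) -> None:
        if len(self.chains) != 2:
            found = [c.id for c in self.chains]
            raise ValueError(f"a trajectory topology holds exactly two chains, got {found}")

    @staticmethod
    def from_frame(frame: Frame) -> "Topology":
        chains = []
        off = 0
        for ch in frame.chains:
            residues = []
            for res in ch.residues:
                names = tuple(res.atoms.keys())
                offsets = tuple(range(off, off + len(names)))
                off += len(names)
                residues.append(TopologyResidue(res.name, res.index, names, offsets))
            chains.append(TopologyChain(ch.id, tuple(residues)))
        return Topology(tuple(chains), off)

    def signature(self) -> tuple:
        """Hashable identity used to check frame-to-frame consistency."""
        return tuple(
            (c.id, tuple((r.name, r.index, r.atom_names) for r in c.residues))
            for c in self.chains
        )


def _frame_coords(frame: Frame, topology: Topology) -> np.ndarray:
    coords = np.empty((topology.n_atoms, 3), dtype=float)
    for ch, tch in zip(frame.chains, topology.chains):
        for res, tres in zip(ch.residues, tch.residues):
            for name, off in zip(tres.atom_names, tres.atom_offsets):
                coords[off] = res.atoms[name]
    return coords


class Trajectory:
    """An ordered sequence of frames sharing one topology.

    Parameters
    ----------
    topology
        Two-chain atom layout shared by every frame.
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in nm.
    times
        Frame times in ps, non-decreasing. Defaults to
        ``frame_index * metadata.frame_spacing_ps``.
    metadata
        Run conditions (pH mode, temperature, frame spacing).
    """

    def __init__(self, topology: Topology, coords: np.ndarray,
                 times: np.ndarray | None = None,
                 metadata: TrajectoryMetadata | None = None) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1:] != (topology.n_atoms, 3):
            raise ValueError(f"coords must have shape (n_frames, {topology.n_atoms}, 3)")
        if coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        self.topology = topology
        self.coords = coords
        self.metadata = metadata or TrajectoryMetadata()
        if times is None:
            times = np.arange(len(coords)) * self.metadata.frame_spacing_ps
        times = np.asarray(times, dtype=float)
        if times.shape != (coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(times) < 0):
            raise ValueError("frame times must be non-decreasing")
        self.times = times

    # -- sequence protocol -------------------------------------------------

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self)

    def __getitem__(self, i: int) -> Frame:
        if not isinstance(i, (int, np.integer)):
            raise TypeError("frame index must be an integer")
        i = int(i)
        if i < 0:
            i += len(self)
        if not 0 <= i < len(self):
            raise IndexError("frame index out of range")
        row = self.coords[i]
        chains = []
        for tch in self.topology.chains:
            residues = [
                Residue(r.name, r.index,
                        {name: row[off].copy()
                         for name, off in zip(r.atom_names, r.atom_offsets)})
                for r in tch.residues
            ]
            chains.append(Chain(tch.id, residues))
        return Frame(chains, time=float(self.times[i]), frame_index=i)

    def iter_frames(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self[i]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frames(cls, frames: Sequence[Frame],
                    metadata: TrajectoryMetadata | None = None) -> "Trajectory":
        if len(frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        topology = Topology.from_frame(frames[0])
        sig = topology.signature()
        coords = np.empty((len(frames), topology.n_atoms, 3), dtype=float)
        for k, fr in enumerate(frames):
            if Topology.from_frame(fr).signature() != sig:
                raise ValueError(f"frame {k} has a different topology than frame 0")
            coords[k] = _frame_coords(fr, topology)
        times = np.array([fr.time for fr in frames], dtype=float)
        return cls(topology, coords, times=times, metadata=metadata)

    def subset(self, frame_indices: Sequence[int]) -> "Trajectory":
        idx = np.asarray(frame_indices, dtype=int)
        return Trajectory(self.topology, self.coords[idx], times=self.times[idx],
                          metadata=self.metadata)


# ---------------------------------------------------------------------------
# Protonation-state charge accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtonationScheme:
    """Integer charges assigned to ionizable groups.

    The two presets match a free N-terminal amine (+1) and a deprotonated
    C-terminal carboxylate (−1). At acidic pH the carboxylic side chains
    (Asp/Glu) are protonated to neutrality and histidine is protonated;
    the C-terminus is kept deprotonated, which is the assignment consistent
    with a +3 net charge per α-syn12 chain (six chloride counterions for
    the dimer).
    """

    lys: int = 1
    arg: int = 1
    asp: int = -1
    glu: int = -1
    his: int = 0
    n_terminus: int = 1
    c_terminus: int = -1

    def __post_init__(self) -> None:
        for group, q in self.group_charges().items():
            if q not in (-1, 0, 1):
                raise ValueError(f"charge of group {group!r} must be in {{-1, 0, +1}}")

    def group_charges(self) -> dict[str, int]:
        return {
            "lys": self.lys, "arg": self.arg, "asp": self.asp, "glu": self.glu,
            "his": self.his, "n_terminus": self.n_terminus,
            "c_terminus": self.c_terminus,
        }


PHYSIOLOGICAL_PH = ProtonationScheme()
ACIDIC_PH = ProtonationScheme(asp=0, glu=0, his=1)

SCHEMES: Mapping[str, ProtonationScheme] = {
    "physiological": PHYSIOLOGICAL_PH,
    "acidic": ACIDIC_PH,
}

_SIDECHAIN_GROUP = {"K": "lys", "R": "arg", "D": "asp", "E": "glu", "H": "his"}


def formal_charge(sequence: str, scheme: ProtonationScheme = PHYSIOLOGICAL_PH) -> int:
    """Net formal charge of one chain: side-chain groups plus both termini.

    Parameters
    ----------
    sequence
        One-letter amino-acid string (standard residues only).
    scheme
        Per-group charge assignment, e.g. :data:`PHYSIOLOGICAL_PH`.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    groups = scheme.group_charges()
    total = groups["n_terminus"] + groups["c_terminus"]
    for letter in sequence.upper():
        if letter not in AA_1TO3:
            raise ValueError(f"unknown residue letter {letter!r}")
        group = _SIDECHAIN_GROUP.get(letter)
        if group is not None:
            total += groups[group]
    return total


class CounterionRequirement(NamedTuple):
    """Number and species of monovalent counterions neutralizing a system."""

    count: int
    species: str | None   # "Cl-" for net-positive systems, "Na+" for net-negative

    def __str__(self) -> str:
        return f"{self.count} {self.species}" if self.species else "0 (neutral)"


def counterion_count(sequences: Sequence[str],
                     scheme: ProtonationScheme = PHYSIOLOGICAL_PH,
                     ) -> CounterionRequirement:
    """Monovalent counterions needed to neutralize a multi-chain system.

    Returns the absolute total charge together with the species: chloride
    for a net-positive solute, sodium for net-negative.
    """
    total = sum(formal_charge(seq, scheme) for seq in sequences)
    if total > 0:
        return CounterionRequirement(total, "Cl-")
    if total < 0:
        return CounterionRequirement(-total, "Na+")
    return CounterionRequirement(0, None)
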