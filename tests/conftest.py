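"""Shared fixtures: ideal conformers and small synthetic trajectories.

Expensive constructions (ideal dimers involve a rigid-body refinement)
are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dimerscape import build_ideal_dimer
from dimerscape.synth import CONFORMER_KINDS, ConformerSpec, MarkovSpec, markov_trajectory


@pytest.fixture(scope="session")
def ideal_frames():
    """kind -> ideal Frame for every conformer kind."""
    return {kind: build_ideal_dimer(ConformerSpec(kind)) for kind in CONFORMER_KINDS}


@pytest.fixture(scope="session")
def small_traj():
    """A 12-frame five-state trajectory with mild noise (seed 11)."""
    kinds = list(CONFORMER_KINDS)
    pi = np.full(len(kinds), 1.0 / len(kinds))
    spec = MarkovSpec(
        states=tuple(ConformerSpec(k) for k in kinds),
        transition=np.tile(pi, (len(kinds), 1)),
        n_frames=12,
        seed=11,
        noise_sigma=0.01,
    )
    traj, truth = markov_trajectory(spec)
    return traj, truth


@pytest.fixture(scope="session")
def noiseless_traj():
    """An 8-frame noise-free two-state trajectory (exact geometry)."""
    spec = MarkovSpec(
        states=(ConformerSpec("antiparallel_sheet"), ConformerSpec("helix_pair")),
        transition=np.array([[0.5, 0.5], [0.5, 0.5]]),
        n_frames=8,
        seed=3,
        noise_sigma=0.0,
    )
    traj, truth = markov_trajectory(spec)
    return traj, truth
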