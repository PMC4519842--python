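"""Discrete conformational states and transition bookkeeping.

The dimer's coarse states are defined by the sign pattern of three
per-frame coordinates — the intra-backbone hydrogen-bond count, the helix
residue count and the strand residue count. Six of the eight combinations
carry the conventional numerals I–VI; the two combinations with helix but
no intra-chain bonds (physically marginal) are kept as X1/X2 so every
frame receives exactly one label.

Orientation classes resolve β-sheet polarity: frames with inter-chain
backbone bonds are binned by the angle θ between the chains' end-to-end
vectors, parallel sheets near 0° and anti-parallel near 180°. The
published bin edges overlap at 50° and 90°; they are resolved as
half-open, lower-inclusive intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import FrameMetrics

#: (NUMintraHB > 0, Lhelix > 0, Lsheet > 0) → region label
REGION_TABLE = {
    (True, True, False): "VI",
    (True, True, True): "V",
    (True, False, False): "IV",
    (True, False, True): "III",
    (False, False, True): "II",
    (False, False, False): "I",
    (False, True, False): "X1",
    (False, True, True): "X2",
}

REGION_LABELS = ("VI", "V", "IV", "III", "X1", "X2", "II", "I")

ORIENTATION_CLASSES = ("noHB", "theta[0,50)", "theta[50,90)",
                       "theta[90,130)", "theta[130,180]")

#: lower-inclusive bin edges in degrees for frames with inter-chain bonds
_THETA_EDGES = (50.0, 90.0, 130.0)


def classify_region(m: FrameMetrics) -> str:
    """Region label from the sign pattern of (NUMintraHB, Lhelix, Lsheet)."""
    return REGION_TABLE[(m.NUMintraHB > 0, m.Lhelix > 0, m.Lsheet > 0)]


def classify_regions(metrics: pd.DataFrame) -> pd.Series:
    """Vectorized region labels for a frame-metrics table."""
    key = list(zip(metrics["NUMintraHB"] > 0, metrics["Lhelix"] > 0,
                   metrics["Lsheet"] > 0))
    return pd.Series([REGION_TABLE[k] for k in key], index=metrics.index,
                     name="region")


def orientation_class(m: FrameMetrics) -> str:
    """Orientation class: noHB without inter-chain bonds, else a θ bin."""
    return _theta_class(m.NUMinterHB, m.theta_deg)


def _theta_class(num_inter: int, theta_deg: float) -> str:
    if num_inter == 0:
        return "noHB"
    k = int(np.searchsorted(_THETA_EDGES, theta_deg, side="right"))
    return ORIENTATION_CLASSES[1 + k]


def orientation_classes(metrics: pd.DataFrame) -> pd.Series:
    """Vectorized orientation classes for a frame-metrics table."""
    out = [
        _theta_class(n, t)
        for n, t in zip(metrics["NUMinterHB"], metrics["theta_deg"])
    ]
    return pd.Series(out, index=metrics.index, name="orientation")


# ---------------------------------------------------------------------------
# Window probability tables
# ---------------------------------------------------------------------------


def window_probability_table(labels, window: int,
                             label_order=None) -> pd.DataFrame:
    """Per-window occupancy probabilities of discrete labels.

    Frames are split into consecutive windows of ``window`` frames; a final
    partial window is kept and flagged. Each row holds the fraction of the
    window's frames carrying each label and sums to 1.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("label sequence is empty")
    if window < 1:
        raise ValueError("window must be at least 1")
    if label_order is None:
        label_order = sorted(set(labels))
    rows = []
    for start in range(0, len(labels), window):
        chunk = labels[start:start + window]
        counts = pd.Series(chunk).value_counts()
        row = {
            "window_start": start,
            "window_end": start + len(chunk),
            "partial": len(chunk) < window,
        }
        for lab in label_order:
            row[lab] = counts.get(lab, 0) / len(chunk)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transition graphs
# ---------------------------------------------------------------------------


@dataclass
class TransitionGraph:
    """Counts of consecutive-frame label transitions.

    Trajectories demultiplexed from replica exchange are discontinuous in
    physical time, so these edges measure *neighbor accessibility* between
    states — which states interconvert without crossing others — not
    kinetic rates.
    """

    nodes: list[str]
    counts: pd.DataFrame      # square, index = from, columns = to
    rates: pd.DataFrame       # row-normalized counts

    @property
    def total_transitions(self) -> int:
        return int(self.counts.values.sum())

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"from": a, "to": b,
             "count": int(self.counts.loc[a, b]),
             "rate": float(self.rates.loc[a, b])}
            for a in self.nodes for b in self.nodes
            if self.counts.loc[a, b] > 0
        ]
        return pd.DataFrame(rows, columns=["from", "to", "count", "rate"])

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["from"], row["to"], count=row["count"], rate=row["rate"])
        return g

    def to_dot(self) -> str:
        lines = ["digraph transitions {",
                 '    label="state accessibility (not kinetics)";']
        for node in self.nodes:
            lines.append(f'    "{node}";')
        for _, row in self.edge_list().iterrows():
            lines.append(f'    "{row["from"]}" -> "{row["to"]}" '
                         f'[label="{int(row["count"])}", weight={int(row["count"])}];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def transition_graph(labels, segments=None) -> TransitionGraph:
    """Count label→label transitions within contiguous segments.

    ``segments`` is a list of (start, stop) frame ranges (default: one
    segment covering everything); no edges are counted across segment
    boundaries. Total edge count equals Σ(segment length − 1).
    """
    labels = list(labels)
    if segments is None:
        segments = [(0, len(labels))]
    nodes = sorted(set(labels))
    counts = pd.DataFrame(0, index=nodes, columns=nodes, dtype=int)
    for start, stop in segments:
        if stop - start < 2:
            raise ValueError(f"segment ({start}, {stop}) is too short")
        for a, b in zip(labels[start:stop - 1], labels[start + 1:stop]):
            counts.loc[a, b] += 1
    totals = counts.sum(axis=1)
    rates = counts.div(totals.replace(0, 1), axis=0).astype(float)
    return TransitionGraph(nodes, counts, rates)
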