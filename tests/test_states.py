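"""Region/orientation classification, probability tables, transition graphs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dimerscape import (
    classify_region, classify_regions, orientation_class, orientation_classes,
    transition_graph, window_probability_table,
)
from dimerscape.annotation import FrameMetrics
from dimerscape.states import ORIENTATION_CLASSES, REGION_LABELS, REGION_TABLE


def _metrics(intra=0, helix=0, sheet=0, inter=0, cos=1.0, con=0):
    return FrameMetrics(Lhelix=helix, Lsheet=sheet, NUMintraHB=intra,
                        NUMinterHB=inter, NUMcon=con, cos_theta=cos)


class TestRegions:
    def test_truth_table_is_total_and_distinct(self):
        assert set(REGION_TABLE.keys()) == set(itertools.product(
            (False, True), repeat=3))
        assert sorted(REGION_TABLE.values()) == sorted(REGION_LABELS)

    def test_all_eight_patterns_reachable(self):
        seen = set()
        for intra, helix, sheet in itertools.product((0, 3), repeat=3):
            seen.add(classify_region(_metrics(intra=intra, helix=helix,
                                              sheet=sheet)))
        assert seen == set(REGION_LABELS)

    def test_named_examples(self):
        assert classify_region(_metrics(intra=2, helix=4)) == "VI"
        assert classify_region(_metrics(intra=2, sheet=6)) == "III"
        assert classify_region(_metrics(sheet=8)) == "II"
        assert classify_region(_metrics()) == "I"
        assert classify_region(_metrics(helix=4)) == "X1"

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 12), st.integers(0, 24), st.integers(0, 24))
    def test_exactly_one_label_per_frame(self, intra, helix, sheet):
        """The 8 labels partition the metric space: always exactly one."""
        m = _metrics(intra=intra, helix=helix, sheet=sheet)
        matches = [lab for key, lab in REGION_TABLE.items()
                   if key == (intra > 0, helix > 0, sheet > 0)]
        assert len(matches) == 1
        assert classify_region(m) == matches[0]

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "NUMintraHB": rng.integers(0, 3, 100),
            "Lhelix": rng.integers(0, 3, 100),
            "Lsheet": rng.integers(0, 3, 100),
        })
        vec = classify_regions(df)
        for k in range(len(df)):
            m = _metrics(intra=df.NUMintraHB[k], helix=df.Lhelix[k],
                         sheet=df.Lsheet[k])
            assert vec[k] == classify_region(m)


class TestOrientationClasses:
    def test_no_bonds_is_noHB(self):
        assert orientation_class(_metrics(inter=0, cos=-1.0)) == "noHB"

    def test_theta_bins_lower_inclusive(self):
        def cls(theta):
            return orientation_class(_metrics(inter=1,
                                              cos=np.cos(np.radians(theta))))
        assert cls(0.0) == "theta[0,50)"
        assert cls(49.999) == "theta[0,50)"
        assert cls(50.0) == "theta[50,90)"
        assert cls(90.0) == "theta[90,130)"
        assert cls(130.0) == "theta[130,180]"
        assert cls(180.0) == "theta[130,180]"

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 10), st.floats(-1.0, 1.0))
    def test_classes_partition(self, inter, cos):
        cls = orientation_class(_metrics(inter=inter, cos=cos))
        assert cls in ORIENTATION_CLASSES
        assert (cls == "noHB") == (inter == 0)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "NUMinterHB": rng.integers(0, 3, 50),
            "cos_theta": rng.uniform(-1, 1, 50),
        })
        df["theta_deg"] = np.degrees(np.arccos(df["cos_theta"]))
        vec = orientation_classes(df)
        for k in range(len(df)):
            m = _metrics(inter=df.NUMinterHB[k], cos=df.cos_theta[k])
            assert vec[k] == orientation_class(m)


class TestWindowTables:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        labels = rng.choice(list(REGION_LABELS), 1234)
        table = window_probability_table(labels, 100, label_order=list(REGION_LABELS))
        sums = table[list(REGION_LABELS)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_partial_window_flagged(self):
        table = window_probability_table(["a"] * 25, 10)
        assert list(table["partial"]) == [False, False, True]
        assert list(table["window_end"]) == [10, 20, 25]

    def test_counts_exact(self):
        table = window_probability_table(list("aabba"), 5, label_order=["a", "b"])
        assert table.loc[0, "a"] == pytest.approx(0.6)
        assert table.loc[0, "b"] == pytest.approx(0.4)

    def test_validation(self):
        with pytest.raises(ValueError, match="empty"):
            window_probability_table([], 10)
        with pytest.raises(ValueError, match="window"):
            window_probability_table(["a"], 0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from("abc"), min_size=1, max_size=60),
           st.integers(1, 20))
    def test_row_sums_property(self, labels, window):
        table = window_probability_table(labels, window)
        value_cols = [c for c in table.columns
                      if c not in ("window_start", "window_end", "partial")]
        np.testing.assert_allclose(table[value_cols].sum(axis=1), 1.0, atol=1e-9)
        assert table["window_end"].iloc[-1] == len(labels)


class TestTransitionGraph:
    def test_counts_and_rates(self):
        g = transition_graph(list("aabab"))
        assert g.total_transitions == 4
        assert g.counts.loc["a", "a"] == 1
        assert g.counts.loc["a", "b"] == 2
        assert g.counts.loc["b", "a"] == 1
        np.testing.assert_allclose(g.rates.sum(axis=1), 1.0)

    def test_segments_do_not_cross(self):
        g = transition_graph(list("aabb"), segments=[(0, 2), (2, 4)])
        assert g.total_transitions == 2
        assert g.counts.loc["a", "b"] == 0

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            transition_graph(list("ab"), segments=[(0, 1)])

    def test_dot_and_edge_list(self):
        g = transition_graph(list("abab"))
        dot = g.to_dot()
        assert dot.startswith("digraph")
        assert '"a" -> "b"' in dot
        edges = g.edge_list()
        assert set(edges.columns) == {"from", "to", "count", "rate"}
        assert edges["count"].sum() == g.total_transitions

    def test_networkx_export(self):
        g = transition_graph(list("aab"))
        nx_graph = g.to_networkx()
        assert nx_graph.number_of_nodes() == 2
        assert nx_graph["a"]["b"]["count"] == 1
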