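"""PCA, free-energy surfaces, minima/basins, representative structures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimerscape import (
    assign_basins, dpca_features, fes_from_projection, find_minima, fit_pca,
    project, relative_depths, representative_structure, thermal_energy,
)
from dimerscape.landscape import _basin_name


class TestPCA:
    def _data(self, seed=0, n=200, p=6):
        rng = np.random.default_rng(seed)
        scales = np.linspace(3.0, 0.1, p)
        return rng.normal(size=(n, p)) * scales

    def test_components_orthonormal_and_sorted(self):
        model = fit_pca(self._data())
        np.testing.assert_allclose(model.components @ model.components.T,
                                   np.eye(model.n_components), atol=1e-10)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert model.variance_fractions.sum() == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        x = self._data(seed=1)
        m1, m2 = fit_pca(x), fit_pca(x.copy())
        np.testing.assert_array_equal(m1.components, m2.components)
        for row in m1.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_projection_reproduces_variance(self):
        x = self._data(seed=2)
        model = fit_pca(x)
        scores = project(model, x, k=2)
        np.testing.assert_allclose(scores.var(axis=0, ddof=1),
                                   model.eigenvalues[:2], rtol=1e-10)

    def test_projection_validation(self):
        model = fit_pca(self._data())
        with pytest.raises(ValueError, match="dimension mismatch"):
            project(model, np.zeros((3, 4)))
        with pytest.raises(ValueError, match="k must be"):
            project(model, self._data(), k=99)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_pca(np.zeros((1, 5)))
        with pytest.raises(ValueError, match="rank-0"):
            fit_pca(np.ones((10, 5)))
        with pytest.raises(ValueError, match="non-finite"):
            fit_pca(np.full((4, 4), np.nan))

    def test_dpca_dimension(self, small_traj):
        traj, _ = small_traj
        feats = dpca_features(traj)
        # 8(n-1) features for two n-residue chains
        assert feats.shape == (len(traj), 8 * 11)
        assert np.all(np.abs(feats) <= 1.0 + 1e-12)


class TestFES:
    def test_normalized_minimum_is_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 5000))
        grid = fes_from_projection(x, y, nbins=30)
        assert np.nanmin(grid.F) == 0.0
        assert np.all(np.isnan(grid.F[~grid.occupied]))
        assert grid.counts.sum() == 5000

    def test_raw_convention_differs_by_constant(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 2000))
        gn = fes_from_projection(x, y, nbins=20, convention="normalized")
        gr = fes_from_projection(x, y, nbins=20, convention="raw")
        occ = gn.occupied
        diff = gr.F[occ] - gn.F[occ]
        np.testing.assert_allclose(diff, diff[0], atol=1e-9)

    def test_kT_default(self):
        assert thermal_energy(300.0) == pytest.approx(2.494, abs=2e-3)

    def test_bin_of_edges(self):
        x = np.linspace(0, 1, 100)
        grid = fes_from_projection(x, x, nbins=10)
        ix, iy = grid.bin_of(np.array([1.0]), np.array([1.0]))
        assert ix[0] == 9 and iy[0] == 9  # top edge falls inward

    def test_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            fes_from_projection(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError, match="nbins"):
            fes_from_projection(np.zeros(9), np.zeros(9), nbins=2)
        with pytest.raises(ValueError, match="convention"):
            fes_from_projection(np.arange(9.0), np.arange(9.0), convention="x")

    def test_single_bin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fes_from_projection(np.zeros(10), np.zeros(10))


def _two_well_scores():
    """Deterministic scores whose 30x30 histogram is two smooth wells on a
    connected count-1 background (node k of linspace(v0, v1, 30) falls in
    bin k of the 30-bin histogram, so the counts are controlled exactly)."""
    nb = 30
    xs = np.linspace(-3.0, 3.0, nb)
    ys = np.linspace(-1.0, 1.0, nb)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    counts = np.rint(1.0 + 200.0 * np.exp(-((gx + 2.0) ** 2 + gy ** 2) / 0.5)
                     + 80.0 * np.exp(-((gx - 2.0) ** 2 + gy ** 2) / 0.5))
    x = np.repeat(gx.ravel(), counts.ravel().astype(int))
    y = np.repeat(gy.ravel(), counts.ravel().astype(int))
    return np.column_stack([x, y])


class TestMinimaAndBasins:
    def test_two_well_surface(self):
        s = _two_well_scores()
        grid = fes_from_projection(s[:, 0], s[:, 1], nbins=30)
        minima = find_minima(grid, prominence=1.0)
        assert len(minima) == 2
        (b0, f0), (b1, f1) = minima
        assert f0 <= f1                      # sorted by F ascending
        assert f0 == 0.0                     # normalized convention
        x0 = grid.x_edges[b0[0]]
        x1 = grid.x_edges[b1[0]]
        assert x0 < 0 < x1                   # wells where they were planted

    def test_flat_surface_has_no_minima(self):
        # one frame per bin on a perfect lattice -> constant F
        g = np.linspace(0.05, 0.95, 5)
        x, y = np.meshgrid(g, g)
        grid = fes_from_projection(x.ravel(), y.ravel(), nbins=5)
        assert find_minima(grid) == []
        with pytest.raises(ValueError, match="no minima"):
            assign_basins(grid)

    def test_basins_partition_occupied_bins(self):
        s = _two_well_scores()
        grid = fes_from_projection(s[:, 0], s[:, 1], nbins=30)
        decomp = assign_basins(grid, prominence=1.0)
        covered = np.zeros(grid.F.shape, dtype=bool)
        for basin in decomp.basins:
            for i, j in basin.bins:
                assert not covered[i, j], "basins must be disjoint"
                covered[i, j] = True
        assert np.array_equal(covered, grid.occupied)
        assert [b.label for b in decomp.basins] == ["A", "B"]
        assert decomp.basins[0].relative_depth == 0.0

    def test_frame_labels_cover_all_frames(self):
        s = _two_well_scores()
        grid = fes_from_projection(s[:, 0], s[:, 1], nbins=30)
        decomp = assign_basins(grid, prominence=1.0)
        labels = decomp.frame_labels(s[:, 0], s[:, 1])
        assert set(labels) <= {"A", "B"}
        # basin A holds the majority component
        assert (labels == "A").mean() > 0.6

    def test_prominence_merges_shallow_minima(self):
        s = _two_well_scores()
        grid = fes_from_projection(s[:, 0], s[:, 1], nbins=30)
        assert len(find_minima(grid, prominence=100.0)) == 1

    def test_smoothing_path(self):
        s = _two_well_scores()
        grid = fes_from_projection(s[:, 0], s[:, 1], nbins=30)
        minima = find_minima(grid, prominence=1.0, smooth_sigma=1.0)
        assert len(minima) == 2

    def test_basin_names(self):
        assert [_basin_name(i) for i in (0, 1, 25, 26)] == ["A", "B", "Z", "AA"]


class TestRelativeDepths:
    def test_deepest_reference_default(self):
        d = relative_depths([-15.6, -13.1, -12.0, -15.5, -13.8, -11.5])
        np.testing.assert_allclose(d, [0.0, 2.5, 3.6, 0.1, 1.8, 4.1], atol=1e-9)

    def test_explicit_reference(self):
        d = relative_depths([-14.2, -13.1, -14.8, -8.1], reference_index=0)
        np.testing.assert_allclose(d, [0.0, 1.1, -0.6, 6.1], atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            relative_depths([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=12),
           st.floats(-100, 100))
    def test_gauge_invariance(self, minima, shift):
        """Adding a constant to all minima leaves relative depths unchanged."""
        base = relative_depths(minima)
        shifted = relative_depths(np.asarray(minima) + shift)
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        assert base[np.argmin(minima)] == 0.0
        assert np.all(base >= 0.0)


class TestRepresentative:
    def test_single_member(self, small_traj):
        traj, _ = small_traj
        assert representative_structure(traj, [7]) == 7

    def test_identical_frames_pick_lowest_index(self, noiseless_traj):
        traj, truth = noiseless_traj
        # noise-free: all frames of one state are identical coordinates
        anti = np.flatnonzero(truth["label"] == "antiparallel_sheet")
        if len(anti) >= 2:
            assert representative_structure(traj, anti) == int(anti[0])

    def test_majority_cluster_wins(self, noiseless_traj):
        traj, truth = noiseless_traj
        labels = truth["label"].values
        best = max((labels == l).sum() for l in set(labels))
        majority = {l for l in set(labels) if (labels == l).sum() == best}
        rep = representative_structure(traj, np.arange(len(traj)), cutoff=0.2)
        assert labels[rep] in majority

    def test_empty_rejected(self, small_traj):
        traj, _ = small_traj
        with pytest.raises(ValueError, match="at least one"):
            representative_structure(traj, [])
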