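"""Hydrogen bonds, secondary structure, contacts, frame metrics, HB maps."""

import numpy as np
import pytest

from dimerscape import (
    AnnotationConfig, assign_secondary_structure, detect_backbone_hbonds,
    frame_metrics, hb_probability_maps, interchain_contacts, trajectory_metrics,
)
from dimerscape.core import Chain, Frame, Residue


class TestHBondDetection:
    def test_helix_has_i_to_i_plus_4_bonds(self, ideal_frames):
        bonds = detect_backbone_hbonds(ideal_frames["helix_pair"])
        intra = [b for b in bonds if not b.is_inter]
        assert intra, "ideal helix must form backbone bonds"
        # donor N(i) -> acceptor O(i-4) within one chain
        offsets = {b.donor[1] - b.acceptor[1] for b in intra}
        assert offsets == {4}

    def test_sheet_has_inter_chain_bonds(self, ideal_frames):
        for kind in ("parallel_sheet", "antiparallel_sheet"):
            bonds = detect_backbone_hbonds(ideal_frames[kind])
            assert sum(b.is_inter for b in bonds) >= 4, kind

    def test_separated_chains_have_no_inter_bonds(self, ideal_frames):
        bonds = detect_backbone_hbonds(ideal_frames["helix_pair"])
        assert all(not b.is_inter for b in bonds)

    def test_geometry_self_consistency(self, small_traj):
        """Every reported bond satisfies the active criterion post hoc."""
        traj, _ = small_traj
        cfg = AnnotationConfig()
        frame = traj[0]
        atom = {(ch.id, r.index, name): xyz
                for ch in frame.chains for r in ch.residues
                for name, xyz in r.atoms.items()}
        for b in detect_backbone_hbonds(frame, cfg):
            n = atom[b.donor]
            h = atom[(b.donor[0], b.donor[1], "H")]
            o = atom[b.acceptor]
            d = np.linalg.norm(o - n)
            assert d <= cfg.hb_distance_cutoff
            cos = (h - n) @ (o - n) / (np.linalg.norm(h - n) * d)
            ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            assert ang <= cfg.hb_angle_cutoff + 1e-9
            if b.donor[0] == b.acceptor[0]:
                assert abs(b.donor[1] - b.acceptor[1]) > 1

    def test_first_residue_never_donates(self, small_traj):
        traj, _ = small_traj
        for f in range(len(traj)):
            for b in detect_backbone_hbonds(traj[f]):
                assert b.donor[1] != 1

    def test_kabsch_sander_criterion_agrees_on_ideal_helix(self, ideal_frames):
        geo = detect_backbone_hbonds(ideal_frames["helix_pair"])
        ks = detect_backbone_hbonds(
            ideal_frames["helix_pair"], AnnotationConfig(hb_method="kabsch_sander"))
        geo_pairs = {(b.donor, b.acceptor) for b in geo}
        ks_pairs = {(b.donor, b.acceptor) for b in ks}
        # the energetic criterion is more permissive but must include the
        # canonical helical i -> i-4 bonds found geometrically
        assert geo_pairs <= ks_pairs

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="hb_method"):
            AnnotationConfig(hb_method="magic")


class TestSecondaryStructure:
    def test_helix_pair(self, ideal_frames):
        per_chain, lhelix, lsheet = assign_secondary_structure(
            ideal_frames["helix_pair"])
        assert lsheet == 0
        assert lhelix >= 10  # most of both 12-mers helical
        assert all(set(labels) <= {"H", "T", "C"} for labels in per_chain)

    def test_sheets(self, ideal_frames):
        for kind in ("parallel_sheet", "antiparallel_sheet"):
            _, lhelix, lsheet = assign_secondary_structure(ideal_frames[kind])
            assert lhelix == 0, kind
            assert lsheet >= 12, kind

    def test_hairpin_has_strand_but_no_helix(self, ideal_frames):
        per_chain, lhelix, lsheet = assign_secondary_structure(
            ideal_frames["hairpin_pair"])
        assert lhelix == 0
        assert lsheet >= 6

    def test_disordered_pair_is_coil(self, ideal_frames):
        _, lhelix, lsheet = assign_secondary_structure(ideal_frames["disordered"])
        assert lhelix == 0 and lsheet == 0


class TestContacts:
    def test_sheet_contacts_in_register(self, ideal_frames):
        pairs, count = interchain_contacts(ideal_frames["parallel_sheet"])
        assert count == len(pairs) > 0
        assert all(1 <= i <= 12 and 1 <= j <= 12 for i, j in pairs)

    def test_far_apart_chains_have_no_contacts(self, ideal_frames):
        pairs, count = interchain_contacts(ideal_frames["disordered"], cutoff=0.4)
        helix_pairs, _ = interchain_contacts(ideal_frames["helix_pair"], cutoff=0.3)
        assert count == len(pairs)
        assert helix_pairs == [] or len(helix_pairs) < 3

    def test_cutoff_monotonicity(self, ideal_frames):
        frame = ideal_frames["antiparallel_sheet"]
        _, small = interchain_contacts(frame, cutoff=0.45)
        _, large = interchain_contacts(frame, cutoff=0.7)
        assert small <= large


class TestMetrics:
    def test_frame_metrics_match_components(self, small_traj):
        traj, _ = small_traj
        m = frame_metrics(traj[0])
        bonds = detect_backbone_hbonds(traj[0])
        assert m.NUMinterHB == sum(b.is_inter for b in bonds)
        assert m.NUMintraHB == sum(not b.is_inter for b in bonds)
        _, count = interchain_contacts(traj[0])
        assert m.NUMcon == count
        assert -1.0 <= m.cos_theta <= 1.0
        assert m.signed_interHB == pytest.approx(m.NUMinterHB * m.cos_theta)

    def test_trajectory_metrics_match_per_frame(self, small_traj):
        traj, _ = small_traj
        df = trajectory_metrics(traj)
        assert list(df.columns) == ["Lhelix", "Lsheet", "NUMintraHB", "NUMinterHB",
                                    "NUMcon", "cos_theta", "theta_deg",
                                    "signed_interHB"]
        for f in (0, len(traj) - 1):
            m = frame_metrics(traj[f])
            row = df.iloc[f]
            assert (row.Lhelix, row.Lsheet, row.NUMintraHB,
                    row.NUMinterHB, row.NUMcon) == (
                m.Lhelix, m.Lsheet, m.NUMintraHB, m.NUMinterHB, m.NUMcon)
            assert row.cos_theta == pytest.approx(m.cos_theta, abs=1e-12)


class TestHBMaps:
    def test_occupancies_bounded_and_located(self, noiseless_traj):
        traj, truth = noiseless_traj
        intra, inter = hb_probability_maps(traj)
        assert intra.matrix.shape == (12, 12)
        assert inter.matrix.shape == (12, 12)
        for m in (intra.matrix, inter.matrix):
            assert np.all(m >= 0) and np.all(m <= 1)
        # inter-chain occupancy only in anti-parallel frames
        frac_anti = (truth["label"] == "antiparallel_sheet").mean()
        assert inter.matrix.max() == pytest.approx(frac_anti, abs=1e-12)

    def test_window_restriction(self, noiseless_traj):
        traj, truth = noiseless_traj
        k = int(np.flatnonzero(truth["label"] == "helix_pair")[0])
        intra, inter = hb_probability_maps(traj, window=(k, k + 1))
        assert inter.matrix.sum() == 0          # helix pair: no inter bonds
        assert intra.matrix.max() == 1.0        # deterministic single frame
        assert intra.window == (k, k + 1)

    def test_bad_window_rejected(self, noiseless_traj):
        traj, _ = noiseless_traj
        with pytest.raises(ValueError, match="window"):
            hb_probability_maps(traj, window=(5, 5))
        with pytest.raises(ValueError, match="window"):
            hb_probability_maps(traj, window=(0, len(traj) + 1))
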