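"""Ramachandran binning, raw differences, normalization, ranking, projection."""

import numpy as np
import pytest

import cinc
from cinc.dihedrals import DihedralSeries, ResidueId
from cinc.scoring import (
    N_BINS,
    RamachandranMatrix,
    aggregate,
    build_rama_matrix,
    fscore2,
    rank_candidates,
    raw_difference,
    score_states,
)


def series_at(phi_psi_by_residue, state="apo", replicate=1):
    """Series with fixed per-residue angle lists (no termini handling)."""
    rids = [ResidueId("A", i + 1, "ALA") for i in range(len(phi_psi_by_residue))]
    phi = np.array([[p for p, _ in frames] for frames in phi_psi_by_residue], float)
    psi = np.array([[s for _, s in frames] for frames in phi_psi_by_residue], float)
    return DihedralSeries(state, replicate, rids, phi, psi)


def freq_matrix(bins):
    return RamachandranMatrix(residue=ResidueId("A", 1, "ALA"), state_label="apo",
                              replicate=1, bins=bins, frames_used=1)


class TestBuildRamaMatrix:
    def test_repeated_angle_fills_single_bin(self):
        s = series_at([[(-60.5, -45.2)] * 4])
        m = build_rama_matrix(s, s.residues[0])
        assert m.bins[59, 67] == 1.0  # floor((-60.5+180)/2), floor((-45.2+180)/2)
        assert m.bins.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(m.bins) == 1

    @pytest.mark.parametrize("angle,bin_idx", [(-180.0, 0), (179.9, 179),
                                               (-0.1, 89), (0.0, 90)])
    def test_edge_and_boundary_bins(self, angle, bin_idx):
        s = series_at([[(angle, angle)]])
        m = build_rama_matrix(s, s.residues[0])
        assert m.bins[bin_idx, bin_idx] == 1.0

    def test_two_distinct_cells_normalize_to_half_each(self):
        s = series_at([[(-60.0, -45.0), (60.0, 75.0)]])
        m = build_rama_matrix(s, s.residues[0])
        nz = m.bins[m.bins > 0]
        assert sorted(nz) == [0.5, 0.5]
        assert m.bins.sum() == pytest.approx(1.0)

    def test_undefined_residue_gives_none(self):
        s = series_at([[(-60.0, -45.0)]])
        s.phi[0, 0] = np.nan
        assert build_rama_matrix(s, s.residues[0]) is None

    def test_count_mode_keeps_raw_counts(self):
        s = series_at([[(-60.0, -45.0)] * 3])
        m = build_rama_matrix(s, s.residues[0], normalize=False)
        assert m.bins.sum() == 3.0


class TestRawDifference:
    def test_identical_matrices_give_zero(self):
        b = np.zeros((N_BINS, N_BINS)); b[10, 10] = 1.0
        assert raw_difference(freq_matrix(b), freq_matrix(b.copy())) == 0.0

    def test_disjoint_support_gives_two(self):
        a = np.zeros((N_BINS, N_BINS)); a[10, 10] = 1.0
        b = np.zeros((N_BINS, N_BINS)); b[100, 100] = 1.0
        assert raw_difference(freq_matrix(b), freq_matrix(a)) == 2.0

    def test_half_overlap_gives_one(self):
        a = np.zeros((N_BINS, N_BINS)); a[10, 10] = 1.0
        b = np.zeros((N_BINS, N_BINS)); b[10, 10] = 0.5; b[100, 100] = 0.5
        assert raw_difference(freq_matrix(b), freq_matrix(a)) == pytest.approx(1.0)

    def test_symmetric_in_arguments_and_matches_brute_force(self, rng):
        for _ in range(20):
            a = rng.random((N_BINS, N_BINS)); a /= a.sum()
            b = rng.random((N_BINS, N_BINS)); b /= b.sum()
            ma, mb = freq_matrix(a), freq_matrix(b)
            brute = sum(abs(a[i, j] - b[i, j])
                        for i in range(N_BINS) for j in range(N_BINS))
            assert raw_difference(mb, ma) == pytest.approx(brute, abs=1e-12)
            assert raw_difference(ma, mb) == raw_difference(mb, ma)

    def test_equals_twice_total_variation(self, rng):
        a = rng.random((N_BINS, N_BINS)); a /= a.sum()
        b = rng.random((N_BINS, N_BINS)); b /= b.sum()
        tv = 0.5 * np.abs(a - b).sum()
        assert raw_difference(freq_matrix(b), freq_matrix(a)) == pytest.approx(2 * tv)


class TestFscore2:
    def test_hand_arithmetic(self):
        r1, r2, r3 = (ResidueId("A", i, "ALA") for i in (1, 2, 3))
        out = fscore2({r1: 0.5, r2: 2.0, r3: 1.0})
        assert out == {r1: 0.25, r2: 1.0, r3: 0.5}

    def test_argmax_scores_exactly_one(self, rng):
        rids = [ResidueId("A", i, "ALA") for i in range(1, 20)]
        diffs = {r: float(rng.random()) for r in rids}
        out = fscore2(diffs)
        assert max(out.values()) == 1.0
        assert all(0.0 <= v <= 1.0 for v in out.values())

    def test_single_residue_scores_one(self):
        r = ResidueId("A", 1, "ALA")
        assert fscore2({r: 0.37}) == {r: 1.0}

    def test_degenerate_all_zero_warns(self):
        rids = [ResidueId("A", i, "ALA") for i in (1, 2)]
        with pytest.warns(UserWarning, match="indistinguishable"):
            out = fscore2({r: 0.0 for r in rids})
        assert all(v == 0.0 for v in out.values())


class TestScoreStates:
    def test_identical_states_hit_degenerate_warning_path(self, small_system):
        apo, _, _, _ = small_system
        with pytest.warns(UserWarning, match="indistinguishable"):
            records = score_states([apo[0]], [apo[0]], ligand_state="self")
        assert all(r.raw_diff == 0.0 for r in records if r.is_defined)

    def test_indexed_pairing_yields_one_record_per_residue_per_replicate(self, small_system):
        apo, bound, _, _ = small_system
        records = score_states(apo, bound)
        per_residue = {}
        for r in records:
            per_residue.setdefault(r.residue, []).append(r.replicate)
        assert all(sorted(v) == [1, 2, 3] for v in per_residue.values())

    def test_indexed_pairing_rejects_unequal_replicates(self, small_system):
        apo, bound, _, _ = small_system
        with pytest.raises(ValueError, match="pooled-apo"):
            score_states(apo[:2], bound)

    def test_pooled_apo_and_all_pairs_cardinality(self, small_system):
        apo, bound, _, _ = small_system
        pooled = score_states(apo, bound, pairing="pooled-apo")
        allp = score_states(apo, bound, pairing="all-pairs")
        n_res = apo[0].n_residues
        assert len(pooled) == 3 * n_res
        assert len(allp) == 9 * n_res

    def test_only_shifted_residue_scores_one(self):
        # 3 residues; residue 2's distribution moves, verified against a
        # brute-force per-cell loop oracle
        apo = series_at([[(-60, -45)] * 8, [(-60, -45)] * 8, [(-60, -45)] * 8], "apo")
        bound = series_at([[(-60, -45)] * 8, [(60, 75)] * 8, [(-60, -45)] * 8], "bound")
        records = score_states([apo], [bound])
        by_num = {r.residue.seq_number: r for r in records}
        assert by_num[2].fscore2 == 1.0 and by_num[2].raw_diff == 2.0
        assert by_num[1].fscore2 == 0.0 and by_num[3].fscore2 == 0.0

    def test_swapping_apo_and_bound_leaves_scores_unchanged(self, small_system):
        apo, bound, _, _ = small_system
        fwd = score_states([apo[0]], [bound[0]])
        rev = score_states([bound[0]], [apo[0]])
        f = {r.residue: r.raw_diff for r in fwd if r.is_defined}
        b = {r.residue: r.raw_diff for r in rev if r.is_defined}
        assert f == b

    def test_frame_permutation_invariance(self, small_system):
        apo, bound, _, _ = small_system
        rng = np.random.default_rng(0)
        perm = rng.permutation(apo[0].n_frames)
        apo_p = DihedralSeries("apo", 1, apo[0].residues,
                               apo[0].phi[:, perm], apo[0].psi[:, perm])
        a = score_states([apo[0]], [bound[0]])
        b = score_states([apo_p], [bound[0]])
        fa = {r.residue: r.fscore2 for r in a if r.is_defined}
        fb = {r.residue: r.fscore2 for r in b if r.is_defined}
        assert fa == fb
        assert ({r.residue for r in a if not r.is_defined}
                == {r.residue for r in b if not r.is_defined})


class TestAggregateAndRank:
    def test_mean_and_sd_match_hand_arithmetic(self):
        rid = ResidueId("A", 1, "ALA")
        recs = [cinc.ScoreRecord(rid, "lig", i + 1, 1.0, v)
                for i, v in enumerate([1.0, 1.0, 0.9994])]
        table = aggregate(recs)
        row = table.per_ligand.iloc[0]
        assert row["mean"] == pytest.approx(0.9998)
        assert row["sd"] == pytest.approx(np.std([1.0, 1.0, 0.9994], ddof=1))

    def test_single_replicate_sd_is_zero(self):
        rid = ResidueId("A", 1, "ALA")
        table = aggregate([cinc.ScoreRecord(rid, "lig", 1, 1.0, 0.7)])
        assert table.per_ligand.iloc[0]["sd"] == 0.0

    def test_cross_ligand_mean_and_min(self):
        rid = ResidueId("A", 1, "ALA")
        recs = [cinc.ScoreRecord(rid, lig, 1, 1.0, v)
                for lig, v in [("l1", 0.8), ("l2", 0.3), ("l3", 0.6)]]
        table = aggregate(recs)
        row = table.summary.iloc[0]
        assert row["cross_mean"] == pytest.approx(np.mean([0.8, 0.3, 0.6]))
        assert row["cross_min"] == pytest.approx(0.3)

    def test_binding_site_max_is_excluded_from_ranking(self):
        r1, r2 = ResidueId("A", 1, "ALA"), ResidueId("A", 2, "ALA")
        recs = [cinc.ScoreRecord(r1, "l", 1, 2.0, 1.0, is_binding_site=True),
                cinc.ScoreRecord(r2, "l", 1, 1.0, 0.5)]
        ranked = rank_candidates(aggregate(recs), n=5)
        assert list(ranked["residue"]) == [r2]

    def test_rank_order_and_tie_break(self):
        rids = [ResidueId("A", i, "ALA") for i in (1, 2, 3, 4)]
        scores = [0.5, 1.0, 1.0, 0.2]
        recs = [cinc.ScoreRecord(r, "l", 1, s, s) for r, s in zip(rids, scores)]
        ranked = rank_candidates(aggregate(recs), n=4)
        assert [r.seq_number for r in ranked["residue"]] == [2, 3, 1, 4]

    def test_n_larger_than_eligible_returns_all(self, score_table):
        ranked = rank_candidates(score_table, n=1000)
        assert len(ranked) == len(score_table.summary)

    def test_scores_lie_in_unit_interval(self, score_table):
        assert (score_table.summary["cross_mean"] >= 0).all()
        assert (score_table.summary["cross_mean"] <= 1).all()


class TestProjectToPdb:
    def test_written_bfactors_recover_scores(self, tmp_path):
        from cinc.synth import synth_toy_peptide
        import MDAnalysis as mda

        pdb = tmp_path / "pep.pdb"
        synth_toy_peptide([(-60.0, -45.0)] * 4, out=pdb)
        rids = [ResidueId("A", i, "ALA") for i in (2, 3)]
        recs = [cinc.ScoreRecord(rids[0], "l", 1, 2.0, 1.0),
                cinc.ScoreRecord(rids[1], "l", 1, 1.0, 0.4321)]
        out = tmp_path / "colored.pdb"
        cinc.project_to_pdb(aggregate(recs), pdb, out)
        u = mda.Universe(str(out))
        by_res = {r.resid: set(np.round(r.atoms.tempfactors, 2)) for r in u.residues}
        assert by_res[2] == {100.0}
        assert by_res[3] == {43.21}
        assert by_res[1] == {0.0} and by_res[4] == {0.0}  # unscored -> 0.00
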