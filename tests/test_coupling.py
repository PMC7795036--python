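import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allodyn.coupling import (
    CouplingMatrix,
    compute_coupling_matrix,
    compute_csite,
    compute_distance_series,
    rank_sites,
    ranking_mean,
    site_scores_from_values,
    strong_coupling_mask,
)
from allodyn.delta import compute_delta, resolve_delta_spec
from allodyn.ensemble_io import ResidueID, concatenate_ensembles, ensemble_from_calpha
from allodyn.sites import SiteDefinition

from _oracles import (
    coupling_matrix as oracle_coupling,
    distance_matrix as oracle_distances,
    pearson_two_pass,
    random_rigid_motion,
)


def _delta_of(ens):
    return compute_delta(
        ens, resolve_delta_spec(None, ens, anchors=tuple(ens.residues[:4]))
    )


def _matrix_from(c: np.ndarray) -> CouplingMatrix:
    """Wrap a bare symmetric coupling table for direct C_site checks."""
    n = len(c)
    valid = ~np.eye(n, dtype=bool)
    residues = [ResidueID("A", i + 1, name="ALA") for i in range(n)]
    return CouplingMatrix(residues=residues, c=np.asarray(c, float), valid=valid, n_frames=99)


class TestDistanceSeries:
    def test_three_four_five_triangle(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1] = [3.0, 4.0, 0.0]
        ens = ensemble_from_calpha(coords)
        series = compute_distance_series(ens)
        assert len(series) == 1
        assert np.allclose(series[0].values, 5.0)

    def test_matches_brute_force_distance_matrix(self, make_random_ensemble):
        ens = make_random_ensemble(n_frames=5, n_res=6)
        series = compute_distance_series(ens)
        assert len(series) == 15
        oracle = [oracle_distances(f) for f in ens.calpha]
        pos = {r: i for i, r in enumerate(ens.residues)}
        for s in series:
            i, j = pos[s.pair[0]], pos[s.pair[1]]
            expected = [oracle[f][i, j] for f in range(5)]
            assert np.abs(s.values - expected).max() < 1e-10

    def test_self_pair_rejected(self, make_random_ensemble):
        ens = make_random_ensemble()
        with pytest.raises(ValueError):
            compute_distance_series(ens, pairs=[(ens.residues[0], ens.residues[0])])


class TestCouplingMatrix:
    def test_perfect_linear_dependence_gives_unit_coupling(self):
        # residues 0..3 are Delta anchors; residue 4/5 distance = 2*Delta + 7,
        # residue 4/6 distance = -Delta + 100
        deltas = np.array([1.0, 3.0, 6.0, 2.0, 5.0])
        frames = []
        for d in deltas:
            frames.append(
                [
                    [0, 0, 0],
                    [10 + d, 0, 0],  # d1 = 10 + delta
                    [0, 50, 0],
                    [0, 50, 10],  # d2 = 10, so Delta = d
                    [0, -50, 0],
                    [0, -50, 2 * d + 7],
                    [100 - d, -50, 0],
                ]
            )
        ens = ensemble_from_calpha(np.array(frames, dtype=float))
        series = _delta_of(ens)
        assert np.allclose(series.delta, deltas)
        cm = compute_coupling_matrix(ens, series)
        assert cm.c[4, 5] == pytest.approx(1.0, abs=1e-12)
        assert cm.c[4, 6] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_pearson_on_random_ensemble(self, make_random_ensemble):
        ens = make_random_ensemble(n_frames=20, n_res=7)
        series = _delta_of(ens)
        cm = compute_coupling_matrix(ens, series)
        oracle = oracle_coupling(ens.calpha, series.delta)
        defined = ~np.isnan(oracle)
        np.fill_diagonal(defined, False)
        assert np.abs(cm.c[defined] - oracle[defined]).max() < 1e-10
        assert (cm.valid == defined).all()

    def test_symmetric_and_bounded(self, make_random_ensemble):
        ens = make_random_ensemble(n_frames=12, n_res=8)
        cm = compute_coupling_matrix(ens, _delta_of(ens))
        assert np.array_equal(cm.c, cm.c.T)
        assert np.abs(cm.c).max() <= 1.0
        assert not cm.valid.diagonal().any()

    def test_constant_delta_is_an_error(self):
        coords = np.zeros((4, 5, 3))
        coords[:, :, 0] = np.arange(5) * 5
        coords[:, 4, 1] = [1, 2, 3, 4]  # something fluctuates, Delta does not
        ens = ensemble_from_calpha(coords)
        with pytest.raises(ValueError, match="constant"):
            compute_coupling_matrix(ens, _delta_of(ens))

    def test_zero_variance_pair_flagged_invalid_and_scored_zero(self):
        deltas = np.array([1.0, 4.0, 2.0, 6.0])
        frames = []
        for d in deltas:
            frames.append(
                [
                    [0, 0, 0],
                    [10 + d, 0, 0],
                    [0, 50, 0],
                    [0, 50, 10],
                    [0, -50, 0],
                    [3, -50, 0],  # rigid w.r.t. residue 4
                    [0, -50, 5 + d],
                ]
            )
        ens = ensemble_from_calpha(np.array(frames, dtype=float))
        cm = compute_coupling_matrix(ens, _delta_of(ens))
        assert not cm.valid[4, 5]
        assert cm.c[4, 5] == 0.0
        site = SiteDefinition("s", [ens.residues[4], ens.residues[5], ens.residues[6]])
        sc = compute_csite(cm, site)
        # rigid pair counts 0 in the sum but stays in the denominator
        expected = (0.0 + abs(cm.c[4, 6]) + abs(cm.c[5, 6])) / 3
        assert sc.c_site == pytest.approx(expected, abs=1e-12)
        assert sc.n_invalid_pairs == 1

    def test_rigid_motion_invariance(self, make_random_ensemble, rng):
        ens = make_random_ensemble(n_frames=15, n_res=6)
        cm = compute_coupling_matrix(ens, _delta_of(ens))
        moved = []
        for frame in ens.calpha:
            R, t = random_rigid_motion(rng)
            moved.append(frame @ R.T + t)
        ens2 = ensemble_from_calpha(np.array(moved))
        cm2 = compute_coupling_matrix(ens2, _delta_of(ens2))
        assert np.abs(cm.c - cm2.c).max() < 1e-9

    def test_frame_permutation_leaves_matrix_bitwise_unchanged(
        self, make_random_ensemble, rng
    ):
        ens = make_random_ensemble(n_frames=17, n_res=6)
        cm = compute_coupling_matrix(ens, _delta_of(ens))
        perm = rng.permutation(ens.n_frames)
        ens2 = ensemble_from_calpha(ens.calpha[perm])
        cm2 = compute_coupling_matrix(ens2, _delta_of(ens2))
        assert np.array_equal(cm.c, cm2.c)

    def test_duplication_invariance(self, make_random_ensemble):
        ens = make_random_ensemble(n_frames=9, n_res=6)
        cm = compute_coupling_matrix(ens, _delta_of(ens))
        both = concatenate_ensembles(ens, ens)
        cm2 = compute_coupling_matrix(both, _delta_of(both))
        assert np.abs(cm.c - cm2.c).max() < 1e-12


class TestStrongMask:
    def test_strict_inequality_at_the_threshold(self):
        cm = _matrix_from([[0.0, 0.76, 0.75], [0.76, 0.0, -0.9], [0.75, -0.9, 0.0]])
        mask = strong_coupling_mask(cm, 0.75)
        assert mask[0, 1] and mask[1, 2]
        assert not mask[0, 2]

    def test_all_zero_matrix_has_empty_mask(self):
        cm = _matrix_from(np.zeros((4, 4)))
        assert not strong_coupling_mask(cm, 0.75).any()

    def test_tiny_threshold_catches_any_nonzero(self):
        cm = _matrix_from([[0.0, 0.01], [0.01, 0.0]])
        assert strong_coupling_mask(cm, 1e-6)[0, 1]


class TestCsite:
    def test_three_residue_worked_example(self):
        c = np.zeros((3, 3))
        c[0, 1] = c[1, 0] = 0.9
        c[0, 2] = c[2, 0] = -0.6
        c[1, 2] = c[2, 1] = 0.3
        cm = _matrix_from(c)
        site = SiteDefinition("s", cm.residues)
        assert compute_csite(cm, site).c_site == pytest.approx(0.6, abs=1e-15)

    def test_two_residue_site_is_single_pair(self):
        cm = _matrix_from([[0.0, -0.42], [-0.42, 0.0]])
        sc = compute_csite(cm, SiteDefinition("s", cm.residues))
        assert sc.c_site == pytest.approx(0.42)
        assert sc.top_pair[2] == pytest.approx(-0.42)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=2, max_value=10),
        st.floats(min_value=-1.0, max_value=1.0, allow_nan=False),
    )
    def test_constant_submatrix_identity(self, n, c):
        mat = np.full((n, n), c)
        np.fill_diagonal(mat, 0.0)
        cm = _matrix_from(mat)
        sc = compute_csite(cm, SiteDefinition("s", cm.residues))
        assert sc.c_site == pytest.approx(abs(c), abs=1e-12)

    def test_top_pair_has_max_absolute_coupling(self, make_random_ensemble):
        ens = make_random_ensemble(n_frames=10, n_res=8)
        cm = compute_coupling_matrix(ens, _delta_of(ens))
        site = SiteDefinition("s", ens.residues[4:])
        sc = compute_csite(cm, site)
        assert abs(sc.top_pair[2]) == np.abs(sc.submatrix).max()

    def test_union_csite_is_not_mean_of_parts(self):
        # cross-pairs enter the union score: guard against averaging shortcut
        c = np.zeros((4, 4))
        c[0, 1] = c[1, 0] = 1.0
        c[2, 3] = c[3, 2] = 1.0  # both halves score 1.0; cross pairs are 0
        cm = _matrix_from(c)
        union = compute_csite(cm, SiteDefinition("u", cm.residues)).c_site
        assert union == pytest.approx(2.0 / 6.0)
        assert union != pytest.approx(1.0)

    def test_single_residue_site_cannot_be_scored(self):
        cm = _matrix_from(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="too small"):
            compute_csite(cm, SiteDefinition("s", cm.residues[:1]))


class TestRanking:
    def test_descending_order_mean_and_above_mean_flags(self):
        values = {
            "site4": 0.76, "site3": 0.61, "site7": 0.60, "site6": 0.59,
            "site5": 0.50, "site2": 0.49, "site8": 0.44, "site9": 0.33,
            "site1": 0.31,
        }
        ranked = rank_sites(site_scores_from_values(values))
        assert [s.site_label for s in ranked] == [
            "site4", "site3", "site7", "site6", "site5", "site2", "site8",
            "site9", "site1",
        ]
        assert round(ranking_mean(ranked), 2) == 0.51
        assert {s.site_label for s in ranked if s.above_mean} == {
            "site4", "site3", "site7", "site6",
        }
        assert [s.rank for s in ranked] == list(range(1, 10))

    def test_single_site_is_not_above_its_own_mean(self):
        (only,) = rank_sites(site_scores_from_values({"a": 0.5}))
        assert only.rank == 1 and only.above_mean is False

    def test_ties_break_by_label(self):
        ranked = rank_sites(site_scores_from_values({"b": 0.4, "a": 0.4, "c": 0.9}))
        assert [s.site_label for s in ranked] == ["c", "a", "b"]

    def test_duplicate_labels_rejected(self):
        scores = site_scores_from_values({"a": 0.4, "b": 0.5})
        scores[1].site_label = "a"
        with pytest.raises(ValueError, match="unique"):
            rank_sites(scores)


class TestFullPipelineOracle:
    def test_distances_correlations_and_csite_match_brute_force(self, rng):
        from _oracles import csite as oracle_csite

        for _ in range(10):
            n_res = int(rng.integers(4, 9))
            n_frames = int(rng.integers(5, 26))
            ens = ensemble_from_calpha(rng.normal(size=(n_frames, n_res, 3)) * 5)
            series = _delta_of(ens)
            cm = compute_coupling_matrix(ens, series)
            oracle = oracle_coupling(ens.calpha, series.delta)
            defined = ~np.isnan(oracle)
            np.fill_diagonal(defined, False)
            assert np.abs(cm.c[defined] - oracle[defined]).max() < 1e-10
            idx = list(rng.choice(n_res, size=3, replace=False))
            site = SiteDefinition("s", [ens.residues[i] for i in idx])
            sc = compute_csite(cm, site)
            assert sc.c_site == pytest.approx(oracle_csite(oracle, idx), abs=1e-10)
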