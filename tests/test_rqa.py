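"""Recurrence matrices, line distributions and RR/DET/LAM against naive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rqaboot import (
    diagonal_line_distribution,
    distance_matrix,
    recurrence_matrix,
    rqa_measures,
    threshold_for_target_rr,
    vertical_line_distribution,
    write_pgm,
)
from rqaboot.rqa import LineDistribution

from _oracles import naive_rqa


def _random_rec(rng, n=40, theiler=1, rr=0.1):
    states = rng.normal(size=(n, 3))
    dm = distance_matrix(states)
    eps, _ = threshold_for_target_rr(dm, rr, theiler=theiler)
    return states, dm, recurrence_matrix(dm, eps, theiler=theiler)


class TestDistanceMatrix:
    def test_named_norms(self):
        states = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert distance_matrix(states, "max").entries[0, 1] == 4.0
        assert distance_matrix(states, "euclidean").entries[0, 1] == 5.0
        assert distance_matrix(states, "manhattan").entries[0, 1] == 7.0

    def test_identical_states_give_zero(self):
        states = np.ones((5, 2))
        assert np.all(distance_matrix(states).entries == 0.0)

    def test_unknown_norm_lists_supported(self):
        with pytest.raises(ValueError, match="euclidean"):
            distance_matrix(np.eye(3), "L7")

    def test_symmetric_zero_diagonal(self, rng):
        dm = distance_matrix(rng.normal(size=(20, 4)))
        np.testing.assert_array_equal(dm.entries, dm.entries.T)
        assert np.all(np.diag(dm.entries) == 0)
        assert np.all(dm.entries >= 0)


class TestAdaptiveThreshold:
    def test_order_statistic_on_known_distances(self):
        # states on a line: unmasked off-diagonal max-norm distances are the
        # pairwise index differences
        states = np.arange(5.0)
        dm = distance_matrix(states)
        eps, rr = threshold_for_target_rr(dm, 0.3, theiler=1)
        n_unmasked = 20
        # distances multiset (upper triangle): 1,1,1,1,2,2,2,3,3,4
        # k = round(0.3 * 20 / 2) = 3 -> eps = third smallest = 1
        assert eps == 1.0
        assert rr == 8 / n_unmasked  # all four pairs at distance 1

    def test_five_percent_target_within_one_cell(self, rng):
        states = rng.normal(size=(880, 6))
        dm = distance_matrix(states)
        eps, rr = threshold_for_target_rr(dm, 0.05, theiler=1)
        n_unmasked = 880 * 880 - 880
        # independent brute-force count of cells at or below eps
        count = int(np.count_nonzero(dm.entries <= eps)) - 880  # minus diagonal zeros
        assert rr == count / n_unmasked
        assert abs(rr - 0.05) <= 1.0 / n_unmasked

    def test_target_near_one_selects_largest_distance(self, rng):
        states = rng.normal(size=(30, 2))
        dm = distance_matrix(states)
        eps, rr = threshold_for_target_rr(dm, 0.999, theiler=1)
        assert eps == dm.entries.max()
        assert rr == 1.0

    def test_identical_distances_not_tunable(self):
        states = np.array([[0.0], [1.0], [2.0]])
        dm = distance_matrix(states)
        dm.entries[:] = 1.0  # degenerate: every off-diagonal distance equal
        np.fill_diagonal(dm.entries, 0.0)
        with pytest.raises(ValueError, match="not tunable"):
            threshold_for_target_rr(dm, 0.5, theiler=1)


class TestRecurrenceMatrix:
    def test_zero_epsilon_marks_only_exact_repeats(self):
        states = np.array([[0.0], [1.0], [0.0]])
        rec = recurrence_matrix(distance_matrix(states), 0.0, theiler=0)
        expected = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]], dtype=bool)
        np.testing.assert_array_equal(rec.matrix, expected)

    def test_huge_epsilon_gives_full_matrix(self, rng):
        states = rng.normal(size=(15, 2))
        dm = distance_matrix(states)
        rec = recurrence_matrix(dm, dm.entries.max(), theiler=0)
        assert np.all(rec.matrix)
        assert rqa_measures(rec).rr == 1.0

    def test_elementwise_heaviside_oracle(self, rng):
        states = rng.normal(size=(30, 3))
        dm = distance_matrix(states)
        eps = np.median(dm.entries)
        rec = recurrence_matrix(dm, eps, theiler=0)
        for i in range(30):
            for j in range(30):
                assert rec.matrix[i, j] == (dm.entries[i, j] <= eps)


class TestLineDistributions:
    def test_diagonal_run_and_isolated_points(self):
        # upper triangle: a run of 3 on offset 2 and isolated points at
        # (0,4) and (1,5); symmetric counterpart below
        n = 6
        m = np.zeros((n, n), dtype=bool)
        for i in range(3):
            m[i, i + 2] = m[i + 2, i] = True
        m[0, 4] = m[4, 0] = True
        m[0, 5] = m[5, 0] = True
        rec = recurrence_matrix(
            distance_matrix(np.arange(float(n))), 0.0, theiler=1
        )
        object.__setattr__(rec, "matrix", m)
        dist = diagonal_line_distribution(rec)
        assert dist.counts == {3: 1, 1: 2}

    def test_empty_matrix_empty_counts(self):
        rec = recurrence_matrix(distance_matrix(np.arange(5.0)), 0.0, theiler=1)
        assert diagonal_line_distribution(rec).counts == {}
        assert vertical_line_distribution(rec).counts == {}

    def test_vertical_run_plus_isolated_point(self):
        n = 7
        m = np.zeros((n, n), dtype=bool)
        m[2:6, 0] = True  # vertical run of 4 in column 0
        m[0, 5] = True  # isolated point elsewhere
        rec = recurrence_matrix(distance_matrix(np.arange(float(n))), 0.0, theiler=1)
        object.__setattr__(rec, "matrix", m)
        dist = vertical_line_distribution(rec)
        assert dist.counts == {4: 1, 1: 1}

    def test_fully_recurrent_matrix_verticals(self, rng):
        states = np.zeros((8, 2))
        rec = recurrence_matrix(distance_matrix(states), 0.5, theiler=0)
        dist = vertical_line_distribution(rec)
        assert dist.counts == {8: 8}

    def test_random_matrices_match_rle_oracle(self, rng):
        for theiler in (0, 1, 2):
            states, dm, rec = _random_rec(rng, n=35, theiler=theiler, rr=0.15)
            _, _, _, diag_oracle, vert_oracle = naive_rqa(
                states, rec.epsilon, theiler
            )
            assert diagonal_line_distribution(rec).counts == diag_oracle
            assert vertical_line_distribution(rec).counts == vert_oracle


class TestMeasures:
    def test_det_from_distribution(self):
        dist = LineDistribution(kind="diagonal", counts={3: 1, 1: 2}, n_cells=100)
        assert dist.fraction_at_least(2) == pytest.approx(0.6)

    def test_lam_from_distribution(self):
        dist = LineDistribution(kind="vertical", counts={4: 1, 1: 1}, n_cells=100)
        assert dist.fraction_at_least(2) == pytest.approx(0.8)

    def test_periodic_trajectory_det_one(self):
        t = np.arange(300)
        values = np.sin(2 * np.pi * t / 47.3)
        states = np.stack([values[:-12], values[12:]], axis=1)
        dm = distance_matrix(states)
        eps, _ = threshold_for_target_rr(dm, 0.05, theiler=1)
        rec = recurrence_matrix(dm, eps, theiler=1)
        meas = rqa_measures(rec, lmin=2, vmin=2)
        assert meas.det > 0.99

    def test_zero_recurrence_convention(self):
        rec = recurrence_matrix(distance_matrix(np.arange(6.0)), 0.0, theiler=1)
        with pytest.warns(UserWarning):
            meas = rqa_measures(rec)
        assert (meas.rr, meas.det, meas.lam) == (0.0, 0.0, 0.0)

    def test_full_agreement_with_naive_oracle(self, rng):
        for _ in range(5):
            states, dm, rec = _random_rec(rng, n=30, theiler=1, rr=0.2)
            rr_o, det_o, lam_o, _, _ = naive_rqa(states, rec.epsilon, 1)
            meas = rqa_measures(rec)
            assert meas.rr == rr_o
            assert meas.det == pytest.approx(det_o, abs=1e-14)
            assert meas.lam == pytest.approx(lam_o, abs=1e-14)


class TestInvariants:
    def test_conservation_of_recurrence_points(self, rng):
        for theiler in (0, 1, 3):
            states, dm, rec = _random_rec(rng, n=40, theiler=theiler, rr=0.12)
            diag = diagonal_line_distribution(rec)
            vert = vertical_line_distribution(rec)
            points = rec.recurrence_points()
            assert vert.total_points == points
            if theiler == 0:
                n = rec.n
                assert 2 * diag.total_points - n == points
            else:
                assert 2 * diag.total_points == points

    def test_monotonicity_in_epsilon(self, rng):
        states = rng.normal(size=(50, 2))
        dm = distance_matrix(states)
        epsilons = np.quantile(dm.entries[dm.entries > 0], [0.1, 0.3, 0.5, 0.8])
        prev_rr = prev_det_num = prev_lam_num = -1.0
        for eps in epsilons:
            rec = recurrence_matrix(dm, eps, theiler=1)
            diag = diagonal_line_distribution(rec)
            vert = vertical_line_distribution(rec)
            rr = rec.recurrence_points() / rec.n_unmasked
            det_num = sum(l * c for l, c in diag.counts.items() if l >= 2)
            lam_num = sum(l * c for l, c in vert.counts.items() if l >= 2)
            assert rr >= prev_rr
            assert det_num >= prev_det_num
            assert lam_num >= prev_lam_num
            prev_rr, prev_det_num, prev_lam_num = rr, det_num, lam_num

    def test_lmin_one_gives_unity_when_recurrent(self, rng):
        states, dm, rec = _random_rec(rng, n=30, theiler=1, rr=0.1)
        meas = rqa_measures(rec, lmin=1, vmin=1)
        assert meas.rr > 0
        assert meas.det == 1.0
        assert meas.lam == 1.0

    def test_transpose_symmetry(self, rng):
        states, dm, rec = _random_rec(rng, n=30, theiler=1, rr=0.15)
        rec_t = recurrence_matrix(
            distance_matrix(states[:, ::-1].copy()), rec.epsilon, theiler=1
        )
        # transposing the matrix directly: measures must be identical
        object.__setattr__(rec_t, "matrix", rec.matrix.T.copy())
        m1, m2 = rqa_measures(rec), rqa_measures(rec_t)
        assert m1.rr == m2.rr
        assert m1.det == m2.det
        assert m1.lam == m2.lam

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), theiler=st.integers(0, 2))
    def test_oracle_equivalence_property(self, seed, theiler):
        rng = np.random.default_rng(seed)
        states = rng.normal(size=(rng.integers(10, 45), rng.integers(1, 4)))
        dm = distance_matrix(states)
        eps = float(np.quantile(dm.entries[dm.entries > 0], 0.2))
        rec = recurrence_matrix(dm, eps, theiler=theiler)
        rr_o, det_o, lam_o, _, _ = naive_rqa(states, eps, theiler)
        meas = rqa_measures(rec)
        assert meas.rr == pytest.approx(rr_o, abs=1e-14)
        assert meas.det == pytest.approx(det_o, abs=1e-14)
        assert meas.lam == pytest.approx(lam_o, abs=1e-14)


class TestPGMExport:
    def test_plain_text_image_round_trip(self, rng, tmp_path):
        states, dm, rec = _random_rec(rng, n=12, theiler=1, rr=0.2)
        path = tmp_path / "rp.pbm"
        write_pgm(rec, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "P1"
        assert lines[1] == "12 12"
        pixels = np.array([[int(x) for x in row.split()] for row in lines[2:]])
        np.testing.assert_array_equal(pixels[::-1], rec.matrix.astype(int))
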