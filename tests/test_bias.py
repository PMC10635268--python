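"""Reverse-correlation bias, permutation tests, and BH-FDR."""

import math

import numpy as np
import pytest

from cuesync.bias import (
    compute_bias,
    fdr_bh,
    group_difference_test,
    map_trs_to_bins,
    session_delta_test,
)
from cuesync.labels import LabelTrack
from cuesync.simulate import generate_label_track


class TestMapTrsToBins:
    def test_single_tr_maps_to_five_lagged_bins(self):
        assert map_trs_to_bins([0], 1023).tolist() == [0, 1, 2, 3, 4]

    def test_adjacent_trs_deduplicate(self):
        assert map_trs_to_bins([0, 1], 1023).tolist() == [0, 1, 2, 3, 4, 5]

    def test_boundary_clipping_discards_negative_bins(self):
        # movie time 3 -> bins -7..-3, all clipped
        assert map_trs_to_bins([3], 1023, tr_offset_seconds=0).size == 0

    def test_empty_input_gives_empty_set(self):
        assert map_trs_to_bins([], 100).size == 0

    def test_invalid_lag_window_rejected(self):
        with pytest.raises(ValueError):
            map_trs_to_bins([0], 100, lag_lo=10, lag_hi=5)


class TestComputeBias:
    def test_half_labeled(self):
        track = LabelTrack(labels=np.array([1, 1, 0, 0], dtype=np.int8))
        assert compute_bias([0, 1, 2, 3], track) == 0.5

    def test_empty_bin_set_undefined(self):
        track = LabelTrack(labels=np.array([1, 0], dtype=np.int8))
        assert math.isnan(compute_bias([], track))

    def test_movie_scale_fraction(self):
        track = generate_label_track(1023, 464 / 1023, seed=0)
        assert compute_bias(np.arange(1023), track) == pytest.approx(0.454, abs=0.001)

    def test_duplicates_ignored(self):
        track = LabelTrack(labels=np.array([1, 0, 0, 0], dtype=np.int8))
        assert compute_bias([0, 0, 1], track) == compute_bias([0, 1], track)

    def test_out_of_range_rejected(self):
        track = LabelTrack(labels=np.array([1, 0], dtype=np.int8))
        with pytest.raises(ValueError):
            compute_bias([5], track)


@pytest.fixture
def toy_track():
    return generate_label_track(120, 0.4, seed=5)


class TestGroupDifferenceTest:
    def test_identical_sets_give_zero_statistic(self, toy_track):
        t = [10, 20, 30]
        res = group_difference_test(t, t, toy_track, range(100), n_perm=300, seed=0)
        assert res.statistic == 0.0
        assert res.p_value > 0.5

    def test_all_drug_track_degenerate(self):
        track = LabelTrack(labels=np.ones(60, dtype=np.int8))
        res = group_difference_test([5, 6], [20, 30], track, range(50), n_perm=200, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_empty_set_undefined_result(self, toy_track):
        res = group_difference_test([], [5], toy_track, range(100), n_perm=100, seed=0)
        assert not res.defined
        assert math.isnan(res.p_value)

    def test_label_swap_symmetry(self, toy_track):
        flipped = LabelTrack(labels=1 - toy_track.labels)
        a, b = [3, 40, 41], [15, 60]
        res = group_difference_test(a, b, toy_track, range(100), n_perm=500, seed=11)
        res_f = group_difference_test(a, b, flipped, range(100), n_perm=500, seed=11)
        assert res_f.statistic == pytest.approx(-res.statistic)
        assert res_f.p_value == pytest.approx(res.p_value)

    def test_oversized_set_rejected(self, toy_track):
        with pytest.raises(ValueError):
            group_difference_test(list(range(20)), [1], toy_track, range(10), n_perm=10)

    def test_p_values_valid_under_null(self, rng):
        """P(p <= alpha) <= alpha + tolerance when T* is random."""
        track = generate_label_track(80, 0.5, seed=1)
        alpha, hits, n_rep = 0.1, 0, 150
        for i in range(n_rep):
            t_a = rng.choice(60, size=4, replace=False)
            t_b = rng.choice(60, size=4, replace=False)
            res = group_difference_test(
                t_a, t_b, track, range(60), n_perm=200, seed=int(rng.integers(2**31))
            )
            hits += res.p_value <= alpha
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert hits / n_rep <= alpha + 3 * se


class TestSessionDeltaTest:
    def _sets(self, a1, a2, b1, b2):
        return {
            ("A", "baseline"): a1,
            ("A", "followup"): a2,
            ("B", "baseline"): b1,
            ("B", "followup"): b2,
        }

    def test_identical_sets_zero_statistic(self, toy_track):
        t = [5, 30, 70]
        res = session_delta_test(
            self._sets(t, t, t, t), toy_track, range(100), n_perm=200, seed=0
        )
        assert res.statistic == 0.0

    def test_group_swap_flips_sign(self, toy_track):
        a1, a2, b1, b2 = [4, 5], [60, 61], [20, 40], [22, 44]
        res = session_delta_test(
            self._sets(a1, a2, b1, b2), toy_track, range(100), n_perm=300, seed=3
        )
        res_sw = session_delta_test(
            self._sets(b1, b2, a1, a2), toy_track, range(100), n_perm=300, seed=3
        )
        assert res_sw.statistic == pytest.approx(-res.statistic)

    def test_any_empty_set_undefined(self, toy_track):
        res = session_delta_test(
            self._sets([1], [], [2], [3]), toy_track, range(100), n_perm=100, seed=0
        )
        assert not res.defined

    def test_missing_cell_rejected(self, toy_track):
        with pytest.raises(KeyError):
            session_delta_test(
                {("A", "baseline"): [1]}, toy_track, range(100), n_perm=10
            )


class TestFdrBh:
    def test_hand_computed_qvalues(self):
        q, reject = fdr_bh([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])
        assert reject.all()

    def test_all_ones_no_discoveries(self):
        q, reject = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_small_p_discovered(self):
        _, reject = fdr_bh([0.04], q=0.05)
        assert reject.all()

    def test_nan_excluded_from_family(self):
        q, reject = fdr_bh([0.01, np.nan, 0.5])
        assert math.isnan(q[1]) and not reject[1]
        # family size is 2, so q for 0.01 is 0.02
        assert q[0] == pytest.approx(0.02)

    def test_empty_input(self):
        q, reject = fdr_bh([])
        assert q.size == 0 and reject.size == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])
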