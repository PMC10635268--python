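"""ISC, Fisher aggregation, behavior correlations, summary statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cuesync.behavior import (
    fisher_aggregate,
    isc_behavior_correlations,
    loo_isc,
    paired_nonparametric,
    pooled_t,
)


class TestLooIsc:
    def test_identical_subjects_give_unit_correlation(self, rng):
        v = rng.standard_normal(60)
        out = loo_isc(np.tile(v, (5, 1)))
        assert np.allclose(out, 1.0)

    def test_negated_subject_gets_minus_one(self, rng):
        v = rng.standard_normal(60)
        values = np.vstack([v, v, v, -v])
        out = loo_isc(values)
        assert out[-1] == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        values = rng.standard_normal((6, 80))
        base = loo_isc(values)
        shifted = values.copy()
        shifted[2] = 3.0 * shifted[2] + 10.0
        assert loo_isc(shifted)[2] == pytest.approx(base[2])

    def test_constant_subject_flagged_nan(self, rng):
        values = rng.standard_normal((4, 50))
        values[1] = 2.0
        with pytest.warns(RuntimeWarning):
            out = loo_isc(values)
        assert np.isnan(out[1])

    def test_requires_three_subjects(self, rng):
        with pytest.raises(ValueError):
            loo_isc(rng.standard_normal((2, 30)))


class TestFisherAggregate:
    def test_fixed_point(self):
        assert fisher_aggregate([0.5, 0.5]) == pytest.approx(0.5)

    def test_antisymmetric_pair_cancels(self):
        assert fisher_aggregate([0.3, -0.3]) == pytest.approx(0.0)

    def test_closed_form(self):
        expected = np.tanh((np.arctanh(0.2) + np.arctanh(0.8)) / 2)
        assert fisher_aggregate([0.2, 0.8]) == pytest.approx(expected)

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError, match="clip"):
            fisher_aggregate([0.5, 1.0])


class TestPooledT:
    @pytest.mark.parametrize(
        "m1,s1,n1,m2,s2,n2,expected,tol",
        [
            (39.97, 10.76, 25, 40.00, 8.41, 30, -0.011, 0.001),
            (110.28, 6.85, 25, 96.53, 11.73, 30, 5.2, 0.05),
            (11.96, 2.76, 25, 10.43, 3.15, 30, 1.9, 0.05),
        ],
    )
    def test_group_profile_statistics(self, m1, s1, n1, m2, s2, n2, expected, tol):
        t, df = pooled_t(m1, s1, n1, m2, s2, n2)
        assert df == 53
        assert t == pytest.approx(expected, abs=tol)

    def test_equal_means_give_zero(self):
        t, _ = pooled_t(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0

    def test_antisymmetric_under_group_swap(self):
        t1, _ = pooled_t(3.0, 1.0, 8, 5.0, 2.0, 9)
        t2, _ = pooled_t(5.0, 2.0, 9, 3.0, 1.0, 8)
        assert t1 == pytest.approx(-t2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pooled_t(1, 1, 1, 2, 1, 5)
        with pytest.raises(ValueError):
            pooled_t(1, 0, 5, 2, 1, 5)


class TestPairedNonparametric:
    def test_all_positive_deltas_exact_tail(self):
        res = paired_nonparametric([1, 2, 3, 4, 5], alternative="greater")
        assert res.w_minus == 0.0
        assert res.p_value == pytest.approx(1 / 32)

    def test_symmetric_pair_two_sided_p_one(self):
        res = paired_nonparametric([-1, 1])
        assert res.p_value == pytest.approx(1.0)

    def test_negation_preserves_two_sided_p(self, rng):
        d = rng.standard_normal(12) + 0.4
        a = paired_nonparametric(d)
        b = paired_nonparametric(-d)
        assert a.p_value == pytest.approx(b.p_value)
        assert a.w_plus == b.w_minus

    def test_matches_scipy_exact_without_ties(self, rng):
        d = rng.standard_normal(15)
        res = paired_nonparametric(d)
        ref = stats.wilcoxon(d, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)
        assert res.statistic == pytest.approx(ref.statistic)

    def test_zeros_dropped_and_all_zero_rejected(self):
        res = paired_nonparametric([0, 0, 1, 2, -3, 4, 5, 0])
        assert res.n_used == 5
        with pytest.raises(ValueError):
            paired_nonparametric([0.0, 0.0])


class TestIscBehaviorCorrelations:
    def _tables(self, n=10, link=True, seed=0):
        rng = np.random.default_rng(seed)
        subs = [f"s{i}" for i in range(n)]
        rows_i, rows_b = [], []
        for s_idx, session in enumerate(("baseline", "followup")):
            isc = rng.uniform(0.1, 0.8, n)
            crav = isc * 5 + rng.normal(0, 0.01, n) if link else rng.normal(5, 1, n)
            for i, sub in enumerate(subs):
                rows_i.append({"subject_id": sub, "session": session, "isc": isc[i]})
                rows_b.append(
                    {"subject_id": sub, "session": session, "craving": crav[i]}
                )
        return pd.DataFrame(rows_i), pd.DataFrame(rows_b)

    def test_tight_link_recovered_at_baseline_and_delta(self):
        isc, beh = self._tables(link=True)
        out = isc_behavior_correlations(isc, beh, ["craving"])
        assert set(out["session_or_delta"]) == {"baseline", "delta"}
        assert (out["r"] > 0.99).all()
        assert (out["q"] < 0.05).all()

    def test_identical_deltas_unit_correlation(self):
        isc, _ = self._tables(link=True)
        beh = isc.rename(columns={"isc": "craving"})
        out = isc_behavior_correlations(isc, beh, ["craving"])
        delta_r = out.loc[out["session_or_delta"] == "delta", "r"].iloc[0]
        assert delta_r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        isc, beh = self._tables(n=3)
        with pytest.raises(ValueError):
            isc_behavior_correlations(isc, beh, ["craving"])

    def test_unknown_measure_rejected(self):
        isc, beh = self._tables()
        with pytest.raises(KeyError):
            isc_behavior_correlations(isc, beh, ["nope"])
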