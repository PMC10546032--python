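"""Kaplan-Meier, log-rank, time-dependent AUC, concordance, calibration."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import lactpair as lp

from conftest import make_clinical


def logrank_oracle(times_a, times_b):
    """Closed-form two-group log-rank: sum(O-E) over death times with the
    hypergeometric variance; no censoring."""
    all_deaths = sorted(set(times_a) | set(times_b))
    O_minus_E = 0.0
    V = 0.0
    for t in all_deaths:
        na = sum(1 for x in times_a if x >= t)
        nb = sum(1 for x in times_b if x >= t)
        n = na + nb
        d = sum(1 for x in times_a if x == t) + sum(1 for x in times_b if x == t)
        oa = sum(1 for x in times_a if x == t)
        O_minus_E += oa - d * na / n
        if n > 1:
            V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestKaplanMeier:
    def test_all_events_distinct_times_closed_form(self):
        curve = lp.km_curve(make_clinical([1, 2, 3, 4], [1, 1, 1, 1]))
        for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            assert curve.at(t) == pytest.approx(s)

    def test_all_censored_flat_at_one(self):
        curve = lp.km_curve(make_clinical([2, 5, 7], [0, 0, 0]))
        assert np.all(curve.survival_prob == 1.0)

    def test_mixed_table_equals_hand_product_limit(self):
        # deaths at 1 (n=5), 3 (n=3 after a censor at 2), censor at 4, death at 5
        clin = make_clinical([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        curve = lp.km_curve(clin)
        assert curve.at(1) == pytest.approx(4 / 5)
        assert curve.at(3) == pytest.approx(4 / 5 * 2 / 3)
        assert curve.at(5) == pytest.approx(4 / 5 * 2 / 3 * 0)

    def test_mass_conservation_product_form(self):
        rng = np.random.default_rng(2)
        t = np.ceil(rng.exponential(5, size=60))
        e = (rng.random(60) < 0.7).astype(int)
        curve = lp.km_curve(make_clinical(t, e))
        # recompute product-limit directly
        s = 1.0
        for i, ti in enumerate(curve.times):
            d = np.sum((t == ti) & (e == 1))
            n = np.sum(t >= ti)
            if n > 0:
                s *= 1 - d / n
            assert curve.survival_prob[i] == pytest.approx(s, abs=1e-12)


class TestLogrank:
    def test_symmetric_interleaved_groups_give_zero(self):
        # identical event-time multisets in both groups: O == E at every death
        clin = make_clinical([1, 1, 2, 2, 3, 3], [1, 1, 1, 1, 1, 1])
        chi2, p = lp.logrank_test(["a", "b", "a", "b", "a", "b"], clin)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_four_sample_example(self):
        # group A deaths at {1,3}, B at {2,4}: chi2 = 0.4444/0.7222 = 0.615
        clin = make_clinical([1, 3, 2, 4], [1, 1, 1, 1])
        chi2, _ = lp.logrank_test(["A", "A", "B", "B"], clin)
        assert chi2 == pytest.approx(logrank_oracle([1, 3], [2, 4]), abs=1e-9)
        assert chi2 == pytest.approx(0.615, abs=5e-4)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        clin = make_clinical(rng.exponential(1, 40), (rng.random(40) < 0.8).astype(int))
        g = np.where(rng.random(40) < 0.5, "x", "y")
        chi2a, _ = lp.logrank_test(g, clin)
        chi2b, _ = lp.logrank_test(np.where(g == "x", "y", "x"), clin)
        assert chi2a == pytest.approx(chi2b, abs=1e-12)

    def test_planted_signal_is_detected(self):
        rng = np.random.default_rng(4)
        n = 300
        g = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(np.exp(-2.0 * g) / 0.04)
        clin = make_clinical(t, np.ones(n, dtype=int))
        _, p = lp.logrank_test(np.where(g > 0, "hi", "lo"), clin)
        assert p < 1e-3

    def test_single_group_rejected(self):
        clin = make_clinical([1, 2], [1, 1])
        with pytest.raises(ValueError, match="two groups"):
            lp.logrank_test(["a", "a"], clin)


class TestTimeDependentAUC:
    def test_perfect_ranking_uncensored_gives_one(self):
        t = np.arange(1.0, 41.0)
        clin = make_clinical(t, np.ones(40, dtype=int))
        auc = lp.time_dependent_auc(-t, clin, [5, 15, 30])
        assert np.allclose(auc.to_numpy(), 1.0)

    def test_equals_binary_auc_without_censoring(self):
        rng = np.random.default_rng(6)
        n = 200
        t = rng.exponential(10, size=n)
        scores = -t + rng.normal(0, 5, size=n)
        clin = make_clinical(t, np.ones(n, dtype=int))
        for h in (5.0, 10.0):
            auc = lp.time_dependent_auc(scores, clin, [h]).iloc[0]
            plain = roc_auc_score((t <= h).astype(int), scores)
            assert auc == pytest.approx(plain, abs=1e-10)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(7)
        n = 150
        t = rng.exponential(10, size=n)
        e = (rng.random(n) < 0.7).astype(int)
        s = rng.normal(size=n)
        clin = make_clinical(t, e)
        a1 = lp.time_dependent_auc(s, clin, [5.0]).iloc[0]
        a2 = lp.time_dependent_auc(np.exp(3 * s) + 7, clin, [5.0]).iloc[0]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_random_scores_near_half(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 400
            t = rng.exponential(10, size=n)
            e = (rng.random(n) < 0.7).astype(int)
            clin = make_clinical(t, e)
            vals.append(lp.time_dependent_auc(rng.normal(size=n), clin, [8.0]).iloc[0])
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_horizon_beyond_followup_rejected(self):
        clin = make_clinical([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="horizon"):
            lp.time_dependent_auc([3, 2, 1], clin, [10.0])


class TestConcordance:
    def test_perfect_and_reversed_ranking(self):
        t = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        clin = make_clinical(t, np.ones(5, dtype=int))
        assert lp.concordance_index(-t, clin) == pytest.approx(1.0)
        assert lp.concordance_index(t, clin) == pytest.approx(0.0)

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(8)
        n = 25
        t = rng.exponential(1, size=n)
        e = (rng.random(n) < 0.6).astype(int)
        s = rng.normal(size=n)
        clin = make_clinical(t, e)
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if i == j or not e[i] or t[i] >= t[j]:
                    continue  # i must fail first, observed
                den += 1
                if s[i] > s[j]:
                    num += 1
                elif s[i] == s[j]:
                    num += 0.5
        assert lp.concordance_index(s, clin) == pytest.approx(num / den, abs=1e-12)


class TestCalibration:
    def test_constant_predictions_collapse_to_single_bin(self):
        clin = make_clinical([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 0])
        table = lp.calibration_at(3.0, np.full(6, 0.7), clin, n_bins=4)
        assert len(table) == 1
        assert table.loc[0, "n"] == 6

    def test_single_bin_equals_overall_km(self):
        clin = make_clinical([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        table = lp.calibration_at(3.5, np.linspace(0.2, 0.9, 6), clin, n_bins=1)
        assert table.loc[0, "km_observed"] == pytest.approx(lp.km_curve(clin).at(3.5))

    def test_well_calibrated_model_agrees_with_km(self):
        rng = np.random.default_rng(10)
        n = 3000
        lam = rng.uniform(0.02, 0.2, size=n)
        t = rng.exponential(1 / lam)
        clin = make_clinical(t, np.ones(n, dtype=int))
        horizon = 10.0
        pred = np.exp(-lam * horizon)  # true model survival
        table = lp.calibration_at(horizon, pred, clin, n_bins=4)
        assert np.max(np.abs(table["mean_predicted"] - table["km_observed"])) < 0.05
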