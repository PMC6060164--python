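import numpy as np
import pytest
from scipy import stats

import tegdist as td
from tegdist.survival_stats import SurvivalData, score_to_survival_probs


def harrell_oracle(scores, times, events):
    """Exhaustive pair enumeration, pure-Python."""
    conc = usable = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j or not events[i]:
                continue
            if times[i] < times[j] or (times[i] == times[j] and not events[j]):
                usable += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / usable


class TestKaplanMeier:
    def test_hand_product_limit(self):
        c = td.km_estimate(SurvivalData([1, 2, 3], [1, 0, 1]))
        assert c.survival_at(1) == pytest.approx(2 / 3)
        assert c.survival_at(2.5) == pytest.approx(2 / 3)  # censoring: no drop
        assert c.survival_at(3) == pytest.approx(0.0)

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 25)
        c = td.km_estimate(SurvivalData(t, np.ones(25, bool)))
        for u in np.quantile(t, [0.2, 0.5, 0.8]):
            assert c.survival_at(u) == pytest.approx((t > u).mean())

    def test_all_censored_flat_and_flagged(self):
        c = td.km_estimate(SurvivalData([1, 2, 3], [0, 0, 0]))
        assert c.no_events
        assert c.survival_at(3) == 1.0

    def test_non_increasing(self):
        rng = np.random.default_rng(1)
        d = SurvivalData(rng.exponential(5, 40), rng.uniform(size=40) > 0.4)
        c = td.km_estimate(d)
        assert np.all(np.diff(c.survival_probs) <= 1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        g = SurvivalData([1, 2, 3, 4], [1, 1, 0, 1])
        r = td.logrank_test([g, SurvivalData([1, 2, 3, 4], [1, 1, 0, 1])])
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_hand_oe_variance_table(self):
        # event times 1,2: O-E = 1/2 + 2/3, V = 1/4 + 2/9
        r = td.logrank_test([SurvivalData([1, 2], [1, 1]),
                             SurvivalData([3, 4], [1, 1])])
        expected = (0.5 + 2 / 3) ** 2 / (0.25 + 2 / 9)
        assert r.chi2 == pytest.approx(expected, abs=1e-6)
        assert r.df == 1

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        gs = [SurvivalData(rng.exponential(5, 15), rng.uniform(size=15) > 0.3)
              for _ in range(3)]
        r1 = td.logrank_test(gs)
        r2 = td.logrank_test(gs[::-1])
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-9)
        assert r1.df == 2

    def test_permutation_null_p_roughly_uniform(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 30)
        e = rng.uniform(size=30) > 0.2
        ps = []
        for _ in range(200):
            lab = rng.permutation(np.arange(30) % 3)
            ps.append(td.logrank_test(
                [SurvivalData(t[lab == k], e[lab == k]) for k in range(3)]).p)
        # uniform p-values: mean ~0.5 and ~10% below 0.1
        assert 0.35 < np.mean(ps) < 0.65
        assert np.mean(np.array(ps) < 0.1) < 0.25

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            td.logrank_test([SurvivalData([1, 2], [1, 1])])


class TestConcordance:
    @pytest.mark.parametrize("scores,expected", [
        ([3, 2, 1], 1.0),        # perfect ranking
        ([3, 1, 2], 2 / 3),      # one discordant pair
        ([1, 1, 1], 0.5),        # all ties
    ])
    def test_known_values(self, scores, expected):
        d = SurvivalData([1, 2, 3], [1, 1, 1])
        assert td.concordance_index(scores, d).c == pytest.approx(expected)

    def test_equals_pair_enumeration_oracle_with_censoring(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            t = rng.exponential(10, n)
            e = rng.uniform(size=n) > 0.35
            s = rng.normal(size=n)
            if not e.any():
                continue
            d = SurvivalData(t, e)
            try:
                r = td.concordance_index(s, d)
            except ValueError:
                continue
            assert r.c == pytest.approx(harrell_oracle(s, t, e), abs=1e-12)

    def test_matches_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 60)
        e = rng.uniform(size=60) > 0.3
        s = rng.normal(size=60)
        r = td.concordance_index(s, SurvivalData(t, e))
        ref = concordance_index_censored(e, t, s)[0]
        assert r.c == pytest.approx(ref, abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, 30)
        e = rng.uniform(size=30) > 0.3
        s = rng.normal(size=30)
        d = SurvivalData(t, e)
        c1 = td.concordance_index(s, d).c
        c2 = td.concordance_index(-s, d).c
        assert c1 + c2 == pytest.approx(1.0, abs=1e-12)

    def test_ci_contains_point_and_null_p(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 80)
        e = rng.uniform(size=80) > 0.3
        r = td.concordance_index(rng.normal(size=80), SurvivalData(t, e))
        assert r.ci_low <= r.c <= r.ci_high
        assert r.p > 0.001  # random scores: no real signal

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            td.concordance_index([1, 2], SurvivalData([1, 2], [0, 0]))


class TestBrier:
    def test_perfect_forecast_zero(self):
        d = SurvivalData([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        probs = np.array([[0.0], [0.0], [1.0], [1.0], [1.0]])
        r = td.ipcw_brier(probs, d, [2.5])
        assert r.brier_at_t[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_quarter(self):
        d = SurvivalData([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        r = td.ipcw_brier(np.full((5, 1), 0.5), d, [2.5])
        assert r.brier_at_t[0] == pytest.approx(0.25, abs=1e-12)

    def test_matches_direct_ipcw_sum(self):
        rng = np.random.default_rng(8)
        n = 20
        t = rng.exponential(10, n)
        e = rng.uniform(size=n) > 0.3
        s = rng.normal(size=n)
        d = SurvivalData(t, e)
        eval_t = float(np.quantile(t, 0.5))
        probs = score_to_survival_probs(s, d, [eval_t])
        r = td.ipcw_brier(probs, d, [eval_t])

        # oracle: direct IPCW sum with censoring KM (censorings as events)
        def g_hat(u):  # survival of the censoring distribution at u
            surv = 1.0
            for v in np.unique(t[(~e) & (t <= u)]):
                at_risk = np.sum(t >= v)
                dd = np.sum((t == v) & ~e)
                surv *= 1 - dd / at_risk
            return surv

        total = 0.0
        for i in range(n):
            pi = probs[i, 0]
            if t[i] <= eval_t and e[i]:
                total += (0.0 - pi) ** 2 / g_hat(t[i])
            elif t[i] > eval_t:
                total += (1.0 - pi) ** 2 / g_hat(eval_t)
        assert r.brier_at_t[0] == pytest.approx(total / n, rel=1e-6)

    def test_in_unit_interval_and_integrated(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(10, 60)
        e = rng.uniform(size=60) > 0.3
        d = SurvivalData(t, e)
        times = np.quantile(t, [0.25, 0.5, 0.75])
        r = td.brier_score(rng.normal(size=60), d, times)
        assert np.all((r.brier_at_t >= 0) & (r.brier_at_t <= 1))
        assert min(r.brier_at_t) <= r.integrated <= max(r.brier_at_t)

    def test_eval_time_out_of_followup_rejected(self):
        d = SurvivalData([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="follow-up"):
            td.brier_score([1, 2, 3], d, [10.0])


class TestTimeDependentRoc:
    def test_perfect_separation(self):
        d = SurvivalData([1, 2, 3, 4], [1, 1, 1, 1])
        auc, _ = td.time_dependent_roc([4, 3, 2, 1], d, 2.5)
        assert auc == pytest.approx(1.0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10, 400)
        d = SurvivalData(t, np.ones(400, bool))
        auc, _ = td.time_dependent_roc(rng.normal(size=400), d, np.median(t))
        assert abs(auc - 0.5) < 0.1

    def test_no_censoring_equals_rank_sum(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10, 40)
        s = rng.normal(size=40)
        horizon = float(np.median(t))
        auc, _ = td.time_dependent_roc(s, SurvivalData(t, np.ones(40, bool)),
                                       horizon)
        cases, ctrl = s[t <= horizon], s[t > horizon]
        u = stats.mannwhitneyu(cases, ctrl, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (len(cases) * len(ctrl)), abs=1e-12)

    def test_no_cases_or_controls_rejected(self):
        d = SurvivalData([5, 6, 7], [1, 1, 1])
        with pytest.raises(ValueError, match="cases"):
            td.time_dependent_roc([1, 2, 3], d, 1.0)
        with pytest.raises(ValueError, match="controls"):
            td.time_dependent_roc([1, 2, 3], d, 8.0)
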