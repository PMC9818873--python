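"""Survival statistics against hand calculations and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter

from icpair import (c_index, compare_cindex_bootstrap, fit_cox, km_estimate,
                    lasso_cox, logrank_test, rms_time, screen_pairs)
from icpair.survival import breslow_partial_loglik

from .conftest import brute_force_cindex, make_survival


# ---------------------------------------------------------------------------
# Kaplan-Meier / RMS


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km(2) == pytest.approx((3 / 4) * (2 / 3))
        assert km(0) == 1.0
        assert km(4) == 0.0

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([2, 5, 9], [0, 0, 0])
        assert km([1, 5, 100]).tolist() == [1.0, 1.0, 1.0]

    def test_single_subject(self):
        km = km_estimate([5.0], [1])
        assert km(4.999) == 1.0 and km(5.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, size=80)
        km = km_estimate(t, np.ones(80))
        for q in [1.0, 5.0, 15.0]:
            assert km(q) == pytest.approx((t > q).mean())

    def test_matches_lifelines(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, size=60)
        e = rng.integers(0, 2, size=60)
        e[0] = 1
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in [0.5, 2.0, 8.0, 20.0]:
            assert km(q) == pytest.approx(
                float(kmf.survival_function_at_times(q).iloc[0]), abs=1e-12)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])


class TestRms:
    def test_hand_step_area(self):
        assert rms_time([1, 2, 3, 4], [1, 1, 1, 1], tau=4) == pytest.approx(2.5)

    def test_no_events_before_tau_gives_tau(self):
        assert rms_time([50, 60], [0, 0], tau=12) == pytest.approx(12.0)

    def test_bounded_by_tau(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 40)
        assert rms_time(t, np.ones(40), tau=30) <= 30.0


# ---------------------------------------------------------------------------
# Log-rank


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_sample_hand_table(self):
        # groups (1,2,3 | 4,5,6), all events: O-E = 1.85, V = 0.6775
        stat, p = logrank_test([1, 2, 3, 4, 5, 6], [1] * 6, [0, 0, 0, 1, 1, 1])
        assert stat == pytest.approx(1.85**2 / 0.6775, rel=1e-9)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        e[:5] = 1
        g = rng.integers(0, 2, 50)
        if g.min() == g.max():
            g[0] = 1 - g[0]
        assert logrank_test(t, e, g) == pytest.approx(logrank_test(t, e, 1 - g))

    def test_rejects_single_group_and_zero_events(self):
        with pytest.raises(ValueError, match="groups"):
            logrank_test([1, 2], [1, 1], [0, 0])
        with pytest.raises(ValueError, match="events"):
            logrank_test([1, 2], [0, 0], [0, 1])


class TestScreen:
    def test_matches_per_pair_logrank(self):
        rng = np.random.default_rng(5)
        n = 80
        surv = make_survival(rng.exponential(20, n), rng.integers(0, 2, n))
        surv.iloc[0, surv.columns.get_loc("event")] = 1
        pairs = pd.DataFrame(rng.integers(0, 2, size=(12, n)),
                             index=[f"p{i}" for i in range(12)],
                             columns=surv.index)
        pairs = pairs[pairs.std(axis=1) > 0]
        table = screen_pairs(pairs, surv, alpha=0.05)
        for pid in pairs.index:
            stat, p = logrank_test(surv["time_months"], surv["event"],
                                   pairs.loc[pid].to_numpy())
            assert table.loc[pid, "statistic"] == pytest.approx(stat, rel=1e-9)
            assert table.loc[pid, "p_value"] == pytest.approx(p, rel=1e-9)

    def test_alpha_zero_selects_nothing(self, small_pairs, small_bundle):
        table = screen_pairs(small_pairs, small_bundle.clinical, alpha=0.0)
        assert not table["selected"].any()

    def test_bh_adjustment_is_monotone_and_larger(self, small_pairs, small_bundle):
        raw = screen_pairs(small_pairs, small_bundle.clinical, adjust="none")
        bh = screen_pairs(small_pairs, small_bundle.clinical, adjust="BH")
        assert (bh["p_adjusted"] >= raw["p_value"] - 1e-15).all()
        assert bh["selected"].sum() <= raw["selected"].sum()


# ---------------------------------------------------------------------------
# Cox


class TestCox:
    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(6)
        n = 1000
        x = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.05 * 2.0**x))
        cens = rng.uniform(0, 40, n)
        surv = make_survival(np.maximum(np.minimum(t, cens), 1e-6),
                             (t <= cens).astype(int))
        fit = fit_cox(pd.DataFrame({"x": x}, index=surv.index), surv)
        hr = float(fit.hazard_ratios.iloc[0])
        assert 1.6 <= hr <= 2.5
        assert fit.converged

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(7)
        n = 500
        surv = make_survival(rng.exponential(10, n), np.ones(n, dtype=int))
        x = pd.DataFrame({"x": rng.normal(size=n)}, index=surv.index)
        fit = fit_cox(x, surv)
        assert float(fit.hazard_ratios.iloc[0]) == pytest.approx(1.0, abs=0.2)

    def test_agrees_with_lifelines_on_tie_free_data(self):
        rng = np.random.default_rng(8)
        n = 120
        x = rng.normal(size=(n, 2))
        t = rng.exponential(1.0 / np.exp(0.02 * x[:, 0] * 10))
        e = rng.integers(0, 2, n)
        e[:10] = 1
        surv = make_survival(t, e)
        feats = pd.DataFrame(x, columns=["a", "b"], index=surv.index)
        fit = fit_cox(feats, surv)
        df = feats.copy()
        df["T"], df["E"] = t, e
        ll = CoxPHFitter().fit(df, "T", "E")
        # no ties -> Breslow and Efron coincide
        np.testing.assert_allclose(fit.params.to_numpy(),
                                   ll.params_[["a", "b"]].to_numpy(), atol=1e-5)
        np.testing.assert_allclose(fit.standard_errors.to_numpy(),
                                   ll.standard_errors_[["a", "b"]].to_numpy(),
                                   atol=1e-4)

    def test_partial_loglik_matches_lifelines(self):
        rng = np.random.default_rng(9)
        n = 60
        x = rng.normal(size=(n, 1))
        t = rng.exponential(5, n)
        e = np.ones(n)
        surv = make_survival(t, e)
        feats = pd.DataFrame(x, columns=["a"], index=surv.index)
        fit = fit_cox(feats, surv)
        df = feats.copy()
        df["T"], df["E"] = t, e
        ll = CoxPHFitter().fit(df, "T", "E")
        assert fit.loglik == pytest.approx(ll.log_likelihood_, rel=1e-5)
        assert breslow_partial_loglik(fit.params.to_numpy(), x, t, e) \
            == pytest.approx(fit.loglik)

    def test_zero_covariates_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            fit_cox(pd.DataFrame(index=small_bundle.clinical.index),
                    small_bundle.clinical)

    def test_constant_covariate_rejected(self):
        surv = make_survival([1, 2, 3], [1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            fit_cox(pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=surv.index), surv)


# ---------------------------------------------------------------------------
# LASSO-Cox


class TestLassoCox:
    @staticmethod
    def _cohort(seed, n=400, beta=1.0, n_null=49):
        rng = np.random.default_rng(seed)
        signal = rng.integers(0, 2, n)
        t = rng.exponential(1.0 / (0.03 * np.exp(beta * signal)))
        cens = rng.uniform(0, 80, n)
        surv = make_survival(np.maximum(np.minimum(t, cens), 1e-6),
                             (t <= cens).astype(int))
        feats = pd.DataFrame(rng.integers(0, 2, size=(n_null, n)),
                             index=[f"null{i}" for i in range(n_null)],
                             columns=surv.index)
        feats.loc["signal"] = signal
        return feats, surv

    def test_selects_the_prognostic_feature(self):
        feats, surv = self._cohort(seed=10)
        res = lasso_cox(feats, surv, n_folds=5, seed=0)
        assert "signal" in res.selected

    def test_selection_is_subset_of_inputs(self):
        feats, surv = self._cohort(seed=11, n=200, n_null=20)
        res = lasso_cox(feats, surv, n_folds=4, seed=1)
        assert set(res.selected) <= set(feats.index)

    def test_huge_penalty_selects_nothing(self):
        feats, surv = self._cohort(seed=12, n=150, n_null=10)
        res = lasso_cox(feats, surv, penalty=1e6)
        assert res.selected == []

    def test_same_seed_is_deterministic(self):
        feats, surv = self._cohort(seed=13, n=200, n_null=20)
        a = lasso_cox(feats, surv, n_folds=4, seed=3)
        b = lasso_cox(feats, surv, n_folds=4, seed=3)
        assert a.selected == b.selected and a.penalty == b.penalty

    def test_selection_size_nonincreasing_in_penalty(self):
        feats, surv = self._cohort(seed=14, n=250, n_null=20)
        sizes = [len(lasso_cox(feats, surv, penalty=p).selected)
                 for p in (0.001, 0.01, 0.1, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_all_constant_rejected(self):
        surv = make_survival([1, 2, 3, 4], [1, 1, 1, 1])
        feats = pd.DataFrame(np.ones((3, 4)), columns=surv.index,
                             index=["a", "b", "c"])
        with pytest.raises(ValueError, match="constant"):
            lasso_cox(feats, surv)


# ---------------------------------------------------------------------------
# Concordance


class TestCIndex:
    def test_negative_time_score_is_perfect(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(10, 50)
        surv = make_survival(t, np.ones(50, dtype=int))
        assert c_index(-t, surv) == 1.0

    def test_random_score_near_half(self):
        rng = np.random.default_rng(16)
        n = 500
        surv = make_survival(rng.exponential(10, n), np.ones(n, dtype=int))
        assert c_index(rng.normal(size=n), surv) == pytest.approx(0.5, abs=0.05)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(17)
        n = 30
        t = rng.exponential(10, n)
        e = rng.integers(0, 2, n)
        e[0] = 1
        s = np.round(rng.normal(size=n), 1)  # induce some score ties
        surv = make_survival(t, e)
        assert c_index(s, surv) == pytest.approx(
            brute_force_cindex(s, t, e), abs=1e-12)

    def test_complement_identity_without_ties(self):
        rng = np.random.default_rng(18)
        n = 40
        surv = make_survival(rng.exponential(5, n), np.ones(n, dtype=int))
        s = rng.normal(size=n)
        assert c_index(s, surv) + c_index(-s, surv) == pytest.approx(1.0)


class TestCompareCIndex:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(19)
        n = 80
        surv = make_survival(rng.exponential(10, n), np.ones(n, dtype=int))
        s = rng.normal(size=n)
        res = compare_cindex_bootstrap(s, s, surv, n_boot=200, seed=0)
        assert res.c_a == res.c_b
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "paired bootstrap"

    def test_oracle_score_beats_noise(self):
        rng = np.random.default_rng(20)
        n = 300
        t = rng.exponential(10, n)
        surv = make_survival(t, np.ones(n, dtype=int))
        res = compare_cindex_bootstrap(-t, rng.normal(size=n), surv,
                                       n_boot=300, seed=1)
        assert res.p_value < 0.05
        assert res.c_a > res.c_b

    def test_same_seed_identical(self):
        rng = np.random.default_rng(21)
        n = 60
        surv = make_survival(rng.exponential(10, n), np.ones(n, dtype=int))
        a, b = rng.normal(size=n), rng.normal(size=n)
        r1 = compare_cindex_bootstrap(a, b, surv, n_boot=150, seed=5)
        r2 = compare_cindex_bootstrap(a, b, surv, n_boot=150, seed=5)
        assert (r1.c_a, r1.c_b, r1.p_value) == (r2.c_a, r2.c_b, r2.p_value)
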