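"""DerSimonian–Laird engine: worked values, invariants, and independent oracles."""

import numpy as np
import pytest

from ozonemeta.effect_sizes import Design, EffectEstimate
from ozonemeta.exceptions import EmptySetError, ValidationError
from ozonemeta.meta import (
    PooledResult,
    Route,
    StudyRecord,
    cochran_q,
    dl_tau_squared,
    forest_table,
    i_squared,
    random_effects_pool,
    reml_tau_squared,
    subgroup_analysis,
)


def _record(g, v, i=0, route=Route.INTRAMUSCULAR, design="rct"):
    return StudyRecord(
        f"s{i}", route, design, EffectEstimate(g, v, 1.0, Design.BETWEEN_GROUPS)
    )


def _dl_oracle(g, v):
    """Direct transcription of the moment-estimator formulas (loops, no numpy)."""
    w = [1.0 / vi for vi in v]
    mean_fe = sum(wi * gi for wi, gi in zip(w, g)) / sum(w)
    q = sum(wi * (gi - mean_fe) ** 2 for wi, gi in zip(w, g))
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (len(g) - 1)) / c)
    w_re = [1.0 / (vi + tau2) for vi in v]
    mu = sum(wi * gi for wi, gi in zip(w_re, g)) / sum(w_re)
    se = (1.0 / sum(w_re)) ** 0.5
    return q, tau2, mu, se


class TestCochranQ:
    def test_identical_effects_zero(self):
        assert cochran_q([1.3, 1.3, 1.3], [0.2, 0.5, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_two_study_hand_value(self):
        assert cochran_q([0, 2], [1, 1]) == pytest.approx(2.0, abs=1e-12)

    def test_q_scales_inversely_with_variances(self):
        g, v = [0.1, 0.9, -0.4], [0.2, 0.3, 0.5]
        q1 = cochran_q(g, v)
        q3 = cochran_q(g, [3 * vi for vi in v])
        assert q3 == pytest.approx(q1 / 3, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(EmptySetError):
            cochran_q([], [])


class TestTau2:
    def test_identical_effects_zero(self):
        assert dl_tau_squared([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]) == 0.0

    def test_two_study_hand_value(self):
        # Q = 2, df = 1, C = 2 - 2/2 = 1 -> tau2 = 1
        assert dl_tau_squared([0, 2], [1, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_truncation_at_zero(self):
        assert dl_tau_squared([0, 0.1], [1, 1]) == 0.0

    def test_k1_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert dl_tau_squared([1.0], [0.5]) == 0.0

    def test_reml_agrees_on_homogeneous_data(self):
        # bounded scalar search converges to the boundary within optimizer tolerance
        assert reml_tau_squared([1.0, 1.0, 1.0, 1.0], [0.2] * 4) == pytest.approx(0.0, abs=1e-4)

    def test_reml_positive_under_heterogeneity(self):
        rng = np.random.default_rng(7)
        g = rng.normal(0, 1.0, size=12)
        assert reml_tau_squared(g, [0.05] * 12) > 0.1


class TestI2:
    def test_reported_heterogeneity_value(self):
        # Q = 860.57 on 6 df corresponds to 99.3% heterogeneity
        assert i_squared(860.57, 6) == pytest.approx(99.3, abs=0.05)

    def test_floor_at_zero(self):
        assert i_squared(3.0, 6) == 0.0
        assert i_squared(0.0, 6) == 0.0

    def test_closed_form_fifty_percent(self):
        assert i_squared(12.0, 6) == pytest.approx(50.0, abs=1e-12)


class TestPooling:
    def test_single_study_passthrough(self):
        with pytest.warns(UserWarning):
            p = random_effects_pool([_record(0.7, 0.09)])
        assert p.mu_hat == pytest.approx(0.7)
        assert p.tau2 == 0.0
        assert p.se == pytest.approx(0.3)

    def test_symmetric_equal_variance_mean(self):
        p = random_effects_pool([_record(1.0, 0.2, 0), _record(3.0, 0.2, 1)])
        assert p.mu_hat == pytest.approx(2.0, abs=1e-12)

    def test_pooled_mean_within_convex_hull(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = int(rng.integers(2, 12))
            g = rng.normal(0, 2, size=k)
            v = rng.uniform(0.02, 1.0, size=k)
            p = random_effects_pool([_record(gi, vi, i) for i, (gi, vi) in enumerate(zip(g, v))])
            assert g.min() - 1e-12 <= p.mu_hat <= g.max() + 1e-12
            assert p.ci_low < p.ci_high
            assert 0 <= p.i2 < 100

    def test_vanishing_weight_continuity(self):
        base = [_record(0.5, 0.1, 0), _record(0.9, 0.2, 1), _record(0.2, 0.15, 2)]
        p0 = random_effects_pool(base)
        p1 = random_effects_pool(base + [_record(50.0, 0.1 * 1e6, 3)])
        assert abs(p1.mu_hat - p0.mu_hat) < 1e-3

    def test_extreme_heterogeneity_equalizes_weights(self):
        # huge spread at tiny within-study variance drives tau2 >> v, so the
        # pooled mean approaches the arithmetic mean of the effects
        g = [0.0, 400.0, -300.0, 900.0]
        p = random_effects_pool([_record(gi, 1e-4, i) for i, gi in enumerate(g)])
        assert p.mu_hat == pytest.approx(float(np.mean(g)), rel=1e-4)
        w = p.weights / p.weights.sum()
        assert np.allclose(w, 0.25, atol=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(EmptySetError):
            random_effects_pool([])

    def test_oracle_equivalence_random_instances(self):
        """DL estimates match a direct formula transcription to 1e-10."""
        rng = np.random.default_rng(20240918)
        for _ in range(100):
            k = int(rng.integers(2, 15))
            g = rng.normal(0, 1.5, size=k)
            v = rng.uniform(0.02, 0.8, size=k)
            p = random_effects_pool([_record(gi, vi, i) for i, (gi, vi) in enumerate(zip(g, v))])
            q, tau2, mu, se = _dl_oracle(list(g), list(v))
            assert p.q_stat == pytest.approx(q, abs=1e-10)
            assert p.tau2 == pytest.approx(tau2, abs=1e-10)
            assert p.mu_hat == pytest.approx(mu, abs=1e-10)
            assert p.se == pytest.approx(se, abs=1e-10)

    def test_cross_check_against_statsmodels(self):
        """Independent library route reproduces tau2 and the pooled mean."""
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(5)
        g = rng.normal(-1, 0.8, size=8)
        v = rng.uniform(0.05, 0.3, size=8)
        p = random_effects_pool([_record(gi, vi, i) for i, (gi, vi) in enumerate(zip(g, v))])
        res = combine_effects(g, v, method_re="chi2")
        assert p.tau2 == pytest.approx(res.tau2, rel=1e-8)
        assert p.mu_hat == pytest.approx(res.mean_effect_re, rel=1e-8)

    def test_parameter_recovery_direct_simulation(self):
        """200 simulated meta-analyses recover mu and tau2 (k=20, mu=-1, tau2=0.2)."""
        rng = np.random.default_rng(42)
        mu_true, tau2_true, k = -1.0, 0.2, 20
        mus, tau2s = [], []
        for _ in range(200):
            v = rng.uniform(0.05, 0.3, size=k)
            theta = rng.normal(mu_true, np.sqrt(tau2_true), size=k)
            g = rng.normal(theta, np.sqrt(v))
            p = random_effects_pool([_record(gi, vi, i) for i, (gi, vi) in enumerate(zip(g, v))])
            mus.append(p.mu_hat)
            tau2s.append(p.tau2)
        mus, tau2s = np.array(mus), np.array(tau2s)
        mc_se = mus.std(ddof=1) / np.sqrt(len(mus))
        assert abs(mus.mean() - mu_true) < 3 * mc_se
        assert abs(tau2s.mean() - tau2_true) < 0.25 * tau2_true


class TestSubgroups:
    def test_single_route_matches_overall(self, intramuscular_rcts):
        sub = subgroup_analysis(intramuscular_rcts)
        overall = random_effects_pool(intramuscular_rcts)
        assert set(sub) == {Route.INTRAMUSCULAR}
        assert sub[Route.INTRAMUSCULAR].mu_hat == pytest.approx(overall.mu_hat)

    def test_published_table_split(self, study_records):
        sub = subgroup_analysis(study_records)
        assert sub[Route.INTRAMUSCULAR].k == 3
        assert sub[Route.INTRADISCAL].k == 4
        # routes pooled independently: each gets its own tau2
        assert sub[Route.INTRAMUSCULAR].tau2 != sub[Route.INTRADISCAL].tau2

    def test_order_invariance(self, study_records):
        fwd = subgroup_analysis(study_records)
        rev = subgroup_analysis(list(reversed(study_records)))
        for route in fwd:
            assert fwd[route].mu_hat == pytest.approx(rev[route].mu_hat, abs=1e-12)
            assert fwd[route].tau2 == pytest.approx(rev[route].tau2, abs=1e-12)

    def test_unknown_route_rejected(self):
        bad = StudyRecord(
            "x", "epidural", "rct", EffectEstimate(0.1, 0.1, 1.0, Design.BETWEEN_GROUPS)
        )
        with pytest.raises(ValueError):
            subgroup_analysis([bad])


class TestForestTable:
    def test_weights_sum_to_hundred(self, study_records):
        pooled = random_effects_pool(study_records)
        tab = forest_table(study_records, pooled)
        study_rows = tab.iloc[:-1]
        assert study_rows["weight_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        # weights proportional to 1/(v + tau2)
        v = np.array([s.effect.variance for s in study_records])
        expected = 1.0 / (v + pooled.tau2)
        ratio = study_rows["weight_pct"].to_numpy() / expected
        assert np.allclose(ratio, ratio[0])

    def test_single_study_full_weight(self):
        with pytest.warns(UserWarning):
            pooled = random_effects_pool([_record(0.3, 0.1)])
        tab = forest_table([_record(0.3, 0.1)], pooled)
        assert tab.iloc[0]["weight_pct"] == pytest.approx(100.0)

    def test_summary_row_equals_pooled(self, study_records):
        pooled = random_effects_pool(study_records)
        tab = forest_table(study_records, pooled)
        assert tab.iloc[-1]["g"] == pytest.approx(pooled.mu_hat)
        assert tab.iloc[-1]["ci_low"] == pytest.approx(pooled.ci_low)
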