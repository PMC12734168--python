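"""Harm-risk arithmetic: published worked values and algebraic identities."""

import numpy as np
import pytest

from ozonemeta import presets
from ozonemeta.exceptions import (
    ConfigurationError,
    UndefinedRatioError,
    ValidationError,
)
from ozonemeta.risk import (
    RouteRisk,
    absolute_risk_increase,
    back_calculate_baseline,
    compare_routes,
    number_needed_to_harm,
    odds_ratio,
    odds_to_probability,
    probability_to_odds,
    relative_risk,
    risk_ledger,
    round_nnh,
    safety_efficacy_summary,
)
from ozonemeta.simulate import simulate_risk_events


class TestOdds:
    @pytest.mark.parametrize("p, expected", [(0.0952, 0.1052), (0.0, 0.0), (0.5, 1.0)])
    def test_worked_values(self, p, expected):
        assert probability_to_odds(p) == pytest.approx(expected, abs=5e-5)

    def test_infinite_odds_rejected(self):
        with pytest.raises(UndefinedRatioError):
            probability_to_odds(1.0)
        with pytest.raises(ValidationError):
            probability_to_odds(1.2)

    def test_strictly_increasing_and_invertible(self):
        ps = np.linspace(0, 0.99, 50)
        odds = [probability_to_odds(p) for p in ps]
        assert all(a < b for a, b in zip(odds, odds[1:]))
        for p, o in zip(ps, odds):
            assert odds_to_probability(o) == pytest.approx(p, abs=1e-12)


class TestRatios:
    def test_combined_risk_rr(self):
        assert relative_risk(0.0952, 0.0145) == pytest.approx(6.57, abs=0.005)

    def test_combined_risk_or(self):
        assert odds_ratio(0.0952, 0.0145) == pytest.approx(7.15, abs=0.005)

    @pytest.mark.parametrize("fn", [relative_risk, odds_ratio])
    def test_equal_risks_give_unity(self, fn):
        assert fn(0.03, 0.03) == pytest.approx(1.0)

    def test_rr_simple_ratio(self):
        assert relative_risk(0.2, 0.1) == pytest.approx(2.0)

    def test_rare_disease_approximation(self):
        orr = odds_ratio(8e-5, 5e-5) / relative_risk(8e-5, 5e-5)
        assert orr == pytest.approx(1.0, abs=1e-3)

    def test_or_dominates_rr_for_harmful_exposures(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            pb = rng.uniform(1e-4, 0.5)
            pe = rng.uniform(pb, 0.9)
            assert odds_ratio(pe, pb) >= relative_risk(pe, pb) - 1e-12

    def test_zero_baseline_rejected(self):
        with pytest.raises(UndefinedRatioError):
            relative_risk(0.1, 0.0)


class TestAriNnh:
    def test_severe_preset_ari(self):
        assert absolute_risk_increase(0.0010, 0.00015) == pytest.approx(0.00085, abs=1e-12)

    def test_ari_antisymmetric(self):
        assert absolute_risk_increase(0.2, 0.05) == -absolute_risk_increase(0.05, 0.2)

    @pytest.mark.parametrize("ari, expected", [(0.0008479, 1 / 0.0008479), (0.5, 2.0), (0.01, 100.0)])
    def test_nnh_worked_values(self, ari, expected):
        assert number_needed_to_harm(ari) == pytest.approx(expected, rel=1e-12)

    def test_headline_rounding(self):
        # both the exact reciprocal (1179.38...) and the preset's 1179.53
        # round to the published headline of 1180
        assert round_nnh(number_needed_to_harm(0.0008479)) == 1180
        assert round_nnh(1179.5332) == 1180

    def test_nnh_times_ari_is_one(self):
        rng = np.random.default_rng(9)
        for ari in rng.uniform(1e-5, 0.9, size=100):
            assert number_needed_to_harm(ari) * ari == pytest.approx(1.0, rel=1e-12)

    def test_protective_ari_rejected(self):
        with pytest.raises(UndefinedRatioError):
            number_needed_to_harm(-0.01)


class TestBackCalculation:
    def test_published_baseline(self):
        assert back_calculate_baseline(0.001, 6.57) == pytest.approx(1.522e-4, abs=5e-8)

    def test_rr_one_identity(self):
        assert back_calculate_baseline(0.3, 1.0) == pytest.approx(0.3)

    def test_round_trips_with_relative_risk(self):
        p_e, rr = 0.004, 3.7
        p_b = back_calculate_baseline(p_e, rr)
        assert relative_risk(p_e, p_b) == pytest.approx(rr, rel=1e-12)


class TestLedgerAndSummary:
    def test_severe_preset_per_10k_cases(self):
        cfg = presets.risk_preset("severe-complication")
        ledger = risk_ledger(cfg["routes"], baseline=cfg["baseline"], n_procedures=10_000)
        by_route = ledger.set_index("route")
        assert by_route.loc["intradiscal", "expected_cases"] == pytest.approx(10.0, abs=0.05)
        assert by_route.loc["intramuscular", "expected_cases"] == pytest.approx(1.5, abs=0.05)
        assert by_route.loc["intradiscal", "rr_vs_baseline"] == pytest.approx(6.57, abs=0.005)

    def test_case_counts_linear_in_volume(self):
        cfg = presets.risk_preset("combined-risk")
        small = risk_ledger(cfg["routes"], baseline="intramuscular", n_procedures=100)
        large = risk_ledger(cfg["routes"], baseline="intramuscular", n_procedures=100_000)
        assert np.allclose(
            large["expected_cases"].to_numpy(), 1000 * small["expected_cases"].to_numpy()
        )

    def test_zero_volume(self):
        cfg = presets.risk_preset("combined-risk")
        ledger = risk_ledger(cfg["routes"], baseline="intramuscular", n_procedures=0)
        assert (ledger["expected_cases"] == 0).all()

    def test_missing_baseline_rejected(self):
        with pytest.raises(ConfigurationError):
            risk_ledger([RouteRisk("intradiscal", 0.1)], baseline="intramuscular")

    def test_safety_scores(self):
        cfg = presets.risk_preset("severe-complication")
        tab = safety_efficacy_summary(
            cfg["routes"], {"intramuscular": -1.55, "intradiscal": 2.87}
        ).set_index("route")
        assert tab.loc["intramuscular", "safety_score"] == pytest.approx(1.0)
        # the riskier route scores the reciprocal of its relative risk
        assert tab.loc["intradiscal", "safety_score"] == pytest.approx(1 / 6.57, abs=1e-9)
        assert tab.loc["intradiscal", "abs_pooled_g"] == pytest.approx(2.87)

    def test_safety_scores_scale_invariant(self):
        routes = [RouteRisk("a", 0.004), RouteRisk("b", 0.001)]
        scaled = [RouteRisk("a", 0.4), RouteRisk("b", 0.1)]
        t1 = safety_efficacy_summary(routes, {}).set_index("route")["safety_score"]
        t2 = safety_efficacy_summary(scaled, {}).set_index("route")["safety_score"]
        assert np.allclose(t1.to_numpy(), t2.to_numpy())


class TestComparisonObject:
    def test_protective_direction_flagged(self):
        c = compare_routes(RouteRisk("a", 0.01), RouteRisk("b", 0.02))
        assert c.protective
        assert c.nnh == pytest.approx(100.0)  # NNT, flagged

    def test_monte_carlo_coherence(self):
        """Binomial simulation at the stated p reproduces p within 3 SEs."""
        n, p = 10**6, 0.001
        count = simulate_risk_events(n, p, seed=123)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(count / n - p) < 3 * se
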