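"""Harm-risk calculus comparing two administration routes.

From per-route probabilities of a serious complication the module derives
odds p/(1−p), relative risk RR = p_e/p_b, odds ratio OR, absolute risk
increase ARI = p_e − p_b, number needed to harm NNH = 1/ARI, and expected
case counts per fixed procedure volume. Severity bands follow the CTCAE
grading (G1 mild … G5 death).

Two published presets are shipped (see :mod:`ozonemeta.presets`): a
"combined-risk" pair (9.52% intradiscal vs 1.45% intramuscular) and a
"severe-complication" pair (0.10% intradiscal with the baseline
back-calculated from the 6.57:1 risk ratio). They are deliberately not
reconciled; the provenance note travels with each preset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigurationError, UndefinedRatioError, ValidationError

__all__ = [
    "RouteRisk",
    "RiskComparison",
    "probability_to_odds",
    "odds_to_probability",
    "relative_risk",
    "odds_ratio",
    "absolute_risk_increase",
    "number_needed_to_harm",
    "back_calculate_baseline",
    "compare_routes",
    "risk_ledger",
    "safety_efficacy_summary",
]


@dataclass(frozen=True)
class RouteRisk:
    """Serious-complication probability for one administration route."""

    route: str
    p_serious: float
    source: str = ""
    ctcae_band: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_serious <= 1.0:
            raise ValidationError(f"p_serious must lie in [0, 1], got {self.p_serious}")


@dataclass(frozen=True)
class RiskComparison:
    """Derived harm metrics for an exposed route versus a baseline route."""

    exposed: RouteRisk
    baseline: RouteRisk
    odds_exposed: float
    odds_baseline: float
    rr: float
    or_: float
    ari: float
    nnh: float | None
    per_10k_exposed: float
    per_10k_baseline: float
    protective: bool = False  # ARI < 0: nnh field then holds the NNT

    def to_dict(self) -> dict:
        return {
            "exposed": self.exposed.route,
            "baseline": self.baseline.route,
            "p_exposed": self.exposed.p_serious,
            "p_baseline": self.baseline.p_serious,
            "odds_exposed": self.odds_exposed,
            "odds_baseline": self.odds_baseline,
            "rr": self.rr,
            "or": self.or_,
            "ari": self.ari,
            "nnh": self.nnh,
            "per_10k_exposed": self.per_10k_exposed,
            "per_10k_baseline": self.per_10k_baseline,
            "protective": self.protective,
        }


def probability_to_odds(p: float) -> float:
    """Odds p/(1−p) of an event with probability p < 1."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability must lie in [0, 1], got {p}")
    if p == 1.0:
        raise UndefinedRatioError("odds are infinite at p = 1")
    return p / (1.0 - p)


def odds_to_probability(o: float) -> float:
    """Inverse of :func:`probability_to_odds`: p = o/(1+o)."""
    if o < 0:
        raise ValidationError(f"odds must be >= 0, got {o}")
    return o / (1.0 + o)


def relative_risk(p_exposed: float, p_baseline: float) -> float:
    """Relative risk p_exposed / p_baseline."""
    _check_prob(p_exposed, "p_exposed")
    _check_prob(p_baseline, "p_baseline")
    if p_baseline == 0:
        raise UndefinedRatioError("relative risk undefined at zero baseline risk")
    return p_exposed / p_baseline


def odds_ratio(p_exposed: float, p_baseline: float) -> float:
    """Odds ratio computed from the exact (unrounded) odds."""
    o_e = probability_to_odds(p_exposed)
    o_b = probability_to_odds(p_baseline)
    if o_b == 0:
        raise UndefinedRatioError("odds ratio undefined at zero baseline odds")
    return o_e / o_b


def absolute_risk_increase(p_exposed: float, p_baseline: float) -> float:
    """Absolute risk increase p_exposed − p_baseline (sign preserved)."""
    _check_prob(p_exposed, "p_exposed")
    _check_prob(p_baseline, "p_baseline")
    return p_exposed - p_baseline


def number_needed_to_harm(ari: float) -> float:
    """Number needed to harm, 1/ARI, defined only for ARI > 0."""
    if ari <= 0:
        raise UndefinedRatioError("NNH undefined for non-positive ARI (protective or null)")
    return 1.0 / ari


def round_nnh(nnh: float, nearest: int = 10) -> int:
    """Headline rounding of NNH (nearest 10 by default)."""
    return int(round(nnh / nearest) * nearest)


def back_calculate_baseline(p_exposed: float, rr: float) -> float:
    """Baseline probability implied by an exposed probability and a risk ratio."""
    _check_prob(p_exposed, "p_exposed")
    if rr <= 0:
        raise ValidationError(f"rr must be > 0, got {rr}")
    return p_exposed / rr


def compare_routes(exposed: RouteRisk, baseline: RouteRisk) -> RiskComparison:
    """Full harm comparison of two routes; handles protective exposures."""
    p_e, p_b = exposed.p_serious, baseline.p_serious
    ari = absolute_risk_increase(p_e, p_b)
    protective = ari < 0
    if ari == 0:
        nnh: float | None = None
    elif protective:
        nnh = 1.0 / abs(ari)  # number needed to treat, flagged via `protective`
    else:
        nnh = number_needed_to_harm(ari)
    return RiskComparison(
        exposed=exposed,
        baseline=baseline,
        odds_exposed=probability_to_odds(p_e),
        odds_baseline=probability_to_odds(p_b),
        rr=relative_risk(p_e, p_b),
        or_=odds_ratio(p_e, p_b),
        ari=ari,
        nnh=nnh,
        per_10k_exposed=p_e * 10_000,
        per_10k_baseline=p_b * 10_000,
        protective=protective,
    )


def risk_ledger(
    routes: list[RouteRisk],
    *,
    baseline: str,
    n_procedures: int = 10_000,
) -> pd.DataFrame:
    """Severity ledger: expected cases and harm metrics versus a baseline route.

    One row per route; the baseline row carries RR = 1 and blank ARI/NNH.
    Expected case counts are linear in ``n_procedures``.
    """
    by_name = {r.route: r for r in routes}
    if baseline not in by_name:
        raise ConfigurationError(f"baseline route {baseline!r} not among supplied routes")
    base = by_name[baseline]
    rows = []
    for r in routes:
        row = {
            "route": r.route,
            "ctcae_band": r.ctcae_band,
            "p_serious": r.p_serious,
            "expected_cases": r.p_serious * n_procedures,
            "n_procedures": n_procedures,
        }
        if r.route == baseline:
            row.update({"rr_vs_baseline": 1.0, "ari": None, "nnh": None})
        else:
            cmp_ = compare_routes(r, base)
            row.update(
                {
                    "rr_vs_baseline": cmp_.rr,
                    "ari": cmp_.ari,
                    "nnh": cmp_.nnh,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def safety_efficacy_summary(
    risks: list[RouteRisk],
    pooled_g: dict[str, float],
) -> pd.DataFrame:
    """Paired safety/efficacy table: normalized safety score vs |pooled g|.

    The safety score is inverse risk scaled so the safest route scores 1;
    a route R times riskier than the safest scores 1/R. Unit-free in p.
    """
    if not risks:
        raise ValidationError("no routes supplied")
    if any(r.p_serious == 0 for r in risks):
        raise ValidationError("zero complication risk makes the safety score undefined")
    p_min = min(r.p_serious for r in risks)
    rows = []
    for r in risks:
        rows.append(
            {
                "route": r.route,
                "safety_score": p_min / r.p_serious,
                "abs_pooled_g": abs(pooled_g[r.route]) if r.route in pooled_g else None,
            }
        )
    return pd.DataFrame(rows)


def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1], got {p}")
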