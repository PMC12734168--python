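"""DerSimonian–Laird random-effects meta-analysis with subgroup support.

The pooled mean is the inverse-variance weighted average

    mu_hat = sum(w_i * g_i) / sum(w_i),   w_i = 1 / (v_i + tau2)

where v_i is the within-study sampling variance and tau2 the between-study
variance. tau2 is estimated by the DerSimonian–Laird moment estimator

    tau2 = max(0, (Q - df) / C),   C = sum(w) - sum(w^2)/sum(w)

with Q Cochran's heterogeneity statistic under fixed-effect weights
w_i = 1/v_i, and df = k − 1. I² = 100·(Q − df)/Q, floored at 0, summarizes
the share of total variability due to heterogeneity.

A restricted maximum-likelihood (REML) tau2 and a Knapp–Hartung CI are
available behind switches; defaults are the moment estimator and a normal
1.96 interval.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .effect_sizes import EffectEstimate
from .exceptions import EmptySetError, ValidationError

__all__ = [
    "Route",
    "StudyRecord",
    "PooledResult",
    "cochran_q",
    "dl_tau_squared",
    "reml_tau_squared",
    "i_squared",
    "random_effects_pool",
    "subgroup_analysis",
    "forest_table",
]

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


class Route(str, enum.Enum):
    """Administration route of the oxygen–ozone mixture."""

    INTRAMUSCULAR = "intramuscular"
    INTRADISCAL = "intradiscal"


@dataclass(frozen=True)
class StudyRecord:
    """One study entering the meta-analysis."""

    study_id: str
    route: Route
    design: str  # "rct" or "cohort"
    effect: EffectEstimate
    comparator: str = ""

    def __post_init__(self) -> None:
        if self.design not in ("rct", "cohort"):
            raise ValidationError(f"design must be 'rct' or 'cohort', got {self.design!r}")


@dataclass
class PooledResult:
    """Random-effects pooling output with heterogeneity statistics."""

    mu_hat: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q_stat: float
    df: int
    i2: float
    weights: np.ndarray
    k: int
    tau2_method: str = "dl"
    ci_method: str = "normal"
    label: str = ""

    def to_dict(self) -> dict:
        d = {
            "mu_hat": self.mu_hat,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "q_stat": self.q_stat,
            "df": self.df,
            "i2": self.i2,
            "weights": [float(w) for w in self.weights],
            "k": self.k,
            "tau2_method": self.tau2_method,
            "ci_method": self.ci_method,
        }
        if self.label:
            d["label"] = self.label
        return d


def _as_arrays(effects, variances) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if g.size == 0:
        raise EmptySetError("no studies supplied")
    if g.shape != v.shape:
        raise ValidationError("effects and variances must have equal length")
    if np.any(v <= 0):
        raise ValidationError("all sampling variances must be > 0")
    return g, v


def cochran_q(effects, variances) -> float:
    """Cochran's Q under fixed-effect weights w_i = 1/v_i."""
    g, v = _as_arrays(effects, variances)
    w = 1.0 / v
    g_fe = float(np.sum(w * g) / np.sum(w))
    return float(np.sum(w * (g - g_fe) ** 2))


def dl_tau_squared(effects, variances) -> float:
    """DerSimonian–Laird moment estimate of the between-study variance."""
    g, v = _as_arrays(effects, variances)
    k = g.size
    if k < 2:
        warnings.warn("tau2 undefined for k < 2; returning 0", stacklevel=2)
        return 0.0
    w = 1.0 / v
    q = cochran_q(g, v)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / c)


def reml_tau_squared(effects, variances) -> float:
    """Restricted maximum-likelihood estimate of tau2 (scalar search)."""
    g, v = _as_arrays(effects, variances)
    if g.size < 2:
        warnings.warn("tau2 undefined for k < 2; returning 0", stacklevel=2)
        return 0.0

    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * g) / np.sum(w)
        return 0.5 * float(
            np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (g - mu) ** 2)
        )

    upper = max(10.0 * dl_tau_squared(g, v) + 10.0 * float(np.max(v)), 1.0)
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, upper), method="bounded")
    return max(0.0, float(res.x))


def i_squared(q_stat: float, df: int) -> float:
    """I² heterogeneity percentage, 100·(Q − df)/Q floored at 0."""
    if q_stat < 0:
        raise ValidationError(f"Q must be >= 0, got {q_stat}")
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    if q_stat == 0:
        return 0.0
    return max(0.0, 100.0 * (q_stat - df) / q_stat)


_TAU2_ESTIMATORS = {"dl": dl_tau_squared, "reml": reml_tau_squared}


def random_effects_pool(
    studies: list[StudyRecord],
    *,
    tau2_method: str = "dl",
    ci_method: str = "normal",
    label: str = "",
) -> PooledResult:
    """Pool study effects under the random-effects model.

    Parameters
    ----------
    studies :
        Study records with positive effect variances.
    tau2_method :
        "dl" (moment, default) or "reml".
    ci_method :
        "normal" (1.96·se, default) or "hksj" (Knapp–Hartung, t quantile
        with a robust variance; requires k >= 2).
    """
    if len(studies) == 0:
        raise EmptySetError("cannot pool zero studies")
    if tau2_method not in _TAU2_ESTIMATORS:
        raise ValidationError(f"unknown tau2_method {tau2_method!r}")
    if ci_method not in ("normal", "hksj"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    g = np.array([s.effect.g for s in studies], dtype=float)
    v = np.array([s.effect.variance for s in studies], dtype=float)
    k = g.size

    if k == 1:
        warnings.warn("pooling a single study: tau2 fixed at 0", stacklevel=2)
        q, tau2, df, i2 = 0.0, 0.0, 0, 0.0
    else:
        q = cochran_q(g, v)
        tau2 = _TAU2_ESTIMATORS[tau2_method](g, v)
        df = k - 1
        i2 = i_squared(q, df)

    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * g) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))

    if ci_method == "hksj" and k >= 2:
        var_hk = float(np.sum(w * (g - mu) ** 2) / ((k - 1) * np.sum(w)))
        se_ci = np.sqrt(var_hk)
        crit = float(stats.t.ppf(0.975, k - 1))
    else:
        se_ci = se
        crit = Z_95

    return PooledResult(
        mu_hat=mu,
        se=se,
        ci_low=mu - crit * se_ci,
        ci_high=mu + crit * se_ci,
        tau2=tau2,
        q_stat=q,
        df=df,
        i2=i2,
        weights=w,
        k=k,
        tau2_method=tau2_method,
        ci_method=ci_method,
        label=label,
    )


def subgroup_analysis(
    studies: list[StudyRecord],
    *,
    tau2_method: str = "dl",
    ci_method: str = "normal",
) -> dict[Route, PooledResult]:
    """Pool each administration route independently (own tau2 per group)."""
    groups: dict[Route, list[StudyRecord]] = {}
    for s in studies:
        route = Route(s.route)  # raises ValueError on unknown labels
        groups.setdefault(route, []).append(s)
    if not groups:
        raise EmptySetError("no studies supplied")
    return {
        route: random_effects_pool(
            members, tau2_method=tau2_method, ci_method=ci_method, label=route.value
        )
        for route, members in groups.items()
    }


def forest_table(studies: list[StudyRecord], pooled: PooledResult) -> pd.DataFrame:
    """Tabular forest plot: one row per study plus a pooled summary row.

    Weight percentages are the random-effects weights normalized to 100.
    """
    if len(studies) != pooled.k:
        raise ValidationError("pooled result was computed from a different study set")
    w_pct = 100.0 * pooled.weights / np.sum(pooled.weights)
    rows = []
    for s, wp in zip(studies, w_pct):
        half = Z_95 * np.sqrt(s.effect.variance)
        rows.append(
            {
                "study_id": s.study_id,
                "route": Route(s.route).value,
                "design": s.design,
                "g": s.effect.g,
                "ci_low": s.effect.g - half,
                "ci_high": s.effect.g + half,
                "weight_pct": float(wp),
            }
        )
    rows.append(
        {
            "study_id": "POOLED" + (f" ({pooled.label})" if pooled.label else ""),
            "route": "",
            "design": "",
            "g": pooled.mu_hat,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)
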