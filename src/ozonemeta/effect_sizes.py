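"""Standardized mean differences (Hedges' g) and their sampling variances.

Two designs are supported:

* **between-groups** (RCT): g = J · (mean_treat − mean_ctrl) / S_pooled, with
  S_pooled the df-weighted pooled SD and J the small-sample correction
  J = 1 − 3/(4·df − 1) evaluated at df = n_t + n_c − 2.
* **pre–post** (single-arm cohort): g = J · (mean_pre − mean_post) / SD_change,
  SD_change = sqrt(sd_pre² + sd_post² − 2·r·sd_pre·sd_post) with pre–post
  correlation r (imputed at 0.5 when the primary study reports none).

Sampling variances use the standard large-sample approximations:

* between-groups: (n_t+n_c)/(n_t·n_c) + g²/(2(n_t+n_c))
* pre–post:       (1/n + g²/(2n)) · 2(1 − r)

The g values are unitless, so the outcome scale (VAS, ODI, ...) cancels.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .exceptions import DegenerateSampleError, ValidationError, ZeroDispersionError

__all__ = [
    "Design",
    "ArmSummary",
    "PrePostSummary",
    "EffectEstimate",
    "pooled_sd",
    "small_sample_correction",
    "hedges_g_between",
    "sd_change",
    "hedges_g_prepost",
    "variance_of_g",
    "DEFAULT_PREPOST_R",
]

#: Pre-post correlation imputed when a cohort study reports no paired data.
DEFAULT_PREPOST_R = 0.5


class Design(str, enum.Enum):
    """Study design behind an effect estimate."""

    BETWEEN_GROUPS = "between_groups"
    PRE_POST = "pre_post"


@dataclass(frozen=True)
class ArmSummary:
    """Summary statistics for one trial arm on the outcome scale."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")


@dataclass(frozen=True)
class PrePostSummary:
    """Paired pre/post summary statistics for a single-arm cohort."""

    mean_pre: float
    mean_post: float
    sd_pre: float
    sd_post: float
    n: int
    r: float = DEFAULT_PREPOST_R

    def __post_init__(self) -> None:
        if self.sd_pre < 0 or self.sd_post < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n}")
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError(f"r must lie in [-1, 1], got {self.r}")


@dataclass(frozen=True)
class EffectEstimate:
    """A small-sample-corrected standardized mean difference.

    Attributes
    ----------
    g : float
        Unitless Hedges' g.
    variance : float
        Large-sample sampling variance of g (> 0).
    j_factor : float
        The correction J actually applied, in (0, 1].
    design : Design
        Which design produced the estimate.
    """

    g: float
    variance: float
    j_factor: float
    design: Design

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValidationError(f"variance must be > 0, got {self.variance}")
        if not 0 < self.j_factor <= 1:
            raise ValidationError(f"j_factor must lie in (0, 1], got {self.j_factor}")


def pooled_sd(treat: ArmSummary, ctrl: ArmSummary, *, denominator: str = "standard") -> float:
    """Pooled standard deviation of two arms.

    ``denominator="standard"`` uses the textbook df n_t + n_c − 2;
    ``"printed"`` uses n_t + n_c + 2, kept only so sensitivity to that
    variant can be audited.
    """
    nt, nc = treat.n, ctrl.n
    if nt + nc <= 2:
        raise DegenerateSampleError("need n_t + n_c > 2 to pool standard deviations")
    if denominator == "standard":
        denom = nt + nc - 2
    elif denominator == "printed":
        denom = nt + nc + 2
    else:
        raise ValidationError(f"unknown denominator convention {denominator!r}")
    return math.sqrt(((nt - 1) * treat.sd**2 + (nc - 1) * ctrl.sd**2) / denom)


def _j_from_df(df: float) -> float:
    """Hedges correction J = 1 − 3/(4·df − 1)."""
    if 4 * df - 1 <= 0:
        raise DegenerateSampleError(f"degrees of freedom {df} too small for J")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def small_sample_correction(n_total: int) -> float:
    """Two-sample small-sample correction J = 1 − 3/(4·n_total − 9).

    Equivalent to J = 1 − 3/(4·df − 1) at df = n_total − 2. Tends to 1 as
    n_total grows; equals 0 at the degenerate boundary n_total = 3.
    """
    if n_total <= 2:
        raise DegenerateSampleError(f"n_total must exceed 2, got {n_total}")
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def hedges_g_between(
    treat: ArmSummary,
    ctrl: ArmSummary,
    *,
    denominator: str = "standard",
) -> EffectEstimate:
    """Between-groups Hedges' g with sampling variance."""
    s_pool = pooled_sd(treat, ctrl, denominator=denominator)
    if s_pool == 0:
        raise ZeroDispersionError("pooled SD is zero; g undefined")
    j = small_sample_correction(treat.n + ctrl.n)
    g = j * (treat.mean - ctrl.mean) / s_pool
    var = variance_of_g(g, Design.BETWEEN_GROUPS, n_treat=treat.n, n_ctrl=ctrl.n)
    return EffectEstimate(g=g, variance=var, j_factor=j, design=Design.BETWEEN_GROUPS)


def sd_change(s: PrePostSummary) -> float:
    """Standard deviation of the pre−post change score."""
    radicand = s.sd_pre**2 + s.sd_post**2 - 2.0 * s.r * s.sd_pre * s.sd_post
    if radicand < -1e-12:
        raise ValidationError(f"negative change-score variance {radicand}")
    return math.sqrt(max(radicand, 0.0))


def hedges_g_prepost(s: PrePostSummary, *, j_convention: str = "single_group") -> EffectEstimate:
    """Pre–post (change-score) Hedges' g with sampling variance.

    ``j_convention`` selects the degrees of freedom fed to the correction:
    ``"single_group"`` (default) uses df = n − 1; ``"total_n"`` mimics the
    two-sample form 1 − 3/(4n − 9). The choice is exposed because primary
    reports rarely state it.
    """
    sdc = sd_change(s)
    if sdc == 0:
        raise ZeroDispersionError("change-score SD is zero; g undefined")
    if j_convention == "single_group":
        j = _j_from_df(s.n - 1)
    elif j_convention == "total_n":
        j = small_sample_correction(s.n)
    else:
        raise ValidationError(f"unknown j_convention {j_convention!r}")
    g = j * (s.mean_pre - s.mean_post) / sdc
    var = variance_of_g(g, Design.PRE_POST, n=s.n, r=s.r)
    return EffectEstimate(g=g, variance=var, j_factor=j, design=Design.PRE_POST)


def variance_of_g(
    g: float,
    design: Design,
    *,
    n_treat: int | None = None,
    n_ctrl: int | None = None,
    n: int | None = None,
    r: float | None = None,
) -> float:
    """Large-sample sampling variance of Hedges' g for either design."""
    if design is Design.BETWEEN_GROUPS:
        if n_treat is None or n_ctrl is None:
            raise ValidationError("between-groups variance needs n_treat and n_ctrl")
        ntot = n_treat + n_ctrl
        return ntot / (n_treat * n_ctrl) + g**2 / (2.0 * ntot)
    if design is Design.PRE_POST:
        if n is None:
            raise ValidationError("pre-post variance needs n")
        r_eff = DEFAULT_PREPOST_R if r is None else r
        return (1.0 / n + g**2 / (2.0 * n)) * 2.0 * (1.0 - r_eff)
    raise ValidationError(f"unknown design {design!r}")
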