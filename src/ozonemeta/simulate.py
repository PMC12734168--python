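"""Synthetic inputs with known ground truth for every pipeline stage.

The trial generator emulates the statistical structure the meta-analytic
model assumes: study-level true effects theta_i ~ N(mu, tau2), normal
outcomes on a VAS-like 0–10 scale, two parallel arms for RCTs and
correlated pre/post pairs for cohorts. RCTs are assigned the intramuscular
route and cohorts the intradiscal route, mirroring the design mix of the
published study table. Complication events are Binomial(n, p) draws and
phantoms are concentric disc/muscle/bone geometries with an optional
hypodense gas inclusion.

Random-number contract: every generator derives its stream as
``default_rng([root_seed, STREAM_ID, *indices])`` with a fixed per-component
``STREAM_ID``, so adding a new generator never perturbs existing streams and
the same seed always reproduces the same output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effect_sizes import (
    ArmSummary,
    PrePostSummary,
    hedges_g_between,
    hedges_g_prepost,
)
from .exceptions import ValidationError
from .imaging import VolumeImage
from .meta import Route, StudyRecord, random_effects_pool

__all__ = [
    "TrialSimSpec",
    "PhantomSpec",
    "SimulatedStudySet",
    "RecoverySummary",
    "simulate_study_set",
    "simulate_risk_events",
    "generate_phantom",
    "parameter_recovery_experiment",
]

# Fixed stream identifiers (see module docstring).
_STREAM_TRIALS = 1
_STREAM_RISK = 2
_STREAM_PHANTOM = 3
_STREAM_RECOVERY = 4

# VAS-like outcome scale: baseline severity and spread (cosmetic; g is
# scale-free).
_CTRL_MEAN, _OUTCOME_SD = 5.0, 2.0
_PRE_MEAN = 7.0


@dataclass(frozen=True)
class TrialSimSpec:
    """Parameters of a simulated set of two-arm / pre-post pain studies."""

    k_studies: int = 7
    true_mu: float = -1.0
    true_tau2: float = 0.2
    design_mix: float = 0.5  # probability a study is an RCT
    n_range: tuple[int, int] = (20, 60)  # per-arm (or cohort) size bounds
    r_true: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 0:
            raise ValidationError("k_studies must be >= 0")
        if self.true_tau2 < 0:
            raise ValidationError("true_tau2 must be >= 0")
        if not 0.0 <= self.design_mix <= 1.0:
            raise ValidationError("design_mix must lie in [0, 1]")
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValidationError("n_range must satisfy 2 <= min <= max")
        if not -1.0 < self.r_true < 1.0:
            raise ValidationError("r_true must lie in (-1, 1)")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of a CT-like phantom with a gas inclusion."""

    shape: tuple[int, int, int] = (48, 48, 48)
    disc_hu: float = 60.0
    muscle_hu: float = 40.0
    bone_hu: float = 400.0
    gas_hu: float = -800.0
    noise_sd: float = 0.0
    gas_fraction: float = 0.1
    spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gas_fraction <= 1.0:
            raise ValidationError("gas_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if min(self.shape) < 16:
            raise ValidationError("shape too small for the concentric geometry")


@dataclass
class SimulatedStudySet:
    """Simulated studies: typed records, a CSV-schema table, and the truth."""

    records: list[StudyRecord]
    table: pd.DataFrame
    true_effects: list[float]
    spec: TrialSimSpec


@dataclass
class RecoverySummary:
    """Bias/RMSE of pooled-effect and tau2 recovery over repeated simulation."""

    n_reps: int
    mean_mu_hat: float
    bias_mu: float
    rmse_mu: float
    mc_se_mu: float
    mean_tau2_hat: float
    bias_tau2: float
    rmse_tau2: float


def simulate_study_set(spec: TrialSimSpec) -> SimulatedStudySet:
    """Simulate ``k_studies`` studies with raw arm summaries and true effects."""
    records: list[StudyRecord] = []
    rows: list[dict] = []
    thetas: list[float] = []
    for i in range(spec.k_studies):
        rng = np.random.default_rng([spec.seed, _STREAM_TRIALS, i])
        theta = spec.true_mu + np.sqrt(spec.true_tau2) * rng.standard_normal()
        thetas.append(float(theta))
        is_rct = rng.random() < spec.design_mix
        n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        if is_rct:
            n_c = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
            treat_raw = _CTRL_MEAN + theta * _OUTCOME_SD + _OUTCOME_SD * rng.standard_normal(n)
            ctrl_raw = _CTRL_MEAN + _OUTCOME_SD * rng.standard_normal(n_c)
            treat = ArmSummary(float(treat_raw.mean()), float(treat_raw.std(ddof=1)), n)
            ctrl = ArmSummary(float(ctrl_raw.mean()), float(ctrl_raw.std(ddof=1)), n_c)
            eff = hedges_g_between(treat, ctrl)
            rec = StudyRecord(f"sim_rct_{i:03d}", Route.INTRAMUSCULAR, "rct", eff, "simulated control")
            rows.append(
                {
                    "study_id": rec.study_id, "route": rec.route.value, "design": "rct",
                    "n_treat": n, "n_ctrl": n_c, "g": "",
                    "mean_treat": treat.mean, "sd_treat": treat.sd,
                    "mean_ctrl": ctrl.mean, "sd_ctrl": ctrl.sd,
                    "mean_pre": "", "sd_pre": "", "mean_post": "", "sd_post": "",
                    "r": "", "comparator": rec.comparator,
                }
            )
        else:
            # Correlated pre/post pairs. theta is on the treat-minus-control
            # orientation (negative = pain reduction); the cohort records its
            # change as pre - post, so its g comes out as -theta, positive
            # for a beneficial treatment.
            sd_change_true = _OUTCOME_SD * np.sqrt(2.0 * (1.0 - spec.r_true))
            pre_raw = _PRE_MEAN + _OUTCOME_SD * rng.standard_normal(n)
            eps = rng.standard_normal(n)
            post_raw = (
                _PRE_MEAN
                + theta * sd_change_true
                + spec.r_true * (pre_raw - _PRE_MEAN)
                + _OUTCOME_SD * np.sqrt(1.0 - spec.r_true**2) * eps
            )
            r_sample = float(np.corrcoef(pre_raw, post_raw)[0, 1])
            pp = PrePostSummary(
                float(pre_raw.mean()), float(post_raw.mean()),
                float(pre_raw.std(ddof=1)), float(post_raw.std(ddof=1)),
                n, r_sample,
            )
            eff = hedges_g_prepost(pp)
            rec = StudyRecord(f"sim_cohort_{i:03d}", Route.INTRADISCAL, "cohort", eff, "Pre-post")
            rows.append(
                {
                    "study_id": rec.study_id, "route": rec.route.value, "design": "cohort",
                    "n_treat": n, "n_ctrl": "", "g": "",
                    "mean_treat": "", "sd_treat": "", "mean_ctrl": "", "sd_ctrl": "",
                    "mean_pre": pp.mean_pre, "sd_pre": pp.sd_pre,
                    "mean_post": pp.mean_post, "sd_post": pp.sd_post,
                    "r": pp.r, "comparator": rec.comparator,
                }
            )
        records.append(rec)
    columns = [
        "study_id", "route", "design", "n_treat", "n_ctrl", "g",
        "mean_treat", "sd_treat", "mean_ctrl", "sd_ctrl",
        "mean_pre", "sd_pre", "mean_post", "sd_post", "r", "comparator",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return SimulatedStudySet(records=records, table=table, true_effects=thetas, spec=spec)


def simulate_risk_events(n_procedures: int, p: float, seed: int = 0) -> int:
    """Binomial(n, p) draw of serious-complication events."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    if n_procedures < 0:
        raise ValidationError("n_procedures must be >= 0")
    rng = np.random.default_rng([seed, _STREAM_RISK])
    return int(rng.binomial(n_procedures, p))


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeImage, VolumeImage, np.ndarray]:
    """Concentric CT-like phantom: (baseline volume, gas volume, truth mask).

    Axial geometry: a central cylindrical "disc" surrounded by a bony
    annulus, embedded in muscle-density background. The gas volume replaces
    a central sphere covering ``gas_fraction`` of the disc voxels with
    ``gas_hu``; identical Gaussian noise fields are added to both volumes so
    they differ only by the inclusion.
    """
    nz, ny, nx = spec.shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cy, cx, cz = (ny - 1) / 2.0, (nx - 1) / 2.0, (nz - 1) / 2.0
    r_xy = np.sqrt((y - cy) ** 2 + (x - cx) ** 2)
    r_disc = min(ny, nx) / 4.0
    r_bone = min(ny, nx) / 3.0
    disc_height = max(nz // 4, 3)
    in_slab = np.abs(z - cz) <= disc_height / 2.0

    base = np.full(spec.shape, spec.muscle_hu, dtype=float)
    base[np.broadcast_to(in_slab & (r_xy < r_bone), spec.shape)] = spec.bone_hu
    disc_mask = np.broadcast_to(in_slab & (r_xy < r_disc), spec.shape)
    base[disc_mask] = spec.disc_hu

    gas_mask = np.zeros(spec.shape, dtype=bool)
    n_gas_target = int(round(spec.gas_fraction * disc_mask.sum()))
    if n_gas_target > 0:
        r3 = np.sqrt((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2)
        # grow a central sphere until it covers the target voxel count
        order = np.sort(r3[disc_mask].ravel())
        r_gas = order[min(n_gas_target, order.size) - 1]
        gas_mask = disc_mask & (r3 <= r_gas)

    gas_vox = base.copy()
    gas_vox[gas_mask] = spec.gas_hu

    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, _STREAM_PHANTOM])
        noise = spec.noise_sd * rng.standard_normal(spec.shape)
        base = base + noise
        gas_vox = gas_vox + noise

    return (
        VolumeImage(base, spacing=spec.spacing),
        VolumeImage(gas_vox, spacing=spec.spacing),
        gas_mask,
    )


def parameter_recovery_experiment(spec: TrialSimSpec, n_reps: int) -> RecoverySummary:
    """Repeatedly simulate → estimate → pool, summarizing recovery of mu and tau2."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    mus = np.empty(n_reps)
    tau2s = np.empty(n_reps)
    for rep in range(n_reps):
        rep_seed_rng = np.random.default_rng([spec.seed, _STREAM_RECOVERY, rep])
        rep_seed = int(rep_seed_rng.integers(0, 2**31 - 1))
        rep_spec = TrialSimSpec(
            k_studies=spec.k_studies, true_mu=spec.true_mu, true_tau2=spec.true_tau2,
            design_mix=spec.design_mix, n_range=spec.n_range, r_true=spec.r_true,
            seed=rep_seed,
        )
        sim = simulate_study_set(rep_spec)
        pooled = random_effects_pool(_orient_records(sim.records))
        mus[rep] = pooled.mu_hat
        tau2s[rep] = pooled.tau2
    bias_mu = float(mus.mean() - spec.true_mu)
    bias_tau2 = float(tau2s.mean() - spec.true_tau2)
    return RecoverySummary(
        n_reps=n_reps,
        mean_mu_hat=float(mus.mean()),
        bias_mu=bias_mu,
        rmse_mu=float(np.sqrt(np.mean((mus - spec.true_mu) ** 2))),
        mc_se_mu=float(mus.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0,
        mean_tau2_hat=float(tau2s.mean()),
        bias_tau2=bias_tau2,
        rmse_tau2=float(np.sqrt(np.mean((tau2s - spec.true_tau2) ** 2))),
    )


def _orient_records(records: list[StudyRecord]) -> list[StudyRecord]:
    """Map cohort effects (pre − post orientation) back onto treat − control.

    Negating a pre-post g puts both designs on the same sign convention;
    the sampling variance is even in g, so it is unchanged.
    """
    from dataclasses import replace

    out = []
    for rec in records:
        if rec.design == "cohort":
            rec = replace(rec, effect=replace(rec.effect, g=-rec.effect.g))
        out.append(rec)
    return out
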