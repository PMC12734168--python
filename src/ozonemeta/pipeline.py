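"""End-to-end orchestration: effect sizes → pooling → subgroups → risk →
diffusion → combined safety–efficacy report.

``run_full_analysis`` emits a deterministic bundle of machine-readable
outputs into one directory:

* ``forest_overall.tsv`` / ``forest_<route>.tsv`` — tabular forest plots
* ``pooled.json`` — overall and per-route :class:`~ozonemeta.meta.PooledResult`
* ``risk_ledger.tsv`` + ``risk_comparison.json`` — harm ledger
* ``arrival_table.tsv`` — per-gas characteristic diffusion times
* ``safety_efficacy.tsv`` — normalized safety score vs |pooled g| per route
* ``provenance.log`` — every estimator switch plus the standing
  source-discrepancy notes (EQ12-UNITS, TAU2-IRREPRODUCIBLE, ...)

Outputs are byte-identical across reruns on identical config and inputs
(no timestamps are written).
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

from . import presets
from .diffusion import arrival_table, observation_consistency
from .exceptions import ConfigurationError, OzoneMetaError
from .io import read_gas_csv, read_risk_json, read_study_csv
from .meta import Route, forest_table, random_effects_pool, subgroup_analysis
from .risk import compare_routes, risk_ledger, safety_efficacy_summary

__all__ = ["RunConfig", "run_full_analysis"]

_TAU2_METHODS = ("dl", "reml")
_CI_METHODS = ("normal", "hksj")
_INCLUSION_RULES = ("all", "cohort_only")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    When ``study_csv`` / ``risk_json`` / ``gas_csv`` are None the shipped
    published presets are used (study table, severe-complication risk pair,
    gas coefficient table).
    """

    output_dir: Path
    study_csv: Path | None = None
    risk_json: Path | None = None
    gas_csv: Path | None = None
    risk_preset: str = "severe-complication"
    tau2_method: str = "dl"
    ci_method: str = "normal"
    intradiscal_inclusion: str = "cohort_only"
    path_lengths_m: list[float] = field(default_factory=lambda: [2e-3, 3e-3])
    scan_schedule_s: list[float] = field(default_factory=lambda: list(presets.CT_SCAN_SCHEDULE_S))
    schedule_pad_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau2_method not in _TAU2_METHODS:
            raise ConfigurationError(f"tau2_method must be one of {_TAU2_METHODS}")
        if self.ci_method not in _CI_METHODS:
            raise ConfigurationError(f"ci_method must be one of {_CI_METHODS}")
        if self.intradiscal_inclusion not in _INCLUSION_RULES:
            raise ConfigurationError(f"intradiscal_inclusion must be one of {_INCLUSION_RULES}")
        if self.risk_preset not in presets.RISK_PRESET_NAMES:
            raise ConfigurationError(f"risk_preset must be one of {presets.RISK_PRESET_NAMES}")
        for p in (self.study_csv, self.risk_json, self.gas_csv):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns it as a dict.

    Any stage failure removes partial outputs and re-raises with a
    stage-tagged message.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: list[str] = [
        f"tau2_method={cfg.tau2_method}",
        f"ci_method={cfg.ci_method}",
        f"intradiscal_inclusion={cfg.intradiscal_inclusion}",
        f"risk_preset={cfg.risk_preset}" if cfg.risk_json is None else f"risk_json={cfg.risk_json}",
        f"seed={cfg.seed}",
    ]
    bundle: dict = {}
    stage = "load-inputs"
    try:
        studies = (
            read_study_csv(cfg.study_csv) if cfg.study_csv is not None else presets.study_table()
        )
        risk_cfg = (
            read_risk_json(cfg.risk_json)
            if cfg.risk_json is not None
            else presets.risk_preset(cfg.risk_preset)
        )
        gases = (
            read_gas_csv(cfg.gas_csv)
            if cfg.gas_csv is not None
            else list(presets.GAS_TABLE.values())
        )

        stage = "meta-analysis"
        overall = random_effects_pool(
            studies, tau2_method=cfg.tau2_method, ci_method=cfg.ci_method, label="overall"
        )
        forest_table(studies, overall).to_csv(out / "forest_overall.tsv", sep="\t", index=False)

        subgroup_input = studies
        if cfg.intradiscal_inclusion == "cohort_only":
            subgroup_input = [
                s for s in studies
                if not (Route(s.route) is Route.INTRADISCAL and s.design == "rct")
            ]
        subgroups = subgroup_analysis(
            subgroup_input, tau2_method=cfg.tau2_method, ci_method=cfg.ci_method
        )
        for route, pooled in subgroups.items():
            members = [s for s in subgroup_input if Route(s.route) is route]
            forest_table(members, pooled).to_csv(
                out / f"forest_{route.value}.tsv", sep="\t", index=False
            )
        bundle["pooled"] = {
            "overall": overall.to_dict(),
            **{route.value: pooled.to_dict() for route, pooled in subgroups.items()},
        }
        provenance.append(
            "TAU2-IRREPRODUCIBLE: " + presets.DISCREPANCY_NOTES["TAU2-IRREPRODUCIBLE"]
        )

        stage = "risk-ledger"
        ledger = risk_ledger(
            risk_cfg["routes"],
            baseline=risk_cfg["baseline"],
            n_procedures=risk_cfg["n_procedures"],
        )
        ledger.to_csv(out / "risk_ledger.tsv", sep="\t", index=False)
        by_name = {r.route: r for r in risk_cfg["routes"]}
        exposed = next(r for r in risk_cfg["routes"] if r.route != risk_cfg["baseline"])
        comparison = compare_routes(exposed, by_name[risk_cfg["baseline"]])
        bundle["risk"] = comparison.to_dict()
        provenance.append(
            "RISK-RATIO-ROUNDING: " + presets.DISCREPANCY_NOTES["RISK-RATIO-ROUNDING"]
        )

        stage = "diffusion"
        arrivals = arrival_table(cfg.path_lengths_m, gases)
        arrivals.to_csv(out / "arrival_table.tsv", sep="\t", index=False)
        consistency = {}
        for _, row in arrivals.iterrows():
            verdicts = observation_consistency(
                row["time_s"], cfg.scan_schedule_s, cfg.schedule_pad_s
            )
            consistency[f"{row['gas']}@{row['distance_m']:g}m"] = verdicts
        bundle["diffusion"] = {
            "arrival_table": arrivals.to_dict(orient="records"),
            "scan_schedule_s": cfg.scan_schedule_s,
            "consistency": consistency,
        }
        provenance.append("EQ12-UNITS: " + presets.DISCREPANCY_NOTES["EQ12-UNITS"])

        stage = "safety-efficacy"
        pooled_g = {route.value: pooled.mu_hat for route, pooled in subgroups.items()}
        summary = safety_efficacy_summary(risk_cfg["routes"], pooled_g)
        summary.to_csv(out / "safety_efficacy.tsv", sep="\t", index=False)
        bundle["safety_efficacy"] = summary.to_dict(orient="records")

        stage = "write-bundle"
        (out / "pooled.json").write_text(json.dumps(bundle["pooled"], indent=2, sort_keys=True))
        (out / "risk_comparison.json").write_text(
            json.dumps(bundle["risk"], indent=2, sort_keys=True)
        )
        (out / "bundle.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        (out / "provenance.log").write_text("\n".join(provenance) + "\n")
    except Exception as exc:  # tag the failing stage, drop partial outputs
        shutil.rmtree(out, ignore_errors=True)
        raise OzoneMetaError(f"stage {stage!r} failed: {exc}") from exc
    return bundle
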