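"""Readers and writers for the pipeline's plain-text interchange formats.

* study CSV — one row per study; either a precomputed ``g`` or raw
  mean/sd summaries must be present (columns: study_id, route, design,
  n_treat, n_ctrl, g, mean_treat, sd_treat, mean_ctrl, sd_ctrl, mean_pre,
  sd_pre, mean_post, sd_post, r, comparator)
* risk JSON — {"routes": [{"name", "p_serious", "ctcae_band", "source"}],
  "baseline": name, "n_procedures": int}
* gas CSV — columns name, D_m2_per_s, source_note
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .diffusion import GasSpecies
from .effect_sizes import (
    ArmSummary,
    Design,
    EffectEstimate,
    PrePostSummary,
    hedges_g_between,
    hedges_g_prepost,
    variance_of_g,
)
from .exceptions import ValidationError
from .meta import Route, StudyRecord
from .risk import RouteRisk

__all__ = [
    "read_study_csv",
    "write_study_csv",
    "read_risk_json",
    "write_risk_json",
    "read_gas_csv",
    "write_gas_csv",
]


def _has(row, col) -> bool:
    if col not in row:
        return False
    v = row[col]
    if v is None or (isinstance(v, str) and v.strip() == ""):
        return False
    if isinstance(v, float) and math.isnan(v):
        return False
    return True


def read_study_csv(path, *, default_r: float = 0.5) -> list[StudyRecord]:
    """Load study records, computing effects from raw summaries when no g given."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        route = Route(str(row["route"]).strip().lower())
        design = str(row["design"]).strip().lower()
        comparator = str(row["comparator"]) if _has(row, "comparator") else ""
        r = float(row["r"]) if _has(row, "r") else default_r
        if _has(row, "g"):
            g = float(row["g"])
            if design == "rct":
                var = variance_of_g(
                    g, Design.BETWEEN_GROUPS,
                    n_treat=int(row["n_treat"]), n_ctrl=int(row["n_ctrl"]),
                )
                eff = EffectEstimate(g, var, 1.0, Design.BETWEEN_GROUPS)
            else:
                var = variance_of_g(g, Design.PRE_POST, n=int(row["n_treat"]), r=r)
                eff = EffectEstimate(g, var, 1.0, Design.PRE_POST)
        elif design == "rct" and _has(row, "mean_treat"):
            treat = ArmSummary(float(row["mean_treat"]), float(row["sd_treat"]), int(row["n_treat"]))
            ctrl = ArmSummary(float(row["mean_ctrl"]), float(row["sd_ctrl"]), int(row["n_ctrl"]))
            eff = hedges_g_between(treat, ctrl)
        elif design == "cohort" and _has(row, "mean_pre"):
            pp = PrePostSummary(
                float(row["mean_pre"]), float(row["mean_post"]),
                float(row["sd_pre"]), float(row["sd_post"]),
                int(row["n_treat"]), r,
            )
            eff = hedges_g_prepost(pp)
        else:
            raise ValidationError(
                f"study {row.get('study_id', '?')}: need either g or raw summaries"
            )
        records.append(
            StudyRecord(str(row["study_id"]), route, design, eff, comparator)
        )
    return records


def write_study_csv(records: list[StudyRecord], path) -> None:
    """Write study records (with their precomputed g) to the CSV schema."""
    rows = []
    for rec in records:
        rows.append(
            {
                "study_id": rec.study_id,
                "route": rec.route.value,
                "design": rec.design,
                "n_treat": "",
                "n_ctrl": "",
                "g": rec.effect.g,
                "variance": rec.effect.variance,
                "comparator": rec.comparator,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_risk_json(path) -> dict:
    """Load a risk configuration: routes, baseline route name, n_procedures."""
    cfg = json.loads(Path(path).read_text())
    routes = [
        RouteRisk(
            route=item["name"],
            p_serious=float(item["p_serious"]),
            source=item.get("source", ""),
            ctcae_band=item.get("ctcae_band", ""),
        )
        for item in cfg["routes"]
    ]
    return {
        "routes": routes,
        "baseline": cfg["baseline"],
        "n_procedures": int(cfg.get("n_procedures", 10_000)),
    }


def write_risk_json(routes: list[RouteRisk], baseline: str, n_procedures: int, path) -> None:
    cfg = {
        "routes": [
            {
                "name": r.route,
                "p_serious": r.p_serious,
                "ctcae_band": r.ctcae_band,
                "source": r.source,
            }
            for r in routes
        ],
        "baseline": baseline,
        "n_procedures": n_procedures,
    }
    Path(path).write_text(json.dumps(cfg, indent=2))


def read_gas_csv(path) -> list[GasSpecies]:
    df = pd.read_csv(path)
    return [
        GasSpecies(str(row["name"]), float(row["D_m2_per_s"])) for _, row in df.iterrows()
    ]


def write_gas_csv(gases: list[GasSpecies], path, notes: dict[str, str] | None = None) -> None:
    notes = notes or {}
    pd.DataFrame(
        [
            {"name": g.name, "D_m2_per_s": g.diffusion_coefficient,
             "source_note": notes.get(g.name, "")}
            for g in gases
        ]
    ).to_csv(path, index=False)
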