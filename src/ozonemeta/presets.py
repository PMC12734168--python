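"""Published inputs shipped as ready-made configurations.

These are the study-level effect sizes, complication-risk figures and gas
diffusion coefficients printed in the source report; they are inputs to the
pipeline, not quantities it estimates. Two mutually inconsistent risk pairs
appear in the source and are shipped side by side as named presets rather
than reconciled:

* ``combined-risk``: 9.52% (intradiscal) vs 1.45% (intramuscular), the
  "combined risk" of complications of any grade attributed to each route.
* ``severe-complication``: 0.10% pooled severe-complication rate for the
  intradiscal route, with the intramuscular baseline back-calculated from
  the 6.57:1 risk ratio (0.10%/6.57 ≈ 0.0152%), per the source's own
  footnote. The literal 0.10/0.015 division is 6.67, not 6.57; exact ratios
  are only reproduced through the back-calculated baseline
  (RISK-RATIO-ROUNDING).
"""

from __future__ import annotations

from .diffusion import GasSpecies
from .effect_sizes import Design, EffectEstimate, variance_of_g
from .meta import Route, StudyRecord
from .risk import RouteRisk, back_calculate_baseline

__all__ = [
    "GAS_TABLE",
    "GAS_O3_ALTERNATE",
    "study_table",
    "risk_preset",
    "RISK_PRESET_NAMES",
    "CT_SCAN_SCHEDULE_S",
    "DEFAULT_PATH_LENGTH_M",
    "DISCREPANCY_NOTES",
]

#: Diffusion coefficients for small gases in water/soft tissue at 37 °C (m²/s).
GAS_TABLE: dict[str, GasSpecies] = {
    "O2": GasSpecies("O2", 2.0e-9),
    "O3": GasSpecies("O3", 1.2e-9),
    "CO": GasSpecies("CO", 2.1e-9),
    "NO": GasSpecies("NO", 3.3e-9),
    "N2": GasSpecies("N2", 2.0e-9),
}

#: Alternate ozone coefficient (1.1e-9 m²/s) also quoted in the source.
GAS_O3_ALTERNATE = GasSpecies("O3", 1.1e-9)

#: CT observation schedule: scans at 0, 3, 7 and 12 min post-injection (s).
CT_SCAN_SCHEDULE_S = [0.0, 180.0, 420.0, 720.0]

#: Paravertebral-space-to-disc path length used in the worked examples (m).
DEFAULT_PATH_LENGTH_M = 3e-3

RISK_PRESET_NAMES = ("combined-risk", "severe-complication")

DISCREPANCY_NOTES = {
    "EQ12-UNITS": (
        "Characteristic times x^2/(2D) at 3 mm evaluate to thousands of seconds "
        "but were published with a 'min' label; mantissas reported in 10^3 s."
    ),
    "TAU2-IRREPRODUCIBLE": (
        "The published overall pooled g = -2.42 (tau2 = 6.176, Q = 860.57) and "
        "intradiscal subgroup g = 2.87 (tau2 = 4.92) are not recoverable from "
        "the study table under standard large-sample variance formulas; the "
        "pipeline reports its own reconstruction without asserting equality."
    ),
    "RISK-RATIO-ROUNDING": (
        "0.10%/0.015% is literally 6.67; the published RR 6.57 is reproduced "
        "only via the back-calculated baseline 0.10%/6.57."
    ),
}

# Study table: (study_id, route, design, g, n_treat, n_ctrl-or-None, comparator).
# Cohort rows carry a single cohort size; their g is a pre-post standardized
# change with r = 0.5 imputed.
_STUDY_ROWS = [
    ("Paoloni 2009", Route.INTRAMUSCULAR, "rct", -2.42, 36, 24, "Placebo"),
    ("Biazzo 2018", Route.INTRAMUSCULAR, "rct", -0.8, 20, 20, "Steroid"),
    ("Ucar 2013", Route.INTRAMUSCULAR, "rct", -1.43, 30, 30, "Steroid"),
    ("Kelekis 2022", Route.INTRADISCAL, "rct", 0.07, 140, 140, "Surgery"),
    ("Giurazza 2017", Route.INTRADISCAL, "cohort", 3.56, 108, None, "Pre-post"),
    ("Ghatge 2011", Route.INTRADISCAL, "cohort", 4.61, 35, None, "Pre-post"),
    ("Muto 2004", Route.INTRADISCAL, "cohort", 3.56, 600, None, "Pre-post"),
]


def study_table(prepost_r: float = 0.5) -> list[StudyRecord]:
    """The seven included studies with large-sample variances attached.

    Only the published g values and sample sizes are inputs; the sampling
    variances are derived here because the source does not print them.
    """
    records = []
    for study_id, route, design, g, n1, n2, comparator in _STUDY_ROWS:
        if design == "rct":
            var = variance_of_g(g, Design.BETWEEN_GROUPS, n_treat=n1, n_ctrl=n2)
            eff = EffectEstimate(g=g, variance=var, j_factor=1.0, design=Design.BETWEEN_GROUPS)
        else:
            var = variance_of_g(g, Design.PRE_POST, n=n1, r=prepost_r)
            eff = EffectEstimate(g=g, variance=var, j_factor=1.0, design=Design.PRE_POST)
        records.append(
            StudyRecord(study_id=study_id, route=route, design=design,
                        effect=eff, comparator=comparator)
        )
    return records


#: Published risk ratio used for the back-calculated baseline.
HEADLINE_RR = 6.57

#: Pooled severe-complication rate for the intradiscal route.
SEVERE_P_INTRADISCAL = 0.0010


def risk_preset(name: str) -> dict:
    """Return a named risk configuration: routes, baseline, procedure volume."""
    if name == "combined-risk":
        routes = [
            RouteRisk("intradiscal", 0.0952, source="combined complication risk", ctcae_band="G3-G5"),
            RouteRisk("intramuscular", 0.0145, source="combined complication risk", ctcae_band="G1-G2"),
        ]
    elif name == "severe-complication":
        p_base = back_calculate_baseline(SEVERE_P_INTRADISCAL, HEADLINE_RR)
        routes = [
            RouteRisk("intradiscal", SEVERE_P_INTRADISCAL,
                      source="pooled severe-complication rate", ctcae_band="G3-G5"),
            RouteRisk("intramuscular", p_base,
                      source="back-calculated from the 6.57:1 risk ratio", ctcae_band="G1-G2"),
        ]
    else:
        raise ValueError(f"unknown risk preset {name!r}; choose from {RISK_PRESET_NAMES}")
    return {"routes": routes, "baseline": "intramuscular", "n_procedures": 10_000}
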