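"""Reconstructed 6-month knee-osteoarthritis decision model: sustained
acoustic medicine (SAM) versus the standard-of-care (SOC) pathway of
sequential ACR-guideline therapies.

The published analysis reports strategy-level totals, headline parameter
values and break-even thresholds, but not the stage-level cost/probability
table behind them (its appendix is not publicly available). This fixture
therefore reconstructs the model from the printed anchors and makes every
non-printed quantity explicit:

* Printed anchors used directly: SAM device price $4,635 (entering the
  SAM arm at certainty); physical-therapy (PT) price $41.80 per 15-min
  session with 2-4 sessions per visit; strategy totals (cost, effect
  size) of ($8,641, 0.52) for SAM vs ($6,282, 0.39) for SOC, and
  ($13,967, 0.77) vs ($9,294, 0.47) for the later-stage pathway
  (SAM+PT vs topical-NSAID+PT).
* Reverse-engineered structural constants: the net PT-session
  differential between arms is fixed from the published break-evens
  themselves — the PT-price break-even of $88/session implies a slope of
  -2359/(88 - 41.80) = -51.06 net sessions (the SOC arm consumes more
  clinic PT than the SAM arm, which substitutes wearable home therapy),
  and the total-session break-even of 144 then pins the base session
  count at 41.8*144/(41.8 + 46.2) = 68.4 sessions (~22.8 visits over 6
  months at 3 sessions/visit, visit range 2-4).
* Placeholder success probabilities, stage therapy costs and stage
  effect sizes at plausible scales (marked "reconstructed" in the model
  file), plus one calibration residual per arm solved so that rollback
  reproduces the printed totals exactly. The residuals absorb every
  unmodelled cost (consumables, clinician visits, imaging) and are
  reported transparently.

Consequences: the base-case increments (delta cost $2,359, delta effect
0.13), both ICERs, and the device-price break-even of $2,276 follow from
printed numbers alone; the $88 and 144-session break-evens are
consistency checks of the reconstruction, not independent validations.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .model import Model, load_model_file, model_from_config
from .tree import CalibrationError, Role

__all__ = [
    "CalibrationTargets",
    "DEFAULT_TARGETS",
    "build_model",
    "calibrate",
    "load",
    "BUNDLED_MODELS",
    "knee_oa_config",
]

# Printed headline values -----------------------------------------------------

SAM_DEVICE_PRICE = 4635.0          # average reimbursement price, USD
PT_PRICE_PER_SESSION = 41.80       # USD per 15-min session
PT_SESSIONS_PER_VISIT = (2, 3, 4)  # (low, base, high) sessions per visit
PT_PRICE_BREAK_EVEN = 88.0         # USD/session at which SAM becomes cheaper
PT_SESSIONS_BREAK_EVEN = 144.0     # total sessions at which SAM becomes cheaper

# Reconstructed structural constants ------------------------------------------

#: Base-case cost difference implied by the printed totals, USD.
BASE_DELTA_COST = 8641.0 - 6282.0  # = 2359

#: Total 15-min PT sessions over 6 months given PT is initiated; pinned
#: by the two published break-evens: n = 41.8*144 / (41.8 + (88-41.8)).
PT_SESSIONS_BASE = (
    PT_PRICE_PER_SESSION * PT_SESSIONS_BREAK_EVEN
    / (PT_PRICE_PER_SESSION + (PT_PRICE_BREAK_EVEN - PT_PRICE_PER_SESSION))
)  # = 68.4

#: Net expected PT-course weight, SAM arm minus SOC arm (probability-
#: weighted fraction of the full session count consumed). Negative: the
#: SOC pathway relies on clinic PT, the SAM arm substitutes home therapy.
PT_WEIGHT_DIFFERENTIAL = -BASE_DELTA_COST / (
    (PT_PRICE_BREAK_EVEN - PT_PRICE_PER_SESSION) * PT_SESSIONS_BASE
)

# Placeholder clinical inputs (reconstructed, see module docstring) -----------

P_SAM_SUCCESS = 0.70      # pain relief sufficient to initiate PT, SAM arm
P_NSAID_SUCCESS = 0.55    # topical NSAID relieves pain enough for PT
P_STEROID_SUCCESS = 0.60  # corticosteroid injection success given NSAID failure
P_HA_SUCCESS = 0.55       # hyaluronic-acid injection success given both fail

#: Fraction of the full PT course delivered when PT starts after the
#: first / second / third SOC stage (later start, fewer sessions remain).
K_PT_EARLY, K_PT_MID, K_PT_LATE = 1.0, 0.8, 0.6

#: Expected PT-course weight of the SOC arm under the placeholders.
_W_SOC = (
    P_NSAID_SUCCESS * K_PT_EARLY
    + (1 - P_NSAID_SUCCESS) * P_STEROID_SUCCESS * K_PT_MID
    + (1 - P_NSAID_SUCCESS) * (1 - P_STEROID_SUCCESS) * P_HA_SUCCESS * K_PT_LATE
)

#: PT-course fraction in the SAM success branch, solved so the net
#: differential matches the published break-evens exactly.
K_PT_SAM = (_W_SOC + PT_WEIGHT_DIFFERENTIAL) / P_SAM_SUCCESS


@dataclass(frozen=True)
class CalibrationTargets:
    """Per-strategy expected (cost USD, effect size) the calibrated
    model must reproduce by rollback."""

    totals: Dict[str, Tuple[float, float]]


#: The published strategy totals over the 6-month horizon.
DEFAULT_TARGETS = CalibrationTargets(
    totals={
        "SAM": (8641.0, 0.52),
        "SOC": (6282.0, 0.39),
        "SAM_PT_later": (13967.0, 0.77),
        "NSAID_PT_later": (9294.0, 0.47),
    }
)


def _parameters() -> list:
    """Parameter table: printed values where available, reconstructed
    placeholders (noted) elsewhere; residuals start at 0 and are set by
    calibration."""
    recon = "reconstructed placeholder (appendix unavailable)"
    n_lo = PT_SESSIONS_BASE * PT_SESSIONS_PER_VISIT[0] / PT_SESSIONS_PER_VISIT[1]
    n_hi = PT_SESSIONS_BASE * PT_SESSIONS_PER_VISIT[2] / PT_SESSIONS_PER_VISIT[1]
    rows = [
        dict(name="sam_device_cost", base=SAM_DEVICE_PRICE, low=2000.0, high=6500.0,
             role="cost", note="published average reimbursement price; range is a fixture choice"),
        dict(name="pt_cost_per_session", base=PT_PRICE_PER_SESSION, low=20.0, high=100.0,
             role="cost", note="published price per 15-min session; range is a fixture choice"),
        dict(name="pt_sessions", base=PT_SESSIONS_BASE, low=n_lo, high=n_hi,
             role="count",
             note="total 15-min sessions over 6 months given PT initiated; "
                  "base pinned by the published break-evens, range follows "
                  "the published 2-4 sessions/visit"),
        dict(name="nsaid_cost", base=75.0, low=40.0, high=110.0, role="cost", note=recon),
        dict(name="steroid_cost", base=150.0, low=100.0, high=200.0, role="cost", note=recon),
        dict(name="ha_cost", base=1000.0, low=600.0, high=1400.0, role="cost", note=recon),
        dict(name="p_sam_success", base=P_SAM_SUCCESS, low=0.55, high=0.85,
             role="probability", note=recon),
        dict(name="p_nsaid_success", base=P_NSAID_SUCCESS, low=0.40, high=0.70,
             role="probability", note=recon),
        dict(name="p_steroid_success", base=P_STEROID_SUCCESS, low=0.45, high=0.75,
             role="probability", note=recon),
        dict(name="p_ha_success", base=P_HA_SUCCESS, low=0.40, high=0.70,
             role="probability", note=recon),
        dict(name="e_sam_success", base=0.60, low=0.45, high=0.75, role="effect", note=recon),
        dict(name="e_sam_fail", base=0.30, low=0.15, high=0.45, role="effect", note=recon),
        dict(name="e_pt_early", base=0.45, low=0.30, high=0.60, role="effect", note=recon),
        dict(name="e_pt_mid", base=0.40, low=0.25, high=0.55, role="effect", note=recon),
        dict(name="e_pt_late", base=0.35, low=0.20, high=0.50, role="effect", note=recon),
        dict(name="e_soc_none", base=0.10, low=0.0, high=0.20, role="effect", note=recon),
    ]
    for arm in ("sam", "soc", "sam_pt_later", "nsaid_pt_later"):
        rows.append(dict(
            name=f"{arm}_cost_residual", base=0.0, low=0.0, high=0.0, role="cost",
            note="calibration residual: unmodelled per-arm cost solved so "
                 "rollback matches the published total",
        ))
        rows.append(dict(
            name=f"{arm}_effect_residual", base=0.0, low=0.0, high=0.0, role="effect",
            note="calibration residual for the published effect total",
        ))
    return rows


def knee_oa_config() -> dict:
    """Uncalibrated model-definition mapping (residuals at 0)."""
    k_sam = repr(K_PT_SAM)
    pt = "pt_cost_per_session*pt_sessions"
    tree = {
        "kind": "decision",
        "label": "knee_oa_6mo",
        "children": [
            {"node": {
                "kind": "chance",
                "label": "SAM",
                "children": [
                    {"p": "p_sam_success",
                     "node": {"kind": "terminal", "label": "SAM_then_PT",
                              "cost": f"sam_device_cost + {k_sam}*{pt} + sam_cost_residual",
                              "effect": "e_sam_success + sam_effect_residual"}},
                    {"p": "1 - p_sam_success",
                     "node": {"kind": "terminal", "label": "SAM_no_PT",
                              "cost": "sam_device_cost + sam_cost_residual",
                              "effect": "e_sam_fail + sam_effect_residual"}},
                ],
            }},
            {"node": {
                "kind": "chance",
                "label": "SOC",
                "children": [
                    {"p": "p_nsaid_success",
                     "node": {"kind": "terminal", "label": "NSAID_then_PT",
                              "cost": f"nsaid_cost + {K_PT_EARLY}*{pt} + soc_cost_residual",
                              "effect": "e_pt_early + soc_effect_residual"}},
                    {"p": "1 - p_nsaid_success",
                     "node": {
                         "kind": "chance",
                         "label": "SOC_stage2",
                         "children": [
                             {"p": "p_steroid_success",
                              "node": {"kind": "terminal", "label": "steroid_then_PT",
                                       "cost": f"nsaid_cost + steroid_cost + {K_PT_MID}*{pt} + soc_cost_residual",
                                       "effect": "e_pt_mid + soc_effect_residual"}},
                             {"p": "1 - p_steroid_success",
                              "node": {
                                  "kind": "chance",
                                  "label": "SOC_stage3",
                                  "children": [
                                      {"p": "p_ha_success",
                                       "node": {"kind": "terminal", "label": "HA_then_PT",
                                                "cost": f"nsaid_cost + steroid_cost + ha_cost + {K_PT_LATE}*{pt} + soc_cost_residual",
                                                "effect": "e_pt_late + soc_effect_residual"}},
                                      {"p": "1 - p_ha_success",
                                       "node": {"kind": "terminal", "label": "SOC_no_relief",
                                                "cost": "nsaid_cost + steroid_cost + ha_cost + soc_cost_residual",
                                                "effect": "e_soc_none + soc_effect_residual"}},
                                  ],
                              }},
                         ],
                     }},
                ],
            }},
            {"node": {"kind": "terminal", "label": "SAM_PT_later",
                      "cost": f"sam_device_cost + {pt} + sam_pt_later_cost_residual",
                      "effect": "e_sam_success + sam_pt_later_effect_residual"}},
            {"node": {"kind": "terminal", "label": "NSAID_PT_later",
                      "cost": f"nsaid_cost + {pt} + nsaid_pt_later_cost_residual",
                      "effect": "e_pt_early + nsaid_pt_later_effect_residual"}},
        ],
    }
    return {
        "format_version": 1,
        "name": "knee_oa_2020",
        "description": (
            "Reconstructed 6-month knee-OA cost-effectiveness model: SAM vs "
            "SOC (initial pathway) and SAM+PT vs topical-NSAID+PT (later "
            "pathway). Stage-level probabilities/costs marked 'reconstructed' "
            "are fixture choices; per-arm residuals are calibrated so rollback "
            "reproduces the published strategy totals."
        ),
        "parameters": _parameters(),
        "tree": tree,
        "strategies": ["SAM", "SOC", "SAM_PT_later", "NSAID_PT_later"],
        "comparisons": [["SAM", "SOC"], ["SAM_PT_later", "NSAID_PT_later"]],
    }


_ARM_RESIDUAL = {
    "SAM": "sam",
    "SOC": "soc",
    "SAM_PT_later": "sam_pt_later",
    "NSAID_PT_later": "nsaid_pt_later",
}


def calibrate(model: Model,
              targets: CalibrationTargets = DEFAULT_TARGETS,
              ) -> Tuple[Model, Dict[str, float]]:
    """Solve the per-arm residual cost/effect constants so that rollback
    reproduces the target totals exactly.

    Each residual enters every terminal of its arm at coefficient 1, so
    the rolled-back total is the residual-free total plus the residual
    and the solution is a direct subtraction (rollback is affine in the
    residual). Returns the calibrated model and the residual mapping.
    Raises :class:`CalibrationError` if a target implies a negative arm
    cost residual.
    """
    residuals: Dict[str, float] = {}
    zeroed = {}
    for arm, stem in _ARM_RESIDUAL.items():
        if arm in targets.totals:
            zeroed[f"{stem}_cost_residual"] = 0.0
            zeroed[f"{stem}_effect_residual"] = 0.0
    pairs = model.evaluate(zeroed)
    for arm, (target_cost, target_effect) in targets.totals.items():
        stem = _ARM_RESIDUAL[arm]
        r_cost = target_cost - pairs[arm].cost
        r_effect = target_effect - pairs[arm].effect
        if r_cost < 0:
            raise CalibrationError(
                f"arm {arm!r}: target cost {target_cost} below the modelled "
                f"stage costs ({pairs[arm].cost:.2f}); negative residual"
            )
        residuals[f"{stem}_cost_residual"] = float(r_cost)
        residuals[f"{stem}_effect_residual"] = float(r_effect)

    config = copy.deepcopy(model.config)
    for row in config["parameters"]:
        if row["name"] in residuals:
            value = residuals[row["name"]]
            row["base"] = value
            row["low"] = value
            row["high"] = value
    return model_from_config(config), residuals


def build_model(config: Optional[dict] = None,
                targets: CalibrationTargets = DEFAULT_TARGETS) -> Model:
    """Build and calibrate the knee-OA model.

    ``config`` defaults to :func:`knee_oa_config`; overrides (e.g. a
    different device price) can be applied by editing the mapping before
    the call.
    """
    model = model_from_config(config or knee_oa_config())
    calibrated, _ = calibrate(model, targets)
    return calibrated


# ---------------------------------------------------------------------------
# Bundled model files
# ---------------------------------------------------------------------------

BUNDLED_MODELS = ("knee_oa_2020",)


def load(name: str = "knee_oa_2020") -> Model:
    """Load a bundled, pre-calibrated model file by name."""
    if name not in BUNDLED_MODELS:
        raise KeyError(f"no bundled model {name!r}; available: {BUNDLED_MODELS}")
    resource = importlib.resources.files("oacea.data").joinpath(f"{name}.yaml")
    with importlib.resources.as_file(resource) as path:
        return load_model_file(path)
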