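"""Shipped solution recipes and circuit presets.

Recipes transcribe the bench bath/pipette solutions; circuit presets
describe the two cell lines studied, with the injection battery and the
access resistance forming a calibrated pair: the preset stores the
battery (~ -0.3 mV) and the measured accumulated drop, and the access
resistance is derived at load time by inverting drop = E/R. The HEK-293
preset has no Na+ conductance (its step families show K+ activity only).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .analysis import calibrate_access_pair
from .circuit import (
    BranchGating,
    CircuitParameters,
    GatingParameters,
    NaGating,
    SwitchState,
)
from .ionics import SaltRecipe

_PKG_PRESETS = resources.files(__package__) / "presets"

RECIPE_NAMES = ("extracellular", "intracellular")
CIRCUIT_NAMES = ("shsy5y", "hek293")


@dataclass(frozen=True)
class CircuitPreset:
    """A named circuit plus the injection statistics it was calibrated from."""

    label: str
    params: CircuitParameters
    mean_drop_na: float
    event_sd_na: float


def _resolve(name_or_path: str | Path) -> Path:
    p = Path(name_or_path)
    if p.exists():
        return p
    candidate = _PKG_PRESETS / f"{name_or_path}.cfg"
    if candidate.is_file():
        return Path(str(candidate))
    raise FileNotFoundError(
        f"no preset named {name_or_path!r} (shipped: "
        f"{', '.join(RECIPE_NAMES + CIRCUIT_NAMES)}) and no such file"
    )


def load_recipe(name_or_path: str | Path) -> SaltRecipe:
    """Load a salt recipe by shipped name or file path."""
    return SaltRecipe.from_file(_resolve(name_or_path))


def load_circuit_preset(name_or_path: str | Path) -> CircuitPreset:
    """Load a circuit preset by shipped name or file path."""
    path = _resolve(name_or_path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "injection" not in raw:
        raise ValueError(f"{path}: not a circuit preset file")

    inj = raw["injection"]
    e_injection = float(inj["e_injection_mv"])
    mean_drop = float(inj["mean_drop_na"])
    event_sd = float(inj.get("event_sd_na", 0.0))
    r_access = calibrate_access_pair(mean_drop, e_injection)

    g = raw.get("gating", {})
    gk = g.get("k", {})
    gna = g.get("na", {})
    gating = GatingParameters(
        k=BranchGating(
            g_max_us=float(gk.get("g_max_us", 0.0)),
            v_half_mv=float(gk.get("v_half_mv", -20.0)),
            slope_mv=float(gk.get("slope_mv", 10.0)),
            tau_act_ms=float(gk.get("tau_act_ms", 5.0)),
        ),
        na=NaGating(
            g_max_us=float(gna.get("g_max_us", 0.0)),
            v_half_mv=float(gna.get("v_half_mv", -25.0)),
            slope_mv=float(gna.get("slope_mv", 6.0)),
            tau_act_ms=float(gna.get("tau_act_ms", 0.3)),
            h_v_half_mv=float(gna.get("h_v_half_mv", -60.0)),
            h_slope_mv=float(gna.get("h_slope_mv", -7.0)),
            tau_inact_ms=float(gna.get("tau_inact_ms", 3.0)),
        ),
        other_g_us=float(g.get("other_g_us", 0.0)),
    )
    params = CircuitParameters(
        r_seal_mohm=float(raw.get("r_seal_mohm", 1000.0)),
        r_access_mohm=r_access,
        c_m_pf=float(raw.get("c_m_pf", 30.0)),
        c_pipette_pf=float(raw.get("c_pipette_pf", 3.0)),
        r_opamp_mohm=float(raw.get("r_opamp_mohm", 0.0)),
        e_k_mv=float(raw.get("e_k_mv", -90.0)),
        e_na_mv=float(raw.get("e_na_mv", 60.0)),
        e_other_mv=float(raw.get("e_other_mv", 0.0)),
        e_injection_mv=e_injection,
        switches=SwitchState(),
        gating=gating,
        compensate_pipette=bool(raw.get("compensate_pipette", True)),
    )
    return CircuitPreset(
        label=str(raw.get("label", Path(path).stem)),
        params=params,
        mean_drop_na=mean_drop,
        event_sd_na=event_sd,
    )
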