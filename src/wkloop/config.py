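"""YAML run-configuration loading, validation and writing.

Configuration files use the literature's units so parameter values can be
copied from published tables verbatim (GPa·s·m⁻³, pm³·Pa⁻¹, mm, mN, kPa,
µL/s); everything is converted to SI exactly once, here.

Schema (all blocks optional unless noted)::

    geometry:                # required
      L0_mm, diameter_mm, r_ref_mm, wall_thickness_mm
    windkessel:              # required: either preset or the triplet
      preset | (Rp_GPa_s_per_m3, C_pm3_per_Pa, Zc_GPa_s_per_m3)
    cycle:
      stim_hz, refill_rate_uL_per_s, refill_trigger_fraction,
      end_diastolic_length_mm
    muscle:
      mode: replay | hill
      twitch_file | (twitch_peak_mN, twitch_rise_ms, twitch_fall_ms)
      temperature: body | room      # hill kinetics preset
    sim:
      mode, dt_us, duration_s, decimation, initial_Pp_kPa, afterload_mN
    interventions:
      - {time_s, path, value, defer_to_diastole}
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from . import units
from .exceptions import ConfigError
from .engine import Intervention, SimConfig, default_refill_rate
from .geometry import (
    DEFAULT_R_REF,
    DEFAULT_WALL_THICKNESS,
    TrabeculaGeometry,
    VentricleGeometry,
)
from .cycle import CyclePolicy
from .muscle import HillMuscleParams, TwitchTrace, synthesize_twitch
from .presets import get_preset
from .windkessel import WindkesselParams

__all__ = ["load_config", "build_config", "config_to_dict", "write_config"]

# intervention values are given in the unit natural to their path
_IV_SCALE = {
    "windkessel.Rp": units.GPA_S_PER_M3,
    "windkessel.C": units.PM3_PER_PA,
    "windkessel.Zc": units.GPA_S_PER_M3,
    "cycle.refill_rate": units.UL_PER_S,
    "cycle.refill_trigger_fraction": 1.0,
    "cycle.end_diastolic_length": units.MM,
}


def build_config(doc: dict) -> SimConfig:
    """Build a validated :class:`SimConfig` from a parsed configuration dict."""
    errs: list[str] = []

    def need(block: dict, key: str, default=None):
        if key in block:
            return block[key]
        if default is not None:
            return default
        errs.append(f"missing required key {key!r}")
        return None

    gblk = doc.get("geometry") or {}
    wblk = doc.get("windkessel") or {}
    cblk = doc.get("cycle") or {}
    mblk = doc.get("muscle") or {}
    sblk = doc.get("sim") or {}

    L0 = need(gblk, "L0_mm")
    diam = need(gblk, "diameter_mm")
    if errs:
        raise ConfigError("; ".join(f"geometry: {e}" for e in errs))
    try:
        geom = TrabeculaGeometry(L0=L0 * units.MM, diameter=diam * units.MM)
        vgeom = VentricleGeometry(
            r_ref=gblk.get("r_ref_mm", DEFAULT_R_REF / units.MM) * units.MM,
            h=gblk.get("wall_thickness_mm",
                       DEFAULT_WALL_THICKNESS / units.MM) * units.MM,
            L_ref=gblk.get("L_ref_mm", L0) * units.MM,
        )
    except ValueError as e:
        raise ConfigError(f"geometry: {e}") from e

    try:
        if "preset" in wblk:
            wk = get_preset(wblk["preset"])
        else:
            wk = WindkesselParams.from_literature_units(
                wblk["Rp_GPa_s_per_m3"], wblk["C_pm3_per_Pa"],
                wblk["Zc_GPa_s_per_m3"],
            )
    except KeyError as e:
        raise ConfigError(
            f"windkessel: give a preset or the full triplet (missing {e})"
        ) from e
    except ValueError as e:
        raise ConfigError(f"windkessel: {e}") from e

    stim_hz = cblk.get("stim_hz", 1.0)
    edl = cblk.get("end_diastolic_length_mm", L0) * units.MM
    rate = cblk.get("refill_rate_uL_per_s")
    if rate is None:
        rate_si = default_refill_rate(vgeom, stim_hz, edl)
    else:
        rate_si = rate * units.UL_PER_S
    try:
        cyc = CyclePolicy(
            stimulus_frequency=stim_hz, refill_rate=rate_si,
            end_diastolic_length=edl,
            refill_trigger_fraction=cblk.get("refill_trigger_fraction", 0.05),
        )
    except ValueError as e:
        raise ConfigError(f"cycle: {e}") from e

    muscle_mode = mblk.get("mode", "replay")
    twitch = None
    hill = None
    if muscle_mode == "replay":
        if "twitch_file" in mblk:
            twitch = TwitchTrace.load(mblk["twitch_file"],
                                      period=1.0 / stim_hz)
        else:
            twitch = synthesize_twitch(
                peak=mblk.get("twitch_peak_mN", 3.5) * units.MN,
                t_rise=mblk.get("twitch_rise_ms", 40.0) * 1e-3,
                t_fall=mblk.get("twitch_fall_ms", 120.0) * 1e-3,
                period=1.0 / stim_hz,
                dt=sblk.get("dt_us", 50.0) * units.US,
            )
    elif muscle_mode == "hill":
        temp = mblk.get("temperature", "body")
        if temp == "body":
            hill = HillMuscleParams.body_temperature()
        elif temp == "room":
            hill = HillMuscleParams.room_temperature()
        else:
            raise ConfigError(f"muscle: unknown temperature {temp!r}")
        overrides = {k: v for k, v in mblk.items()
                     if k not in ("mode", "temperature")}
        if overrides:
            try:
                hill = replace(hill, **overrides)
            except TypeError as e:
                raise ConfigError(f"muscle: {e}") from e

    ivs = []
    for iv in doc.get("interventions") or []:
        path = iv.get("path", "")
        value = iv.get("value")
        if path in _IV_SCALE and not isinstance(value, str):
            value = value * _IV_SCALE[path]
        ivs.append(Intervention(
            time=iv.get("time_s", 0.0), path=path, value=value,
            defer_to_diastole=iv.get("defer_to_diastole", True),
        ))

    afterload = sblk.get("afterload_mN")
    cfg = SimConfig(
        geometry=geom, ventricle=vgeom, windkessel=wk, cycle=cyc,
        mode=sblk.get("mode", "windkessel"), muscle_mode=muscle_mode,
        twitch=twitch, hill=hill,
        afterload=None if afterload is None else afterload * units.MN,
        dt=sblk.get("dt_us", 50.0) * units.US,
        duration=sblk.get("duration_s", 10.0),
        decimation=sblk.get("decimation", 10),
        initial_Pp=sblk.get("initial_Pp_kPa", 0.0) * units.KPA,
        interventions=tuple(ivs),
    )
    # keep the original muscle block so write_config round-trips replay
    # synthesis parameters that SimConfig itself does not retain
    cfg._muscle_doc = dict(mblk)
    return cfg


def load_config(path) -> SimConfig:
    """Parse and validate a YAML configuration file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return build_config(doc)


def config_to_dict(cfg: SimConfig) -> dict:
    """Serialise a :class:`SimConfig` back to the YAML schema (literature units)."""
    g, vg, wk, cyc = cfg.geometry, cfg.ventricle, cfg.windkessel, cfg.cycle
    doc = {
        "geometry": {
            "L0_mm": g.L0 / units.MM,
            "diameter_mm": g.diameter / units.MM,
            "r_ref_mm": vg.r_ref / units.MM,
            "wall_thickness_mm": vg.h / units.MM,
            "L_ref_mm": vg.L_ref / units.MM,
        },
        "windkessel": {
            "Rp_GPa_s_per_m3": wk.Rp / units.GPA_S_PER_M3,
            "C_pm3_per_Pa": wk.C / units.PM3_PER_PA,
            "Zc_GPa_s_per_m3": wk.Zc / units.GPA_S_PER_M3,
        },
        "cycle": {
            "stim_hz": cyc.stimulus_frequency,
            "refill_rate_uL_per_s": cyc.refill_rate / units.UL_PER_S,
            "refill_trigger_fraction": cyc.refill_trigger_fraction,
            "end_diastolic_length_mm": cyc.end_diastolic_length / units.MM,
        },
        "muscle": {**getattr(cfg, "_muscle_doc", {}), "mode": cfg.muscle_mode},
        "sim": {
            "mode": cfg.mode,
            "dt_us": cfg.dt / units.US,
            "duration_s": cfg.duration,
            "decimation": cfg.decimation,
            "initial_Pp_kPa": cfg.initial_Pp / units.KPA,
        },
    }
    if cfg.afterload is not None:
        doc["sim"]["afterload_mN"] = cfg.afterload / units.MN
    if cfg.muscle_mode == "hill" and cfg.hill is not None:
        h = cfg.hill
        doc["muscle"].update(
            sigma_max=h.sigma_max, fl_width=h.fl_width, v_max=h.v_max,
            a_curv=h.a_curv, passive_k=h.passive_k,
            passive_beta=h.passive_beta, slack_length=h.slack_length,
            act_rise=h.act_rise, act_fall=h.act_fall,
            fv_lengthening_cap=h.fv_lengthening_cap,
        )
    if cfg.interventions:
        doc["interventions"] = [
            {
                "time_s": iv.time, "path": iv.path,
                "value": (iv.value if isinstance(iv.value, str)
                          else iv.value / _IV_SCALE.get(iv.path, 1.0)),
                "defer_to_diastole": iv.defer_to_diastole,
            }
            for iv in cfg.interventions
        ]
    return doc


def write_config(cfg: SimConfig, path) -> None:
    """Write a configuration to YAML; round-trips through load_config."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
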