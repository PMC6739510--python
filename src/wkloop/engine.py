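"""Fixed-step coupled simulation of muscle, valve, Windkessel and refill.

The engine mirrors a real-time loading rig: a deterministic fixed-rate loop
(default 20 kHz, dt = 50 µs) in which, every step, (1) the force source
produces muscle force, (2) geometry converts it to ventricular pressure,
(3) the ideal valve decides whether flow crosses the characteristic
impedance, (4) the Windkessel state advances, (5) diastolic refill inflow
is added, and (6) the net chamber volume change is mapped back to muscle
length.  The muscle velocity fed back to the force source is the
previous-step velocity, breaking the algebraic loop exactly as a causal
hardware implementation does.

Within a step the driving pressure is taken as the average of the force
source evaluated at the step's two endpoints (at frozen length), and both
the compliance update and the volume update are trapezoidal, so the
per-step error is second order in dt wherever the dynamics are smooth.

Everything is deterministic: identical configurations give bit-identical
output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, SimulationError
from .geometry import (
    TrabeculaGeometry,
    VentricleGeometry,
    default_ventricle,
    length_to_volume,
)
from .cycle import CyclePolicy
from .muscle import (
    HillMuscleParams,
    IsotonicController,
    TwitchTrace,
    activation_waveform,
)
from .windkessel import WindkesselParams
from . import presets as _presets

__all__ = [
    "Intervention",
    "SimConfig",
    "BeatRecord",
    "run",
    "run_sweep",
    "apply_intervention",
    "default_refill_rate",
]

_COLUMNS = ("t", "F", "sigma", "L", "P", "Pa", "Pp", "Q", "V")

_INTERVENTION_PATHS = {
    "windkessel.Rp", "windkessel.C", "windkessel.Zc", "windkessel.preset",
    "cycle.refill_rate", "cycle.refill_trigger_fraction",
    "cycle.end_diastolic_length",
}


@dataclass(frozen=True)
class Intervention:
    """A mid-run parameter change.

    ``path`` is a dotted parameter path (e.g. ``"windkessel.Rp"`` with an SI
    value, or ``"windkessel.preset"`` with a preset name, which swaps all
    three Windkessel parameters atomically).  With ``defer_to_diastole``
    (the default) the change is held until the first diastolic relaxation
    at or after ``time``; otherwise it applies at the first step with
    ``t >= time``.
    """

    time: float
    path: str
    value: object
    defer_to_diastole: bool = True


def default_refill_rate(vgeom: VentricleGeometry, policy_frequency: float,
                        end_diastolic_length: float) -> float:
    """Refill rate (m³/s) that restores 40% of the end-diastolic volume in
    30% of the beat period — comfortably completing within diastole for
    every protocol studied."""
    V_ed = length_to_volume(end_diastolic_length, vgeom)
    return 0.4 * V_ed * policy_frequency / 0.3


@dataclass
class SimConfig:
    """Complete description of one virtual experiment.

    ``mode`` selects the loading protocol: ``"windkessel"`` (impedance
    load), ``"isotonic"`` (flat-topped afterload, requires the Hill muscle
    and ``afterload``), or ``"isometric"`` (length clamped; the Windkessel
    circuit still responds to pressure).  ``muscle_mode`` selects the force
    source: ``"replay"`` (prescribed twitch) or ``"hill"``.
    """

    geometry: TrabeculaGeometry
    windkessel: WindkesselParams
    cycle: CyclePolicy
    ventricle: VentricleGeometry | None = None
    mode: str = "windkessel"
    muscle_mode: str = "replay"
    twitch: TwitchTrace | None = None
    hill: HillMuscleParams | None = None
    afterload: float | None = None
    dt: float = 5e-5
    duration: float = 10.0
    decimation: int = 10
    initial_Pp: float = 0.0
    initial_length: float | None = None
    interventions: tuple = ()

    def __post_init__(self) -> None:
        if self.ventricle is None:
            self.ventricle = default_ventricle(self.geometry)
        if isinstance(self.interventions, list):
            self.interventions = tuple(self.interventions)
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing every violated invariant."""
        errs: list[str] = []
        if not self.dt > 0:
            errs.append(f"dt must be positive, got {self.dt}")
        period = 1.0 / self.cycle.stimulus_frequency
        if self.duration < period:
            errs.append(
                f"duration ({self.duration}) must cover at least one beat "
                f"period ({period})"
            )
        if self.mode not in ("windkessel", "isotonic", "isometric"):
            errs.append(f"unknown mode {self.mode!r}")
        if self.muscle_mode not in ("replay", "hill"):
            errs.append(f"unknown muscle_mode {self.muscle_mode!r}")
        if self.muscle_mode == "replay" and self.twitch is None:
            errs.append("replay muscle_mode requires a twitch trace")
        if self.muscle_mode == "hill" and self.hill is None:
            errs.append("hill muscle_mode requires HillMuscleParams")
        if self.mode == "isotonic":
            if self.muscle_mode != "hill":
                errs.append("isotonic mode requires the hill muscle")
            if self.afterload is None or not self.afterload > 0:
                errs.append("isotonic mode requires a positive afterload")
        if self.decimation < 1:
            errs.append("decimation must be >= 1")
        if self.initial_Pp < 0:
            errs.append("initial_Pp must be non-negative")
        for iv in self.interventions:
            if iv.path not in _INTERVENTION_PATHS:
                errs.append(
                    f"unknown intervention path {iv.path!r}; valid paths: "
                    f"{sorted(_INTERVENTION_PATHS)}"
                )
            if not 0.0 <= iv.time <= self.duration:
                errs.append(
                    f"intervention time {iv.time} outside run duration"
                )
        if errs:
            raise ConfigError("; ".join(errs))


@dataclass
class BeatRecord:
    """Uniformly sampled time series of one run.

    Arrays share a common length; spacing is ``dt × decimation``.  ``beat``
    is the integer beat index, ``valve_open`` and ``refilling`` flag the
    hybrid phase at each sample.  ``meta`` carries a config echo and any
    run flags (e.g. ``steady_state_reached`` for sweep records).
    """

    t: np.ndarray
    F: np.ndarray
    sigma: np.ndarray
    L: np.ndarray
    P: np.ndarray
    Pa: np.ndarray
    Pp: np.ndarray
    Q: np.ndarray
    V: np.ndarray
    valve_open: np.ndarray
    refilling: np.ndarray
    beat: np.ndarray
    dt: float
    meta: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return int(self.beat[-1]) + 1 if len(self.beat) else 0

    def beat_slice(self, j: int) -> "BeatRecord":
        """Sub-record containing only beat ``j``."""
        m = self.beat == j
        if not m.any():
            raise IndexError(f"no samples for beat {j}")
        return BeatRecord(
            **{c: getattr(self, c)[m] for c in _COLUMNS},
            valve_open=self.valve_open[m], refilling=self.refilling[m],
            beat=self.beat[m], dt=self.dt, meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {c: getattr(self, c) for c in _COLUMNS}
        cols["valve_open"] = self.valve_open.astype(int)
        cols["refilling"] = self.refilling.astype(int)
        cols["beat"] = self.beat
        return pd.DataFrame(cols)

    def save_csv(self, path) -> None:
        """Write the time series as CSV (SI units) plus a JSON sidecar."""
        df = self.to_dataframe()
        df.columns = [
            "t_s", "F_N", "sigma_Pa", "L_m", "P_Pa", "Pa_Pa", "Pp_Pa",
            "Q_m3_per_s", "V_m3", "valve_open", "refilling", "beat",
        ]
        df.to_csv(path, index=False)
        sidecar = str(path) + ".meta.json"
        with open(sidecar, "w") as fh:
            json.dump(self.meta, fh, indent=2, default=str)


def apply_intervention(windkessel: WindkesselParams, cycle: CyclePolicy,
                       intervention: Intervention):
    """Return ``(windkessel, cycle)`` with the intervention applied."""
    path, value = intervention.path, intervention.value
    if path == "windkessel.preset":
        return _presets.get_preset(str(value)), cycle
    if path.startswith("windkessel."):
        return replace(windkessel, **{path.split(".", 1)[1]: float(value)}), cycle
    if path.startswith("cycle."):
        return windkessel, replace(cycle, **{path.split(".", 1)[1]: float(value)})
    raise ConfigError(f"unknown intervention path {path!r}")


class _Engine:
    """Mutable integrator state; drives the fixed-step loop."""

    def __init__(self, config: SimConfig):
        self.cfg = config
        g = config.geometry
        vg = config.ventricle
        self.area = g.area
        self.vg = vg
        self.wk = config.windkessel
        self.cycle = config.cycle
        self.dt = config.dt
        per = 1.0 / config.cycle.stimulus_frequency
        self.period_steps = max(1, int(round(per / config.dt)))
        self.period = self.period_steps * config.dt

        # per-beat lookup tables for the prescribed inputs
        k = np.arange(self.period_steps + 1)  # +1: predictor needs t+dt
        tb = k * config.dt
        if config.muscle_mode == "replay":
            tr = config.twitch
            self.F_beat = np.interp(tb % tr.period, tr.t, tr.force,
                                    left=tr.force[0], right=tr.force[-1])
            self.act_beat = self.F_beat / max(tr.peak, 1e-300)
            self.peak_active_stress0 = tr.peak / self.area
        else:
            h = config.hill
            self.act_beat = np.array([
                activation_waveform(x, h, self.period) for x in tb
            ])
            self.F_beat = None
            self.peak_active_stress0 = h.sigma_max

        # dynamic state
        self.L = config.initial_length or config.cycle.end_diastolic_length
        self.V = length_to_volume(self.L, vg)
        self.Pp = config.initial_Pp
        self.valve_open = False
        self.v = 0.0            # shortening velocity (m/s, +ve shortening)
        self.Q = 0.0
        self.peak_active_prev = self.peak_active_stress0
        self.peak_active_cur = 0.0
        self.istep = 0
        self.ejected = 0.0      # cumulative ejected volume (m^3)
        self.refilled = 0.0     # cumulative refill inflow (m^3)
        self.initial_V = self.V

        self.pending = sorted(config.interventions, key=lambda iv: iv.time)
        self.controller = None
        if config.mode == "isotonic":
            self.controller = IsotonicController(
                afterload=config.afterload, params=config.hill, geom=g,
                end_diastolic_length=config.cycle.end_diastolic_length,
                period=self.period,
                refill_trigger_fraction=config.cycle.refill_trigger_fraction,
            )

    # -- hill muscle, inlined for the hot loop ------------------------------
    def _hill_sigma(self, L, v, act, active_only=False):
        h = self.cfg.hill
        g = self.cfg.geometry
        x = (L - g.L0) / (h.fl_width * g.L0)
        fl = 1.0 - x * x
        if fl < 0.0:
            fl = 0.0
        vn = v / g.L0
        if vn >= h.v_max:
            fv = 0.0
        elif vn >= 0.0:
            fv = (1.0 - vn / h.v_max) / (1.0 + vn / (h.a_curv * h.v_max))
        else:
            ramp = -vn / (0.1 * h.v_max)
            if ramp > 1.0:
                ramp = 1.0
            fv = 1.0 + (h.fv_lengthening_cap - 1.0) * ramp
        active = act * h.sigma_max * fl * fv
        if active_only:
            return active
        slack = h.slack_length * g.L0
        passive = 0.0
        if L > slack:
            passive = h.passive_k * (
                math.exp(h.passive_beta * (L - slack) / g.L0) - 1.0
            )
        return active + passive

    def _solve_ejection(self, L, act, Pp):
        """Self-consistent ejection state of the Hill muscle at one instant.

        During ejection the shortening velocity, muscle stress, ventricular
        pressure and aortic flow form an algebraic loop:
        ``v = c·(P − Pp)``, ``P = (2h/r)·σ``, ``σ = s_a·fv(v/L0) + s_p``.
        Updating ``v`` with a one-step lag makes that loop unstable at this
        loop gain (period-2 valve chatter), so it is solved exactly: on the
        Hill hyperbola the balance reduces to a quadratic in the normalised
        velocity with a unique non-negative root.

        Returns ``(v, sigma, active_sigma, P, Q)`` or ``None`` when no
        non-negative flow is consistent (the valve must close).
        """
        h = self.cfg.hill
        g = self.cfg.geometry
        vg = self.vg
        Zc = self.wk.Zc
        L0 = g.L0
        r = vg.r_ref / vg.L_ref * L
        # velocity per unit driving pressure, then per unit stress
        c = (vg.L_ref / vg.r_ref) / (4.0 * math.pi * r * r) / Zc
        alpha = c * 2.0 * vg.h / r
        beta = c * Pp
        x = (L - L0) / (h.fl_width * L0)
        fl = max(0.0, 1.0 - x * x)
        s_a = act * h.sigma_max * fl
        slack = h.slack_length * L0
        s_p = 0.0
        if L > slack:
            s_p = h.passive_k * (math.exp(h.passive_beta * (L - slack) / L0) - 1.0)
        f0 = alpha * (s_a + s_p) - beta  # velocity demanded at v = 0
        if f0 <= 0.0:
            return None
        vm, a = h.v_max, h.a_curv
        A = L0 / (a * vm)
        B = L0 + alpha * s_a / vm - (alpha * s_p - beta) / (a * vm)
        Cq = -f0
        disc = B * B - 4.0 * A * Cq
        u = (-B + math.sqrt(disc)) / (2.0 * A)
        if u >= vm:
            # force-velocity factor is zero: only passive stress drives flow
            u = max(vm, (alpha * s_p - beta) / L0)
            fv = 0.0
        else:
            u = max(0.0, u)
            fv = (1.0 - u / vm) / (1.0 + u / (a * vm))
        active = s_a * fv
        sigma = active + s_p
        P = 2.0 * sigma * vg.h / r
        Q = (P - Pp) / Zc
        if Q <= 0.0:
            return None
        return u * L0, sigma, active, P, Q

    def run_steps(self, n_steps: int, decimation: int):
        """Advance ``n_steps``; return decimated logs as a dict of arrays."""
        cfg = self.cfg
        dt = self.dt
        mode = cfg.mode
        replay = cfg.muscle_mode == "replay"
        vg = self.vg
        area = self.area
        r_scale = vg.r_ref / vg.L_ref
        two_h = 2.0 * vg.h
        fourpi = 4.0 * math.pi / 3.0
        inv_cbrt = 1.0 / 3.0
        Lref_over_rref = vg.L_ref / vg.r_ref

        n_log = (n_steps + decimation - 1) // decimation
        logs = {c: np.empty(n_log) for c in _COLUMNS}
        lv = np.empty(n_log, dtype=bool)
        lr = np.empty(n_log, dtype=bool)
        lb = np.empty(n_log, dtype=np.int64)
        jlog = 0

        Rp, C, Zc = self.wk.Rp, self.wk.C, self.wk.Zc
        tau = Rp * C
        decay = math.exp(-dt / tau)
        gtrap = dt / (2.0 * C) * (1.0 / Zc + 1.0 / Rp)
        trig = self.cycle.refill_trigger_fraction
        refill_rate = self.cycle.refill_rate
        taper_t = self.cycle.refill_taper_time
        EDL = self.cycle.end_diastolic_length
        V_ed = length_to_volume(EDL, vg)
        ctrl = self.controller

        L, V, Pp, v, valve = self.L, self.V, self.Pp, self.v, self.valve_open
        peak_prev, peak_cur = self.peak_active_prev, self.peak_active_cur
        ejected, refilled = self.ejected, self.refilled
        pending = self.pending
        F_beat, act_beat = self.F_beat, self.act_beat
        nper = self.period_steps

        for local_i in range(n_steps):
            i = self.istep + local_i
            t = i * dt
            k = i % nper
            if k == 0 and i > 0:
                peak_prev = max(peak_cur, 1e-12)
                peak_cur = 0.0
                if ctrl is not None:
                    ctrl.on_stimulus()

            # --- force source ------------------------------------------------
            if replay:
                F = F_beat[k]
                sigma = F / area
                active_sigma = sigma
                sigma_next = F_beat[k + 1] / area
            else:
                act = act_beat[k]
                if mode == "isotonic":
                    # controller handles force and length together below
                    sigma = None
                elif mode == "isometric":
                    sigma = self._hill_sigma(L, 0.0, act)
                    active_sigma = self._hill_sigma(L, 0.0, act,
                                                    active_only=True)
                    sigma_next = self._hill_sigma(L, 0.0, act_beat[k + 1])
                    F = sigma * area
                else:
                    # provisional closed-valve stress; during ejection the
                    # implicit solve below replaces it.  The refill trigger
                    # tracks the isometric (v = 0) relaxation envelope so the
                    # lengthening force-velocity cap cannot re-arm it.
                    sigma = self._hill_sigma(L, v, act)
                    active_sigma = self._hill_sigma(L, 0.0, act,
                                                    active_only=True)
                    sigma_next = sigma
                    F = sigma * area

            refilling = False

            if mode == "isotonic":
                L_new, v_new, F = ctrl.step(k * dt, L, dt)
                sigma = F / area
                # geometry-equivalent pressure/volume logged for completeness
                r = r_scale * L
                P = sigma * two_h / r
                V_new = fourpi * (r_scale * L_new) ** 3
                Pa = 0.0
                Pp_log = 0.0
                Q = 0.0
                refilling = ctrl.phase == ctrl.RELENGTHEN
                if peak_cur < sigma:
                    peak_cur = sigma
            else:
                if peak_cur < active_sigma:
                    peak_cur = active_sigma
                r = r_scale * L
                P = sigma * two_h / r
                P_next = sigma_next * two_h / r

                # --- pending interventions ---------------------------------
                if pending and t >= pending[0].time:
                    in_diastole = (not valve) and (
                        active_sigma < trig * peak_prev
                    )
                    while pending and t >= pending[0].time and (
                        in_diastole or not pending[0].defer_to_diastole
                    ):
                        self.wk, self.cycle = apply_intervention(
                            self.wk, self.cycle, pending.pop(0)
                        )
                        Rp, C, Zc = self.wk.Rp, self.wk.C, self.wk.Zc
                        tau = Rp * C
                        decay = math.exp(-dt / tau)
                        gtrap = dt / (2.0 * C) * (1.0 / Zc + 1.0 / Rp)
                        trig = self.cycle.refill_trigger_fraction
                        refill_rate = self.cycle.refill_rate
                        taper_t = self.cycle.refill_taper_time
                        EDL = self.cycle.end_diastolic_length
                        V_ed = length_to_volume(EDL, vg)

                # --- valve + windkessel ------------------------------------
                Pp_log = Pp
                if not valve and P > Pp:
                    valve = True
                dV = 0.0
                if valve and not replay and mode == "windkessel":
                    # Hill muscle: solve the velocity/flow balance implicitly
                    s1 = self._solve_ejection(L, act, Pp)
                    if s1 is None:
                        valve = False
                        Q = 0.0
                        Pa = Pp
                    else:
                        v_ej, sigma, _active, P, Q = s1
                        F = sigma * area
                        Pa = Pp + Q * Zc
                        # Heun pass: re-solve at the predicted end state
                        Pp_star = (Pp * (1.0 - gtrap) + dt * P / (C * Zc)) \
                            / (1.0 + gtrap)
                        s2 = self._solve_ejection(L - v_ej * dt,
                                                  act_beat[k + 1], Pp_star)
                        if s2 is None:
                            Pp_new = Pp_star
                            Q_end = 0.0
                        else:
                            Pbar = 0.5 * (P + s2[3])
                            Pp_new = (Pp * (1.0 - gtrap)
                                      + dt * Pbar / (C * Zc)) / (1.0 + gtrap)
                            Q_end = (s2[3] - Pp_new) / Zc
                            if Q_end < 0.0:
                                Q_end = 0.0
                        dV = -0.5 * dt * (Q + Q_end)
                        ejected -= dV
                        Pp = Pp_new
                elif valve:
                    Q = (P - Pp) / Zc
                    if Q <= 0.0:
                        valve = False
                        Q = 0.0
                        Pa = Pp
                    else:
                        Pa = Pp + Q * Zc
                        Pbar = 0.5 * (P + P_next)
                        Pp_new = (Pp * (1.0 - gtrap) + dt * Pbar / (C * Zc)) \
                            / (1.0 + gtrap)
                        Q_end = (P_next - Pp_new) / Zc
                        if Q_end < 0.0:
                            Q_end = 0.0
                        dV = -0.5 * dt * (Q + Q_end)
                        ejected -= dV
                        Pp = Pp_new
                if not valve:
                    Q = 0.0
                    Pa = Pp
                    Pp = Pp * decay
                    if active_sigma < trig * peak_prev and V + dV < V_ed:
                        deficit = V_ed - V - dV
                        rate = refill_rate
                        # taper near completion: continuous velocity; snap
                        # shut once the deficit is negligible so the refill
                        # phase terminates
                        if deficit <= 1e-7 * V_ed:
                            rate = 0.0
                            inflow = deficit
                        elif taper_t > 0.0 and deficit < rate * taper_t:
                            rate = deficit / taper_t
                        if rate > 0.0:
                            inflow = rate * dt
                        if inflow > deficit:
                            inflow = deficit
                        dV += inflow
                        refilled += inflow
                        refilling = inflow > 0.0

                # --- volume -> length --------------------------------------
                if mode == "isometric":
                    V_new = V
                    L_new = L
                    v_new = 0.0
                else:
                    V_new = V + dV
                    if not V_new > 0.0:
                        raise SimulationError(
                            f"chamber volume non-positive ({V_new:.3e} m^3) "
                            f"during volume update at t = {t:.6f} s"
                        )
                    L_new = Lref_over_rref * (V_new / fourpi) ** inv_cbrt
                    v_new = (L - L_new) / dt

            if L_new != L_new or not L_new > 0.0:
                raise SimulationError(
                    f"invalid muscle length {L_new!r} after length update "
                    f"at t = {t:.6f} s"
                )

            # --- log ---------------------------------------------------------
            if local_i % decimation == 0:
                logs["t"][jlog] = t
                logs["F"][jlog] = F
                logs["sigma"][jlog] = sigma
                logs["L"][jlog] = L
                logs["P"][jlog] = P
                logs["Pa"][jlog] = Pa
                logs["Pp"][jlog] = Pp_log
                logs["Q"][jlog] = Q
                logs["V"][jlog] = V
                lv[jlog] = valve
                lr[jlog] = refilling
                lb[jlog] = i // nper
                jlog += 1

            L, V, v = L_new, V_new, v_new

        self.L, self.V, self.Pp, self.v, self.valve_open = L, V, Pp, v, valve
        self.peak_active_prev, self.peak_active_cur = peak_prev, peak_cur
        self.ejected, self.refilled = ejected, refilled
        self.istep += n_steps
        logs = {c: a[:jlog] for c, a in logs.items()}
        logs["valve_open"] = lv[:jlog]
        logs["refilling"] = lr[:jlog]
        logs["beat"] = lb[:jlog]
        return logs


def _make_record(logs: dict, cfg: SimConfig, meta_extra: dict | None = None
                 ) -> BeatRecord:
    meta = {
        "mode": cfg.mode,
        "muscle_mode": cfg.muscle_mode,
        "dt": cfg.dt,
        "decimation": cfg.decimation,
        "windkessel": {"Rp": cfg.windkessel.Rp, "C": cfg.windkessel.C,
                       "Zc": cfg.windkessel.Zc},
        "stimulus_frequency": cfg.cycle.stimulus_frequency,
    }
    if meta_extra:
        meta.update(meta_extra)
    return BeatRecord(
        **{c: logs[c] for c in _COLUMNS},
        valve_open=logs["valve_open"], refilling=logs["refilling"],
        beat=logs["beat"], dt=cfg.dt * cfg.decimation, meta=meta,
    )


def run(config: SimConfig) -> BeatRecord:
    """Simulate the configured experiment and return its full time series."""
    config.validate()
    eng = _Engine(config)
    n_steps = int(round(config.duration / config.dt))
    logs = eng.run_steps(n_steps, config.decimation)
    return _make_record(logs, config, {
        "initial_V": eng.initial_V, "final_V": eng.V,
        "ejected_volume": eng.ejected, "refilled_volume": eng.refilled,
    })


def run_sweep(config: SimConfig, path: str, values, max_beats: int = 40,
              settle_tol: float = 5e-3, carry_state: bool = True):
    """Simulate to periodic steady state at each parameter value.

    For each value the parameter at ``path`` (an intervention path, e.g.
    ``"windkessel.Rp"``) is set, the model is run beat by beat until the
    beat-to-beat change of both peak stress and shortening extent falls
    below ``settle_tol`` (default 0.5%), and the final beat's record is
    collected.  With ``carry_state`` (default) the circuit state carries
    over from one value to the next, mirroring a sweep performed on a
    single preparation; each value then settles in a handful of beats.

    Returns a list of single-beat :class:`BeatRecord` objects whose meta
    carries ``sweep_value`` and ``steady_state_reached``.
    """
    if path not in _INTERVENTION_PATHS:
        raise ConfigError(f"unknown sweep parameter path {path!r}")
    records = []
    eng = None
    for value in values:
        wk, cyc = config.windkessel, config.cycle
        wk, cyc = apply_intervention(wk, cyc, Intervention(0.0, path, value))
        cfg_v = replace(config, windkessel=wk, cycle=cyc, interventions=())
        if eng is None or not carry_state:
            eng = _Engine(cfg_v)
        else:
            eng.wk, eng.cycle = wk, cyc
            eng = _retune(eng, cfg_v)
        rec = _run_until_steady(eng, cfg_v, max_beats, settle_tol)
        rec.meta["sweep_value"] = value
        rec.meta["sweep_path"] = path
        records.append(rec)
    return records


def _retune(eng: _Engine, cfg: SimConfig) -> _Engine:
    """Carry dynamic state into a fresh engine bound to new parameters."""
    new = _Engine(cfg)
    new.L, new.V, new.Pp = eng.L, eng.V, eng.Pp
    new.v, new.valve_open = eng.v, eng.valve_open
    new.peak_active_prev = eng.peak_active_prev
    new.peak_active_cur = eng.peak_active_cur
    return new


def _run_until_steady(eng: _Engine, cfg: SimConfig, max_beats: int,
                      settle_tol: float) -> BeatRecord:
    prev = None
    steady = False
    last_logs = None
    for _ in range(max_beats):
        logs = eng.run_steps(eng.period_steps, cfg.decimation)
        last_logs = logs
        peak = float(np.max(logs["sigma"]))
        dL = float(logs["L"][0] - np.min(logs["L"]))
        if prev is not None:
            p0, d0 = prev
            ok_p = abs(peak - p0) <= settle_tol * max(abs(p0), 1e-30)
            scale = max(abs(d0), 1e-9 * cfg.geometry.L0)
            ok_d = abs(dL - d0) <= settle_tol * scale
            if ok_p and ok_d:
                steady = True
                break
        prev = (peak, dL)
    rec = _make_record(last_logs, cfg,
                       {"steady_state_reached": steady})
    rec.beat = rec.beat - rec.beat[0]
    return rec
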