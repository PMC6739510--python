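"""Hybrid-event logic of the cardiac cycle.

Three pieces of per-beat bookkeeping live here: the ideal aortic valve
(opens when ventricular pressure exceeds aortic pressure, closes when flow
would reverse), the prescribed diastolic refill inflow that restores
end-diastolic length between beats, and the stimulus schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import SimulationError
from .geometry import VentricleGeometry, length_to_volume
from .windkessel import WindkesselParams, WindkesselState

__all__ = ["CyclePolicy", "update_valve", "refill_step", "stimulus_times"]


@dataclass(frozen=True)
class CyclePolicy:
    """Per-beat stimulus and refill policy.

    Parameters
    ----------
    stimulus_frequency : float
        Beat rate (Hz); beats start at t = k / frequency.
    refill_rate : float
        Prescribed diastolic volume inflow (m³/s).  There is no atrial or
        mitral model: refill is purely kinematic.
    refill_trigger_fraction : float
        Refill may start once active stress falls below this fraction of the
        previous beat's peak active stress ("during diastole").
    end_diastolic_length : float
        Target muscle length (m) at refill completion; inflow is clipped so
        the length never overshoots it.
    """

    stimulus_frequency: float
    refill_rate: float
    end_diastolic_length: float
    refill_trigger_fraction: float = 0.05
    #: inflow tapers to zero over this timescale (s) as the chamber nears its
    #: end-diastolic volume, so the commanded lengthening velocity is
    #: continuous (a step change is unrealisable by any finite-bandwidth
    #: motor and spoils step-size convergence at the completion instant)
    refill_taper_time: float = 0.005

    def __post_init__(self) -> None:
        if not self.stimulus_frequency > 0:
            raise ValueError("stimulus_frequency must be positive")
        if self.refill_rate < 0:
            raise ValueError("refill_rate must be non-negative")
        if not 0.0 <= self.refill_trigger_fraction <= 1.0:
            raise ValueError("refill_trigger_fraction must lie in [0, 1]")
        if not self.end_diastolic_length > 0:
            raise ValueError("end_diastolic_length must be positive")
        if self.refill_taper_time < 0:
            raise ValueError("refill_taper_time must be non-negative")

    @property
    def period(self) -> float:
        return 1.0 / self.stimulus_frequency


def update_valve(P: float, state: WindkesselState,
                 params: WindkesselParams) -> WindkesselState:
    """Ideal-diode valve transition logic.

    Closed → open when ventricular pressure strictly exceeds aortic pressure
    (ties keep the valve closed, avoiding zero-gradient chattering); open →
    closed the moment the algebraic flow ``(P − Pp)/Zc`` is no longer
    positive, snapping ``Q`` to zero.
    """
    if not state.valve_open:
        if P > state.Pa:
            Q = (P - state.Pp) / params.Zc
            return WindkesselState(Pp=state.Pp, Pa=state.Pp + Q * params.Zc,
                                   Q=Q, valve_open=True)
        return state
    Q = (P - state.Pp) / params.Zc
    if Q <= 0.0:
        return WindkesselState(Pp=state.Pp, Pa=state.Pp, Q=0.0,
                               valve_open=False)
    return WindkesselState(Pp=state.Pp, Pa=state.Pp + Q * params.Zc, Q=Q,
                           valve_open=True)


def refill_step(V: float, active_stress: float, peak_stress_prev_beat: float,
                policy: CyclePolicy, vgeom: VentricleGeometry,
                state: WindkesselState, dt: float) -> float:
    """Net diastolic inflow volume (m³) for one step.

    Inflow runs at ``policy.refill_rate`` while the muscle is relaxed
    (active stress below the trigger fraction of the previous beat's peak)
    and the chamber is below its end-diastolic volume; it is clipped so the
    end-diastolic length is met exactly, never overshot.  Calling this with
    the valve open is a logic error in the caller.
    """
    if state.valve_open:
        raise SimulationError("refill attempted while the aortic valve is open")
    if active_stress >= policy.refill_trigger_fraction * peak_stress_prev_beat:
        return 0.0
    V_ed = length_to_volume(policy.end_diastolic_length, vgeom)
    if V >= V_ed:
        return 0.0
    deficit = V_ed - V
    if deficit <= 1e-7 * V_ed:
        return deficit  # snap shut: complete the refill exactly
    rate = policy.refill_rate
    taper_vol = rate * policy.refill_taper_time
    if taper_vol > 0.0 and deficit < taper_vol:
        rate = deficit / policy.refill_taper_time
    return min(rate * dt, deficit)


def stimulus_times(policy: CyclePolicy, duration: float) -> np.ndarray:
    """Beat-onset times t_k = k / f for 0 ≤ t_k < duration."""
    if not duration > 0:
        raise ValueError("duration must be positive")
    n = int(np.floor(duration * policy.stimulus_frequency))
    # guard against floor(x) catching an exact multiple
    times = np.arange(n + 1) / policy.stimulus_frequency
    return times[times < duration]
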