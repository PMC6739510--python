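"""High-accuracy adaptive integration of the replay-mode hybrid system.

This is an independent formulation of the same physics the fixed-step
engine integrates: the valve phases are handled by event detection inside
:func:`scipy.integrate.solve_ivp` (tight tolerances, dense output) instead
of a 20 kHz causal loop, and the twitch forcing is evaluated in closed form
rather than from a sampled table.  It exists to cross-validate the engine;
it is far too slow to be the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .engine import SimConfig
from .geometry import length_to_volume

__all__ = ["ReferenceSolution", "simulate_replay_beat"]

_4PI_3 = 4.0 * math.pi / 3.0


@dataclass
class ReferenceSolution:
    """Dense reference trajectory sampled on a uniform grid."""

    t: np.ndarray
    Pp: np.ndarray
    V: np.ndarray
    L: np.ndarray
    Q: np.ndarray
    P: np.ndarray


def simulate_replay_beat(config: SimConfig, Pp0: float, V0: float,
                         peak_active_stress: float,
                         force_fn=None, rtol: float = 1e-10,
                         atol_P: float = 1e-6) -> ReferenceSolution:
    """Integrate one replay-mode beat from the given initial state.

    Parameters
    ----------
    config : SimConfig
        Replay-mode, windkessel-load configuration; supplies geometry,
        Windkessel parameters, cycle policy and the twitch trace.
    Pp0, V0 : float
        Peripheral pressure (Pa) and chamber volume (m³) at beat onset.
    peak_active_stress : float
        Previous-beat peak active stress (Pa) for the refill trigger; in
        replay mode this is the twitch peak over the muscle cross-section.
    force_fn : callable, optional
        Continuous force waveform F(t_in_beat) (N).  Defaults to linear
        interpolation of the configured twitch trace.
    """
    g = config.geometry
    vg = config.ventricle
    wk = config.windkessel
    cyc = config.cycle
    period = 1.0 / cyc.stimulus_frequency
    area = g.area
    Rp, C, Zc = wk.Rp, wk.C, wk.Zc
    h = vg.h
    scale_L = vg.L_ref / vg.r_ref
    V_ed = length_to_volume(cyc.end_diastolic_length, vg)
    trig_stress = cyc.refill_trigger_fraction * peak_active_stress
    refill_rate = cyc.refill_rate

    if force_fn is None:
        tr = config.twitch
        force_fn = lambda t: np.interp(t % tr.period, tr.t, tr.force,
                                       left=tr.force[0], right=tr.force[-1])

    def sigma(t):
        return force_fn(t) / area

    def pressure(t, V):
        r = (V / _4PI_3) ** (1.0 / 3.0)
        return 2.0 * sigma(t) * h / r

    def rhs(t, y, valve, refilling):
        Pp, V = y
        if valve:
            Q = (pressure(t, V) - Pp) / Zc
            return [(Q - Pp / Rp) / C, -Q]
        dV = refill_rate if refilling else 0.0
        return [-Pp / (Rp * C), dV]

    # events -----------------------------------------------------------------
    def ev_open(t, y, *a):          # valve opens: P - Pp crosses 0 upward
        return pressure(t, y[1]) - y[0] - 1e-9
    ev_open.terminal = True
    ev_open.direction = 1.0

    def ev_close(t, y, *a):         # valve closes: Q crosses 0 downward
        return (pressure(t, y[1]) - y[0]) / Zc
    ev_close.terminal = True
    ev_close.direction = -1.0

    def ev_relaxed(t, y, *a):       # active stress falls below the trigger
        return sigma(t) - trig_stress
    ev_relaxed.terminal = True
    ev_relaxed.direction = -1.0

    def ev_activated(t, y, *a):     # active stress rises above the trigger
        return sigma(t) - trig_stress
    ev_activated.terminal = True
    ev_activated.direction = 1.0

    def ev_full(t, y, *a):          # chamber reaches end-diastolic volume
        return y[1] - V_ed
    ev_full.terminal = True
    ev_full.direction = 1.0

    t_now = 0.0
    y = [Pp0, V0]
    valve = False
    relaxed = sigma(0.0) < trig_stress
    segments = []

    while t_now < period - 1e-12:
        refilling = (not valve) and relaxed and y[1] < V_ed - 1e-18
        if valve:
            events = [ev_close]
        else:
            events = [ev_open, ev_activated if relaxed else ev_relaxed]
            if refilling:
                events.append(ev_full)
        sol = solve_ivp(
            rhs, (t_now, period), y, args=(valve, refilling),
            events=events, dense_output=True, rtol=rtol,
            atol=[atol_P, 1e-18], max_step=(period - t_now) / 10,
            method="Radau",
        )
        segments.append((t_now, sol.t[-1], sol.sol, valve, refilling))
        y = [float(sol.y[0, -1]), float(sol.y[1, -1])]
        t_prev = t_now
        t_now = float(sol.t[-1])
        if sol.status == 1:  # an event fired; which one?
            fired = [k for k, te in enumerate(sol.t_events) if te.size]
            ev = events[fired[0]]
            if ev is ev_close:
                valve = False
            elif ev is ev_open:
                valve = True
            elif ev is ev_relaxed:
                relaxed = True
            elif ev is ev_activated:
                relaxed = False
            # ev_full: refilling simply stops (flag recomputed next segment)
        if t_now <= t_prev + 1e-15:
            t_now = t_prev + 1e-12  # safety against zero-length segments

    # sample on the engine grid ---------------------------------------------
    t_grid = np.arange(0.0, period, config.dt)
    Pp = np.empty_like(t_grid)
    V = np.empty_like(t_grid)
    Q = np.zeros_like(t_grid)
    P = np.empty_like(t_grid)
    for (t0, t1, interp, valve_seg, _r) in segments:
        m = (t_grid >= t0 - 1e-15) & (t_grid <= t1 + 1e-15)
        if not m.any():
            continue
        yy = interp(np.clip(t_grid[m], t0, t1))
        Pp[m] = yy[0]
        V[m] = yy[1]
        P[m] = [pressure(tt, vv) for tt, vv in zip(t_grid[m], yy[1])]
        if valve_seg:
            Q[m] = (P[m] - Pp[m]) / Zc
        else:
            Q[m] = 0.0
    L = scale_L * (V / _4PI_3) ** (1.0 / 3.0)
    return ReferenceSolution(t=t_grid, Pp=Pp, V=V, L=L, Q=Q, P=P)
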