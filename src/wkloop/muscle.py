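"""Force sources for the virtual work-loop rig.

Three loading protocols need three muscle surrogates:

* **Replay** — a prescribed twitch-force trace, invariant with shortening,
  emulating a recorded isometric twitch fed back through the loading system
  ("dry run" validation).  :class:`TwitchTrace`, :func:`synthesize_twitch`.
* **Hill fixture** — a minimal active-muscle model (activation waveform ×
  force–length parabola × force–velocity hyperbola + exponential passive
  stress).  It is deliberately memoryless: it supplies the load-dependent
  force feedback a living trabecula provides, without claiming to model its
  intrinsic restitution.  :class:`HillMuscleParams`, :func:`hill_stress`.
* **Isotonic ("flat-topped") controller** — the classical comparison
  protocol: isometric rise, shortening at constant afterload, isometric
  relaxation, re-lengthening.  :class:`IsotonicController`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import WkloopError
from .geometry import TrabeculaGeometry

__all__ = [
    "TwitchTrace",
    "twitch_force",
    "synthesize_twitch",
    "HillMuscleParams",
    "activation_waveform",
    "force_length",
    "force_velocity",
    "passive_stress",
    "hill_stress",
    "IsotonicController",
]


# ---------------------------------------------------------------------------
# replay mode
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwitchTrace:
    """One beat of sampled twitch force.

    ``t`` (s) and ``force`` (N) are equal-length arrays covering
    ``[0, period)``; the trace is extended periodically when queried outside
    that window.
    """

    t: np.ndarray
    force: np.ndarray
    period: float
    peak: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "force", f)
        if t.shape != f.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("t and force must be matching 1-D arrays (n >= 2)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not self.period > t[-1]:
            raise ValueError("period must exceed the last sample time")
        if np.any(f < 0):
            raise ValueError("twitch force must be non-negative")
        if f.max() > 0 and abs(f.max() - self.peak) > 1e-3 * self.peak:
            raise ValueError(
                f"sampled maximum {f.max():g} differs from stated peak "
                f"{self.peak:g} by more than 0.1%"
            )

    def save(self, path) -> None:
        """Write as two-column delimited text (header: time_s, force_N)."""
        np.savetxt(path, np.column_stack([self.t, self.force]),
                   header="time_s\tforce_N", delimiter="\t", comments="")

    @classmethod
    def load(cls, path, period: float | None = None) -> "TwitchTrace":
        """Read a two-column (time_s, force_N) text file."""
        data = np.loadtxt(path, skiprows=1)
        t, f = data[:, 0], data[:, 1]
        if period is None:
            period = t[-1] + (t[-1] - t[-2])
        return cls(t=t, force=f, period=period, peak=float(f.max()))


def twitch_force(t_in_beat: float, trace: TwitchTrace) -> float:
    """Linearly interpolated force at ``t_in_beat``; periodic outside the beat."""
    t = t_in_beat % trace.period
    return float(np.interp(t, trace.t, trace.force,
                           left=trace.force[0], right=trace.force[-1]))


def _double_exp(t, t_rise: float, t_fall: float):
    """Unnormalised rise–fall waveform and its continuous maximum."""
    if t_rise <= 0 or t_fall <= 0:
        raise ValueError("time constants must be positive")
    if math.isclose(t_rise, t_fall, rel_tol=1e-12):
        tau = t_fall
        w = t / tau * np.exp(1.0 - t / tau)   # peaks at exactly 1 when t = tau
        return w, 1.0, tau
    w = np.exp(-t / t_fall) - np.exp(-t / t_rise)
    t_peak = t_rise * t_fall / (t_fall - t_rise) * math.log(t_fall / t_rise)
    w_max = math.exp(-t_peak / t_fall) - math.exp(-t_peak / t_rise)
    return w, w_max, t_peak


def synthesize_twitch(peak: float, t_rise: float, t_fall: float,
                      period: float, dt: float = 5e-5) -> TwitchTrace:
    """Generate a double-exponential twitch scaled to the given peak force.

    The waveform ``exp(−t/t_fall) − exp(−t/t_rise)`` (limiting to
    ``t·exp(−t/τ)`` when the constants coincide) peaks at
    ``t* = t_rise·t_fall/(t_fall − t_rise)·ln(t_fall/t_rise)``.
    """
    if peak < 0:
        raise ValueError("peak must be non-negative")
    t = np.arange(0.0, period, dt)
    w, w_max, _ = _double_exp(t, t_rise, t_fall)
    w = np.clip(w, 0.0, None)
    force = peak * w / w_max if peak > 0 else np.zeros_like(t)
    return TwitchTrace(t=t, force=force, period=period,
                       peak=float(force.max()) if peak > 0 else 0.0)


# ---------------------------------------------------------------------------
# Hill fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillMuscleParams:
    """Parameters of the Hill-type muscle surrogate.

    Velocities are normalised to optimal lengths per second (L0/s);
    shortening velocity is positive.
    """

    sigma_max: float = 66e3        # peak isometric active stress at L0 (Pa)
    fl_width: float = 0.35         # force-length parabola half-width (/L0)
    v_max: float = 4.0             # unloaded shortening velocity (L0/s)
    a_curv: float = 0.25           # Hill hyperbola curvature a/F0
    passive_k: float = 150.0       # passive stress scale (Pa)
    passive_beta: float = 15.0     # passive exponential steepness
    slack_length: float = 0.85     # passive slack length (fraction of L0)
    act_rise: float = 0.03         # activation rise time constant (s)
    act_fall: float = 0.08         # activation decay time constant (s)
    fv_lengthening_cap: float = 1.1

    def __post_init__(self) -> None:
        for name in ("sigma_max", "fl_width", "v_max", "a_curv", "passive_k",
                     "passive_beta", "slack_length", "act_rise", "act_fall"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def body_temperature(cls) -> "HillMuscleParams":
        """Fast kinetics suited to 5 Hz pacing (37 °C-like)."""
        return cls(act_rise=0.012, act_fall=0.03, v_max=5.0)

    @classmethod
    def room_temperature(cls) -> "HillMuscleParams":
        """Slow kinetics suited to 1 Hz pacing (24 °C-like)."""
        return cls(act_rise=0.06, act_fall=0.18, v_max=1.5)


def activation_waveform(t_in_beat: float, params: HillMuscleParams,
                        period: float) -> float:
    """Normalised activation (0..1) at time within the beat; peaks at 1."""
    t = t_in_beat % period
    w, w_max, _ = _double_exp(np.asarray(t, dtype=float), params.act_rise,
                              params.act_fall)
    return float(max(0.0, w / w_max))


def force_length(L: float, params: HillMuscleParams,
                 geom: TrabeculaGeometry) -> float:
    """Parabolic active force–length factor; 1 at L0, 0 outside the width."""
    x = (L - geom.L0) / (params.fl_width * geom.L0)
    return max(0.0, 1.0 - x * x)


def force_velocity(v_norm: float, params: HillMuscleParams) -> float:
    """Hill force–velocity factor for normalised velocity (L0/s).

    Shortening (``v > 0``) follows the rectangular hyperbola
    ``(1 − v/v_max)/(1 + v/(a·v_max))`` clamped below at 0; lengthening
    (``v < 0``) ramps linearly to the cap (default 1.1) over 10% of
    ``v_max`` to prevent unphysical force spikes during re-stretch.
    """
    if v_norm >= 0.0:
        if v_norm >= params.v_max:
            return 0.0
        return (1.0 - v_norm / params.v_max) / (1.0 + v_norm / (params.a_curv * params.v_max))
    cap = params.fv_lengthening_cap
    ramp = min(1.0, -v_norm / (0.1 * params.v_max))
    return 1.0 + (cap - 1.0) * ramp


def passive_stress(L: float, params: HillMuscleParams,
                   geom: TrabeculaGeometry) -> float:
    """Exponential passive stress; zero at and below the slack length."""
    slack = params.slack_length * geom.L0
    if L <= slack:
        return 0.0
    return params.passive_k * (
        math.exp(params.passive_beta * (L - slack) / geom.L0) - 1.0
    )


def hill_stress(L: float, v: float, activation: float,
                params: HillMuscleParams, geom: TrabeculaGeometry) -> float:
    """Total muscle stress (Pa) at length ``L`` (m), shortening velocity
    ``v`` (m/s, positive shortening) and activation level 0..1."""
    if not L > 0:
        raise WkloopError(f"muscle length must be positive, got {L}")
    v_norm = v / geom.L0
    act = activation * params.sigma_max * force_length(L, params, geom) \
        * force_velocity(v_norm, params)
    return act + passive_stress(L, params, geom)


def hill_active_stress(L: float, v: float, activation: float,
                       params: HillMuscleParams,
                       geom: TrabeculaGeometry) -> float:
    """Active component only (used for the diastolic refill trigger)."""
    v_norm = v / geom.L0
    return activation * params.sigma_max * force_length(L, params, geom) \
        * force_velocity(v_norm, params)


# ---------------------------------------------------------------------------
# isotonic ("flat-topped") afterload controller
# ---------------------------------------------------------------------------

class IsotonicController:
    """Per-beat phase machine producing flat-topped work-loops.

    Phases: (1) isometric force development until the developed force
    reaches the afterload; (2) isotonic shortening with length servoed so
    force stays on the afterload (the force–velocity relation is inverted in
    closed form each step); (3) isometric relaxation at the shortest length
    once no non-negative shortening velocity can sustain the afterload;
    (4) constant-velocity re-lengthening back to the end-diastolic length
    once the muscle has relaxed below the refill trigger.

    If the afterload exceeds the peak isometric force the beat simply stays
    isometric; the condition is flagged on :attr:`afterload_unreachable`.
    """

    ISOMETRIC, SHORTEN, HOLD, RELENGTHEN = range(4)

    def __init__(self, afterload: float, params: HillMuscleParams,
                 geom: TrabeculaGeometry, end_diastolic_length: float,
                 period: float, refill_trigger_fraction: float = 0.05,
                 relengthen_fraction: float = 0.15):
        self.afterload = afterload
        self.params = params
        self.geom = geom
        self.EDL = end_diastolic_length
        self.period = period
        self.trigger = refill_trigger_fraction
        self.relengthen_time = relengthen_fraction * period
        self.phase = self.ISOMETRIC
        self.peak_active_prev = params.sigma_max  # conservative first-beat guess
        self._peak_active = 0.0
        self._v_re = 0.0
        F_max = (params.sigma_max * force_length(end_diastolic_length, params, geom)
                 + passive_stress(end_diastolic_length, params, geom)) * geom.area
        self.afterload_unreachable = afterload > F_max

    def on_stimulus(self) -> None:
        """Reset the phase machine at a beat onset."""
        self.peak_active_prev = max(self._peak_active, 1e-12)
        self._peak_active = 0.0
        self.phase = self.ISOMETRIC

    def _solve_velocity(self, L: float, activation: float) -> float:
        """Shortening velocity (m/s) at which total force equals the afterload.

        Inverts the Hill hyperbola: with x the required force–velocity
        factor, v = v_max (1 − x)/(1 + x/a).  Returns 0 when even v = 0
        cannot reach the afterload (x ≥ 1).
        """
        p, g = self.params, self.geom
        sig_pass = passive_stress(L, p, g)
        denom = activation * p.sigma_max * force_length(L, p, g)
        target = self.afterload / g.area - sig_pass
        if denom <= 0.0 or target >= denom:
            return 0.0
        if target <= 0.0:
            return p.v_max * g.L0  # afterload below passive: shorten flat out
        x = target / denom
        v_norm = p.v_max * (1.0 - x) / (1.0 + x / p.a_curv)
        return v_norm * g.L0

    def step(self, t_in_beat: float, L: float, dt: float):
        """Advance one step; returns (new length m, velocity m/s, force N).

        Velocity is positive during shortening, negative during
        re-lengthening.
        """
        p, g = self.params, self.geom
        act = activation_waveform(t_in_beat, p, self.period)
        active_iso = hill_active_stress(L, 0.0, act, p, g)
        self._peak_active = max(self._peak_active, active_iso)
        F_iso = (active_iso + passive_stress(L, p, g)) * g.area

        if self.phase == self.ISOMETRIC:
            if F_iso >= self.afterload:
                self.phase = self.SHORTEN
            else:
                return L, 0.0, F_iso

        if self.phase == self.SHORTEN:
            if F_iso < self.afterload:
                self.phase = self.HOLD
            else:
                v = self._solve_velocity(L, act)
                if v <= 0.0:
                    self.phase = self.HOLD
                else:
                    return L - v * dt, v, self.afterload

        if self.phase == self.HOLD:
            if active_iso < self.trigger * self.peak_active_prev and L < self.EDL:
                self.phase = self.RELENGTHEN
                self._v_re = (self.EDL - L) / self.relengthen_time
            else:
                return L, 0.0, F_iso

        # RELENGTHEN
        L_new = min(self.EDL, L + self._v_re * dt)
        v = -(L_new - L) / dt
        F = hill_stress(L_new, v, act, p, g) * g.area
        if L_new >= self.EDL:
            # wait isometrically at EDL until the next stimulus resets phases
            self.phase = self.HOLD
        return L_new, v, F
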