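"""Three-element Windkessel arterial impedance.

The arterial load is the classic lumped circuit: a characteristic aortic
impedance ``Zc`` in series with the parallel combination of peripheral
resistance ``Rp`` and arterial compliance ``C``.  The aortic valve is an
ideal diode: when closed, no flow crosses ``Zc`` and aortic pressure equals
peripheral pressure, which decays exponentially with time constant
``Rp·C``; when open, flow ``Q = (P − Pp)/Zc`` charges the compliance.

Two numerically distinct formulations are provided and cross-checked:

* a state-space update (:func:`step_closed` exact exponential,
  :func:`step_open` trapezoidal) used by the simulation engine, and
* a discrete transfer function (:func:`discretize_admittance`, bilinear /
  Tustin transform of the input admittance ``Y(s) = 1/Z(s)``) mirroring a
  fixed-rate real-time implementation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import InvalidStepError, WkloopError
from . import units

__all__ = [
    "WindkesselParams",
    "WindkesselState",
    "DiscreteAdmittance",
    "input_impedance",
    "input_admittance",
    "time_constant",
    "step_closed",
    "step_open",
    "discretize_admittance",
]


@dataclass(frozen=True)
class WindkesselParams:
    """The impedance triplet, strict SI.

    Parameters
    ----------
    Rp : float
        Peripheral resistance (Pa·s·m⁻³); dominant determinant of the
        work-loop magnitude.
    C : float
        Arterial compliance (m³·Pa⁻¹); with ``Rp`` sets the diastolic decay
        time constant ``Rp·C``.
    Zc : float
        Characteristic aortic impedance (Pa·s·m⁻³); series opposition to
        pulsatile flow during ejection.
    """

    Rp: float
    C: float
    Zc: float

    def __post_init__(self) -> None:
        for name in ("Rp", "C", "Zc"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.Zc >= self.Rp:
            warnings.warn(
                f"Zc ({self.Zc:g}) >= Rp ({self.Rp:g}): characteristic "
                "impedance normally lies well below peripheral resistance",
                stacklevel=2,
            )

    @classmethod
    def from_literature_units(cls, Rp_GPa: float, C_pm3: float, Zc_GPa: float
                         ) -> "WindkesselParams":
        """Build from literature units (GPa·s·m⁻³, pm³·Pa⁻¹, GPa·s·m⁻³)."""
        return cls(
            Rp=Rp_GPa * units.GPA_S_PER_M3,
            C=C_pm3 * units.PM3_PER_PA,
            Zc=Zc_GPa * units.GPA_S_PER_M3,
        )

    @property
    def tau(self) -> float:
        """Diastolic decay time constant Rp·C (s)."""
        return self.Rp * self.C


@dataclass(frozen=True)
class WindkesselState:
    """Instantaneous circuit state.

    ``valve_open = False`` implies ``Q = 0`` and ``Pa = Pp``;
    ``valve_open = True`` implies ``Pa = Pp + Q·Zc`` with ``Q ≥ 0``.
    """

    Pp: float
    Pa: float
    Q: float
    valve_open: bool

    @classmethod
    def closed(cls, Pp: float) -> "WindkesselState":
        """Diastolic state at peripheral pressure ``Pp``."""
        return cls(Pp=Pp, Pa=Pp, Q=0.0, valve_open=False)


def input_impedance(params: WindkesselParams, s: complex) -> complex:
    """Input impedance Z(s) = Zc + Rp / (1 + s·Rp·C) of the 3-element circuit.

    At ``s = 0`` this is ``Rp + Zc`` (DC: capacitor open); as ``|s| → ∞`` it
    tends to ``Zc`` (capacitor short).
    """
    return params.Zc + params.Rp / (1.0 + s * params.Rp * params.C)


def input_admittance(params: WindkesselParams, s: complex) -> complex:
    """Y(s) = 1 / Z(s); the pressure→flow transfer function."""
    return 1.0 / input_impedance(params, s)


def time_constant(params: WindkesselParams) -> float:
    """The RC decay constant Rp·C (s) governing diastolic pressure decay."""
    return params.Rp * params.C


def step_closed(state: WindkesselState, params: WindkesselParams, dt: float,
                method: str = "exact") -> WindkesselState:
    """Advance a closed-valve (diastolic) state by ``dt``.

    The compliance discharges through ``Rp`` alone, so
    ``Pp(t+dt) = Pp(t)·exp(−dt/(Rp·C))`` exactly.  ``method="trapezoidal"``
    uses the implicit-midpoint update instead (provided for cross-checks
    against the open-valve integrator).
    """
    if not dt > 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    tau = params.Rp * params.C
    if method == "exact":
        Pp = state.Pp * math.exp(-dt / tau)
    elif method == "trapezoidal":
        a = dt / (2.0 * tau)
        Pp = state.Pp * (1.0 - a) / (1.0 + a)
    else:
        raise ValueError(f"unknown method {method!r}")
    return WindkesselState(Pp=Pp, Pa=Pp, Q=0.0, valve_open=False)


def step_open(state: WindkesselState, P: float, params: WindkesselParams,
              dt: float) -> WindkesselState:
    """Advance an open-valve (ejecting) state by ``dt`` under ventricular
    pressure ``P`` held constant over the step.

    Flow is algebraic, ``Q = (P − Pp)/Zc``; the compliance obeys
    ``C·dPp/dt = Q − Pp/Rp``, integrated by the trapezoidal (implicit
    midpoint) rule, which is A-stable and matches the circuit's DC gain.
    """
    if not dt > 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    if params.Zc == 0:
        raise WkloopError(
            "Zc = 0 (2-element mode) is not supported by the open-valve "
            "stepper; use a small positive Zc instead"
        )
    Rp, C, Zc = params.Rp, params.C, params.Zc
    # dPp/dt = (P - Pp)/(Zc C) - Pp/(Rp C) = P/(Zc C) - Pp/(tau*)
    g = dt / (2.0 * C) * (1.0 / Zc + 1.0 / Rp)
    Pp = (state.Pp * (1.0 - g) + dt * P / (C * Zc)) / (1.0 + g)
    Q = (P - Pp) / Zc
    return WindkesselState(Pp=Pp, Pa=Pp + Q * Zc, Q=Q, valve_open=True)


@dataclass(frozen=True)
class DiscreteAdmittance:
    """z-domain transfer function from pressure samples to flow samples.

    Obtained by the bilinear (Tustin) transform of
    ``Y(s) = (1 + s·Rp·C) / ((Rp + Zc) + s·Rp·C·Zc)`` at sample interval
    ``dt``.  The denominator is normalised to a leading coefficient of 1 and
    its pole lies strictly inside the unit circle for all valid parameters.
    """

    b: tuple
    a: tuple
    dt: float

    def filter(self, P: np.ndarray, zi: np.ndarray | None = None):
        """Apply the filter to a pressure sequence, returning flow samples.

        ``zi`` is the optional initial filter delay state as accepted by
        :func:`scipy.signal.lfilter`.
        """
        if zi is None:
            return signal.lfilter(self.b, self.a, np.asarray(P, dtype=float))
        return signal.lfilter(self.b, self.a, np.asarray(P, dtype=float), zi=zi)

    @property
    def dc_gain(self) -> float:
        """Gain at z = 1; equals 1/(Rp + Zc) by construction."""
        return float(np.sum(self.b) / np.sum(self.a))

    def poles(self) -> np.ndarray:
        return np.roots(self.a)


def discretize_admittance(params: WindkesselParams, dt: float = 5e-5
                          ) -> DiscreteAdmittance:
    """Tustin discretisation of the input admittance at interval ``dt``.

    The returned filter, applied to a ventricular-pressure sequence sampled
    every ``dt`` seconds, yields the aortic-flow sequence of the circuit
    with the valve held open.
    """
    if not dt > 0:
        raise InvalidStepError(f"dt must be positive, got {dt}")
    Rp, C, Zc = params.Rp, params.C, params.Zc
    num = [Rp * C, 1.0]
    den = [Rp * C * Zc, Rp + Zc]
    b, a = signal.bilinear(num, den, fs=1.0 / dt)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    b, a = b / a[0], a / a[0]
    return DiscreteAdmittance(b=tuple(b), a=tuple(a), dt=dt)
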