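"""Per-beat work-loop and pressure–volume metrics.

Work per beat is the enclosed area of the force–length trajectory
(−∮F dL > 0 for an ejecting beat); the stress–length area and the
pressure–volume stroke work are reported alongside it to keep both of the
field's unit conventions available.  End-systole is defined as the instant
of aortic-valve closure.  The diastolic decay constant is recovered by a
log-linear fit of aortic pressure over the closed-valve, refill-excluded
window and should equal Rp·C.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .engine import BeatRecord

__all__ = [
    "LoopMetrics",
    "loop_area",
    "beat_metrics",
    "fit_diastolic_decay",
    "work_afterload_table",
    "fit_origin_constrained_poly",
]


@dataclass(frozen=True)
class LoopMetrics:
    """Derived quantities for one beat (SI units)."""

    work: float                  # |∮F dL| (J)
    stress_length_area: float    # |∮σ dL| (Pa·m)
    stroke_work: float           # |∮P dV| (J)
    peak_stress: float           # max σ over the beat (Pa)
    end_systolic_stress: float   # σ at valve closure (Pa)
    end_systolic_length: float   # L at valve closure (m)
    shortening_extent: float     # (L_ED − L_min)/L0, dimensionless
    stroke_volume: float         # ∫Q dt over the beat (m³)
    fitted_tau: float            # diastolic decay constant (s); inf if flat
    ejecting: bool               # False for a beat with no valve opening

    def to_dict(self) -> dict:
        return asdict(self)


def loop_area(x, y) -> float:
    """Signed area enclosed by the closed path of ``(x, y)`` samples.

    Shoelace formula; the last point is joined back to the first.  Sign
    follows traversal orientation (counterclockwise positive).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("loop area needs >= 3 paired samples")
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def fit_diastolic_decay(t, Pa) -> float:
    """Least-squares exponential decay constant of an aortic-pressure segment.

    Fits ``log(Pa)`` against ``t``; returns ``−1/slope`` (s).  A constant
    signal has zero slope and is reported as ``inf``.  Requires strictly
    positive samples.
    """
    t = np.asarray(t, dtype=float)
    Pa = np.asarray(Pa, dtype=float)
    if t.size < 10:
        raise ValueError("decay fit needs at least 10 samples")
    if np.any(Pa <= 0):
        raise ValueError("decay fit requires strictly positive pressures")
    logP = np.log(Pa)
    if np.ptp(logP) < 1e-12:
        return math.inf  # flat signal: no measurable decay
    slope, _ = np.polyfit(t - t[0], logP, 1)
    span = (t[-1] - t[0])
    if slope == 0.0:
        return math.inf
    tau = -1.0 / slope
    if tau > 0 and span < 0.2 * tau:
        warnings.warn(
            f"decay segment spans only {span:.3g} s < 0.2·tau ({tau:.3g} s); "
            "fit is best-effort", stacklevel=2,
        )
    return tau


def _decay_window(rec: BeatRecord):
    """Closed-valve, refill-excluded, relaxed-tail window of one beat."""
    closed = ~rec.valve_open & ~rec.refilling
    # use the trailing contiguous closed run (after ejection and refill)
    idx = np.flatnonzero(~closed)
    start = idx[-1] + 1 if idx.size else 0
    return slice(start, len(rec.t))


def beat_metrics(record: BeatRecord, beat: int | None = None) -> LoopMetrics:
    """Compute :class:`LoopMetrics` for one beat of a record.

    ``record`` must contain the full beat including refill; pass ``beat``
    to select one beat of a multi-beat record.
    """
    rec = record if beat is None else record.beat_slice(beat)
    L0 = rec.L[0]  # beat starts at end-diastolic length by construction
    isotonic = rec.meta.get("mode") == "isotonic"
    if isotonic:
        # no valve: end-systole is the end of the shortening phase
        i_min = int(np.argmin(rec.L))
        ejecting = rec.L[i_min] < L0 * (1.0 - 1e-9)
    else:
        open_idx = np.flatnonzero(rec.valve_open)
        ejecting = open_idx.size > 0

    work = abs(loop_area(rec.L, rec.F))
    sla = abs(loop_area(rec.L, rec.sigma))
    sw = abs(loop_area(rec.V, rec.P))
    peak = float(np.max(rec.sigma))

    if ejecting:
        i_es = i_min if isotonic else open_idx[-1]  # valve closure
        es_stress = float(rec.sigma[i_es])
        es_length = float(rec.L[i_es])
        shortening = float((L0 - np.min(rec.L)) / L0)
        if isotonic:
            sv = float(rec.V[0] - np.min(rec.V))
        else:
            sv = float(np.trapezoid(rec.Q, rec.t))
    else:
        es_stress = peak
        es_length = float(L0)
        shortening = 0.0
        sv = 0.0
        work = 0.0
        sla = 0.0
        sw = 0.0

    win = _decay_window(rec)
    tau = math.nan
    if len(rec.t[win]) >= 10 and np.all(rec.Pa[win] > 0):
        tau = fit_diastolic_decay(rec.t[win], rec.Pa[win])
    return LoopMetrics(
        work=work, stress_length_area=sla, stroke_work=sw, peak_stress=peak,
        end_systolic_stress=es_stress, end_systolic_length=es_length,
        shortening_extent=shortening, stroke_volume=sv, fitted_tau=tau,
        ejecting=bool(ejecting),
    )


def fit_origin_constrained_poly(x, y, degree: int = 2) -> np.ndarray:
    """Least-squares polynomial through the origin.

    Returns coefficients ``c[0..degree-1]`` of ``y = Σ c_k x^(k+1)`` (no
    constant term), so the fit evaluates to exactly 0 at 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    A = np.column_stack([x ** (k + 1) for k in range(degree)])
    coeffs, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coeffs


def evaluate_origin_poly(coeffs: np.ndarray, x) -> np.ndarray:
    """Evaluate a polynomial produced by :func:`fit_origin_constrained_poly`."""
    x = np.asarray(x, dtype=float)
    return sum(c * x ** (k + 1) for k, c in enumerate(coeffs))


def work_afterload_table(entries) -> pd.DataFrame:
    """Relate end-systolic stress to work per beat across loading modes.

    ``entries`` is an iterable of ``(label, LoopMetrics)`` pairs, where the
    label names the loading mode (e.g. ``"windkessel"`` / ``"isotonic"``).
    Returns a DataFrame sorted by mode and end-systolic stress, with a
    degree-2 origin-constrained polynomial fitted per mode (coefficients in
    the ``fit_c1``/``fit_c2`` columns, shared within a mode) whenever the
    mode has at least two entries.
    """
    rows = []
    for label, m in entries:
        rows.append({"mode": label, "end_systolic_stress": m.end_systolic_stress,
                     "work": m.work, "stress_length_area": m.stress_length_area,
                     "shortening_extent": m.shortening_extent,
                     "peak_stress": m.peak_stress,
                     "stroke_volume": m.stroke_volume})
    df = pd.DataFrame(rows).sort_values(["mode", "end_systolic_stress"])
    df["fit_c1"] = np.nan
    df["fit_c2"] = np.nan
    for mode, grp in df.groupby("mode"):
        if len(grp) >= 2:
            c = fit_origin_constrained_poly(grp["end_systolic_stress"],
                                            grp["work"], degree=2)
            df.loc[grp.index, "fit_c1"] = c[0]
            df.loc[grp.index, "fit_c2"] = c[1]
    return df.reset_index(drop=True)
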