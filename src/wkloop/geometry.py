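"""Mapping between 1-D muscle mechanics and equivalent ventricular variables.

A thin strand of ventricular muscle (a trabecula) produces force ``F`` at
length ``L``; the loading system treats it as the wall of a thin-walled
elastic spherical chamber.  Force maps to wall stress through the muscle
cross-section, wall stress maps to chamber pressure through Laplace's law
``P = 2 σ h / r``, and muscle length maps linearly to chamber radius, which
gives the cubic length–volume relation ``V(L) ∝ L³``.

All quantities are SI.  The inverse maps are exact, so round-tripping any
of the conversions is lossless to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidGeometryError, InvalidStateError

__all__ = [
    "TrabeculaGeometry",
    "VentricleGeometry",
    "default_ventricle",
    "DEFAULT_R_REF",
    "DEFAULT_WALL_THICKNESS",
    "force_to_stress",
    "stress_to_pressure",
    "length_to_radius",
    "radius_to_length",
    "radius_to_volume",
    "volume_to_radius",
    "length_to_volume",
    "volume_to_length",
    "flow_to_length_rate",
]

_4PI_3 = 4.0 * math.pi / 3.0

#: Default chamber radius (m) at the reference length.  Chosen so that the
#: chamber holds enough volume (~0.52 mL) to charge a rat-scale arterial
#: compliance through a full pulse pressure without emptying; see the methods
#: note for the sizing argument.
DEFAULT_R_REF = 5.0e-3

#: Default wall thickness (m).  Together with ``DEFAULT_R_REF`` this places
#: peak ventricular pressure near 4.5 kPa for a 66 kPa peak wall stress,
#: which keeps replay-mode ejection self-limiting across the studied
#: peripheral-resistance range.
DEFAULT_WALL_THICKNESS = 0.15e-3


@dataclass(frozen=True)
class TrabeculaGeometry:
    """Dimensions of the muscle preparation.

    Parameters
    ----------
    L0 : float
        Optimal muscle length (m): the length at which developed force is
        maximal, determined experimentally.
    diameter : float
        Muscle diameter (m), assumed circular cross-section.
    """

    L0: float
    diameter: float

    def __post_init__(self) -> None:
        if not self.L0 > 0:
            raise InvalidGeometryError(f"L0 must be positive, got {self.L0}")
        if not self.diameter > 0:
            raise InvalidGeometryError(
                f"diameter must be positive, got {self.diameter}"
            )

    @property
    def area(self) -> float:
        """Cross-sectional area π d²/4 (m²)."""
        return math.pi * self.diameter**2 / 4.0


@dataclass(frozen=True)
class VentricleGeometry:
    """Thin-walled sphere standing in for the left ventricle.

    Parameters
    ----------
    r_ref : float
        Chamber radius (m) when the muscle sits at ``L_ref``.
    h : float
        Wall thickness (m), held constant (wall thinning during ejection is
        ignored).  Must satisfy ``0 < h < r_ref`` (thin-wall regime).
    L_ref : float
        Muscle length (m) mapped onto ``r_ref``; conventionally the optimal
        length L0.
    """

    r_ref: float
    h: float
    L_ref: float

    def __post_init__(self) -> None:
        if not self.r_ref > 0:
            raise InvalidGeometryError(f"r_ref must be positive, got {self.r_ref}")
        if not 0 < self.h < self.r_ref:
            raise InvalidGeometryError(
                f"wall thickness must satisfy 0 < h < r_ref, got h={self.h}, "
                f"r_ref={self.r_ref}"
            )
        if not self.L_ref > 0:
            raise InvalidGeometryError(f"L_ref must be positive, got {self.L_ref}")


def default_ventricle(geom: TrabeculaGeometry) -> VentricleGeometry:
    """Ventricle geometry with package defaults, referenced to the muscle's L0."""
    return VentricleGeometry(
        r_ref=DEFAULT_R_REF, h=DEFAULT_WALL_THICKNESS, L_ref=geom.L0
    )


def force_to_stress(F: float, geom: TrabeculaGeometry) -> float:
    """Convert muscle force (N) to wall stress σ = F / (π d²/4) (Pa).

    Negative forces are permitted (passive push during re-stretch) and simply
    yield negative stress.
    """
    return F / geom.area


def stress_to_pressure(sigma: float, vgeom: VentricleGeometry, r: float) -> float:
    """Laplace's law for a thin-walled sphere: P = 2 σ h / r (Pa)."""
    if not r > 0:
        raise InvalidStateError(f"chamber radius must be positive, got {r}")
    return 2.0 * sigma * vgeom.h / r


def length_to_radius(L: float, vgeom: VentricleGeometry) -> float:
    """Linear length→radius map r = r_ref · L / L_ref.

    Linearity through the origin is the unique map consistent with a cubic
    length–volume relation for a sphere.
    """
    if not L > 0:
        raise InvalidStateError(f"muscle length must be positive, got {L}")
    return vgeom.r_ref * L / vgeom.L_ref


def radius_to_length(r: float, vgeom: VentricleGeometry) -> float:
    """Inverse of :func:`length_to_radius`."""
    if not r > 0:
        raise InvalidStateError(f"chamber radius must be positive, got {r}")
    return vgeom.L_ref * r / vgeom.r_ref


def radius_to_volume(r: float) -> float:
    """Sphere volume V = (4/3) π r³ (m³)."""
    if r < 0:
        raise InvalidStateError(f"chamber radius must be non-negative, got {r}")
    return _4PI_3 * r**3


def volume_to_radius(V: float) -> float:
    """Real cube root inverse of :func:`radius_to_volume`."""
    if V < 0:
        raise InvalidStateError(f"chamber volume must be non-negative, got {V}")
    return (V / _4PI_3) ** (1.0 / 3.0)


def length_to_volume(L: float, vgeom: VentricleGeometry) -> float:
    """Composite map V(L) = (4/3) π (r_ref L / L_ref)³."""
    return radius_to_volume(length_to_radius(L, vgeom))


def volume_to_length(V: float, vgeom: VentricleGeometry) -> float:
    """Inverse of :func:`length_to_volume`."""
    return radius_to_length(volume_to_radius(V), vgeom)


def flow_to_length_rate(Q_net: float, L: float, vgeom: VentricleGeometry) -> float:
    """Convert net chamber inflow (m³/s) to muscle lengthening rate (m/s).

    ``Q_net = refill inflow − ejected flow``; ejection (negative ``Q_net``)
    shortens the muscle.  From V = (4/3)π r(L)³ and r = r_ref L / L_ref:

        dL/dt = (L_ref / r_ref) · Q_net / (4 π r(L)²)
    """
    r = length_to_radius(L, vgeom)
    if r == 0.0:
        raise InvalidStateError("chamber radius is zero; length rate undefined")
    return (vgeom.L_ref / vgeom.r_ref) * Q_net / (4.0 * math.pi * r**2)
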