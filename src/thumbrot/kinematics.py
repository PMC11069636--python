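"""Cone model of thumb abduction.

Thumb abduction is modelled as rotation of the thumb IP joint on a cone
around the second metacarpal (the *base axis*).  The IP joint position is
described by rotational displacement coordinates ``(r, theta)``: ``r`` is the
distance from the base axis (fixed at 3 cm by the measurement device) and
``theta`` the rotation angle measured from the palmar plane, which defines
0 deg.  In the hand frame used throughout this package the first axis is the
palmar-plane normal, the second axis runs along the second metacarpal, and
the third axis lies in the palmar plane perpendicular to the base axis, so
the IP joint sits at ``(r sin(theta), B, r cos(theta))`` where ``B`` is the
distance from the frame origin to the reference joint along the base axis.

The same ``(r, theta)`` pair decomposes into the two clinical abduction
angles: *radial abduction* (motion within the palm plane away from the index
ray) and *palmar abduction* (motion away from the palm plane).  Both are
computed here as planar projections of the IP position.

Angles are degrees at every public boundary; trigonometry is done in
radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import DomainError

__all__ = [
    "ConeCoordinate",
    "SkeletonConfig",
    "AbductionAngles",
    "ip_position",
    "to_abduction",
    "from_abduction",
]


@dataclass(frozen=True)
class ConeCoordinate:
    """Rotational displacement coordinates (r, theta) of the thumb IP joint.

    Parameters
    ----------
    r : float
        Distance from the base axis, cm.  The study device fixes this at
        3 cm.  Must be positive.
    theta_deg : float
        Rotation angle from the palmar plane, degrees, in [0, 180).  The
        study protocol uses [0, 90].
    """

    r: float
    theta_deg: float

    def __post_init__(self) -> None:
        if not (self.r > 0.0 and math.isfinite(self.r)):
            raise DomainError(f"r must be positive and finite, got {self.r!r}")
        if not (0.0 <= self.theta_deg < 180.0):
            raise DomainError(
                f"theta must lie in [0, 180) degrees, got {self.theta_deg!r}"
            )

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta_deg)


@dataclass(frozen=True)
class SkeletonConfig:
    """Fixed skeletal dimensions of the cone model.

    Parameters
    ----------
    B : float
        Distance from the rotation-centre joint (frame origin) to the
        reference joint along the second metacarpal, cm.  The source
        measurements never state it numerically; the default is an
        anthropometrically plausible 6 cm.
    A : float
        Thumb-ray length from the CM joint to the thumb IP joint, cm.
        Unused by the conversion formulas but needed by the simulator's
        thumb-ray construction; must be at least the cone radius.
    r_default : float
        Default cone radius, cm; 3.0 matches the measurement device.
    origin_joint : str
        Which joint the hand frame is anchored at.  The measurement
        definition uses the second MP joint as rotation centre; the polar
        expression (r sin, B, r cos) is also natural with a CM-joint origin.
        Informational only — the formulas are identical either way.
    """

    B: float = 6.0
    A: float = 7.0
    r_default: float = 3.0
    origin_joint: str = "second_mp"

    def __post_init__(self) -> None:
        if not (self.B > 0.0 and math.isfinite(self.B)):
            raise DomainError(f"B must be positive and finite, got {self.B!r}")
        if not (self.A >= self.r_default > 0.0):
            raise DomainError(
                "need A >= r_default > 0 (the thumb ray must reach the cone "
                f"radius); got A={self.A!r}, r_default={self.r_default!r}"
            )


@dataclass(frozen=True)
class AbductionAngles:
    """Clinical decomposition of thumb abduction, degrees.

    ``radial_deg`` is the angle of the IP position projected onto the palmar
    plane, measured from the base axis; ``palmar_deg`` the angle of the
    projection onto the plane normal to the palm that contains the base
    axis.  Both lie in [0, 90).
    """

    radial_deg: float
    palmar_deg: float

    def __post_init__(self) -> None:
        for name in ("radial_deg", "palmar_deg"):
            v = getattr(self, name)
            if not (0.0 <= v < 90.0):
                raise DomainError(f"{name} must lie in [0, 90) degrees, got {v!r}")


def ip_position(cone: ConeCoordinate, skel: SkeletonConfig) -> tuple[float, float, float]:
    """3D position of the thumb IP joint in the hand frame, cm.

    Returns ``(r sin(theta), B, r cos(theta))``: the first component is the
    displacement out of the palmar plane, the second the offset along the
    base axis, the third the in-palm displacement perpendicular to the base
    axis.  At theta = 0 the point lies in the palmar plane; at theta = 90 deg
    it is lifted a full radius out of it.
    """
    t = cone.theta_rad
    return (cone.r * math.sin(t), skel.B, cone.r * math.cos(t))


def to_abduction(cone: ConeCoordinate, skel: SkeletonConfig) -> AbductionAngles:
    """Convert rotational displacement coordinates to abduction angles.

    Projections of the IP point ``(r sin t, B, r cos t)``:

    * radial abduction — onto the palmar plane: ``atan2(r cos t, B)``;
    * palmar abduction — onto the plane normal to the palm containing the
      base axis: ``atan2(r sin t, B)``.

    The two formulas swap under ``theta -> 90 - theta``.
    """
    x, y, z = ip_position(cone, skel)
    # z is the in-palm offset, x the out-of-palm offset; both non-negative
    # for theta in [0, 90], giving angles in [0, 90).
    return AbductionAngles(
        radial_deg=math.degrees(math.atan2(z, y)),
        palmar_deg=math.degrees(math.atan2(x, y)),
    )


def from_abduction(ab: AbductionAngles, skel: SkeletonConfig) -> ConeCoordinate:
    """Recover the unique ``(r, theta)`` with r > 0, theta in [0, 90] that
    maps to the given abduction pair under :func:`to_abduction`.

    Inverting the projection formulas gives ``r cos t = B tan(radial)`` and
    ``r sin t = B tan(palmar)``, hence ``theta = atan2(tan(palmar),
    tan(radial))`` and ``r = B hypot(tan(radial), tan(palmar))``.

    Raises
    ------
    DomainError
        If both abduction angles are zero: that is only consistent with the
        degenerate radius r = 0, which the cone model excludes.
    """
    tr = math.tan(math.radians(ab.radial_deg))
    tp = math.tan(math.radians(ab.palmar_deg))
    if tr == 0.0 and tp == 0.0:
        raise DomainError(
            "radial and palmar abduction both zero: consistent only with "
            "the degenerate radius r = 0"
        )
    r = skel.B * math.hypot(tr, tp)
    theta = math.degrees(math.atan2(tp, tr))
    return ConeCoordinate(r=r, theta_deg=theta)
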