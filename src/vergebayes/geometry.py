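"""Deterministic binocular viewing geometry.

Vergence is the horizontal angular difference between the orientations of the
two eyes.  For fixation on the median plane the geometry reduces to a
right-angled triangle with base ``h`` (half the interocular separation), so the
half-vergence angle is ``theta_F = atan(h / D_F)`` and inverting it recovers
the fixation distance ``D_F = h / tan(theta_F)``.  The same triangle algebra
yields the half retinal disparity of a probe placed in front of fixation, the
depth recovered by disparity scaling, and the "scaling distance" implied by a
depth judgement.

Conventions: all angles are in radians and all lengths in centimetres.
Degrees appear only at command-line and file boundaries.  Inputs outside the
geometric domain raise :class:`ValueError` rather than being clipped, so that
stochastic callers have to handle truncation explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ViewingGeometry",
    "FixationPoint",
    "DepthProbe",
    "EyeAngles",
    "DEFAULT_GEOMETRY",
    "eye_angles_general",
    "half_vergence_from_distance",
    "distance_from_half_vergence",
    "half_disparity",
    "depth_from_disparity",
    "scaling_distance",
]


@dataclass(frozen=True)
class ViewingGeometry:
    """Interocular separation of the observer, in centimetres.

    The default of 6.5 cm is the conventional adult average used throughout
    the simulations.
    """

    interocular: float = 6.5

    def __post_init__(self) -> None:
        if not self.interocular > 0:
            raise ValueError(f"interocular must be > 0, got {self.interocular}")

    @property
    def half_interocular(self) -> float:
        """Half the interocular separation, ``h`` (cm)."""
        return self.interocular / 2.0


DEFAULT_GEOMETRY = ViewingGeometry()


@dataclass(frozen=True)
class FixationPoint:
    """A fixated point: median-plane distance ``D_F`` and lateral offset ``B``."""

    distance_median: float
    lateral_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.distance_median > 0:
            raise ValueError(
                f"distance_median must be > 0, got {self.distance_median}"
            )


@dataclass(frozen=True)
class DepthProbe:
    """A probe at depth ``d`` in front of a fixation at distance ``D_F``.

    The probe sits on the median plane at ``D_P = D_F - d``, strictly between
    the observer and the fixation point.
    """

    fixation_distance: float
    depth_offset: float

    def __post_init__(self) -> None:
        if not self.fixation_distance > 0:
            raise ValueError(
                f"fixation_distance must be > 0, got {self.fixation_distance}"
            )
        if not 0 < self.depth_offset < self.fixation_distance:
            raise ValueError(
                "depth_offset must satisfy 0 < d < fixation_distance, got "
                f"d={self.depth_offset}, D_F={self.fixation_distance}"
            )


class EyeAngles(NamedTuple):
    theta_left: float
    theta_right: float
    vergence: float


def eye_angles_general(geom: ViewingGeometry, fix: FixationPoint) -> EyeAngles:
    """Left/right eye rotation angles and their sum for an arbitrary fixation.

    ``theta_L = atan((h + B) / D_F)``, ``theta_R = atan((h - B) / D_F)`` and
    the full vergence angle is ``theta_V = theta_L + theta_R``.  For ``B = 0``
    the two eye angles are equal and ``theta_V = 2 * theta_F``.
    """
    h = geom.half_interocular
    theta_l = float(np.arctan2(h + fix.lateral_offset, fix.distance_median))
    theta_r = float(np.arctan2(h - fix.lateral_offset, fix.distance_median))
    return EyeAngles(theta_l, theta_r, theta_l + theta_r)


def half_vergence_from_distance(geom: ViewingGeometry, distance):
    """Half-vergence angle ``theta_F = atan(h / D_F)`` (radians).

    Strictly decreasing in distance, with range (0, pi/2).  Accepts scalars
    or arrays; non-positive distances raise :class:`ValueError`.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be strictly positive")
    out = np.arctan(geom.half_interocular / d)
    return out if out.ndim else float(out)


def distance_from_half_vergence(geom: ViewingGeometry, angle):
    """Fixation distance ``D_F = h / tan(theta_F)`` (cm).

    Exact inverse of :func:`half_vergence_from_distance` on (0, pi/2).
    """
    a = np.asarray(angle, dtype=float)
    if np.any((a <= 0) | (a >= np.pi / 2)):
        raise ValueError("angle must lie in the open interval (0, pi/2)")
    out = geom.half_interocular / np.tan(a)
    return out if out.ndim else float(out)


def half_disparity(geom: ViewingGeometry, probe: DepthProbe) -> float:
    """Half retinal disparity ``eta`` of a probe in front of fixation (radians).

    ``eta = atan(d h / (-d D_F + D_F^2 + h^2))``, equal to the difference of
    the probe's and the fixation point's half-vergence angles.
    """
    h = geom.half_interocular
    d = probe.depth_offset
    df = probe.fixation_distance
    denom = -d * df + df * df + h * h
    if denom <= 0:
        raise ValueError("geometrically impossible probe: disparity denominator <= 0")
    return float(np.arctan(d * h / denom))


def depth_from_disparity(geom: ViewingGeometry, fixation_distance, disparity):
    """Depth recovered by disparity scaling (cm).

    ``d = ((D_F^2 + h^2) tan(eta)) / (h + D_F tan(eta))``; the inverse of
    :func:`half_disparity` for geometrically valid inputs.
    """
    df = np.asarray(fixation_distance, dtype=float)
    eta = np.asarray(disparity, dtype=float)
    if np.any(df <= 0):
        raise ValueError("fixation_distance must be strictly positive")
    if np.any(eta < 0):
        raise ValueError("disparity must be non-negative")
    h = geom.half_interocular
    t = np.tan(eta)
    out = (df * df + h * h) * t / (h + df * t)
    return out if out.ndim else float(out)


def scaling_distance(geom: ViewingGeometry, perceived_depth, disparity):
    """Fixation distance implied by a depth judgement ("scaling distance", cm).

    ``D_F = (d + sqrt(d^2 - 4 h^2 + 4 d h cot(eta))) / 2``.  If the depth
    estimate equals the true depth this recovers the true fixation distance.
    A negative radicand means no geometrically consistent distance exists and
    raises :class:`ValueError`.
    """
    d = np.asarray(perceived_depth, dtype=float)
    eta = np.asarray(disparity, dtype=float)
    if np.any(d <= 0):
        raise ValueError("perceived_depth must be strictly positive")
    if np.any(eta <= 0):
        raise ValueError("disparity must be strictly positive")
    h = geom.half_interocular
    radicand = d * d - 4 * h * h + 4 * d * h / np.tan(eta)
    if np.any(radicand < 0):
        raise ValueError(
            "no geometrically consistent scaling distance (negative radicand)"
        )
    out = 0.5 * (d + np.sqrt(radicand))
    return out if out.ndim else float(out)
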