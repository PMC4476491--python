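"""Stain ellipse geometry: impact angles and backward launch directions.

An elliptical bloodstain on a vertical wall encodes the direction its parent
droplet was travelling when it hit.  The ratio of the ellipse width to its
length gives the impact angle via ``sin(alpha) = W_max / L_max``, and the
directional angle ``gamma`` (measured in the wall plane against the vertical)
fixes the in-plane component of travel.  Together they determine the full 3D
impact-velocity direction, whose reversal is the launch ray used for backward
trajectory reconstruction.

Units at this interface follow forensic reporting practice: stain positions in
cm, ellipse dimensions in mm, angles in degrees.  Everything downstream of
:func:`stain_to_room_coords` / :func:`backward_direction` is SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WallFrame",
    "Stain",
    "ImpactGeometry",
    "InvalidEllipseError",
    "impact_angle_from_ellipse",
    "backward_direction",
    "stain_to_room_coords",
]


class InvalidEllipseError(ValueError):
    """Raised when W_max > L_max, i.e. the ellipse is mismeasured."""


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"{name} must be a non-zero vector")
    return v / n


@dataclass(frozen=True)
class WallFrame:
    """Right-handed coordinate frame attached to a planar vertical wall.

    Parameters
    ----------
    point_cm : array-like, shape (3,)
        A point on the wall plane, in room coordinates (cm).
    normal : array-like, shape (3,)
        Inward wall normal (pointing into the room).  Normalized on
        construction.
    up : array-like, shape (3,)
        Vertical unit vector lying in the wall plane.  Must be orthogonal
        to ``normal``.

    The lateral axis ``s = up x normal`` completes the right-handed frame;
    wall coordinates ``(x, y)`` map to ``point + x*s + y*up``.
    """

    point_cm: np.ndarray
    normal: np.ndarray
    up: np.ndarray
    s: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "point_cm", np.asarray(self.point_cm, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal, "normal"))
        object.__setattr__(self, "up", _unit(self.up, "up"))
        if abs(float(np.dot(self.normal, self.up))) > 1e-9:
            raise ValueError("wall normal and up vector must be orthogonal")
        # only vertical target surfaces are supported
        if abs(abs(self.up[2]) - 1.0) > 1e-9:
            raise ValueError("wall must be vertical: 'up' must point along +/-z")
        object.__setattr__(self, "s", np.cross(self.up, self.normal))


@dataclass
class Stain:
    """One measured bloodstain: the atomic input record.

    ``wall_xy`` (cm, in the wall frame) or ``room_xyz`` (cm, room frame) must
    be present.  ``width_mm``/``length_mm`` are the fitted ellipse axes,
    ``gamma_deg`` the directional angle in [0, 360), ``v_dry_ul`` the dried
    stain volume and ``v0_ul`` an optional fresh-volume override.
    """

    id: str
    width_mm: float
    length_mm: float
    gamma_deg: float
    wall_xy: tuple[float, float] | None = None
    room_xyz: tuple[float, float, float] | None = None
    v_dry_ul: float | None = None
    v0_ul: float | None = None
    selected: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.width_mm):
            raise ValueError(f"stain {self.id}: width must be positive")
        if self.width_mm > self.length_mm:
            raise InvalidEllipseError(
                f"stain {self.id}: width {self.width_mm} mm exceeds length "
                f"{self.length_mm} mm"
            )
        if not (0.0 <= self.gamma_deg < 360.0):
            self.gamma_deg = self.gamma_deg % 360.0
        for v, name in ((self.v_dry_ul, "v_dry_ul"), (self.v0_ul, "v0_ul")):
            if v is not None and v < 0:
                raise ValueError(f"stain {self.id}: {name} must be >= 0")
        if self.wall_xy is None and self.room_xyz is None:
            raise ValueError(f"stain {self.id}: needs wall_xy or room_xyz")


@dataclass(frozen=True)
class ImpactGeometry:
    """Derived impact geometry for one stain."""

    alpha_deg: float
    travel_dir_in_plane: np.ndarray  # unit 2-vector (s, up) components
    backward_dir: np.ndarray  # unit 3-vector into the room


def impact_angle_from_ellipse(width_mm: float, length_mm: float) -> float:
    """Impact angle alpha (degrees) from ellipse axes, sin(alpha) = W/L.

    A circular stain (W = L) is a head-on impact, alpha = 90 deg; increasingly
    elongated stains come from increasingly grazing impacts.
    """
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("ellipse axes must be positive")
    if width_mm > length_mm:
        raise InvalidEllipseError(
            f"width {width_mm} mm exceeds length {length_mm} mm"
        )
    return math.degrees(math.asin(width_mm / length_mm))


def backward_direction(
    gamma_deg: float,
    alpha_deg: float,
    frame: WallFrame,
    *,
    clockwise: bool = True,
) -> np.ndarray:
    """Unit vector from the stain back into the room along reversed travel.

    The in-plane travel direction is ``d = cos(gamma)*up + sin(gamma)*s``,
    with gamma measured clockwise from the upward vertical as seen from
    inside the room facing the wall (set ``clockwise=False`` for the
    opposite convention).  The impact velocity direction is
    ``v_hat = cos(alpha)*d - sin(alpha)*n``; the return value is ``-v_hat``.
    """
    if not (0.0 < alpha_deg <= 90.0):
        raise ValueError("alpha must be in (0, 90] degrees")
    g = math.radians(gamma_deg if clockwise else -gamma_deg)
    a = math.radians(alpha_deg)
    d = math.cos(g) * frame.up + math.sin(g) * frame.s
    v_hat = math.cos(a) * d - math.sin(a) * frame.normal
    return -v_hat


def impact_geometry(
    stain: Stain, frame: WallFrame, *, clockwise: bool = True
) -> ImpactGeometry:
    """Full derived geometry (alpha, in-plane travel, backward ray) for a stain."""
    alpha = impact_angle_from_ellipse(stain.width_mm, stain.length_mm)
    g = math.radians(stain.gamma_deg if clockwise else -stain.gamma_deg)
    travel2d = np.array([math.sin(g), math.cos(g)])  # (s, up) components
    bdir = backward_direction(stain.gamma_deg, alpha, frame, clockwise=clockwise)
    return ImpactGeometry(alpha_deg=alpha, travel_dir_in_plane=travel2d, backward_dir=bdir)


def stain_to_room_coords(stain: Stain, frame: WallFrame) -> np.ndarray:
    """Room-frame 3D position of a stain (cm)."""
    if stain.room_xyz is not None:
        return np.asarray(stain.room_xyz, dtype=float)
    if stain.wall_xy is None:
        raise ValueError(f"stain {stain.id}: no coordinates given")
    x, y = stain.wall_xy
    return frame.point_cm + x * frame.s + y * frame.up
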