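"""Droplet flight under gravity, sphere drag and uniform wind.

Three trajectory models are supported, named after the forces they keep:

* ``straight`` — no forces; the classical straight-line (stringing)
  approximation.
* ``gravity`` — ballistic parabola, no air resistance.
* ``gravity_drag`` — gravity plus Reynolds-dependent sphere drag
  (Schiller–Naumann correlation, capped at its Re = 1000 value) with an
  optional uniform wind.

The equation of motion for a droplet of diameter D is

    a = -g z_hat - (3/4) (rho_air / rho_blood) (C_D(Re_rel) / D) |v_rel| v_rel

with v_rel = v - wind and Re_rel = rho_air |v_rel| D / eta_air.  Buoyancy,
added mass, in-flight deformation and evaporation are neglected: all are
second-order for millimetric drops over the few metres of flight considered
here.

Integration is fixed-step classical RK4 (default dt = 1e-4 s), deterministic
across platforms.  Backward reconstruction steps the *same* ODE with negative
dt, so forward and backward integration are mutually inverse to integrator
tolerance; along a backward path the speed grows, because drag decelerated
the forward flight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AirEnvironment",
    "DropletState",
    "Trajectory",
    "RunawayIntegrationError",
    "drag_coefficient",
    "acceleration",
    "integrate",
    "backward_trajectory",
]

MODELS = ("straight", "gravity", "gravity_drag")

# C_D is held constant above this Re; Schiller-Naumann is a sub-critical fit
_RE_CAP = 1000.0
_CD_CAP = (24.0 / _RE_CAP) * (1.0 + 0.15 * _RE_CAP**0.687)


class RunawayIntegrationError(RuntimeError):
    """Step budget exhausted before any stop condition was met."""


@dataclass(frozen=True)
class AirEnvironment:
    """Still or uniformly moving air, plus gravity.

    Defaults: air at 20 C (density 1.204 kg/m3, viscosity 1.82e-5 Pa s),
    g = 9.81 m/s2 acting along -z, no wind.
    """

    air_density: float = 1.204  # kg/m^3
    air_viscosity: float = 1.82e-5  # Pa s
    g: float = 9.81  # m/s^2, along -z
    wind: tuple[float, float, float] = (0.0, 0.0, 0.0)  # m/s

    def __post_init__(self) -> None:
        if self.air_density <= 0 or self.air_viscosity <= 0 or self.g <= 0:
            raise ValueError("air density, viscosity and g must be positive")


@dataclass(frozen=True)
class DropletState:
    """Instantaneous kinematic state of a droplet in flight (SI units)."""

    time: float
    position: np.ndarray  # m
    velocity: np.ndarray  # m/s
    diameter: float  # m

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("droplet diameter must be positive")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))


@dataclass
class Trajectory:
    """A computed flight path: sampled states, plus the exact line for 'straight'."""

    model: str
    times: np.ndarray  # s, shape (N,)
    positions: np.ndarray  # m, shape (N, 3)
    velocities: np.ndarray  # m/s, shape (N, 3)
    diameter: float  # m
    stain_id: str | None = None
    line_point: np.ndarray | None = field(default=None, repr=False)  # m
    line_dir: np.ndarray | None = field(default=None, repr=False)  # unit

    @property
    def end_state(self) -> DropletState:
        return DropletState(
            time=float(self.times[-1]),
            position=self.positions[-1],
            velocity=self.velocities[-1],
            diameter=self.diameter,
        )


def drag_coefficient(re: float) -> float:
    """Sphere drag coefficient, Schiller-Naumann below Re = 1000, constant above.

    C_D = (24/Re)(1 + 0.15 Re^0.687); the Re -> 0 Stokes limit is finite only
    through the product C_D*Re = 24, which is how the equations of motion use
    it.  Returns ``inf`` at Re = 0.
    """
    if re < 0:
        raise ValueError("Reynolds number must be non-negative")
    if re == 0.0:
        return math.inf
    if re > _RE_CAP:
        return _CD_CAP
    return (24.0 / re) * (1.0 + 0.15 * re**0.687)


def _drag_factor_fn(diameter: float, rho_blood: float, env: AirEnvironment):
    """Return f(|v_rel|) with a_drag = -f * v_rel; Stokes-finite at v_rel = 0."""
    d = diameter
    stokes = 18.0 * env.air_viscosity / (rho_blood * d * d)
    re_per_v = env.air_density * d / env.air_viscosity
    cap_coef = 0.75 * (env.air_density / rho_blood) * _CD_CAP / d

    def factor(vr: float) -> float:
        re = re_per_v * vr
        if re <= _RE_CAP:
            return stokes * (1.0 + 0.15 * re**0.687)
        return cap_coef * vr

    return factor


def acceleration(state: DropletState, props, env: AirEnvironment) -> np.ndarray:
    """Instantaneous acceleration (m/s2) under gravity and sphere drag."""
    factor = _drag_factor_fn(state.diameter, props.density, env)
    vrel = state.velocity - np.asarray(env.wind, dtype=float)
    f = factor(float(np.linalg.norm(vrel)))
    a = -f * vrel
    a[2] -= env.g
    return a


def _rhs_for(model: str, diameter: float, props, env: AirEnvironment):
    """Scalar-tuple acceleration function for the inner RK4 loop."""
    g = env.g
    if model == "straight":
        return lambda vx, vy, vz: (0.0, 0.0, 0.0)
    if model == "gravity":
        return lambda vx, vy, vz: (0.0, 0.0, -g)
    if model == "gravity_drag":
        wx, wy, wz = env.wind
        factor = _drag_factor_fn(diameter, props.density, env)

        def accel(vx: float, vy: float, vz: float):
            rx, ry, rz = vx - wx, vy - wy, vz - wz
            f = factor(math.sqrt(rx * rx + ry * ry + rz * rz))
            return (-f * rx, -f * ry, -f * rz - g)

        return accel
    raise ValueError(f"unknown trajectory model {model!r}")


def _rk4_path(state0: DropletState, accel, dt: float, n_steps_max: int, stop=None):
    """Fixed-step RK4 from state0; records every step; returns list of 7-tuples.

    ``stop(t, x, y, z)`` terminates integration after the step on which it
    first returns True (that state is still recorded).
    """
    t = state0.time
    x, y, z = (float(c) for c in state0.position)
    vx, vy, vz = (float(c) for c in state0.velocity)
    out = [(t, x, y, z, vx, vy, vz)]
    h = dt
    for _ in range(n_steps_max):
        ax1, ay1, az1 = accel(vx, vy, vz)
        k2vx, k2vy, k2vz = vx + 0.5 * h * ax1, vy + 0.5 * h * ay1, vz + 0.5 * h * az1
        ax2, ay2, az2 = accel(k2vx, k2vy, k2vz)
        k3vx, k3vy, k3vz = vx + 0.5 * h * ax2, vy + 0.5 * h * ay2, vz + 0.5 * h * az2
        ax3, ay3, az3 = accel(k3vx, k3vy, k3vz)
        k4vx, k4vy, k4vz = vx + h * ax3, vy + h * ay3, vz + h * az3
        ax4, ay4, az4 = accel(k4vx, k4vy, k4vz)
        x += h * (vx + 2.0 * k2vx + 2.0 * k3vx + k4vx) / 6.0
        y += h * (vy + 2.0 * k2vy + 2.0 * k3vy + k4vy) / 6.0
        z += h * (vz + 2.0 * k2vz + 2.0 * k3vz + k4vz) / 6.0
        vx += h * (ax1 + 2.0 * ax2 + 2.0 * ax3 + ax4) / 6.0
        vy += h * (ay1 + 2.0 * ay2 + 2.0 * ay3 + ay4) / 6.0
        vz += h * (az1 + 2.0 * az2 + 2.0 * az3 + az4) / 6.0
        t += h
        out.append((t, x, y, z, vx, vy, vz))
        if stop is not None and stop(t, x, y, z):
            return out, True
    return out, False


def _to_trajectory(
    model: str, rows, diameter: float, stain_id: str | None = None
) -> Trajectory:
    arr = np.asarray(rows, dtype=float)
    return Trajectory(
        model=model,
        times=arr[:, 0],
        positions=arr[:, 1:4],
        velocities=arr[:, 4:7],
        diameter=diameter,
        stain_id=stain_id,
    )


def integrate(
    state0: DropletState,
    props,
    env: AirEnvironment,
    model: str = "gravity_drag",
    dt: float = 1e-4,
    t_end: float = 1.0,
    max_steps: int = 2_000_000,
    stop=None,
) -> Trajectory:
    """Propagate a droplet state with fixed-step RK4; negative dt runs backward.

    Terminates at ``t_end`` (relative to ``state0.time``), or earlier when the
    optional ``stop(t, x, y, z)`` predicate fires.  Raises
    :class:`RunawayIntegrationError` if ``max_steps`` would be exceeded.
    """
    if dt == 0:
        raise ValueError("dt must be non-zero")
    if math.copysign(1.0, dt) != math.copysign(1.0, t_end):
        raise ValueError("dt and t_end must have the same sign")
    if abs(t_end) < abs(dt):
        raise ValueError("|t_end| must be at least |dt|")
    n_steps = int(round(abs(t_end) / abs(dt)))
    if n_steps > max_steps:
        raise RunawayIntegrationError(
            f"{n_steps} steps requested, budget is {max_steps}"
        )
    accel = _rhs_for(model, state0.diameter, props, env)
    rows, _ = _rk4_path(state0, accel, dt, n_steps, stop=stop)
    return _to_trajectory(model, rows, state0.diameter)


def backward_trajectory(
    position_m,
    speed: float,
    backward_dir,
    diameter_m: float,
    props,
    env: AirEnvironment,
    model: str = "gravity_drag",
    dt: float = 1e-4,
    max_depth_m: float = 3.0,
    z_range_m: tuple[float, float] = (0.0, 3.0),
    wall_point_m=(0.0, 0.0, 0.0),
    wall_normal=(1.0, 0.0, 0.0),
    max_steps: int = 500_000,
    stain_id: str | None = None,
) -> Trajectory:
    """Reconstruct a flight path backward in time from a stain on the wall.

    The droplet hit the wall at ``position_m`` with speed ``speed`` along
    ``-backward_dir``; the same equations of motion are stepped with negative
    dt until the path is deeper than ``max_depth_m`` from the wall (along the
    inward normal) or its height leaves ``z_range_m``.  For the ``straight``
    model the exact ray is also stored for closed-form distance queries.
    """
    bdir = np.asarray(backward_dir, dtype=float)
    bdir = bdir / np.linalg.norm(bdir)
    if speed <= 0:
        raise ValueError("impact speed must be positive")
    p0 = np.asarray(position_m, dtype=float)
    state0 = DropletState(
        time=0.0, position=p0, velocity=-speed * bdir, diameter=diameter_m
    )
    wp = np.asarray(wall_point_m, dtype=float)
    wn = np.asarray(wall_normal, dtype=float)
    wn = wn / np.linalg.norm(wn)
    z_lo, z_hi = z_range_m

    def stop(t: float, x: float, y: float, z: float) -> bool:
        depth = (x - wp[0]) * wn[0] + (y - wp[1]) * wn[1] + (z - wp[2]) * wn[2]
        return depth > max_depth_m or z < z_lo or z > z_hi

    accel = _rhs_for(model, diameter_m, props, env)
    rows, stopped = _rk4_path(state0, accel, -dt, max_steps, stop=stop)
    if not stopped:
        raise RunawayIntegrationError(
            f"backward path for stain {stain_id!r} did not leave the scene "
            f"within {max_steps} steps"
        )
    traj = _to_trajectory(model, rows, diameter_m, stain_id=stain_id)
    if model == "straight":
        traj.line_point = p0
        traj.line_dir = bdir
    return traj
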