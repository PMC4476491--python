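"""Forward simulation of impact spatter patterns with full ground truth.

An impact pattern is emulated as droplets ejected from a point source toward
a vertical wall: diameters are log-normal, launch speeds uniform (or
log-normal), and launch directions drawn from azimuth/elevation windows
biased toward the wall and upward.  Each droplet is flown forward under
gravity and drag until it crosses the wall plane; its impact state is then
converted into exactly the stain observables the inverse pipeline consumes
(ellipse width and length via the spreading law, directional angle, dried
volume via the drying ratio), so every reconstruction stage can be tested
against a known origin.

The default source reproduces the reference measurement geometry: origin
(100, 150, 63.7) cm, one metre from a vertical wall.  Launch speed 2-8 m/s
and diameter median 1 mm are plausible impact-spatter values; the real
distributions of such patterns are unpublished, so these are declared,
configurable assumptions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blood_volume import DryingModel, drying_ratio
from .flight_model import AirEnvironment, _rhs_for, _rk4_path, DropletState
from .impact_velocity import BloodProperties, dimensionless_numbers, max_spread_ratio
from .stain_geometry import Stain, WallFrame

__all__ = [
    "SourceModel",
    "EmptyPatternError",
    "default_wall_frame",
    "simulate_pattern",
    "wind_drift_experiment",
]


class EmptyPatternError(RuntimeError):
    """No simulated droplet reached the wall."""


def default_wall_frame() -> WallFrame:
    """Wall in the x = 0 plane, inward normal +x, up +z, lateral axis +y."""
    return WallFrame(point_cm=(0.0, 0.0, 0.0), normal=(1.0, 0.0, 0.0), up=(0.0, 0.0, 1.0))


@dataclass(frozen=True)
class SourceModel:
    """Droplet source for the forward simulator.

    origin_cm is the true origin; directions are sampled with azimuth
    (degrees, about the vertical, 0 = straight at the wall) and elevation
    (degrees above horizontal) drawn uniformly from the given windows.
    ``position_jitter_cm`` scatters launch positions isotropically around the
    origin to emulate a finite breakup region; ``measurement_noise`` applies
    multiplicative Gaussian noise of that relative width to W, L and V_dry.
    """

    origin_cm: tuple[float, float, float] = (100.0, 150.0, 63.7)
    n_droplets: int = 250
    diameter_median_mm: float = 1.0
    diameter_gsd: float = 1.3
    speed_range_m_s: tuple[float, float] = (2.0, 8.0)
    speed_distribution: str = "uniform"  # or "lognormal" (median, gsd)
    azimuth_range_deg: tuple[float, float] = (-30.0, 30.0)
    elevation_range_deg: tuple[float, float] = (10.0, 60.0)
    position_jitter_cm: float = 0.0
    measurement_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("need at least one droplet")
        if self.diameter_median_mm <= 0 or self.diameter_gsd < 1.0:
            raise ValueError("diameter median must be positive and gsd >= 1")
        if self.speed_distribution not in ("uniform", "lognormal"):
            raise ValueError("speed_distribution must be 'uniform' or 'lognormal'")


def _sample_speed(rng: np.random.Generator, source: SourceModel) -> float:
    lo, hi = source.speed_range_m_s
    if source.speed_distribution == "uniform":
        return float(rng.uniform(lo, hi))
    # lognormal: interpret the range as (median, gsd)
    return float(lo * math.exp(rng.normal(0.0, math.log(hi))))


def _refine_wall_crossing(accel, prev_row, h_full, depth_fn):
    """Bisect the last RK4 step length so the state lands on the wall plane."""
    t0, x0, y0, z0, vx0, vy0, vz0 = prev_row
    state = DropletState(time=t0, position=(x0, y0, z0), velocity=(vx0, vy0, vz0), diameter=1.0)
    lo, hi = 0.0, h_full
    row = prev_row
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        rows, _ = _rk4_path(state, accel, mid, 1)
        row = rows[1]
        if depth_fn(row[1], row[2], row[3]) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15:
            break
    return row


def simulate_pattern(
    source: SourceModel,
    props: BloodProperties | None = None,
    env: AirEnvironment | None = None,
    frame: WallFrame | None = None,
    drying: DryingModel | None = None,
    dt: float = 1e-4,
    max_flight_s: float = 10.0,
) -> tuple[list[Stain], pd.DataFrame]:
    """Simulate one impact pattern; returns (stains, ground-truth table).

    Droplets are integrated with the gravity-and-drag model until they cross
    the wall plane (the crossing step is bisected onto the plane); droplets
    that hit the floor or time out first are dropped and counted in the truth
    table's attrs.  Stain observables are generated by the same physics the
    inverse pipeline inverts: ``W_max = D0 * xi(v_impact)``,
    ``L_max = W_max / sin(alpha)``, ``V_dry = kappa(Hct) * V0``.
    """
    props = props or BloodProperties()
    env = env or AirEnvironment()
    frame = frame or default_wall_frame()
    drying = drying or DryingModel()
    rng = np.random.default_rng(source.seed)

    origin_m = np.asarray(source.origin_cm, dtype=float) / 100.0
    wall_point_m = frame.point_cm / 100.0
    n_vec, u_vec, s_vec = frame.normal, frame.up, frame.s
    kappa = drying_ratio(props.hematocrit, drying)

    def depth_fn(x: float, y: float, z: float) -> float:
        p = np.array([x, y, z]) - wall_point_m
        return float(p @ n_vec)

    stains: list[Stain] = []
    truth_rows: list[dict] = []
    n_missed = 0
    n_steps_max = int(max_flight_s / dt)

    for i in range(source.n_droplets):
        d0_mm = source.diameter_median_mm * math.exp(
            rng.normal(0.0, math.log(source.diameter_gsd))
        )
        speed = _sample_speed(rng, source)
        az = math.radians(rng.uniform(*source.azimuth_range_deg))
        el = math.radians(rng.uniform(*source.elevation_range_deg))
        horiz = -math.cos(az) * n_vec + math.sin(az) * s_vec
        direction = math.cos(el) * horiz + math.sin(el) * u_vec
        launch_pos = origin_m.copy()
        if source.position_jitter_cm > 0:
            launch_pos = launch_pos + rng.normal(0.0, source.position_jitter_cm / 100.0, 3)

        d0_m = d0_mm * 1e-3
        state0 = DropletState(
            time=0.0, position=launch_pos, velocity=speed * direction, diameter=d0_m
        )
        accel = _rhs_for("gravity_drag", d0_m, props, env)
        stop = lambda t, x, y, z: depth_fn(x, y, z) <= 0.0 or z <= 0.0
        rows, stopped = _rk4_path(state0, accel, dt, n_steps_max, stop=stop)
        if not stopped or rows[-1][3] <= 0.0:
            n_missed += 1
            continue
        # land exactly on the wall plane
        row = _refine_wall_crossing(accel, rows[-2], dt, depth_fn)
        t_imp = row[0]
        p_imp = np.array(row[1:4])
        v_imp = np.array(row[4:7])
        v_speed = float(np.linalg.norm(v_imp))

        sin_alpha = float(-(v_imp @ n_vec)) / v_speed
        sin_alpha = min(max(sin_alpha, 0.0), 1.0)
        if sin_alpha <= 1e-6:
            n_missed += 1  # grazing parallel impact leaves no ellipse
            continue
        alpha_deg = math.degrees(math.asin(sin_alpha))
        d_plane = v_imp - (v_imp @ n_vec) * n_vec
        norm_d = np.linalg.norm(d_plane)
        if norm_d < 1e-12:
            gamma_deg = 0.0  # head-on impact: gamma undefined, conventionally 0
        else:
            d_plane = d_plane / norm_d
            gamma_deg = math.degrees(
                math.atan2(float(d_plane @ s_vec), float(d_plane @ u_vec))
            ) % 360.0

        nums = dimensionless_numbers(props, d0_m, v_speed)
        w_mm = max_spread_ratio(nums, props.spreading_A) * d0_mm
        l_mm = w_mm / sin_alpha
        v0_ul = math.pi / 6.0 * d0_mm**3  # 1 mm^3 = 1 ul
        v_dry_ul = kappa * v0_ul
        if source.measurement_noise > 0:
            w_mm *= 1.0 + rng.normal(0.0, source.measurement_noise)
            l_mm *= 1.0 + rng.normal(0.0, source.measurement_noise)
            v_dry_ul *= 1.0 + rng.normal(0.0, source.measurement_noise)
            l_mm = max(l_mm, w_mm)  # noise must not produce W > L

        p_imp_cm = p_imp * 100.0
        rel = p_imp_cm - frame.point_cm
        stains.append(
            Stain(
                id=f"s{i:03d}",
                width_mm=w_mm,
                length_mm=l_mm,
                gamma_deg=gamma_deg,
                wall_xy=(float(rel @ s_vec), float(rel @ u_vec)),
                room_xyz=tuple(p_imp_cm),
                v_dry_ul=v_dry_ul,
            )
        )
        truth_rows.append(
            {
                "id": f"s{i:03d}",
                "launch_x_cm": launch_pos[0] * 100.0,
                "launch_y_cm": launch_pos[1] * 100.0,
                "launch_z_cm": launch_pos[2] * 100.0,
                "v_launch_m_s": speed,
                "v_impact_m_s": v_speed,
                "vx_impact_m_s": v_imp[0],
                "vy_impact_m_s": v_imp[1],
                "vz_impact_m_s": v_imp[2],
                "t_flight_s": t_imp,
                "D0_mm": d0_mm,
                "alpha_deg": alpha_deg,
                "gamma_deg": gamma_deg,
            }
        )

    if not stains:
        raise EmptyPatternError(
            f"none of {source.n_droplets} droplets reached the wall"
        )
    truth = pd.DataFrame(truth_rows)
    truth.attrs["n_missed"] = n_missed
    truth.attrs["seed"] = source.seed
    return stains, truth


def wind_drift_experiment(
    diameter_mm: float,
    drop_height_m: float,
    wind_speed_m_s: float,
    props: BloodProperties | None = None,
    env: AirEnvironment | None = None,
    dt: float = 1e-4,
    max_steps: int = 5_000_000,
) -> float:
    """Lateral drift (m) of a droplet falling from rest in a uniform crosswind.

    The droplet is released at rest from ``drop_height_m`` and integrated
    with gravity and drag (wind along +x) until it reaches the floor; the
    touchdown point's horizontal displacement from the release point is
    returned.  Without wind the fall is vertical, so this displacement *is*
    the deviation from the no-wind path.
    """
    if diameter_mm <= 0 or drop_height_m <= 0:
        raise ValueError("diameter and drop height must be positive")
    props = props or BloodProperties()
    base = env or AirEnvironment()
    env_wind = AirEnvironment(
        air_density=base.air_density,
        air_viscosity=base.air_viscosity,
        g=base.g,
        wind=(wind_speed_m_s, 0.0, 0.0),
    )
    d_m = diameter_mm * 1e-3
    state0 = DropletState(
        time=0.0, position=(0.0, 0.0, drop_height_m), velocity=(0.0, 0.0, 0.0),
        diameter=d_m,
    )
    accel = _rhs_for("gravity_drag", d_m, props, env_wind)
    rows, stopped = _rk4_path(state0, accel, dt, max_steps, stop=lambda t, x, y, z: z <= 0.0)
    if not stopped:
        raise RuntimeError("droplet did not reach the floor within the step budget")
    # interpolate the touchdown point between the last two states
    (t0, x0, y0, z0, *_), (t1, x1, y1, z1, *_) = rows[-2], rows[-1]
    frac = z0 / (z0 - z1) if z0 != z1 else 1.0
    x_td = x0 + frac * (x1 - x0)
    y_td = y0 + frac * (y1 - y0)
    return math.hypot(x_td, y_td)
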