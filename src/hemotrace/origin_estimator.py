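"""Point and region of origin from a bundle of backward trajectories.

Each analysed stain yields one backward flight path; in an ideal world all
paths from one impact pattern would intersect at the blood source.  In
practice they form a narrow bundle, and the point of origin (PO) is defined
here as the point minimizing the sum of squared shortest distances to the
trajectories — the natural generalization of the stringing method to curved
paths.  The region of origin (RO) is the sphere centred on the PO with radius
twice the standard deviation of those shortest distances.

Accuracy statistics over repeated patterns with a known true origin follow
the usual deviation bookkeeping: per-axis mean deviation of the PO, its
variance, the average per-pattern SD, and a 95%-style maximum deviation
|mean deviation| + 2 * <SD>.

All public interfaces in this module use centimetres (the reporting unit);
trajectories store SI positions and are converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .flight_model import Trajectory

__all__ = [
    "OriginEstimate",
    "AccuracyReport",
    "InsufficientTrajectoriesError",
    "DegenerateGeometryError",
    "shortest_distance",
    "estimate_origin",
    "accuracy_report",
]

_M_TO_CM = 100.0


class InsufficientTrajectoriesError(ValueError):
    """Fewer than three trajectories, or a bundle with no unique convergence."""


class DegenerateGeometryError(ValueError):
    """Trajectory bundle is (near-)parallel: the PO is not identifiable."""


@dataclass
class OriginEstimate:
    """Estimated point of origin with its uncertainty region."""

    po_cm: np.ndarray  # shape (3,)
    distances_cm: np.ndarray  # per-stain shortest distance, shape (n,)
    sd_cm: float
    ro_radius_cm: float  # = 2 * sd_cm
    model: str
    n_stains: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class AccuracyReport:
    """Deviation statistics over repeated patterns with a known true origin."""

    mean_deviation_cm: np.ndarray  # per axis, shape (3,)
    deviation_variance_cm2: np.ndarray  # per axis, shape (3,)
    mean_sd_cm: float
    max_deviation_cm: np.ndarray  # per axis: |mean dev| + 2*<SD>
    n_patterns: int
    model: str


def _line_of(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Anchor point (cm) and unit direction of a trajectory's straight version."""
    if traj.line_point is not None and traj.line_dir is not None:
        return traj.line_point * _M_TO_CM, traj.line_dir
    if len(traj.times) < 2:
        raise ValueError("trajectory must have at least two states")
    a = traj.positions[0] * _M_TO_CM
    d = traj.positions[1] - traj.positions[0]
    return a, d / np.linalg.norm(d)


def shortest_distance(traj: Trajectory, point_cm) -> float:
    """Shortest distance (cm) from a point to a trajectory.

    Straight trajectories use the exact point-to-line perpendicular distance;
    sampled paths use the minimum over their polyline segments (samples every
    integration step, so the polyline error is far below measurement noise).
    """
    p = np.asarray(point_cm, dtype=float)
    if traj.model == "straight" and traj.line_point is not None:
        a = traj.line_point * _M_TO_CM
        d = traj.line_dir
        r = p - a
        return float(np.linalg.norm(r - np.dot(r, d) * d))
    pts = traj.positions * _M_TO_CM
    if pts.shape[0] < 2:
        raise ValueError("trajectory must have at least two states")
    a, b = pts[:-1], pts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.maximum(denom, 1e-30), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return float(np.sqrt(np.min(np.einsum("ij,ij->i", p - closest, p - closest))))


def _straight_line_po(trajectories) -> tuple[np.ndarray, float]:
    """Closed-form least-squares intersection point of the straight versions.

    Solves sum_i (I - d_i d_i^T) (p - a_i) = 0.  Returns the point (cm) and
    the condition number of the normal matrix (large = near-parallel bundle).
    """
    m = np.zeros((3, 3))
    rhs = np.zeros(3)
    for traj in trajectories:
        a, d = _line_of(traj)
        proj = np.eye(3) - np.outer(d, d)
        m += proj
        rhs += proj @ a
    cond = float(np.linalg.cond(m))
    if not np.isfinite(cond) or cond > 1e8:
        raise DegenerateGeometryError(
            f"trajectory bundle is near-parallel (condition number {cond:.3g})"
        )
    return np.linalg.solve(m, rhs), cond


def estimate_origin(
    trajectories,
    *,
    tol_cm: float = 0.01,
    loss: str = "sum_sq",
    max_iter: int = 2000,
) -> OriginEstimate:
    """Estimate the point and region of origin from >= 3 backward trajectories.

    The PO is initialized at the closed-form least-squares intersection of
    each trajectory's straight-line version, then refined by derivative-free
    (Nelder-Mead) minimization of the sum of squared shortest distances
    (``loss='sum_abs'`` minimizes the plain sum instead) to ``tol_cm``.
    The SD over per-stain distances uses the sample (n-1) denominator and
    the RO radius is exactly twice the SD.
    """
    trajectories = list(trajectories)
    if len(trajectories) < 3:
        raise InsufficientTrajectoriesError(
            f"need at least 3 trajectories, got {len(trajectories)}"
        )
    models = {t.model for t in trajectories}
    if len(models) != 1:
        raise ValueError(f"mixed trajectory models: {sorted(models)}")
    model = models.pop()
    if loss not in ("sum_sq", "sum_abs"):
        raise ValueError("loss must be 'sum_sq' or 'sum_abs'")

    p0, cond = _straight_line_po(trajectories)

    if model == "straight" and loss == "sum_sq":
        # for infinite lines the normal equations solve the quadratic
        # objective exactly; no iterative polish is needed
        po = p0
        dists = np.array([shortest_distance(t, po) for t in trajectories])
        sd = float(np.std(dists, ddof=1))
        return OriginEstimate(
            po_cm=po,
            distances_cm=dists,
            sd_cm=sd,
            ro_radius_cm=2.0 * sd,
            model=model,
            n_stains=len(trajectories),
            diagnostics={
                "init_po_cm": p0.tolist(),
                "normal_matrix_cond": cond,
                "method": "closed_form",
                "loss": loss,
            },
        )

    if loss == "sum_sq":
        objective = lambda p: sum(shortest_distance(t, p) ** 2 for t in trajectories)
    else:
        objective = lambda p: sum(shortest_distance(t, p) for t in trajectories)

    res = minimize(
        objective,
        p0,
        method="Nelder-Mead",
        options={
            "xatol": tol_cm,
            "fatol": tol_cm**2,
            "maxiter": max_iter,
            "maxfev": 2 * max_iter,
        },
    )
    if not res.success and res.status != 2:  # status 2 = maxiter
        raise RuntimeError(f"PO search failed: {res.message}")
    if not res.success:
        raise InsufficientTrajectoriesError(
            f"PO search did not converge within {max_iter} iterations "
            f"(best objective {res.fun:.4g} cm^2)"
        )
    po = np.asarray(res.x, dtype=float)
    dists = np.array([shortest_distance(t, po) for t in trajectories])
    sd = float(np.std(dists, ddof=1))
    return OriginEstimate(
        po_cm=po,
        distances_cm=dists,
        sd_cm=sd,
        ro_radius_cm=2.0 * sd,
        model=model,
        n_stains=len(trajectories),
        diagnostics={
            "init_po_cm": p0.tolist(),
            "normal_matrix_cond": cond,
            "n_iterations": int(res.nit),
            "objective": float(res.fun),
            "loss": loss,
        },
    )


def accuracy_report(estimates, true_origin_cm) -> AccuracyReport:
    """Per-axis deviation statistics of PO estimates against a known origin.

    The mean deviation per axis is the average of (PO_i - true origin); the
    maximum deviation is |mean deviation| + 2 * <SD>, where <SD> averages the
    per-pattern distance SDs — a 95%-level bound on how far an estimated PO
    may lie from the truth.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("need at least one origin estimate")
    models = {e.model for e in estimates}
    if len(models) != 1:
        raise ValueError(f"mixed estimate models: {sorted(models)}")
    true_origin = np.asarray(true_origin_cm, dtype=float)
    devs = np.array([e.po_cm - true_origin for e in estimates])  # (n, 3)
    mean_dev = devs.mean(axis=0)
    var = (
        devs.var(axis=0, ddof=1) if len(estimates) > 1 else np.zeros(3)
    )
    mean_sd = float(np.mean([e.sd_cm for e in estimates]))
    return AccuracyReport(
        mean_deviation_cm=mean_dev,
        deviation_variance_cm2=var,
        mean_sd_cm=mean_sd,
        max_deviation_cm=np.abs(mean_dev) + 2.0 * mean_sd,
        n_patterns=len(estimates),
        model=models.pop(),
    )
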