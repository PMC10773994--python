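"""Trajectory and kymograph estimators, and shape-comparison scores.

Implements the measurement conventions used on extracted root centerlines:
the steady-state tip angle as the mean over the final window of the record,
the time to gravitropic equilibrium as the first entry into the steady-state
band, growth-zone length from where curvature change vanishes in the
tip-attached frame, and the two scores quantifying how well a simulated
shape matches a measured centerline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Centerline, Kymograph, TipTrajectory, _finite_scalar

__all__ = [
    "ResponseSummary",
    "ShapeScores",
    "steady_state_angle",
    "time_to_equilibrium",
    "estimate_growth_zone",
    "shape_scores",
    "summarize_response",
]

#: Floor on the steady-state band half-width (rad) so that noiseless
#: trajectories, whose last-window standard deviation can vanish, still
#: define a non-empty band.
SIGMA_FLOOR = 1e-3


@dataclass
class ResponseSummary:
    """Summary statistics of one gravitropic response."""

    theta_f: float
    sigma_theta_f: float
    tau_eq: float
    reached_equilibrium: bool
    Lgz_est: float | None = None
    nd_growth: float | None = None  # eps0 * tau_eq, growth in units of Lgz


@dataclass
class ShapeScores:
    """Agreement between an observed and a modelled centerline.

    ``dist_score`` is the mean distance between same-arc-length points
    normalized by the organ radius (dimensionless); ``angle_score`` is the
    mean absolute tangent-angle difference (degrees).  Both are zero iff the
    shapes coincide on the comparison grid.
    """

    dist_score: float
    angle_score: float


def steady_state_angle(
    traj: TipTrajectory, window: float = 5.0
) -> tuple[float, float]:
    """Mean and standard deviation of theta_tip over the final ``window`` hours."""
    window = _finite_scalar(window, "window")
    if window <= 0:
        raise ValueError("window must be positive")
    if traj.duration <= window:
        raise ValueError(
            f"trajectory spans {traj.duration:.3g} h, shorter than the "
            f"{window:.3g} h averaging window"
        )
    sel = traj.times_t >= traj.times_t[-1] - window
    tail = traj.theta_tip[sel]
    return float(tail.mean()), float(tail.std())


def time_to_equilibrium(
    traj: TipTrajectory,
    theta_f: float,
    sigma: float,
    mode: str = "entry",
    sigma_floor: float = SIGMA_FLOOR,
) -> tuple[float, bool]:
    """Time for theta_tip(t) to approach the band theta_f +/- sigma.

    ``mode="entry"`` (default) returns the first sample inside the band;
    ``mode="sustained"`` returns the first sample after which every later
    sample stays inside (a much stricter reading that is degenerate for
    noisy records, since samples keep leaving a one-standard-deviation
    band).  ``sigma`` is floored at ``sigma_floor``.  Returns
    ``(tau_eq, reached)``; if the band is never entered, ``tau_eq`` is the
    end of the record, ``reached`` is False and a warning is emitted.
    """
    theta_f = _finite_scalar(theta_f, "theta_f")
    band = max(_finite_scalar(sigma, "sigma"), sigma_floor)
    inside = np.abs(traj.theta_tip - theta_f) <= band
    t = traj.times_t
    if mode == "entry":
        idx = np.flatnonzero(inside)
        first = idx[0] if idx.size else None
    elif mode == "sustained":
        outside = np.flatnonzero(~inside)
        if outside.size == 0:
            first = 0
        elif outside[-1] == t.size - 1:
            first = None
        else:
            first = outside[-1] + 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if first is None:
        warnings.warn(
            "steady-state band never entered; reporting the end of the record",
            stacklevel=2,
        )
        return float(t[-1] - t[0]), False
    return float(t[first] - t[0]), True


def estimate_growth_zone(
    kymo: Kymograph,
    tau_eq: float,
    threshold_frac: float = 0.05,
    cell: float = 0.01,
    coverage: float = 0.5,
) -> float:
    """Growth-zone length from where curvature change vanishes.

    Computes |dkappa/dt| on the grid, re-indexes it by distance from the tip
    ``d = L(t) - s`` (linear interpolation onto a uniform ``cell``-spaced
    grid), averages over the response (times below ``tau_eq``), and returns
    the largest distance at which the averaged profile still exceeds
    ``threshold_frac`` times its spatial mean -- the minimal distance from
    the tip beyond which curvature no longer changes.  The magnitude is used
    because bending reversals would cancel in a signed mean.  Only distance
    bins covered by at least ``coverage`` of the selected times enter the
    spatial mean.  Returns NaN with a warning if curvature never changes.
    """
    tau_eq = _finite_scalar(tau_eq, "tau_eq")
    t = kymo.t_grid
    if t.size < 3:
        raise ValueError("kymograph needs at least 3 time samples")
    kappa = kymo.kappa
    # forward differences between consecutive snapshots, indexed midway
    dt = np.diff(t)
    kdot = (kappa[1:, :] - kappa[:-1, :]) / dt[:, None]  # masked where either is
    t_mid = 0.5 * (t[1:] + t[:-1])
    L_mid = np.interp(t_mid, t, kymo.length_per_time)
    sel = np.flatnonzero(t_mid - t[0] < tau_eq)
    if sel.size < 1:
        raise ValueError("kymograph does not cover times below tau_eq")

    d_max = float(np.max(L_mid[sel]))
    d_grid = np.arange(0.0, d_max + cell / 2, cell)
    profiles = np.full((sel.size, d_grid.size), np.nan)
    for row, i in enumerate(sel):
        d = L_mid[i] - kymo.s_grid  # distance from tip, decreasing in s
        valid = ~np.ma.getmaskarray(kdot[i]) & (d >= 0)
        if valid.sum() < 2:
            continue
        dv = d[valid][::-1]
        kv = np.abs(np.ma.filled(kdot[i], np.nan)[valid])[::-1]
        in_range = d_grid <= dv[-1]
        profiles[row, in_range] = np.interp(d_grid[in_range], dv, kv)

    counts = np.sum(~np.isnan(profiles), axis=0)
    covered = counts >= max(1, int(np.ceil(coverage * sel.size)))
    if not np.any(covered):
        raise ValueError("no distance bin has sufficient time coverage")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_profile = np.nanmean(profiles[:, covered], axis=0)
    d_used = d_grid[covered]
    spatial_mean = float(np.mean(mean_profile))
    if spatial_mean <= 0:
        warnings.warn("curvature never changed; growth zone undefined", stacklevel=2)
        return float("nan")
    above = np.flatnonzero(mean_profile > threshold_frac * spatial_mean)
    return float(d_used[above[-1]])


def shape_scores(
    exp_shape: Centerline,
    model_shape: Centerline,
    radius_r: float,
    ds: float = 0.01,
) -> ShapeScores:
    """Compare two centerlines point-by-point at common arc length from the base.

    Both shapes are resampled onto a uniform ``ds``-spaced arc-length grid
    truncated to the shorter organ; organs differing in length by more than
    10% make the point correspondence ill-defined and raise.
    """
    radius_r = _finite_scalar(radius_r, "radius_r")
    if radius_r <= 0:
        raise ValueError("radius_r must be positive")
    L1, L2 = exp_shape.length, model_shape.length
    if abs(L1 - L2) > 0.10 * max(L1, L2):
        raise ValueError(
            f"organ lengths differ by more than 10% ({L1:.3g} vs {L2:.3g} mm)"
        )
    grid = np.arange(0.0, min(L1, L2) + ds / 2, ds)

    def resample(shape: Centerline):
        s = shape.arclength_s - shape.arclength_s[0]
        if shape.coords_xy is None:
            raise ValueError("centerline has no coordinates; use integrate_shape")
        x = np.interp(grid, s, shape.coords_xy[:, 0])
        y = np.interp(grid, s, shape.coords_xy[:, 1])
        theta = np.interp(grid, s, shape.angles_theta)
        return x, y, theta

    x1, y1, th1 = resample(exp_shape)
    x2, y2, th2 = resample(model_shape)
    dist = float(np.mean(np.hypot(x1 - x2, y1 - y2)) / radius_r)
    angle = float(np.degrees(np.mean(np.abs(th1 - th2))))
    return ShapeScores(dist_score=dist, angle_score=angle)


def summarize_response(
    traj: TipTrajectory,
    eps0: float | None = None,
    kymo: Kymograph | None = None,
    window: float = 5.0,
    mode: str = "entry",
) -> ResponseSummary:
    """Full response summary: steady state, time to equilibrium, and (with a
    kymograph) the growth-zone length estimate."""
    theta_f, sigma = steady_state_angle(traj, window=window)
    tau_eq, reached = time_to_equilibrium(traj, theta_f, sigma, mode=mode)
    lgz = None
    if kymo is not None:
        lgz = estimate_growth_zone(kymo, tau_eq)
    return ResponseSummary(
        theta_f=theta_f,
        sigma_theta_f=sigma,
        tau_eq=tau_eq,
        reached_equilibrium=reached,
        Lgz_est=lgz,
        nd_growth=None if eps0 is None else eps0 * tau_eq,
    )
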