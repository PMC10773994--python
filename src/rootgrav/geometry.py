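"""Physical quantities, unit conventions and planar centerline geometry.

Internal units are millimetres, hours and radians throughout the package;
conversions from micrometres, degrees or minutes happen only at I/O
boundaries.  Angles are measured from the horizontal axis, the gravity
stimulus points "down the plate" at ``theta_g = pi/2``, and positive
curvature corresponds to a counterclockwise turn of the tangent with
increasing arc length.  Arc length ``s`` runs from the clamped base
(``s = 0``) to the tip (``s = L(t)``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "THETA_G",
    "OrganGeometry",
    "Sensitivities",
    "Centerline",
    "TipTrajectory",
    "Kymograph",
    "curvature_from_angles",
    "integrate_shape",
    "local_average_angle",
    "nondimensionalize",
    "dimensionalize",
    "eta_from_beta",
    "beta_from_eta",
]

#: Direction of the gravity stimulus (rad from horizontal).
THETA_G = float(np.pi / 2)

_REL_TOL = 1e-9  # relative tolerance for redundant-field consistency checks


def _finite_scalar(x, name: str) -> float:
    x = float(x)
    if not np.isfinite(x):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return x


def _as_1d(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or inf")
    return arr


def _strictly_increasing(a: np.ndarray, name: str) -> None:
    if a.size >= 2 and not np.all(np.diff(a) > 0):
        raise ValueError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class OrganGeometry:
    """Per-root physical parameters.

    Parameters
    ----------
    radius_r : float
        Organ radius (mm).
    growth_zone_Lgz : float
        Length of the subapical growth zone (mm).
    tip_velocity_vg : float
        Tip growth velocity (mm h^-1), the slope of L(t).
    initial_length_L0 : float, optional
        Initial organ length (mm).  Defaults to ``growth_zone_Lgz``; a larger
        value only adds a pre-existing straight mature zone at the base.
    growth_rate_eps0 : float, optional
        Uniform elemental growth rate in the growth zone (h^-1).  Derived as
        ``tip_velocity_vg / growth_zone_Lgz`` when omitted; when supplied it
        must be consistent with that ratio.
    """

    radius_r: float
    growth_zone_Lgz: float
    tip_velocity_vg: float
    initial_length_L0: float | None = None
    growth_rate_eps0: float | None = None

    def __post_init__(self):
        r = _finite_scalar(self.radius_r, "radius_r")
        lgz = _finite_scalar(self.growth_zone_Lgz, "growth_zone_Lgz")
        vg = _finite_scalar(self.tip_velocity_vg, "tip_velocity_vg")
        if r <= 0:
            raise ValueError("radius_r must be positive")
        if lgz <= 0:
            raise ValueError("growth_zone_Lgz must be positive")
        if vg < 0:
            raise ValueError("tip_velocity_vg must be non-negative")
        l0 = lgz if self.initial_length_L0 is None else _finite_scalar(
            self.initial_length_L0, "initial_length_L0"
        )
        if l0 < lgz * (1 - _REL_TOL):
            raise ValueError("initial_length_L0 must be at least growth_zone_Lgz")
        eps_derived = vg / lgz
        if self.growth_rate_eps0 is None:
            eps0 = eps_derived
        else:
            eps0 = _finite_scalar(self.growth_rate_eps0, "growth_rate_eps0")
            if abs(eps0 - eps_derived) > _REL_TOL * max(abs(eps_derived), 1e-300):
                raise ValueError(
                    "growth_rate_eps0 inconsistent with tip_velocity_vg / "
                    f"growth_zone_Lgz ({eps0!r} vs {eps_derived!r})"
                )
        object.__setattr__(self, "radius_r", r)
        object.__setattr__(self, "growth_zone_Lgz", lgz)
        object.__setattr__(self, "tip_velocity_vg", vg)
        object.__setattr__(self, "initial_length_L0", l0)
        object.__setattr__(self, "growth_rate_eps0", eps0)

    @property
    def slenderness(self) -> float:
        """Slenderness ratio Lgz / r of the growth zone."""
        return self.growth_zone_Lgz / self.radius_r

    def length_at(self, t) -> np.ndarray | float:
        """Organ length L(t) = L0 + Lgz * eps0 * t under linear growth."""
        return self.initial_length_L0 + self.growth_zone_Lgz * self.growth_rate_eps0 * np.asarray(t, dtype=float)


def eta_from_beta(beta: float, geometry: OrganGeometry) -> float:
    """Effective gravitropic sensitivity eta = beta * Lgz / r."""
    return float(beta) * geometry.slenderness


def beta_from_eta(eta: float, geometry: OrganGeometry) -> float:
    """Invert eta = beta * Lgz / r."""
    return float(eta) / geometry.slenderness


@dataclass(frozen=True)
class Sensitivities:
    """Tropic model parameters.

    ``gamma`` is the proprioceptive sensitivity, ``beta`` the gravitropic
    sensitivity and ``eta = beta * Lgz / r`` the effective gravitropic
    sensitivity entering the nondimensional dynamics; at least one of
    ``beta``/``eta`` must be given.  ``theta0`` is the clamped base angle and
    ``thetag`` the stimulus direction (both rad).
    """

    gamma: float
    beta: float | None = None
    eta: float | None = None
    theta0: float = 0.0
    thetag: float = THETA_G

    def __post_init__(self):
        g = _finite_scalar(self.gamma, "gamma")
        if g < 0:
            raise ValueError("gamma must be non-negative")
        if self.beta is None and self.eta is None:
            raise ValueError("at least one of beta/eta must be supplied")
        for name in ("beta", "eta"):
            v = getattr(self, name)
            if v is not None:
                v = _finite_scalar(v, name)
                if v <= 0:
                    raise ValueError(f"{name} must be positive")
                object.__setattr__(self, name, v)
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "theta0", _finite_scalar(self.theta0, "theta0"))
        object.__setattr__(self, "thetag", _finite_scalar(self.thetag, "thetag"))

    @property
    def theta0_tilde(self) -> float:
        """Initial tip angle relative to the stimulus, theta0 - thetag."""
        return self.theta0 - self.thetag

    def resolve(self, geometry: OrganGeometry) -> "Sensitivities":
        """Return a copy with both ``beta`` and ``eta`` filled in.

        When both are already set they must satisfy ``eta = beta * Lgz / r``
        to relative 1e-9.
        """
        beta, eta = self.beta, self.eta
        if beta is not None and eta is not None:
            expected = eta_from_beta(beta, geometry)
            if abs(eta - expected) > _REL_TOL * max(abs(expected), 1e-300):
                raise ValueError(
                    f"eta={eta!r} inconsistent with beta*Lgz/r={expected!r}"
                )
            return self
        if beta is None:
            beta = beta_from_eta(eta, geometry)
        else:
            eta = eta_from_beta(beta, geometry)
        return dataclasses.replace(self, beta=beta, eta=eta)


@dataclass
class Centerline:
    """Planar centerline sampled on a strictly increasing arc-length grid."""

    arclength_s: np.ndarray
    angles_theta: np.ndarray
    coords_xy: np.ndarray | None = None

    def __post_init__(self):
        self.arclength_s = _as_1d(self.arclength_s, "arclength_s")
        self.angles_theta = _as_1d(self.angles_theta, "angles_theta")
        if self.arclength_s.size != self.angles_theta.size:
            raise ValueError("arclength_s and angles_theta must have equal length")
        _strictly_increasing(self.arclength_s, "arclength_s")
        if self.coords_xy is not None:
            xy = np.asarray(self.coords_xy, dtype=float)
            if xy.shape != (self.arclength_s.size, 2):
                raise ValueError("coords_xy must have shape (n, 2)")
            if not np.all(np.isfinite(xy)):
                raise ValueError("coords_xy contains NaN or inf")
            self.coords_xy = xy

    @property
    def length(self) -> float:
        return float(self.arclength_s[-1] - self.arclength_s[0])


@dataclass
class TipTrajectory:
    """Sampled tip-angle record theta_tip(t), optionally with the angle at
    the base of the growth zone and the organ length."""

    times_t: np.ndarray
    theta_tip: np.ndarray
    theta_gz0: np.ndarray | None = None
    length_L: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_t = _as_1d(self.times_t, "times_t")
        self.theta_tip = _as_1d(self.theta_tip, "theta_tip")
        _strictly_increasing(self.times_t, "times_t")
        n = self.times_t.size
        if self.theta_tip.size != n:
            raise ValueError("theta_tip must have the same length as times_t")
        for name in ("theta_gz0", "length_L"):
            v = getattr(self, name)
            if v is not None:
                v = _as_1d(v, name)
                if v.size != n:
                    raise ValueError(f"{name} must have the same length as times_t")
                setattr(self, name, v)

    @property
    def n_samples(self) -> int:
        return int(self.times_t.size)

    @property
    def dt_sampling(self) -> float:
        """Median sampling interval (h)."""
        if self.times_t.size < 2:
            raise ValueError("need at least 2 samples for a sampling interval")
        return float(np.median(np.diff(self.times_t)))

    @property
    def duration(self) -> float:
        return float(self.times_t[-1] - self.times_t[0])


@dataclass
class Kymograph:
    """Curvature field kappa(s, t) on an (time x arc-length) grid.

    Cells with ``s > L(t)`` do not exist physically and are masked, never
    zero-filled.  ``kappa`` has shape ``(t_grid.size, s_grid.size)``.
    """

    s_grid: np.ndarray
    t_grid: np.ndarray
    kappa: np.ma.MaskedArray
    length_per_time: np.ndarray

    def __post_init__(self):
        self.s_grid = _as_1d(self.s_grid, "s_grid")
        self.t_grid = _as_1d(self.t_grid, "t_grid")
        _strictly_increasing(self.s_grid, "s_grid")
        _strictly_increasing(self.t_grid, "t_grid")
        self.length_per_time = _as_1d(self.length_per_time, "length_per_time")
        if self.length_per_time.size != self.t_grid.size:
            raise ValueError("length_per_time must match t_grid")
        kappa = np.ma.masked_invalid(np.ma.asarray(self.kappa, dtype=float))
        if kappa.shape != (self.t_grid.size, self.s_grid.size):
            raise ValueError(
                "kappa must have shape (t_grid.size, s_grid.size), got "
                f"{kappa.shape}"
            )
        # cells beyond the organ do not exist: force the mask there
        beyond = self.s_grid[None, :] > self.length_per_time[:, None] + 1e-12
        kappa = np.ma.masked_where(beyond | np.ma.getmaskarray(kappa), kappa)
        self.kappa = kappa


def curvature_from_angles(centerline: Centerline) -> np.ndarray:
    """Curvature kappa = d(theta)/ds by finite differences.

    Central differences on the interior, second-order one-sided at the
    endpoints; supports non-uniform grids.  Requires at least 3 grid points.
    """
    s, theta = centerline.arclength_s, centerline.angles_theta
    if s.size < 3:
        raise ValueError("curvature needs at least 3 grid points")
    return np.gradient(theta, s, edge_order=2)


def integrate_shape(
    arclength_s,
    theta_profile,
    base_xy=(0.0, 0.0),
) -> Centerline:
    """Reconstruct a centerline from its tangent-angle profile.

    Cumulative trapezoidal integration of (cos theta, sin theta) along s,
    starting from ``base_xy``; the inverse of :func:`curvature_from_angles`
    up to the constant theta(0).
    """
    s = _as_1d(arclength_s, "arclength_s")
    theta = _as_1d(theta_profile, "theta_profile")
    if s.size != theta.size:
        raise ValueError("arclength_s and theta_profile must have equal length")
    _strictly_increasing(s, "arclength_s")
    x0, y0 = (float(v) for v in base_xy)
    x = x0 + cumulative_trapezoid(np.cos(theta), s, initial=0.0)
    y = y0 + cumulative_trapezoid(np.sin(theta), s, initial=0.0)
    return Centerline(arclength_s=s, angles_theta=theta, coords_xy=np.column_stack([x, y]))


def local_average_angle(centerline: Centerline, s0: float, window: float = 0.1) -> float:
    """Mean tangent angle over ``[s0 - window/2, s0 + window/2]``, clipped to
    the organ.

    The 0.1 mm default window is the characteristic smoothing length used
    when reading tip and growth-zone-base angles off extracted centerlines.
    """
    s, theta = centerline.arclength_s, centerline.angles_theta
    s0 = _finite_scalar(s0, "s0")
    window = _finite_scalar(window, "window")
    if window <= 0:
        raise ValueError("window must be positive")
    lo = max(s0 - window / 2, s[0])
    hi = min(s0 + window / 2, s[-1])
    if hi < lo:
        raise ValueError("averaging window does not intersect the organ")
    if hi == lo:
        return float(np.interp(lo, s, theta))
    inner = s[(s > lo) & (s < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, s, theta)
    return float(np.trapezoid(vals, grid) / (hi - lo))


def nondimensionalize(
    geometry: OrganGeometry, sens: Sensitivities, t
) -> tuple[float, np.ndarray | float]:
    """Map (beta, t) to the nondimensional pair (eta, tau).

    eta = beta * Lgz / r and tau = eps0 * t: time measured in units of the
    growth-zone turnover, equivalently organ growth in units of Lgz.
    """
    sens = sens.resolve(geometry)
    tau = geometry.growth_rate_eps0 * np.asarray(t, dtype=float)
    return float(sens.eta), tau if np.ndim(t) else float(tau)


def dimensionalize(
    geometry: OrganGeometry, eta: float, tau
) -> tuple[float, np.ndarray | float]:
    """Exact floating-point inverse of :func:`nondimensionalize`."""
    beta = beta_from_eta(eta, geometry)
    t = np.asarray(tau, dtype=float) / geometry.growth_rate_eps0
    return beta, t if np.ndim(tau) else float(t)
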