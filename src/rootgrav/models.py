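"""Forward simulators for tropic dynamics of growing organs.

The central object is the *root model*: a growing organ with a subapical
growth zone of fixed length ``Lgz``, apical gravisensing, and proprioception.
Inside the growth zone curvature evolves according to

    (r / eps0) * Dkappa/Dt = -beta * sin(theta_tip - theta_g) - gamma * r * kappa

while curvature is frozen in the mature zone.  With uniform growth rate and
apical sensing the growth-zone curvature is spatially uniform and the PDE
reduces exactly to a pair of nondimensional ODEs for ``k = Lgz * kappa_gz``
and its running integral ``K``:

    K' = k,    k' = -eta * sin(K + k + theta0_tilde) - gamma * k

with ``eta = beta * Lgz / r``, ``tau = eps0 * t``, ``K(0) = k(0) = 0`` and
``theta_tip = theta0 + K + k``.  This augmented first-order system is
algebraically equivalent to the second-order arcsin form

    -(k'' + gamma k') / sqrt(eta^2 - (k' + gamma k)^2) = k + k'

(one differentiation apart) but stays regular at horizontal gravistimulation,
where the arcsin form is a 0/0 limit at tau = 0; the arcsin form is retained
only as a residual cross-check.

Also provided: a direct Lagrangian material-point simulation of the full PDE
(the independent oracle for the reduction, with arbitrary growth-rate
profiles and local or apical sensing), the no-growth AC model and the
whole-organ exponential-growth ACE model used for comparison, shape and
kymograph reconstruction, and the small-angle damped-oscillator reduction
``k'' + (eta + gamma) k' + eta k = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .geometry import (
    THETA_G,
    Centerline,
    Kymograph,
    OrganGeometry,
    Sensitivities,
    TipTrajectory,
    _as_1d,
    _finite_scalar,
    integrate_shape,
)

__all__ = [
    "ModelSolution",
    "OscillatorQuantities",
    "GrowthProfile",
    "solve_root_model",
    "residual_arcsin_form",
    "tip_angle_from_solution",
    "reconstruct_shape_history",
    "solve_ac_model",
    "solve_ace_exponential",
    "lagrangian_oracle",
    "oscillator_quantities",
    "small_angle_solution",
    "gravity_crossings",
    "overshoots_gravity",
]

_RTOL = 1e-8
_ATOL = 1e-10


def _check_params(eta: float, gamma: float, tau_max: float) -> tuple[float, float, float]:
    eta = _finite_scalar(eta, "eta")
    gamma = _finite_scalar(gamma, "gamma")
    tau_max = _finite_scalar(tau_max, "tau_max")
    if eta <= 0:
        raise ValueError("eta must be positive")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if tau_max <= 0:
        raise ValueError("tau_max must be positive")
    return eta, gamma, tau_max


@dataclass
class ModelSolution:
    """Nondimensional solution of a tropic model.

    ``k`` is the angle traced by the growth zone (``Lgz * kappa_gz``, equal to
    ``theta_tip - theta_gz0``), ``K`` its running integral (the angle stored in
    the mature zone), and ``theta_tip = theta0 + K + k`` pointwise.
    """

    tau_grid: np.ndarray
    k: np.ndarray
    K: np.ndarray
    theta_tip: np.ndarray
    params: Sensitivities
    geometry: OrganGeometry | None = None
    model: str = "root"
    _dense: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def tau_max(self) -> float:
        return float(self.tau_grid[-1])

    def interp(self, tau) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate (K, k) at arbitrary tau within the solved range."""
        tau = np.asarray(tau, dtype=float)
        if np.any(tau < self.tau_grid[0] - 1e-12) or np.any(tau > self.tau_max + 1e-12):
            raise ValueError("tau outside the solved range")
        if self._dense is not None:
            out = self._dense(np.clip(tau, self.tau_grid[0], self.tau_max))
            return out[0], out[1]
        return (
            np.interp(tau, self.tau_grid, self.K),
            np.interp(tau, self.tau_grid, self.k),
        )


def solve_root_model(
    eta: float,
    gamma: float,
    theta0_tilde: float,
    tau_max: float = 10.0,
    n_steps: int = 1001,
    theta_g: float = THETA_G,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> ModelSolution:
    """Solve the reduced root model on ``tau in [0, tau_max]``.

    Integrates the augmented system ``K' = k``,
    ``k' = -eta sin(K + k + theta0_tilde) - gamma k`` with
    ``K(0) = k(0) = 0`` (adaptive explicit Runge-Kutta, dense output).  The
    initial slope ``k'(0) = -eta sin(theta0_tilde)`` of the second-order form
    is recovered automatically.
    """
    eta, gamma, tau_max = _check_params(eta, gamma, tau_max)
    theta0_tilde = _finite_scalar(theta0_tilde, "theta0_tilde")
    theta_g = _finite_scalar(theta_g, "theta_g")

    def rhs(tau, y):
        K, k = y
        return (k, -eta * np.sin(K + k + theta0_tilde) - gamma * k)

    tau_grid = np.linspace(0.0, tau_max, int(n_steps))
    sol = solve_ivp(
        rhs,
        (0.0, tau_max),
        (0.0, 0.0),
        method="RK45",
        t_eval=tau_grid,
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"root-model integration failed: {sol.message}")
    K, k = sol.y
    theta0 = theta0_tilde + theta_g
    params = Sensitivities(gamma=gamma, eta=eta, theta0=theta0, thetag=theta_g)
    return ModelSolution(
        tau_grid=tau_grid,
        k=k,
        K=K,
        theta_tip=theta0 + K + k,
        params=params,
        model="root",
        _dense=sol.sol,
    )


def residual_arcsin_form(
    solution: ModelSolution, denom_floor: float = 1e-8
) -> np.ma.MaskedArray:
    """Residual of the second-order arcsin-form ODE on a solved trajectory.

    Evaluates ``-(k'' + gamma k') / sqrt(eta^2 - (k' + gamma k)^2) - (k + k')``
    with finite-difference derivatives on the stored grid.  Points where the
    squared denominator falls below ``denom_floor`` are masked (the form is a
    0/0 limit at tau = 0 for horizontal gravistimulation, where
    ``k'(0) + gamma k(0) = eta``), as are the two samples at each end where
    the compounded one-sided differences are low-order.  A cross-check, not
    a solver.
    """
    eta = solution.params.eta
    gamma = solution.params.gamma
    tau, k = solution.tau_grid, solution.k
    kp = np.gradient(k, tau)
    kpp = np.gradient(kp, tau)
    denom_sq = eta**2 - (kp + gamma * k) ** 2
    res = np.full_like(k, np.nan)
    ok = denom_sq >= denom_floor
    res[ok] = -(kpp[ok] + gamma * kp[ok]) / np.sqrt(denom_sq[ok]) - (k[ok] + kp[ok])
    masked = np.ma.masked_invalid(res)
    masked[:2] = np.ma.masked
    masked[-2:] = np.ma.masked
    return masked


def tip_angle_from_solution(
    solution: ModelSolution,
    theta0: float,
    eps0: float,
    times_t,
    geometry: OrganGeometry | None = None,
    include_gz0: bool = False,
) -> TipTrajectory:
    """Dimensional tip-angle trajectory theta_tip(t) = theta0 + K + k.

    Times are mapped to nondimensional time via ``tau = eps0 * t`` and must
    fall inside the solved range.  With ``include_gz0`` the angle at the base
    of the growth zone (``theta_tip - k``) is attached; with ``geometry`` the
    linear length record L(t) is attached.
    """
    times = _as_1d(times_t, "times_t")
    eps0 = _finite_scalar(eps0, "eps0")
    if eps0 <= 0:
        raise ValueError("eps0 must be positive")
    K, k = solution.interp(eps0 * times)
    theta_tip = theta0 + K + k
    theta_gz0 = theta_tip - k if include_gz0 else None
    length = geometry.length_at(times) if geometry is not None else None
    return TipTrajectory(
        times_t=times, theta_tip=theta_tip, theta_gz0=theta_gz0, length_L=length
    )


def reconstruct_shape_history(
    solution: ModelSolution,
    geometry: OrganGeometry,
    t_grid,
    ds: float = 0.01,
) -> tuple[Kymograph, list[Centerline]]:
    """Rebuild the curvature kymograph and centerlines from a reduced solution.

    The growth zone carries the uniform curvature ``k(tau)/Lgz``; a material
    point now at arc length ``s`` in the mature zone froze its curvature when
    it exited the growth zone at ``s = L_mz(t')``, i.e. at nondimensional time
    ``tau' = (s - (L0 - Lgz)) / Lgz``.  Any pre-existing mature zone
    (``L0 > Lgz``) is straight.  The resulting curvature field is continuous
    but not smooth at ``s = L_mz(t)``.
    """
    if geometry is None:
        raise ValueError("geometry is required to reconstruct shapes")
    t = _as_1d(t_grid, "t_grid")
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    lgz = geometry.growth_zone_Lgz
    l0 = geometry.initial_length_L0
    eps0 = geometry.growth_rate_eps0
    theta0 = solution.params.theta0
    base_mz = l0 - lgz  # pre-existing straight mature zone
    lengths = np.asarray(geometry.length_at(t), dtype=float)
    s_grid = np.arange(0.0, lengths[-1] + ds / 2, ds)

    kappa = np.ma.masked_all((t.size, s_grid.size))
    centerlines: list[Centerline] = []
    for i, (ti, li) in enumerate(zip(t, lengths)):
        tau_i = eps0 * ti
        lmz = li - lgz
        row = np.empty_like(s_grid)
        frozen = (s_grid > base_mz) & (s_grid < lmz)
        in_gz = (s_grid >= lmz) & (s_grid <= li + 1e-12)
        row[s_grid <= base_mz] = 0.0
        if np.any(frozen):
            tau_exit = (s_grid[frozen] - base_mz) / lgz
            _, k_exit = solution.interp(tau_exit)
            row[frozen] = k_exit / lgz
        _, k_now = solution.interp(tau_i)
        row[in_gz] = k_now / lgz
        valid = s_grid <= li + 1e-12
        kappa[i, valid] = row[valid]

        s_fine = np.arange(0.0, li + ds / 2, ds)
        if s_fine[-1] < li:
            s_fine = np.append(s_fine, li)
        prof = np.interp(s_fine, s_grid[valid], row[valid])
        theta = theta0 + cumulative_trapezoid(prof, s_fine, initial=0.0)
        centerlines.append(integrate_shape(s_fine, theta))

    kymo = Kymograph(s_grid=s_grid, t_grid=t, kappa=kappa, length_per_time=lengths)
    return kymo, centerlines


def solve_ac_model(
    eta: float,
    gamma: float,
    theta0_tilde: float,
    tau_max: float = 10.0,
    n_steps: int = 1001,
    theta_g: float = THETA_G,
) -> ModelSolution:
    """No-growth comparison model with apical sensing.

    The organ keeps fixed length and spatially uniform curvature; ``k`` is the
    organ-length-normalized curvature and ``theta_tip = theta0 + k``:
    ``k' = -eta sin(k + theta0_tilde) - gamma k``.  Growth is implicitly the
    driver of bending but is not accounted for, so the mature-zone memory term
    (and with it passive orientation drift) is absent: with proprioception the
    tip stalls short of the stimulus at the fixed point
    ``eta sin(k* + theta0_tilde) = -gamma k*``.
    """
    eta, gamma, tau_max = _check_params(eta, gamma, tau_max)
    theta0_tilde = _finite_scalar(theta0_tilde, "theta0_tilde")

    def rhs(tau, y):
        return (-eta * np.sin(y[0] + theta0_tilde) - gamma * y[0],)

    tau_grid = np.linspace(0.0, tau_max, int(n_steps))
    sol = solve_ivp(
        rhs,
        (0.0, tau_max),
        (0.0,),
        method="RK45",
        t_eval=tau_grid,
        dense_output=True,
        rtol=_RTOL,
        atol=_ATOL,
    )
    if not sol.success:
        raise RuntimeError(f"AC-model integration failed: {sol.message}")
    k = sol.y[0]
    theta0 = theta0_tilde + theta_g
    params = Sensitivities(gamma=gamma, eta=eta, theta0=theta0, thetag=theta_g)
    dense = sol.sol
    return ModelSolution(
        tau_grid=tau_grid,
        k=k,
        K=np.zeros_like(k),
        theta_tip=theta0 + k,
        params=params,
        model="ac",
        _dense=lambda tau: np.vstack([np.zeros(np.shape(tau)), dense(tau)[0]]),
    )


def solve_ace_exponential(
    eta0: float,
    gamma: float,
    theta0_tilde: float,
    tau_max: float = 10.0,
    n_steps: int = 2001,
    theta_g: float = THETA_G,
    sensing: Literal["local", "apical"] = "local",
    n_points: int = 120,
    eta_with_instantaneous_length: bool = False,
) -> ModelSolution:
    """Whole-organ exponential-growth comparison model.

    The growth zone spans the whole organ (the coleoptile-like early growth
    phase), ``L(tau) = L0 * exp(tau)``, with uniform elemental growth rate.
    ``eta0 = beta * L0 / r`` is defined with the initial length.

    With ``sensing="local"`` (default) every element responds to its own
    inclination: the curvature field ``khat(x, tau) = L0 * kappa`` on the
    material coordinate ``x in [0, 1]`` obeys
    ``d khat/d tau = -eta0 sin(theta(x) - theta_g) - gamma khat`` with
    ``theta(x) = theta0 + exp(tau) * integral_0^x khat dx'``, solved as a
    stiff method-of-lines system.  The tip crosses the stimulus direction at
    least once for every gamma, and for small proprioception keeps
    oscillating about it -- passive orientation drift (the exp(tau) factor)
    is never frozen away by a mature zone.

    With ``sensing="apical"`` the signal is ``theta_tip`` for every element,
    the curvature stays spatially uniform, and the field collapses to the
    scalar ``khat' = -eta(tau) sin(exp(tau) khat + theta0_tilde) -
    gamma khat`` (``eta(tau) = eta0``, or ``eta0 * exp(tau)`` with
    ``eta_with_instantaneous_length``).  This scalar flow is first-order and
    relaxes onto a quasi-static equilibrium pinned to the stimulus, so it
    cannot sustain oscillations -- the oscillatory whole-organ phenomenology
    requires distributed sensing.

    Returned ``k`` is the whole-organ traced angle ``theta_tip - theta0``.
    """
    eta0, gamma, tau_max = _check_params(eta0, gamma, tau_max)
    theta0_tilde = _finite_scalar(theta0_tilde, "theta0_tilde")
    theta0 = theta0_tilde + theta_g
    params = Sensitivities(gamma=gamma, eta=eta0, theta0=theta0, thetag=theta_g)
    tau_grid = np.linspace(0.0, tau_max, int(n_steps))

    if sensing == "apical":

        def rhs(tau, y):
            eta_eff = eta0 * np.exp(tau) if eta_with_instantaneous_length else eta0
            return (
                -eta_eff * np.sin(np.exp(tau) * y[0] + theta0_tilde) - gamma * y[0],
            )

        sol = solve_ivp(
            rhs,
            (0.0, tau_max),
            (0.0,),
            method="LSODA",
            t_eval=tau_grid,
            rtol=_RTOL,
            atol=_ATOL,
        )
        if not sol.success:
            raise RuntimeError(f"exponential-ACE integration failed: {sol.message}")
        k = np.exp(tau_grid) * sol.y[0]
    elif sensing == "local":
        if eta_with_instantaneous_length:
            raise ValueError(
                "eta_with_instantaneous_length applies to apical sensing only"
            )
        x = np.linspace(0.0, 1.0, int(n_points))
        dx = x[1] - x[0]

        def rhs(tau, khat):
            integral = np.concatenate(
                [[0.0], np.cumsum(0.5 * (khat[1:] + khat[:-1]) * dx)]
            )
            phi = theta0_tilde + np.exp(tau) * integral
            return -eta0 * np.sin(phi) - gamma * khat

        sol = solve_ivp(
            rhs,
            (0.0, tau_max),
            np.zeros(x.size),
            method="BDF",
            t_eval=tau_grid,
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise RuntimeError(f"exponential-ACE integration failed: {sol.message}")
        tip_integral = np.trapezoid(sol.y, x, axis=0)
        k = np.exp(tau_grid) * tip_integral
    else:
        raise ValueError(f"unknown sensing mode {sensing!r}")

    return ModelSolution(
        tau_grid=tau_grid,
        k=k,
        K=np.zeros_like(k),
        theta_tip=theta0 + k,
        params=params,
        model="ace_exp",
    )


@dataclass(frozen=True)
class GrowthProfile:
    """Axial growth-rate profile over the growth zone.

    ``density(x)`` is the normalized elemental growth rate as a function of
    relative position ``x = (s - L_mz) / Lgz`` in [0, 1] (0 at the base of
    the growth zone, 1 at the tip), with ``integral_0^1 density = 1`` so that
    the local rate is ``eps0 * density(x)`` and the profile integrates to the
    tip velocity ``vg = eps0 * Lgz``.  ``cumulative(x)`` is its integral,
    giving the local growth velocity ``v(s) = vg * cumulative(x)``.
    """

    shape: Literal["uniform", "triangular", "custom"]
    density: Callable[[np.ndarray], np.ndarray]
    cumulative: Callable[[np.ndarray], np.ndarray]

    @staticmethod
    def uniform() -> "GrowthProfile":
        return GrowthProfile("uniform", lambda x: np.ones_like(x), lambda x: x)

    @staticmethod
    def triangular() -> "GrowthProfile":
        """Symmetric triangular profile peaking mid-zone, zero at both ends."""

        def density(x):
            return np.where(x < 0.5, 4.0 * x, 4.0 * (1.0 - x))

        def cumulative(x):
            return np.where(x < 0.5, 2.0 * x**2, 1.0 - 2.0 * (1.0 - x) ** 2)

        return GrowthProfile("triangular", density, cumulative)

    @staticmethod
    def custom(density: Callable[[np.ndarray], np.ndarray], n_check: int = 2001) -> "GrowthProfile":
        """Arbitrary profile; the density is renormalized-checked to unit mass."""
        x = np.linspace(0.0, 1.0, n_check)
        d = np.asarray(density(x), dtype=float)
        mass = np.trapezoid(d, x)
        if abs(mass - 1.0) > 1e-9:
            raise ValueError(
                f"growth-rate density must integrate to 1 over the zone, got {mass!r}"
            )
        cum = cumulative_trapezoid(d, x, initial=0.0)
        return GrowthProfile(
            "custom", density, lambda q: np.interp(q, x, cum)
        )


def lagrangian_oracle(
    geometry: OrganGeometry,
    sens: Sensitivities,
    growth_profile: GrowthProfile | None = None,
    sensing: Literal["apical", "local"] = "apical",
    t_max: float = 24.0,
    n_material_points: int = 400,
    dt_tau: float | None = None,
    n_output: int = 201,
    kymo_ds: float = 0.01,
) -> tuple[TipTrajectory, Kymograph]:
    """Direct material-point simulation of the growing-organ PDE.

    Integrates ``(r / eps_local) Dkappa/Dt = -beta sin(theta_sense - theta_g)
    - gamma r kappa`` following material points: points advect with the growth
    velocity ``v(s, t)``, stretch apart inside the growth zone (new points are
    inserted near the tip as gaps open), and freeze their curvature once the
    growth-zone base sweeps past them (the local growth rate, and with it the
    right-hand side, vanishes in the mature zone).  Sensing is apical
    (``theta_sense = theta_tip``) or local (``theta_sense = theta(s, t)``).
    Fixed-step Heun updates with ``dt_tau <= 0.5 / (eta + gamma + 1)``.

    This is the independent oracle for the reduced model: with apical sensing,
    a uniform profile and ``L0 = Lgz`` it must reproduce
    :func:`solve_root_model`.
    """
    if n_material_points < 50:
        raise ValueError("need at least 50 material points")
    sens = sens.resolve(geometry)
    beta, gamma = sens.beta, sens.gamma
    theta0, theta_g = sens.theta0, sens.thetag
    r = geometry.radius_r
    lgz = geometry.growth_zone_Lgz
    l0 = geometry.initial_length_L0
    eps0 = geometry.growth_rate_eps0
    vg = geometry.tip_velocity_vg
    profile = growth_profile or GrowthProfile.uniform()
    if sensing not in ("apical", "local"):
        raise ValueError(f"unknown sensing mode {sensing!r}")

    eta = sens.eta
    if dt_tau is None:
        dt_tau = min(0.5 / (eta + gamma + 1.0), 2e-3)
    dt = dt_tau / eps0
    n_steps = int(np.ceil(t_max / dt))
    dt = t_max / n_steps

    s = np.linspace(0.0, l0, n_material_points)
    kappa = np.zeros_like(s)
    ds0 = l0 / (n_material_points - 1)

    def theta_of(s_arr, kappa_arr):
        dtheta = 0.5 * (kappa_arr[1:] + kappa_arr[:-1]) * np.diff(s_arr)
        return theta0 + np.concatenate([[0.0], np.cumsum(dtheta)])

    def rates(s_arr, kappa_arr):
        L = s_arr[-1]
        lmz = L - lgz
        x = np.clip((s_arr - lmz) / lgz, 0.0, 1.0)
        eps_local = np.where(s_arr > lmz, eps0 * profile.density(x), 0.0)
        v = vg * profile.cumulative(x)
        theta = theta_of(s_arr, kappa_arr)
        theta_sense = theta[-1] if sensing == "apical" else theta
        dkappa = (eps_local / r) * (
            -beta * np.sin(theta_sense - theta_g) - gamma * r * kappa_arr
        )
        return v, dkappa, theta

    rec_times = np.linspace(0.0, t_max, n_output)
    rec_idx = np.unique(np.round(rec_times / dt).astype(int))
    rec_t, rec_tip, rec_gz0, rec_len = [], [], [], []
    rec_snapshots = []  # (t, s, kappa) for the kymograph

    for step in range(n_steps + 1):
        t_now = step * dt
        if step in rec_idx or step == n_steps:
            theta = theta_of(s, kappa)
            L = s[-1]
            rec_t.append(t_now)
            rec_tip.append(theta[-1])
            rec_gz0.append(float(np.interp(L - lgz, s, theta)))
            rec_len.append(L)
            rec_snapshots.append((t_now, s.copy(), kappa.copy()))
        if step == n_steps:
            break

        v1, dk1, _ = rates(s, kappa)
        s_mid = s + dt * v1
        kappa_mid = kappa + dt * dk1
        if not np.all(np.isfinite(kappa_mid)):
            raise RuntimeError(
                "material-point update became unstable; reduce dt_tau"
            )
        v2, dk2, _ = rates(s_mid, kappa_mid)
        s = s + 0.5 * dt * (v1 + v2)
        kappa = kappa + 0.5 * dt * (dk1 + dk2)

        # keep resolution where material stretches apart near the tip
        gaps = np.diff(s)
        wide = np.flatnonzero(gaps > 1.5 * ds0)
        if wide.size:
            new_s = 0.5 * (s[wide] + s[wide + 1])
            new_kappa = np.interp(new_s, s, kappa)
            s = np.insert(s, wide + 1, new_s)
            kappa = np.insert(kappa, wide + 1, new_kappa)

    times = np.asarray(rec_t)
    traj = TipTrajectory(
        times_t=times,
        theta_tip=np.asarray(rec_tip),
        theta_gz0=np.asarray(rec_gz0),
        length_L=np.asarray(rec_len),
    )
    lengths = np.asarray(rec_len)
    s_grid = np.arange(0.0, lengths[-1] + kymo_ds / 2, kymo_ds)
    kgrid = np.ma.masked_all((times.size, s_grid.size))
    for i, (_, s_i, kappa_i) in enumerate(rec_snapshots):
        valid = s_grid <= s_i[-1] + 1e-12
        kgrid[i, valid] = np.interp(s_grid[valid], s_i, kappa_i)
    kymo = Kymograph(
        s_grid=s_grid, t_grid=times, kappa=kgrid, length_per_time=lengths
    )
    return traj, kymo


@dataclass(frozen=True)
class OscillatorQuantities:
    """Damped-oscillator reduction of the root model at small angles.

    ``k'' + (eta + gamma) k' + eta k = 0``: natural frequency
    ``omega0 = sqrt(eta)``, attenuation rate ``Gamma = eta + gamma``, quality
    factor ``Q = omega0 / Gamma`` and critical proprioception
    ``gamma_crit = 2 sqrt(eta) - eta``; the tip overshoots the stimulus
    (underdamped regime) iff ``gamma < gamma_crit``.
    """

    omega0: float
    Gamma: float
    Q: float
    gamma_crit: float
    regime: Literal["underdamped", "critically_damped", "overdamped"]


def oscillator_quantities(eta: float, gamma: float) -> OscillatorQuantities:
    """Oscillator constants of the linearized root model."""
    eta, gamma, _ = _check_params(eta, gamma, 1.0)
    omega0 = np.sqrt(eta)
    Gamma = eta + gamma
    gamma_crit = 2.0 * omega0 - eta
    disc = Gamma**2 / 4.0 - eta
    if abs(disc) <= 1e-12 * max(eta, 1.0):
        regime = "critically_damped"
    elif disc < 0:
        regime = "underdamped"
    else:
        regime = "overdamped"
    return OscillatorQuantities(
        omega0=float(omega0),
        Gamma=float(Gamma),
        Q=float(omega0 / Gamma),
        gamma_crit=float(gamma_crit),
        regime=regime,
    )


def small_angle_solution(
    eta: float, gamma: float, k0: float, kprime0: float, tau_grid
) -> np.ndarray:
    """Closed-form solution of ``k'' + (eta + gamma) k' + eta k = 0``.

    Under-, critically- and over-damped branches with initial data
    ``k(0) = k0``, ``k'(0) = kprime0``.
    """
    eta, gamma, _ = _check_params(eta, gamma, 1.0)
    tau = _as_1d(tau_grid, "tau_grid")
    k0 = _finite_scalar(k0, "k0")
    kprime0 = _finite_scalar(kprime0, "kprime0")
    Gamma = eta + gamma
    disc = Gamma**2 / 4.0 - eta
    envelope = np.exp(-Gamma * tau / 2.0)
    c = kprime0 + Gamma * k0 / 2.0
    if abs(disc) <= 1e-12 * max(eta, 1.0):
        return envelope * (k0 + c * tau)
    if disc < 0:
        wd = np.sqrt(-disc)
        return envelope * (k0 * np.cos(wd * tau) + (c / wd) * np.sin(wd * tau))
    mu = np.sqrt(disc)
    return envelope * (k0 * np.cosh(mu * tau) + (c / mu) * np.sinh(mu * tau))


def gravity_crossings(
    eta: float,
    gamma: float,
    theta0_tilde: float = -0.05,
    tau_max: float = 80.0,
    max_count: int = 2,
    rtol: float = 1e-12,
) -> int:
    """Count crossings of the stimulus direction by the nonlinear root model.

    Integrates the equivalent system in ``phi = theta_tip - theta_g`` and
    ``k`` (``phi' = (1 - gamma) k - eta sin phi``,
    ``k' = -eta sin phi - gamma k``) with effectively pure relative error
    control, locating sign changes of ``phi`` by event detection.  Working
    with ``phi`` as a state variable avoids the catastrophic cancellation of
    evaluating ``theta0_tilde + K + k`` near critical damping, where
    crossings have amplitude many orders below the angles themselves.
    Counting stops at ``max_count``.
    """
    eta, gamma, tau_max = _check_params(eta, gamma, tau_max)
    theta0_tilde = _finite_scalar(theta0_tilde, "theta0_tilde")
    if theta0_tilde == 0.0:
        return 0

    def rhs(tau, y):
        phi, k = y
        sphi = np.sin(phi)
        return ((1.0 - gamma) * k - eta * sphi, -eta * sphi - gamma * k)

    def crossing(tau, y):
        return y[0]

    crossing.terminal = max_count
    crossing.direction = 0.0

    sol = solve_ivp(
        rhs,
        (0.0, tau_max),
        (theta0_tilde, 0.0),
        method="RK45",
        events=crossing,
        rtol=rtol,
        atol=1e-60,  # far beneath any crossing amplitude: relative control
        first_step=1e-3,
    )
    if not sol.success:
        raise RuntimeError(f"crossing detection failed: {sol.message}")
    return int(min(sol.t_events[0].size, max_count))


def overshoots_gravity(
    eta: float,
    gamma: float,
    theta0_tilde: float = -0.05,
    tau_max: float = 80.0,
    rtol: float = 1e-12,
) -> bool:
    """Whether the root model shows a returning (oscillatory) overshoot.

    A damped-oscillation overshoot -- the tip passing the stimulus direction
    and swinging back through it -- occurs exactly in the underdamped regime
    ``gamma < gamma_crit = 2 sqrt(eta) - eta`` and is detected here as at
    least two stimulus crossings.  A single *non-returning* crossing is not
    an oscillation: for ``eta > 1`` the two decay modes carry opposite-sign
    coefficients under the tilt-from-rest initial condition, so even
    critically damped and overdamped solutions (``gamma_crit <= gamma < 1``)
    pass the stimulus once and then converge monotonically from the far
    side; see :func:`gravity_crossings` to count those.
    """
    return (
        gravity_crossings(
            eta, gamma, theta0_tilde, tau_max=tau_max, max_count=2, rtol=rtol
        )
        >= 2
    )
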