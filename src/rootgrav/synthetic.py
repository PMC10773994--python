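"""Synthetic gravistimulation experiments with known ground truth.

Emulates the standard protocol for Arabidopsis primary roots: seedlings
grown vertically, tilted horizontally (theta0 near 0, stimulus at pi/2) and
imaged every 10 minutes for 24 hours.  Per-root geometry and sensitivities
are drawn around the wild-type cohort values (radius 65 um, growth zone
0.6 mm, tip velocity 0.13 mm/h, beta 0.12, gamma 1.6), trajectories are the
forward root model sampled on the imaging grid, and measurement error is
additive i.i.d. Gaussian angle noise (default 0.02 rad, about one degree).
All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .geometry import Kymograph, OrganGeometry, Sensitivities, TipTrajectory
from .models import reconstruct_shape_history, solve_root_model, tip_angle_from_solution

__all__ = [
    "WILD_TYPE_MEANS",
    "WILD_TYPE_SPREADS",
    "CohortSpec",
    "generate_trajectory",
    "generate_kymograph",
    "generate_cohort",
]

#: Cohort means for wild-type Arabidopsis primary roots
#: (mm, mm/h and dimensionless sensitivities).
WILD_TYPE_MEANS = {
    "r": 0.065,
    "Lgz": 0.60,
    "vg": 0.13,
    "beta": 0.12,
    "gamma": 1.6,
}

#: Corresponding population spreads (one standard deviation).
WILD_TYPE_SPREADS = {
    "r": 0.011,
    "Lgz": 0.14,
    "vg": 0.04,
    "beta": 0.06,
    "gamma": 1.0,
}


@dataclass
class CohortSpec:
    """Specification of a synthetic root cohort.

    Parameters are drawn independently per root: truncated normals (positive
    support) for beta, gamma, r, Lgz and vg at the given means/spreads, and a
    half-normal of scale ``theta0_scale`` for the initial angle (tilting is
    horizontal up to small placement scatter).
    """

    n_roots: int
    means: dict = field(default_factory=lambda: dict(WILD_TYPE_MEANS))
    spreads: dict = field(default_factory=lambda: dict(WILD_TYPE_SPREADS))
    theta0_scale: float = 0.05
    noise_sigma: float = 0.02
    dt_sampling: float = 1.0 / 6.0
    duration: float = 24.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_roots < 0:
            raise ValueError("n_roots must be non-negative")
        for key in ("r", "Lgz", "vg", "beta", "gamma"):
            if key not in self.means or key not in self.spreads:
                raise ValueError(f"means/spreads must both define {key!r}")
            if self.means[key] <= 0:
                raise ValueError(f"mean of {key!r} must be positive")
        if self.duration / self.dt_sampling < 9:
            raise ValueError("duration must cover at least 10 samples")


def _sampling_grid(dt: float, duration: float) -> np.ndarray:
    n = int(round(duration / dt)) + 1
    return np.linspace(0.0, duration, n)


def generate_trajectory(
    geometry: OrganGeometry,
    sens: Sensitivities,
    noise_sigma: float = 0.02,
    dt: float = 1.0 / 6.0,
    duration: float = 24.0,
    seed=None,
    include_gz0: bool = True,
    include_length: bool = True,
) -> tuple[TipTrajectory, dict]:
    """Forward-simulate one root and sample it on the imaging grid.

    Returns the (optionally noisy) trajectory and a truth record holding all
    generating inputs.  Deterministic given ``seed`` (an int or a Generator).
    """
    rng = np.random.default_rng(seed)
    sens = sens.resolve(geometry)
    eps0 = geometry.growth_rate_eps0
    times = _sampling_grid(dt, duration)
    sol = solve_root_model(
        sens.eta,
        sens.gamma,
        sens.theta0_tilde,
        tau_max=eps0 * duration * 1.001 + 1e-9,
        theta_g=sens.thetag,
    )
    traj = tip_angle_from_solution(
        sol,
        sens.theta0,
        eps0,
        times,
        geometry=geometry if include_length else None,
        include_gz0=include_gz0,
    )
    if noise_sigma > 0:
        traj.theta_tip = traj.theta_tip + rng.normal(0.0, noise_sigma, times.size)
        if traj.theta_gz0 is not None:
            traj.theta_gz0 = traj.theta_gz0 + rng.normal(0.0, noise_sigma, times.size)
    truth = {
        "beta": sens.beta,
        "gamma": sens.gamma,
        "eta": sens.eta,
        "theta0": sens.theta0,
        "thetag": sens.thetag,
        "r": geometry.radius_r,
        "Lgz": geometry.growth_zone_Lgz,
        "vg": geometry.tip_velocity_vg,
        "eps0": eps0,
        "noise_sigma": noise_sigma,
        "dt": dt,
        "duration": duration,
    }
    return traj, truth


def generate_kymograph(
    geometry: OrganGeometry,
    sens: Sensitivities,
    t_grid=None,
    ds: float = 0.01,
    noise_rel: float = 0.0,
    seed=None,
) -> tuple[Kymograph, dict]:
    """Model curvature kymograph, optionally with multiplicative noise.

    Cells beyond the organ tip are masked, never zero-filled.
    """
    rng = np.random.default_rng(seed)
    sens = sens.resolve(geometry)
    eps0 = geometry.growth_rate_eps0
    if t_grid is None:
        t_grid = _sampling_grid(1.0 / 6.0, 24.0)
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_root_model(
        sens.eta,
        sens.gamma,
        sens.theta0_tilde,
        tau_max=eps0 * t_grid[-1] * 1.001 + 1e-9,
        theta_g=sens.thetag,
    )
    kymo, _ = reconstruct_shape_history(sol, geometry, t_grid, ds=ds)
    if noise_rel > 0:
        noise = 1.0 + noise_rel * rng.standard_normal(kymo.kappa.shape)
        kymo.kappa = kymo.kappa * noise
    truth = {
        "beta": sens.beta,
        "gamma": sens.gamma,
        "eta": sens.eta,
        "theta0": sens.theta0,
        "Lgz": geometry.growth_zone_Lgz,
        "eps0": eps0,
        "ds": ds,
        "noise_rel": noise_rel,
    }
    return kymo, truth


def _draw_positive(rng, mean, sd, size):
    """Truncated-normal draw on (0, inf)."""
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[TipTrajectory, dict]], pd.DataFrame]:
    """Generate a cohort of independent synthetic roots.

    Returns one (trajectory, truth) pair per root and a machine-readable
    truth table (one row per root, all generating parameters).  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m, s = spec.means, spec.spreads
    n = spec.n_roots
    draws = {
        key: _draw_positive(rng, m[key], s[key], n)
        for key in ("beta", "gamma", "r", "Lgz", "vg")
    }
    theta0 = np.abs(rng.normal(0.0, spec.theta0_scale, n))

    roots: list[tuple[TipTrajectory, dict]] = []
    rows = []
    for i in range(n):
        geometry = OrganGeometry(
            radius_r=draws["r"][i],
            growth_zone_Lgz=draws["Lgz"][i],
            tip_velocity_vg=draws["vg"][i],
        )
        sens = Sensitivities(
            gamma=draws["gamma"][i], beta=draws["beta"][i], theta0=theta0[i]
        )
        traj, truth = generate_trajectory(
            geometry,
            sens,
            noise_sigma=spec.noise_sigma,
            dt=spec.dt_sampling,
            duration=spec.duration,
            seed=rng,
        )
        truth["root_id"] = i
        roots.append((traj, truth))
        rows.append(truth)
    columns = [
        "root_id",
        "beta",
        "gamma",
        "eta",
        "theta0",
        "thetag",
        "r",
        "Lgz",
        "vg",
        "eps0",
        "noise_sigma",
        "dt",
        "duration",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return roots, table
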