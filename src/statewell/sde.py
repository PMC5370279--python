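"""Euler-Maruyama integration of the overdamped Langevin equation.

The model is dx/dt = -U'(x, t) + sqrt(2 D) Gamma(t) with Gamma white
Gaussian noise and U the nonstationary double-well landscape of
:mod:`statewell.potential`.  The slow latent trajectory prescribes the
landscape coefficients at every step via nearest-time lookup; the update is

    x_{n+1} = x_n - U'(x_n, t_n) dt + sqrt(2 D dt) z_n

with z_n i.i.d. standard normal.  Identical seeds give bitwise-identical
trajectories.  The state is never clamped: the quartic confines
trajectories, and a non-finite state aborts with an error naming the step
(silent clamping would bias residence-time statistics).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .latent import LatentTrajectory
from .potential import LatentMap

__all__ = [
    "SdeConfig",
    "Trajectory",
    "IntegrationError",
    "LatentCoverageError",
    "NoCrossingError",
    "coefficients_over_time",
    "fixed_points_over_time",
    "simulate",
    "simulate_ensemble",
    "simulate_endpoints",
    "align_on_unstable_crossing",
]


class IntegrationError(RuntimeError):
    """The state became non-finite during integration."""


class LatentCoverageError(ValueError):
    """The latent trajectory does not cover the requested duration."""


class NoCrossingError(RuntimeError):
    """No downward crossing of the unstable point was found."""


@dataclass(frozen=True)
class SdeConfig:
    """Integration parameters.

    D is the noise intensity (unitless^2/s), dt the time step (0.01 s by
    default, the resolution at which the behavioral signal is sampled), x0
    the initial state and seed the RNG seed.
    """

    D: float
    duration: float
    x0: float = 1.0
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.D < 0:
            raise ValueError("noise intensity D must be nonnegative")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one time step")


@dataclass(frozen=True)
class Trajectory:
    """A simulated path: uniformly spaced times t (s) and states x."""

    t: np.ndarray
    x: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@njit(cache=False)
def _em_loop(x0, a, b, c, z, dt, sigma):
    n = z.size
    x = np.empty(n + 1)
    x[0] = x0
    for i in range(n):
        y = x[i] - 0.5
        drift = a[i] + 2.0 * b[i] * y + 4.0 * c[i] * y * y * y
        x[i + 1] = x[i] - drift * dt + sigma * z[i]
        if not np.isfinite(x[i + 1]):
            return x, i
    return x, -1


@njit(cache=False)
def _em_ensemble_step_block(x, a, b, c, z, dt, sigma):
    # advance all ensemble members through a block of steps; z is (steps, n)
    nsteps, n = z.shape
    for i in range(nsteps):
        for j in range(n):
            y = x[j] - 0.5
            drift = a[i] + 2.0 * b[i] * y + 4.0 * c[i] * y * y * y
            x[j] = x[j] - drift * dt + sigma * z[i, j]


def coefficients_over_time(
    times: np.ndarray, latent: LatentTrajectory, lmap: LatentMap, h: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Landscape coefficients (a, b, c) at each time, via the latent map."""
    s = latent.sample_nearest(times)
    a = np.asarray(lmap.tilt(s), dtype=float)
    d = np.asarray(lmap.separation(s), dtype=float)
    d2 = d * d
    b = 2.0 * h / d2
    c = -h / (d2 * d2)
    return a, b, c


def fixed_points_over_time(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fixed-point structure of the tilted quartic per time step.

    Returns arrays ``(x_lo, x_un, x_hi)``: lower stable point, unstable
    point, upper stable point.  Where the landscape is monostable the
    unstable entry is NaN and the single stable point is stored on the side
    of the barrier it sits on (the other side is NaN).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    p = b / (2.0 * c)
    q = a / (4.0 * c)
    disc = -4.0 * p**3 - 27.0 * q**2

    x_lo = np.full(a.shape, np.nan)
    x_un = np.full(a.shape, np.nan)
    x_hi = np.full(a.shape, np.nan)

    tri = disc > tol
    if np.any(tri):
        pt, qt = p[tri], q[tri]
        m = 2.0 * np.sqrt(-pt / 3.0)
        arg = np.clip(3.0 * qt / (pt * m), -1.0, 1.0)
        theta = np.arccos(arg) / 3.0
        roots = np.stack(
            [m * np.cos(theta - 2.0 * np.pi * k / 3.0) for k in range(3)]
        )
        roots.sort(axis=0)
        x_lo[tri] = roots[0] + 0.5
        x_un[tri] = roots[1] + 0.5
        x_hi[tri] = roots[2] + 0.5

    mono = ~tri
    if np.any(mono):
        pm, qm = p[mono], q[mono]
        s = np.sqrt(np.maximum(qm**2 / 4.0 + pm**3 / 27.0, 0.0))
        u = np.cbrt(-qm / 2.0 + s)
        v = np.cbrt(-qm / 2.0 - s)
        root = u + v + 0.5
        lo = np.full(root.shape, np.nan)
        hi = np.full(root.shape, np.nan)
        below = root < 0.5
        lo[below] = root[below]
        hi[~below] = root[~below]
        x_lo[mono] = lo
        x_hi[mono] = hi
    return x_lo, x_un, x_hi


def _check_coverage(config: SdeConfig, latent: LatentTrajectory) -> None:
    if not latent.covers(config.duration):
        raise LatentCoverageError(
            f"latent trajectory spans [{latent.t[0]}, {latent.t[-1]}] s but the "
            f"simulation requires coverage of [0, {config.duration}] s"
        )


def simulate(
    config: SdeConfig, latent: LatentTrajectory, lmap: LatentMap, h: float
) -> Trajectory:
    """Integrate the Langevin equation under a prescribed latent trajectory."""
    _check_coverage(config, latent)
    n = int(round(config.duration / config.dt))
    t = np.arange(n + 1) * config.dt
    a, b, c = coefficients_over_time(t[:-1], latent, lmap, h)
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal(n)
    sigma = np.sqrt(2.0 * config.D * config.dt)
    x, bad = _em_loop(config.x0, a, b, c, z, config.dt, sigma)
    if bad >= 0:
        raise IntegrationError(
            f"state diverged (non-finite) at step {bad + 1} (t = {(bad + 1) * config.dt} s)"
        )
    return Trajectory(t=t, x=x)


def simulate_ensemble(
    config: SdeConfig,
    latent: LatentTrajectory,
    lmap: LatentMap,
    h: float,
    n: int,
) -> list[Trajectory]:
    """n independent realizations seeded seed, seed+1, ..., seed+n-1."""
    if n < 1:
        raise ValueError("ensemble size must be at least 1")
    out = []
    for i in range(n):
        cfg = SdeConfig(
            D=config.D,
            duration=config.duration,
            x0=config.x0,
            dt=config.dt,
            seed=config.seed + i,
        )
        out.append(simulate(cfg, latent, lmap, h))
    return out


def simulate_endpoints(
    config: SdeConfig,
    latent: LatentTrajectory,
    lmap: LatentMap,
    h: float,
    checkpoint_times,
    n: int,
    block: int = 2000,
) -> np.ndarray:
    """Joint evolution of ``n`` states, returning snapshots at checkpoints.

    All members share one RNG stream (one standard-normal vector per step),
    so this is the memory-light route to marginal distributions at a few
    times — e.g. for comparison with the Fokker-Planck solution — rather
    than to per-member paths.  Returns an array of shape
    ``(len(checkpoint_times), n)``.
    """
    _check_coverage(config, latent)
    checkpoint_times = np.asarray(checkpoint_times, dtype=float)
    nsteps = int(round(config.duration / config.dt))
    t = np.arange(nsteps + 1) * config.dt
    a, b, c = coefficients_over_time(t[:-1], latent, lmap, h)
    ck_idx = np.rint(checkpoint_times / config.dt).astype(int)
    if np.any(ck_idx < 0) or np.any(ck_idx > nsteps):
        raise ValueError("checkpoint times outside the simulated interval")
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(2.0 * config.D * config.dt)
    x = np.full(n, config.x0, dtype=float)
    snaps = np.empty((len(ck_idx), n))
    order = np.argsort(ck_idx)
    step = 0
    next_idx = 0
    sorted_idx = ck_idx[order]
    if len(sorted_idx) and sorted_idx[0] == 0:
        raise ValueError("checkpoints must be after t = 0")
    while step < nsteps:
        stop = min(step + block, nsteps)
        # stop the block early at the next checkpoint
        while next_idx < len(sorted_idx) and sorted_idx[next_idx] <= step:
            next_idx += 1
        if next_idx < len(sorted_idx):
            stop = min(stop, int(sorted_idx[next_idx]))
        z = rng.standard_normal((stop - step, n))
        _em_ensemble_step_block(
            x, a[step:stop], b[step:stop], c[step:stop], z, config.dt, sigma
        )
        step = stop
        while next_idx < len(sorted_idx) and sorted_idx[next_idx] == step:
            snaps[order[next_idx]] = x
            next_idx += 1
    if not np.all(np.isfinite(x)):
        raise IntegrationError("one or more ensemble members diverged")
    return snaps


def align_on_unstable_crossing(
    traj: Trajectory,
    coeffs_over_time: tuple[np.ndarray, np.ndarray, np.ndarray],
    settling_margin: float = 5.0,
) -> float:
    """First downward crossing of the instantaneous unstable point.

    A crossing is accepted only after the state has resided in the active
    (upper) basin continuously for at least ``settling_margin`` seconds, so
    each realization of an event-locked scenario contributes exactly one
    stamp even when noise produces brief re-crossings.  Detection is
    suspended while the landscape is monostable (the unstable point does not
    exist there) and resumes when bistability reappears.

    Returns the crossing time (s).  Raises :class:`NoCrossingError` when the
    landscape is never bistable or the state never crosses.
    """
    a, b, c = coeffs_over_time
    _, x_un, _ = fixed_points_over_time(a, b, c)
    x = traj.x
    dt = traj.dt
    need = int(round(settling_margin / dt))
    m = min(len(x_un), len(x) - 1)
    run = 0
    any_bistable = False
    for i in range(m):
        if np.isnan(x_un[i]):
            run = 0
            continue
        any_bistable = True
        if x[i] > x_un[i]:
            run += 1
            if run >= need and i + 1 < len(x):
                nxt_un = x_un[i + 1] if i + 1 < m and not np.isnan(x_un[i + 1]) else x_un[i]
                if x[i + 1] <= nxt_un:
                    return float(traj.t[i + 1])
        else:
            run = 0
    if not any_bistable:
        raise NoCrossingError("the landscape is never bistable")
    raise NoCrossingError("no accepted downward crossing of the unstable point")
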