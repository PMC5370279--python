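"""Ground-truthed synthetic sessions and distribution samples.

No public recordings of the behavioral series exist, so every stage of the
pipeline is exercised against synthetic data whose ground truth is known by
construction: a slow Ornstein-Uhlenbeck latent trajectory drives the
Langevin model, the true transition times are defined from the *noise-free*
basin membership of the simulated state (which side of the instantaneous
unstable point it is on, debounced with a 1 s refractory), and a movement
channel is derived from that membership so the segmentation stage is
exercised nontrivially (1 s smoothing plus Gaussian observation noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .config import ModelParams
from .latent import LatentTrajectory
from .rtd import sample_stretched_exponential
from .sde import (
    SdeConfig,
    Trajectory,
    coefficients_over_time,
    fixed_points_over_time,
    simulate,
)
from .segmentation import TransitionSet, smooth_signal

__all__ = [
    "SessionTruth",
    "SyntheticSession",
    "TemplateStateSpec",
    "generate_latent_ou",
    "generate_session",
    "generate_template_states",
    "sample_stretched_exponential",
]

#: Refractory period (s) for the ground-truth basin-membership debounce.
TRUTH_REFRACTORY = 1.0
#: Observation noise on the synthetic movement channel: small enough that
#: its histogram is cleanly bimodal, large enough that detection is
#: nontrivial.
MOVEMENT_NOISE_SD = 0.05


@dataclass(frozen=True)
class SessionTruth:
    """Everything the generator knows that an analyst would not."""

    latent: LatentTrajectory
    params: ModelParams
    transitions: TransitionSet
    seed: int
    s_at_onset: np.ndarray
    d_at_onset: np.ndarray
    a_at_onset: np.ndarray


@dataclass(frozen=True)
class SyntheticSession:
    """A synthetic recording: co-registered signal and movement channels."""

    t: np.ndarray
    eodr: np.ndarray
    movement: np.ndarray
    truth: SessionTruth


@dataclass(frozen=True)
class TemplateStateSpec:
    """Exactly realizable feature targets for one template active state."""

    f1: float
    f2: float
    f5: float
    f4: float = 0.0


def generate_latent_ou(
    tau: float,
    bounds: tuple[float, float],
    duration: float,
    dt: float = 1.0,
    seed: int = 0,
    sigma: float = 2.0,
) -> LatentTrajectory:
    """Slow mean-reverting latent trajectory squashed onto ``bounds``.

    An Ornstein-Uhlenbeck process with correlation time ``tau`` and
    stationary standard deviation ``sigma`` (exact discrete update, drawn
    from its stationary law at t = 0) is mapped through its own Gaussian
    CDF onto the requested interval (a Gaussian copula): the marginal is
    uniform on ``bounds``, so the latent traverses its full range — the
    range endpoints anchor the affine latent-to-shape map — while the
    monotone map attenuates the autocorrelation by only a few percent
    ((6/pi) arcsin(rho/2) vs rho).  ``sigma = 0`` gives a constant
    trajectory at the interval midpoint.
    """
    if tau <= dt:
        raise ValueError(f"latent correlation time tau={tau} must exceed dt={dt}")
    lo, hi = bounds
    if not hi > lo:
        raise ValueError("bounds must be increasing")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)
    z = np.empty(n)
    if sigma == 0:
        z[:] = 0.0
    else:
        rho = np.exp(-dt / tau)
        innov_sd = sigma * np.sqrt(1.0 - rho * rho)
        z[0] = rng.normal(0.0, sigma)
        noise = rng.standard_normal(n - 1) * innov_sd
        for i in range(1, n):
            z[i] = rho * z[i - 1] + noise[i - 1]
    if sigma == 0:
        s = np.full(n, 0.5 * (lo + hi))
    else:
        s = lo + (hi - lo) * ndtr(z / sigma)
    return LatentTrajectory(t=t, s=s, provenance="synthetic")


def _session_coefficients(
    times: np.ndarray, latent: LatentTrajectory, params: ModelParams
):
    """Coefficient arrays over time; a constant latent uses the midpoint shape."""
    if latent.s_max > latent.s_min:
        lmap = params.latent_map(latent)
        return coefficients_over_time(times, latent, lmap, params.h)
    a = np.full(len(times), params.mid_tilt)
    d = params.mid_separation
    b = np.full(len(times), 2.0 * params.h / d**2)
    c = np.full(len(times), -params.h / d**4)
    return a, b, c


def _truth_transitions(
    t: np.ndarray, x: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> TransitionSet:
    """Ground-truth transitions from noise-free basin membership.

    Membership is the side of the instantaneous unstable point the state
    sits on; during monostable phases it is the basin of the surviving
    stable point.  Membership changes shorter than the 1 s refractory are
    discarded, then leading/trailing incomplete states are trimmed so the
    stamps strictly alternate starting with an onset.
    """
    x_lo, x_un, x_hi = fixed_points_over_time(a, b, c)
    m = min(len(x), len(x_un))
    threshold = np.where(np.isnan(x_un[:m]), np.nan, x_un[:m])
    active = np.empty(m, dtype=bool)
    bistable = ~np.isnan(threshold)
    active[bistable] = x[:m][bistable] > threshold[bistable]
    mono = ~bistable
    # monostable: the surviving stable point defines the basin
    active[mono] = ~np.isnan(x_hi[:m][mono])

    dt = t[1] - t[0]
    n_refr = max(1, int(round(TRUTH_REFRACTORY / dt)))
    # run-length segments of the membership sequence
    change = np.flatnonzero(np.diff(active)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [m]])
    onsets: list[float] = []
    offsets: list[float] = []
    current: bool | None = None
    for s0, e0 in zip(starts, ends):
        state = bool(active[s0])
        if e0 - s0 < n_refr and current is not None:
            continue  # too brief: refractory swallows it
        if current is None:
            current = state
            continue
        if state != current:
            (onsets if state else offsets).append(float(t[s0]))
            current = state
    # trim to alternation starting with an onset
    if offsets and (not onsets or offsets[0] < onsets[0]):
        offsets = offsets[1:]
    k = min(len(onsets), len(offsets))
    return TransitionSet(onsets=np.array(onsets[:k]), offsets=np.array(offsets[:k]))


def generate_session(
    params: ModelParams, latent: LatentTrajectory, seed: int = 0
) -> SyntheticSession:
    """Full synthetic session: signal, movement channel, and ground truth."""
    duration = float(latent.t[-1])
    config = SdeConfig(
        D=params.D, duration=duration, x0=0.0, dt=params.dt, seed=seed
    )
    traj = simulate_with_coeffs(config, latent, params)
    a, b, c = _session_coefficients(traj.t, latent, params)
    transitions = _truth_transitions(traj.t, traj.x, a, b, c)

    # movement channel: debounced membership indicator, smoothed, plus noise
    indicator = np.zeros(len(traj.t))
    for onset, offset in zip(transitions.onsets, transitions.offsets):
        i0 = int(round(onset / params.dt))
        i1 = int(round(offset / params.dt))
        indicator[i0:i1] = 1.0
    movement = smooth_signal(indicator, params.dt, window=1.0)
    rng = np.random.default_rng(seed + 1_000_003)
    movement = movement + rng.normal(0.0, MOVEMENT_NOISE_SD, size=len(movement))

    s_on = latent.sample_nearest(transitions.onsets) if len(transitions) else np.array([])
    if latent.s_max > latent.s_min:
        lmap = params.latent_map(latent)
        d_on = np.asarray(lmap.separation(s_on), dtype=float)
        a_on = np.asarray(lmap.tilt(s_on), dtype=float)
    else:
        d_on = np.full(len(s_on), params.mid_separation)
        a_on = np.full(len(s_on), params.mid_tilt)

    truth = SessionTruth(
        latent=latent,
        params=params,
        transitions=transitions,
        seed=seed,
        s_at_onset=np.asarray(s_on, dtype=float),
        d_at_onset=d_on,
        a_at_onset=a_on,
    )
    return SyntheticSession(t=traj.t, eodr=traj.x, movement=movement, truth=truth)


def simulate_with_coeffs(
    config: SdeConfig, latent: LatentTrajectory, params: ModelParams
) -> Trajectory:
    """Langevin run under a session parameter set (handles constant latents)."""
    if latent.s_max > latent.s_min:
        return simulate(config, latent, params.latent_map(latent), params.h)
    # constant latent: freeze the midpoint shape via a trivially flat map
    from .sde import _em_loop  # reuse the integrator kernel

    if not latent.covers(config.duration):
        from .sde import LatentCoverageError

        raise LatentCoverageError("latent trajectory does not cover the run")
    n = int(round(config.duration / config.dt))
    t = np.arange(n + 1) * config.dt
    a, b, c = _session_coefficients(t[:-1], latent, params)
    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal(n)
    sigma = np.sqrt(2.0 * config.D * config.dt)
    x, bad = _em_loop(config.x0, a, b, c, z, config.dt, sigma)
    if bad >= 0:
        from .sde import IntegrationError

        raise IntegrationError(f"state diverged at step {bad + 1}")
    return Trajectory(t=t, x=x)


def generate_template_states(
    specs: list[TemplateStateSpec],
    dt: float = 0.01,
    lead_in: float = 40.0,
    gap: float = 40.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, TransitionSet]:
    """Piecewise signal whose extracted features equal the targets exactly.

    Each state is a boxcar of height f1 lasting f2 seconds followed by a
    linear decay back to baseline over f5 seconds; a nonzero f4 target adds
    a seeded, state-demeaned perturbation of the specified variance.
    Returns ``(t, signal, transitions)``.
    """
    rng = np.random.default_rng(seed)
    for spec in specs:
        if spec.f2 <= 0 or spec.f5 < 0 or spec.f4 < 0:
            raise ValueError("inconsistent template targets")
        if spec.f2 < 30.0:
            raise ValueError(
                "template states must last at least the 30 s onset window "
                "for f1 to be exactly realizable"
            )
    total = lead_in + sum(s.f2 + s.f5 + gap for s in specs)
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt
    x = np.zeros(n)
    onsets, offsets = [], []
    cursor = lead_in
    for spec in specs:
        onset = round(cursor / dt) * dt
        offset = onset + spec.f2
        i0, i1 = int(round(onset / dt)), int(round(offset / dt))
        x[i0:i1] = spec.f1
        if spec.f4 > 0:
            noise = rng.standard_normal(i1 - i0)
            noise -= noise.mean()
            noise *= np.sqrt(spec.f4) / noise.std()
            x[i0:i1] += noise
        # linear decay hitting baseline exactly at offset + f5
        if spec.f5 > 0:
            i2 = int(round((offset + spec.f5) / dt))
            ramp = np.linspace(spec.f1, 0.0, i2 - i1 + 1)[:-1]
            x[i1:i2] = ramp
        onsets.append(onset)
        offsets.append(offset)
        cursor = offset + spec.f5 + gap
    return t, x, TransitionSet(onsets=np.array(onsets), offsets=np.array(offsets))
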