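"""The slow latent forcing s(t).

The latent variable is the slow (~1000 s) process that tilts the double-well
landscape and thereby modulates the switching rates.  It is never observed
directly; it is either *estimated* from data by heavy moving-average
filtering, *prescribed* as a linear decay for short event-locked scenarios,
or generated *synthetically* with known ground truth (see
:mod:`statewell.synthetic`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LatentTrajectory", "estimate_latent", "linear_latent"]


@dataclass(frozen=True)
class LatentTrajectory:
    """A sampled latent trajectory s(t).

    Attributes
    ----------
    t, s : ndarray
        Times (s) and latent values (rescaled-signal units), same length.
    provenance : str
        One of ``"estimated"``, ``"linear"``, ``"synthetic"``.
    window : float or None
        Averaging window (s) when estimated.
    slope : float or None
        Decay slope (1/s) when linear.
    """

    t: np.ndarray
    s: np.ndarray
    provenance: str = "synthetic"
    window: float | None = None
    slope: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        s = np.asarray(self.s, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("t and s must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise ValueError("latent trajectory contains non-finite values")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "s", s)

    @property
    def s_min(self) -> float:
        return float(self.s.min())

    @property
    def s_max(self) -> float:
        return float(self.s.max())

    def sample_nearest(self, times) -> np.ndarray:
        """Latent values at the nearest sampled time points (no interpolation).

        The latent varies on ~1000 s scales, so nearest-neighbor lookup at
        simulation resolution is exact for all practical purposes and keeps
        runs bitwise reproducible.
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.t, times)
        idx = np.clip(idx, 1, len(self.t) - 1)
        left = self.t[idx - 1]
        right = self.t[idx]
        idx = np.where(times - left <= right - times, idx - 1, idx)
        return self.s[idx]

    def covers(self, duration: float) -> bool:
        return self.t[0] <= 0.0 and self.t[-1] >= duration


def estimate_latent(
    t: np.ndarray,
    eodr: np.ndarray,
    mean_active: float,
    mean_inactive: float,
) -> LatentTrajectory:
    """Estimate s(t) as a heavy centered moving average of the signal.

    The window is W = 4 (<T_act> + <T_inact>), four times the sum of the mean
    active and inactive residence times: large enough that a change in the
    filtered signal reflects a sustained deviation of the state durations
    from their averages, i.e. a change in the tilt of the landscape.  Edges
    use shrinking windows (no padding) so the endpoint extrema of s(t) are
    not biased toward the interior mean.

    Parameters
    ----------
    t, eodr : ndarray
        Uniformly sampled time base (s) and signal.
    mean_active, mean_inactive : float
        Mean residence times (s) of the two states; both must be positive.
    """
    if not (mean_active > 0 and mean_inactive > 0):
        raise ValueError("mean residence times must be positive")
    t = np.asarray(t, dtype=float)
    x = np.asarray(eodr, dtype=float)
    dt = t[1] - t[0]
    window = 4.0 * (mean_active + mean_inactive)
    n_win = int(round(window / dt))
    if n_win > len(x):
        raise ValueError(
            f"averaging window {window} s ({n_win} samples) exceeds the "
            f"series length ({len(x)} samples)"
        )
    s = (
        pd.Series(x)
        .rolling(n_win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return LatentTrajectory(t=t, s=s, provenance="estimated", window=window)


def linear_latent(
    slope: float,
    duration: float,
    dt: float,
    intercept: float = 0.0,
) -> LatentTrajectory:
    """Prescribed linear decay s(t) = intercept + slope * t on [0, duration].

    Used for short event-locked scenarios where the landscape tilts at a
    constant rate.  The y-intercept is arbitrary: only the affine rescaling
    of s(t) into tilt and separation matters, and that is anchored to the
    trajectory's own extrema.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    return LatentTrajectory(
        t=t, s=intercept + slope * t, provenance="linear", slope=slope
    )
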