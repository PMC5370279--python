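"""Hysteresis segmentation of a bimodal behavioral series.

A bimodal signal (movement variable or rescaled sensing-rate) is split into
alternating active/inactive states with a two-threshold Schmitt trigger:
the histogram of the signal supplies a local minimum flanked by two local
maxima, and the two thresholds are the halfway points between the minimum
and each maximum.  An upward crossing of the upper threshold marks a
movement onset, a downward crossing of the lower threshold a movement
offset; hysteresis guarantees the detected events strictly alternate no
matter how noisy the signal is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "TransitionSet",
    "HysteresisThresholds",
    "BimodalityError",
    "derive_thresholds",
    "rescale_eodr",
    "smooth_signal",
    "detect_transitions",
    "residence_times",
]

#: Histogram settings for threshold derivation: equal-width bins and a short
#: moving average over the counts, making extremum search robust to binning
#: noise.
HIST_BINS = 100
HIST_SMOOTH = 5


class BimodalityError(ValueError):
    """The signal's histogram does not show two separated modes."""


@dataclass(frozen=True)
class HysteresisThresholds:
    """Schmitt-trigger thresholds derived from the signal histogram."""

    lower: float
    upper: float
    hist_min: float
    hist_max_lo: float
    hist_max_hi: float


@dataclass(frozen=True)
class TransitionSet:
    """Alternating movement onset/offset time stamps (s).

    Invariant: onsets[i] < offsets[i] < onsets[i+1]; equal lengths.
    """

    onsets: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        offsets = np.asarray(self.offsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "offsets", offsets)
        if len(onsets) != len(offsets):
            raise ValueError("onsets and offsets must pair up")
        if len(onsets):
            merged = np.empty(2 * len(onsets))
            merged[0::2] = onsets
            merged[1::2] = offsets
            if np.any(np.diff(merged) <= 0):
                raise ValueError("events do not strictly alternate onset < offset < next onset")

    def __len__(self) -> int:
        return len(self.onsets)


def derive_thresholds(signal: np.ndarray) -> HysteresisThresholds:
    """Two-threshold hysteresis levels from the (raw) signal histogram."""
    signal = np.asarray(signal, dtype=float)
    counts, edges = np.histogram(signal, bins=HIST_BINS)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = uniform_filter1d(counts.astype(float), HIST_SMOOTH, mode="nearest")
    # local maxima of the smoothed counts
    interior = np.arange(1, HIST_BINS - 1)
    is_max = (smooth[interior] >= smooth[interior - 1]) & (
        smooth[interior] > smooth[interior + 1]
    )
    maxima = interior[is_max]
    # include the plateau-safe endpoints
    if smooth[0] > smooth[1]:
        maxima = np.concatenate([[0], maxima])
    if smooth[-1] > smooth[-2]:
        maxima = np.concatenate([maxima, [HIST_BINS - 1]])
    if len(maxima) < 2:
        raise BimodalityError("signal histogram is not bimodal")
    # the two most populated maxima, kept in location order
    top2 = maxima[np.argsort(smooth[maxima])][-2:]
    i_lo, i_hi = int(top2.min()), int(top2.max())
    if i_lo == i_hi:
        raise BimodalityError("signal histogram is not bimodal")
    i_min = i_lo + int(np.argmin(smooth[i_lo : i_hi + 1]))
    hist_min = float(centers[i_min])
    hist_max_lo = float(centers[i_lo])
    hist_max_hi = float(centers[i_hi])
    return HysteresisThresholds(
        lower=0.5 * (hist_min + hist_max_lo),
        upper=0.5 * (hist_min + hist_max_hi),
        hist_min=hist_min,
        hist_max_lo=hist_max_lo,
        hist_max_hi=hist_max_hi,
    )


def rescale_eodr(raw: np.ndarray, active_mask: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Affine rescale sending the inactive median to 0 and the active median to 1.

    ``active_mask`` is a provisional per-sample active/inactive labeling
    (e.g. from segmenting the movement channel).  Returns the rescaled
    series and the ``(offset, scale)`` of the map v -> (v - offset)/scale.
    """
    raw = np.asarray(raw, dtype=float)
    active_mask = np.asarray(active_mask, dtype=bool)
    if active_mask.shape != raw.shape:
        raise ValueError("labels must match the series shape")
    if active_mask.all() or not active_mask.any():
        raise ValueError("both active and inactive samples are required")
    med_inactive = float(np.median(raw[~active_mask]))
    med_active = float(np.median(raw[active_mask]))
    scale = med_active - med_inactive
    if scale == 0:
        raise ValueError("degenerate rescale: active and inactive medians are equal")
    return (raw - med_inactive) / scale, (med_inactive, scale)


def smooth_signal(signal: np.ndarray, dt: float, window: float = 1.0) -> np.ndarray:
    """Centered moving-average filter (symmetric window, default 1 s).

    A centered window avoids the systematic lag a causal filter would add
    to every transition stamp.
    """
    n_win = max(1, int(round(window / dt)))
    return uniform_filter1d(np.asarray(signal, dtype=float), n_win, mode="nearest")


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t1
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_transitions(
    t: np.ndarray,
    signal: np.ndarray,
    smooth_window: float = 1.0,
    thresholds: HysteresisThresholds | None = None,
) -> TransitionSet:
    """Schmitt-trigger transition detection on a bimodal series.

    Thresholds are derived from the *raw* signal histogram; crossings are
    evaluated on the moving-average-filtered signal, with sub-sample linear
    interpolation of the crossing times.  Leading and trailing incomplete
    states are discarded so the result strictly alternates starting with an
    onset.  A signal with no crossings yields an empty set (bimodality of
    the histogram is still required).
    """
    t = np.asarray(t, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if thresholds is None:
        thresholds = derive_thresholds(signal)
    dt = t[1] - t[0]
    sm = smooth_signal(signal, dt, smooth_window)

    hi, lo = thresholds.upper, thresholds.lower
    above_hi = sm >= hi
    below_lo = sm <= lo

    # candidate crossings, then an alternation sweep over the (few) candidates
    up_idx = np.nonzero(above_hi[1:] & ~above_hi[:-1])[0] + 1
    down_idx = np.nonzero(below_lo[1:] & ~below_lo[:-1])[0] + 1
    events = sorted(
        [(int(i), True) for i in up_idx] + [(int(i), False) for i in down_idx]
    )

    onsets: list[float] = []
    offsets: list[float] = []
    # state: True = active (last threshold crossed was upper), None = unknown
    state: bool | None = True if above_hi[0] else (False if below_lo[0] else None)
    for i, is_up in events:
        if is_up and state is not True:
            onsets.append(_interp_crossing(t[i - 1], t[i], sm[i - 1], sm[i], hi))
            state = True
        elif not is_up and state is not False:
            if state is True and onsets:
                offsets.append(
                    _interp_crossing(t[i - 1], t[i], sm[i - 1], sm[i], lo)
                )
            state = False

    k = min(len(onsets), len(offsets))
    return TransitionSet(onsets=np.array(onsets[:k]), offsets=np.array(offsets[:k]))


def residence_times(ts: TransitionSet) -> tuple[np.ndarray, np.ndarray]:
    """Active and inactive state durations (s) from an alternating set.

    active_i = offset_i - onset_i; inactive_i = onset_{i+1} - offset_i.
    """
    active = ts.offsets - ts.onsets
    inactive = ts.onsets[1:] - ts.offsets[:-1]
    return active, inactive
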