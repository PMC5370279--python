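"""Geometric features of active states, PCA reduction, and shape groups.

Each active state (segment between a movement onset and the following
offset) is summarized by five features:

* f1 — transition amplitude: mean signal over the 30 s after onset minus a
  pre-onset baseline (mean over [onset-30 s, onset-5 s]; the last 5 s
  before onset are excluded because of the short preparatory rise of the
  signal ahead of the transition),
* f2 — state duration (s),
* f3 — mean signal over the state,
* f4 — variance of the linearly detrended signal over the state,
* f5 — decay duration: time after offset for the signal to return to the
  pre-onset baseline, capped at the next onset.

PCA over the standardized features orders states along a single axis (PC1)
by geometric similarity; five overlapping groups of 20 states each sample
that axis from the extreme shapes down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .segmentation import TransitionSet

__all__ = [
    "StateFeatures",
    "PcaResult",
    "GroupAssignment",
    "extract_features",
    "extract_all_features",
    "features_matrix",
    "pca_over_features",
    "define_groups",
    "group_average_trace",
]

#: Feature-window durations (s): onset/baseline averaging windows and the
#: pre-onset exclusion for the preparatory ramp.
ONSET_WINDOW = 30.0
BASELINE_EXCLUDE = 5.0

GROUP_SIZE = 20
#: Relative PC1 thresholds (fractions of max PC1) anchoring groups 2-4.
GROUP_FRACTIONS = (4.0 / 5.0, 3.0 / 5.0, 1.0 / 6.0)


@dataclass(frozen=True)
class StateFeatures:
    """The five geometric features of one active state, plus its stamps."""

    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    onset: float
    offset: float
    f5_capped: bool = False


@dataclass(frozen=True)
class PcaResult:
    loadings: np.ndarray  # (n_components, 5), unit rows
    scores: np.ndarray  # (n_states, n_components)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray


@dataclass(frozen=True)
class GroupAssignment:
    """Member-state indices per shape group 1..5 (20 each; may overlap)."""

    groups: tuple[np.ndarray, ...]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.groups[i]


def _window_slice(t, lo, hi):
    i0, i1 = np.searchsorted(t, [lo, hi], side="left")
    if i1 <= i0:
        raise ValueError(f"no samples in window [{lo}, {hi}] s")
    return i0, i1


def _window_mean(t, x, lo, hi):
    i0, i1 = _window_slice(t, lo, hi)
    return float(x[i0:i1].mean())


def extract_features(
    t: np.ndarray,
    eodr: np.ndarray,
    onset: float,
    offset: float,
    next_onset: float | None = None,
    prev_offset: float | None = None,
) -> StateFeatures:
    """Five geometric features of the active state [onset, offset].

    Requires 30 s of pre-onset history (window error otherwise).  When the
    signal never returns to baseline before the next onset, f5 is capped at
    ``next_onset - offset`` and flagged.  When the preceding inactive gap is
    shorter than the baseline window, the window is clipped at
    ``prev_offset`` so the baseline measures the inactive level only (an
    unclipped window would fold the previous active state into the
    baseline, corrupting f1 exactly when states follow each other closely).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(eodr, dtype=float)
    if not offset > onset:
        raise ValueError("offset must follow onset")
    if onset - ONSET_WINDOW < t[0]:
        raise ValueError(
            f"insufficient pre-onset history: need {ONSET_WINDOW} s before "
            f"onset at {onset} s"
        )
    base_lo = onset - ONSET_WINDOW
    if prev_offset is not None:
        base_lo = max(base_lo, prev_offset)
    if base_lo >= onset - BASELINE_EXCLUDE:
        raise ValueError(
            f"no usable baseline window before onset at {onset} s "
            f"(preceding inactive gap shorter than {BASELINE_EXCLUDE} s)"
        )
    baseline = _window_mean(t, x, base_lo, onset - BASELINE_EXCLUDE)
    # amplitude window is capped at the state's end: averaging past the
    # offset would fold the following inactive period into the amplitude of
    # any state shorter than the window, mechanically coupling f1 to f2
    f1 = _window_mean(t, x, onset, min(onset + ONSET_WINDOW, offset)) - baseline

    i0, i1 = _window_slice(t, onset, offset)
    xs = x[i0:i1]
    ts = t[i0:i1]
    f2 = offset - onset
    f3 = float(xs.mean())
    # variance of the least-squares linearly detrended signal
    resid = xs - np.polynomial.polynomial.polyval(
        ts - ts[0], np.polynomial.polynomial.polyfit(ts - ts[0], xs, 1)
    )
    f4 = float(resid.var())

    cap = (next_onset - offset) if next_onset is not None else (t[-1] - offset)
    j0, j1 = _window_slice(t, offset, offset + cap)
    xa = x[j0:j1]
    ta = t[j0:j1]
    returned = np.nonzero(xa <= baseline)[0]
    if len(returned):
        f5 = float(ta[returned[0]] - offset)
        capped = False
    else:
        f5 = float(cap)
        capped = True
    return StateFeatures(
        f1=f1, f2=f2, f3=f3, f4=f4, f5=f5, onset=onset, offset=offset,
        f5_capped=capped,
    )


def extract_all_features(
    t: np.ndarray, eodr: np.ndarray, transitions: TransitionSet
) -> list[StateFeatures]:
    """Features for every active state with sufficient pre-onset history."""
    out = []
    n = len(transitions)
    for i in range(n):
        onset = transitions.onsets[i]
        offset = transitions.offsets[i]
        next_onset = transitions.onsets[i + 1] if i + 1 < n else None
        prev_offset = transitions.offsets[i - 1] if i > 0 else None
        try:
            out.append(
                extract_features(t, eodr, onset, offset, next_onset, prev_offset)
            )
        except ValueError:
            continue  # no usable pre-onset history or baseline window
    return out


def features_matrix(features: list[StateFeatures]) -> np.ndarray:
    return np.array([[f.f1, f.f2, f.f3, f.f4, f.f5] for f in features])


def pca_over_features(features: np.ndarray) -> PcaResult:
    """PCA of the standardized (zero-mean, unit-variance) feature matrix.

    Standardizing first makes the decomposition correlation-based, which is
    the only sensible convention for features of wildly different units
    (amplitudes, seconds, variances).  PC1 is oriented so that the sum of
    its loadings is positive.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != 5:
        raise ValueError("expected an (n_states, 5) feature matrix")
    if features.shape[0] < 5:
        raise ValueError("need at least 5 states for a 5-feature PCA")
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    if np.any(scale == 0):
        bad = int(np.nonzero(scale == 0)[0][0]) + 1
        raise ValueError(f"feature f{bad} has zero variance; PCA is degenerate")
    z = (features - mean) / scale
    pca = PCA(n_components=5, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.copy()
    flip = np.where(loadings.sum(axis=1) < 0, -1.0, 1.0)
    loadings *= flip[:, None]
    scores = scores * flip[None, :]
    return PcaResult(
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=mean,
        scale=scale,
    )


def define_groups(scores: np.ndarray, group_size: int = GROUP_SIZE) -> GroupAssignment:
    """Five shape groups of ``group_size`` states along the PC1 axis.

    Group 1 holds the highest-scoring states and group 5 the lowest;
    groups 2-4 hold the ``group_size`` lowest-scoring states at or above
    4/5, 3/5 and 1/6 of the maximum PC1 score.  Groups may overlap.  When
    fewer than ``group_size`` states clear a threshold, the group is topped
    up with the highest-scoring states below it (with exactly
    ``group_size`` states every group is the full set).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < group_size:
        raise ValueError(f"need at least {group_size} states, got {n}")
    smax = scores.max()
    if smax <= 0:
        raise ValueError("maximum PC1 score must be positive to anchor group thresholds")
    order = np.argsort(scores)
    group1 = order[-group_size:]
    group5 = order[:group_size]
    mids = []
    for frac in GROUP_FRACTIONS:
        n_below = int(np.searchsorted(scores[order], frac * smax, side="left"))
        start = min(n_below, n - group_size)
        mids.append(order[start : start + group_size])
    return GroupAssignment(groups=(group1, mids[0], mids[1], mids[2], group5))


def group_average_trace(
    t: np.ndarray,
    eodr: np.ndarray,
    features: list[StateFeatures],
    members: np.ndarray,
    align_on: str = "onset",
    window: tuple[float, float] = (-50.0, 250.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-aligned traces of a group's states and their pointwise mean.

    Traces are extracted on a common relative-time window around each
    member's onset or offset stamp.  States whose window leaves the
    recording are excluded pointwise (missing samples do not drag the
    mean).  Returns ``(rel_time, mean_trace, traces)`` where ``traces`` has
    one row per member with NaN for missing samples.
    """
    if align_on not in ("onset", "offset"):
        raise ValueError("align_on must be 'onset' or 'offset'")
    if len(members) == 0:
        raise ValueError("empty group")
    t = np.asarray(t, dtype=float)
    x = np.asarray(eodr, dtype=float)
    dt = t[1] - t[0]
    rel = np.arange(window[0], window[1] + dt / 2, dt)
    traces = np.full((len(members), len(rel)), np.nan)
    for row, idx in enumerate(members):
        stamp = getattr(features[int(idx)], align_on)
        sample_t = stamp + rel
        pos = np.rint((sample_t - t[0]) / dt).astype(int)
        valid = (pos >= 0) & (pos < len(x))
        traces[row, valid] = x[pos[valid]]
    present = ~np.isnan(traces)
    counts = present.sum(axis=0)
    sums = np.where(present, traces, 0.0).sum(axis=0)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return rel, mean, traces
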