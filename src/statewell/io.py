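"""Plain-text time-series and table I/O.

All exchange formats are delimited text at desk scale: two-column series
(time in seconds from session start, value at the timestamp), transition
tables, and density matrices with a one-line header carrying the x grid.
Lines beginning with ``#`` are comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fokker_planck import PdfGrid
from .segmentation import TransitionSet

__all__ = [
    "TimeSeriesFormatError",
    "read_timeseries",
    "write_timeseries",
    "read_transitions",
    "write_transitions",
    "write_density",
    "write_metadata",
]

#: Allowed relative deviation of sample spacing from the nominal dt.
UNIFORMITY_RTOL = 1e-6


class TimeSeriesFormatError(ValueError):
    pass


def read_timeseries(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (time_s, value) delimited text series.

    Comments ('#') are skipped and a single non-numeric header line is
    allowed.  Time must be strictly increasing and uniformly sampled (max
    spacing deviation below 1e-6 of dt); violations raise
    :class:`TimeSeriesFormatError` naming the offending row.
    """
    rows: list[tuple[float, float]] = []
    lineno_of_row: list[int] = []
    header_skipped = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise TimeSeriesFormatError(
                    f"{path}:{ln}: expected two columns, got {len(parts)}"
                )
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if not header_skipped and not rows:
                    header_skipped = True
                    continue
                raise TimeSeriesFormatError(
                    f"{path}:{ln}: non-numeric values {parts!r}"
                ) from None
            lineno_of_row.append(ln)
    if len(rows) < 2:
        raise TimeSeriesFormatError(f"{path}: need at least two samples")
    t = np.array([r[0] for r in rows])
    x = np.array([r[1] for r in rows])
    d = np.diff(t)
    bad = np.nonzero(d <= 0)[0]
    if len(bad):
        raise TimeSeriesFormatError(
            f"{path}:{lineno_of_row[int(bad[0]) + 1]}: time is not strictly increasing"
        )
    dt = float(np.median(d))
    dev = np.abs(d - dt)
    bad = np.nonzero(dev > UNIFORMITY_RTOL * dt)[0]
    if len(bad):
        raise TimeSeriesFormatError(
            f"{path}:{lineno_of_row[int(bad[0]) + 1]}: non-uniform sampling "
            f"(spacing {d[int(bad[0])]:g} vs dt {dt:g})"
        )
    return t, x


def write_timeseries(path: str | Path, t: np.ndarray, x: np.ndarray) -> None:
    """Write a two-column series at full float precision (value round-trips)."""
    np.savetxt(
        path,
        np.column_stack([t, x]),
        fmt="%.17g",
        header="time_s\tvalue",
        delimiter="\t",
    )


def read_transitions(path: str | Path) -> TransitionSet:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return TransitionSet(onsets=np.array([]), offsets=np.array([]))
    return TransitionSet(onsets=data[:, 0], offsets=data[:, 1])


def write_transitions(path: str | Path, ts: TransitionSet) -> None:
    np.savetxt(
        path,
        np.column_stack([ts.onsets, ts.offsets]),
        fmt="%.17g",
        header="onset_s\toffset_s",
        delimiter="\t",
    )


def write_density(path: str | Path, pdf: PdfGrid) -> None:
    """Density matrix (rows = output times) with a one-line x-grid header."""
    header = "t_s\t" + "\t".join(f"{x:.10g}" for x in pdf.x_centers)
    body = np.column_stack([pdf.t, pdf.p])
    np.savetxt(path, body, fmt="%.10g", header=header, delimiter="\t")


def write_metadata(path: str | Path, **fields) -> None:
    """Sidecar metadata so every run is reproducible from it alone."""
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(fields, indent=2, default=_default) + "\n")
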