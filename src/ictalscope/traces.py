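"""Trace containers and CSV I/O.

A :class:`TraceMatrix` holds raw fluorescence (arbitrary units) on a uniform
time grid, one column per ROI (a brain region, a single glial cell, or the
whole brain).  A :class:`DffTrace` holds the derived ΔF/F₀ signal in percent
together with the baseline it was normalised against.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TraceMatrix", "DffTrace", "read_trace_csv", "write_trace_csv"]

#: relative tolerance for declaring the time grid uniform
GRID_RTOL = 1e-6


@dataclass
class TraceMatrix:
    """Raw fluorescence traces, time x ROI.

    Parameters
    ----------
    time : ndarray, shape (n,)
        Sample times in seconds, uniformly spaced.
    values : ndarray, shape (n, m)
        Raw fluorescence, arbitrary units, one column per ROI.
    sampling_rate : float
        Samples per second.
    roi_labels : list of str
        Column names.
    region_of : dict, optional
        Map from ROI label to anatomical region name.
    """

    time: np.ndarray
    values: np.ndarray
    sampling_rate: float
    roi_labels: list[str]
    region_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.values.shape[0] != self.time.shape[0]:
            raise ValueError("time and values row counts differ")
        if len(self.roi_labels) != self.values.shape[1]:
            raise ValueError("roi_labels must match value columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        self._check_grid()

    def _check_grid(self) -> None:
        if len(self.time) < 2:
            return
        dt = np.diff(self.time)
        expected = 1.0 / self.sampling_rate
        bad = np.nonzero(np.abs(dt - expected) > GRID_RTOL * max(expected, 1.0))[0]
        if bad.size:
            raise ValueError(
                f"non-uniform time grid: first offending row {bad[0] + 2} "
                f"(dt={dt[bad[0]]:g}, expected {expected:g})"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n samples / rate)."""
        return self.n_samples / self.sampling_rate

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"no ROI named {label!r}") from None
        return self.values[:, j]

    def copy(self) -> "TraceMatrix":
        return replace(
            self,
            time=self.time.copy(),
            values=self.values.copy(),
            roi_labels=list(self.roi_labels),
            region_of=dict(self.region_of) if self.region_of else None,
        )


@dataclass
class DffTrace:
    """ΔF/F₀ traces in percent, plus the baseline they were computed from.

    ``baseline`` is either a scalar per ROI (shape ``(m,)``, whole-trace
    percentile method) or a full baseline trace (shape ``(n, m)``,
    moving-window method).
    """

    time: np.ndarray
    dff: np.ndarray
    baseline: np.ndarray
    method: str
    sampling_rate: float
    roi_labels: list[str]
    region_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim == 1:
            self.dff = self.dff[:, None]
        self.baseline = np.asarray(self.baseline, dtype=float)
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff must be finite")
        if self.method not in ("whole_trace_percentile", "moving_window_percentile"):
            raise ValueError(f"unknown baseline method {self.method!r}")

    @property
    def n_samples(self) -> int:
        return self.dff.shape[0]

    @property
    def n_rois(self) -> int:
        return self.dff.shape[1]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.roi_labels.index(label)
        except ValueError:
            raise KeyError(f"no ROI named {label!r}") from None
        return self.dff[:, j]


def write_trace_csv(trace: TraceMatrix, path, metadata: dict | None = None) -> None:
    """Write a trace matrix as CSV: ``time_s`` column plus one column per ROI.

    Optional metadata is embedded as ``# key: value`` header comment lines so
    every output file self-describes the parameters that produced it.
    """
    buf = io.StringIO()
    meta = {"sampling_rate_hz": trace.sampling_rate}
    if metadata:
        meta.update(metadata)
    for k, v in meta.items():
        buf.write(f"# {k}: {v}\n")
    df = pd.DataFrame(trace.values, columns=trace.roi_labels)
    df.insert(0, "time_s", trace.time)
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_trace_csv(path, sampling_rate: float | None = None) -> TraceMatrix:
    """Read a trace matrix written by :func:`write_trace_csv`.

    The header row must contain ``time_s`` plus at least one ROI column.
    ``# key: value`` comment lines are parsed for the sampling rate; when the
    file carries none, the rate is inferred from the time grid (or taken from
    the ``sampling_rate`` argument).
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    n_comment = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_comment += 1
        body = line.lstrip("#").strip()
        if ":" in body:
            k, v = body.split(":", 1)
            meta[k.strip()] = v.strip()
    try:
        df = pd.read_csv(io.StringIO("\n".join(lines[n_comment:])))
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed trace CSV {path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    roi_cols = [c for c in df.columns if c != "time_s"]
    if not roi_cols:
        raise ValueError(f"{path}: no ROI columns")
    values = df[roi_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path}: non-numeric or non-finite cell at row {bad[0] + 2}, "
            f"column {roi_cols[bad[1]]!r}"
        )
    time = df["time_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        if "sampling_rate_hz" in meta:
            sampling_rate = float(meta["sampling_rate_hz"])
        elif len(time) >= 2:
            sampling_rate = 1.0 / float(np.median(np.diff(time)))
        else:
            raise ValueError(f"{path}: cannot infer sampling rate")
    return TraceMatrix(
        time=time, values=values, sampling_rate=sampling_rate, roi_labels=roi_cols
    )
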