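"""Baseline estimation, ΔF/F₀ computation and resampling.

Shared preprocessing for every imaging modality in the pipeline: F₀ is a low
percentile of the raw trace (whole-trace for regional neuronal imaging,
moving-window for glutamate/glial imaging), ΔF/F₀ = 100·(F − F₀)/F₀, and
traces are resampled with mean-decimation followed by shape-preserving
piecewise-cubic (pchip) interpolation.

Percentiles use the nearest-rank (lower) convention: the k-th smallest sample
with k = ceil(p·n).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.base import BaseEstimator, TransformerMixin

from .traces import DffTrace, TraceMatrix

__all__ = [
    "PercentileBaseline",
    "MovingWindowBaseline",
    "baseline_whole_trace",
    "baseline_moving_window",
    "compute_dff",
    "resample",
    "nearest_rank_percentile",
]

log = logging.getLogger(__name__)


def nearest_rank_percentile(x: np.ndarray, percentile: float) -> float:
    """Nearest-rank lower percentile: the ceil(p·n)-th smallest sample."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(percentile * n))
    k = min(max(k, 1), n)
    return float(np.partition(x, k - 1)[k - 1])


class PercentileBaseline(BaseEstimator, TransformerMixin):
    """Whole-trace percentile baseline, one scalar F₀ per ROI.

    The default 1st percentile of the entire trace is the standard choice for
    regional neuronal recordings, where seizures occupy a minority of samples
    and the dim tail of the distribution tracks resting fluorescence.

    Parameters
    ----------
    percentile : float in (0, 0.5)
        Fraction of samples below the returned baseline (nearest rank).

    Attributes
    ----------
    baseline_ : ndarray, shape (n_rois,)
        Estimated F₀ per ROI.
    """

    def __init__(self, percentile: float = 0.01):
        self.percentile = percentile

    def _validate(self) -> None:
        if not 0 < self.percentile < 0.5:
            raise ValueError("percentile must lie in (0, 0.5)")

    def fit(self, trace: TraceMatrix, y=None) -> "PercentileBaseline":
        self._validate()
        if trace.n_samples == 0:
            raise ValueError("empty trace")
        if trace.n_samples < 100:
            log.warning(
                "whole-trace percentile baseline on only %d samples", trace.n_samples
            )
        self.baseline_ = np.array(
            [
                nearest_rank_percentile(trace.values[:, j], self.percentile)
                for j in range(trace.n_rois)
            ]
        )
        return self

    def transform(self, trace: TraceMatrix) -> DffTrace:
        return compute_dff(trace, self.baseline_, method="whole_trace_percentile")


class MovingWindowBaseline(BaseEstimator, TransformerMixin):
    """Moving-window percentile baseline F₀(t) per ROI.

    The baseline is evaluated at anchors spaced ``step`` seconds apart as the
    nearest-rank ``percentile`` of the samples inside a centered window of
    ``window`` seconds (truncated at the recording edges), linearly
    interpolated to the full time grid and, by default, smoothed with a
    centered moving average of the same window length.  Traces shorter than
    the window fall back to the whole-trace percentile at every anchor.

    Attributes
    ----------
    baseline_ : ndarray, shape (n_samples, n_rois)
        Baseline trace per ROI.
    """

    def __init__(
        self,
        window: float = 80.0,
        percentile: float = 0.08,
        step: float = 1.0,
        smooth: bool = True,
    ):
        self.window = window
        self.percentile = percentile
        self.step = step
        self.smooth = smooth

    def fit(self, trace: TraceMatrix, y=None) -> "MovingWindowBaseline":
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if trace.duration < self.step:
            raise ValueError("trace shorter than anchor step")
        t = trace.time
        anchors = np.arange(t[0], t[-1] + 0.5 * self.step, self.step)
        anchors = anchors[anchors <= t[-1] + 1e-12]
        half = 0.5 * self.window
        short = trace.duration < self.window
        base = np.empty((trace.n_samples, trace.n_rois))
        for j in range(trace.n_rois):
            col = trace.values[:, j]
            if short:
                anchor_vals = np.full(
                    anchors.shape, nearest_rank_percentile(col, self.percentile)
                )
            else:
                anchor_vals = np.empty(anchors.shape)
                for i, ta in enumerate(anchors):
                    lo = np.searchsorted(t, ta - half, side="left")
                    hi = np.searchsorted(t, ta + half, side="right")
                    anchor_vals[i] = nearest_rank_percentile(
                        col[lo:hi], self.percentile
                    )
            interp = np.interp(t, anchors, anchor_vals)
            if self.smooth:
                interp = _moving_average(interp, int(round(self.window * trace.sampling_rate)))
            base[:, j] = interp
        self.baseline_ = base
        return self

    def transform(self, trace: TraceMatrix) -> DffTrace:
        return compute_dff(trace, self.baseline_, method="moving_window_percentile")


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge truncation (true local mean)."""
    width = min(max(width, 1), x.size)
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def baseline_whole_trace(trace: TraceMatrix, percentile: float = 0.01) -> np.ndarray:
    """F₀ per ROI as the whole-trace nearest-rank percentile."""
    return PercentileBaseline(percentile=percentile).fit(trace).baseline_


def baseline_moving_window(
    trace: TraceMatrix,
    window: float = 80.0,
    percentile: float = 0.08,
    step: float = 1.0,
    smooth: bool = True,
) -> np.ndarray:
    """F₀(t) per ROI from the moving-window percentile estimator."""
    est = MovingWindowBaseline(
        window=window, percentile=percentile, step=step, smooth=smooth
    )
    return est.fit(trace).baseline_


def compute_dff(
    trace: TraceMatrix,
    baseline: np.ndarray,
    method: str = "whole_trace_percentile",
) -> DffTrace:
    """ΔF/F₀ in percent: 100·(F − F₀)/F₀.

    ``baseline`` is either one scalar per ROI or a full (n, m) baseline trace.
    Raises if any baseline value used as a divisor is non-positive, naming the
    offending ROI.
    """
    baseline = np.asarray(baseline, dtype=float)
    F = trace.values
    if baseline.ndim == 1:
        if baseline.shape[0] != trace.n_rois:
            raise ValueError("baseline length must equal number of ROIs")
        bad = np.nonzero(baseline <= 0)[0]
        if bad.size:
            raise ValueError(
                f"non-positive baseline for ROI {trace.roi_labels[bad[0]]!r}"
            )
        dff = 100.0 * (F - baseline[None, :]) / baseline[None, :]
    else:
        if baseline.shape != F.shape:
            raise ValueError("baseline trace shape must match values")
        bad_cols = np.nonzero(np.any(baseline <= 0, axis=0))[0]
        if bad_cols.size:
            raise ValueError(
                f"non-positive baseline for ROI {trace.roi_labels[bad_cols[0]]!r}"
            )
        dff = 100.0 * (F - baseline) / baseline
    return DffTrace(
        time=trace.time.copy(),
        dff=dff,
        baseline=baseline,
        method=method,
        sampling_rate=trace.sampling_rate,
        roi_labels=list(trace.roi_labels),
        region_of=dict(trace.region_of) if trace.region_of else None,
    )


def resample(trace: TraceMatrix, target_rate: float) -> TraceMatrix:
    """Resample to ``target_rate`` (Hz).

    Downsampling first takes block means (anti-aliasing mean decimation by the
    integer factor closest to the rate ratio), then pchip-interpolates the
    block-center series onto the uniform target grid.  Upsampling
    pchip-interpolates directly; asking for more than 10× the source rate logs
    a warning.  Constant traces map to the same constant and the duration is
    preserved within one output sample.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    src = trace.sampling_rate
    if np.isclose(target_rate, src, rtol=1e-9):
        return trace.copy()
    if target_rate > 10 * src:
        log.warning(
            "upsampling %.4g Hz -> %.4g Hz exceeds 10x the source rate",
            src,
            target_rate,
        )
    n_out = max(int(round(trace.duration * target_rate)), 1)
    t_out = trace.time[0] + np.arange(n_out) / target_rate
    if target_rate < src:
        # decimate to ~2x the target rate: anti-aliases without flattening
        # features at the target band edge, pchip does the rest
        q = max(int(np.floor(src / (2.0 * target_rate))), 1)
        n_blocks = trace.n_samples // q
        trimmed = trace.values[: n_blocks * q]
        block_vals = trimmed.reshape(n_blocks, q, trace.n_rois).mean(axis=1)
        block_t = trace.time[: n_blocks * q].reshape(n_blocks, q).mean(axis=1)
        if n_blocks >= 2:
            out = PchipInterpolator(block_t, block_vals, axis=0, extrapolate=True)(t_out)
        else:
            out = np.repeat(block_vals, n_out, axis=0)
    else:
        out = PchipInterpolator(trace.time, trace.values, axis=0, extrapolate=True)(
            t_out
        )
    return TraceMatrix(
        time=t_out,
        values=out,
        sampling_rate=target_rate,
        roi_labels=list(trace.roi_labels),
        region_of=dict(trace.region_of) if trace.region_of else None,
    )
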