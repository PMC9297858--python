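"""Seizure detection, classification and propagation timing.

A seizure candidate is a maximal interval during which the reference-region
(midbrain) ΔF/F₀ stays above 50%.  A candidate is *global* when it recruits
all monitored regions including the anterior forebrain and lasts more than
one minute; otherwise it is *local*.  Propagation across regions is timed by
the half-maximum of each region's ictal transient (first upward crossing of
max(ΔF/F₀)/2, linearly interpolated), reported relative to the earliest
region, which defines the seizure origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .events import _as_1d, _find_runs
from .traces import DffTrace

__all__ = [
    "Seizure",
    "SeizureDetector",
    "detect_seizures",
    "classify_seizure",
    "propagation_halfmax",
    "basal_activity_sd",
    "pick_basal_windows",
    "glial_seizure_onset",
]

log = logging.getLogger(__name__)

#: fixed anatomical order used to break origin ties
REGION_ORDER = ("hindbrain", "midbrain", "anterior_forebrain")

#: duration (s) above which a forebrain-recruiting seizure counts as global
GLOBAL_MIN_DURATION = 60.0


@dataclass
class Seizure:
    """A classified ictal episode (times in s, half-open [onset, offset))."""

    onset: float
    offset: float
    recruited_regions: set[str] = field(default_factory=set)
    seizure_class: str = "local"
    origin: str | None = None
    halfmax_time: dict[str, float] = field(default_factory=dict)
    origin_tie: bool = False
    excluded_regions: set[str] = field(default_factory=set)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


class SeizureDetector(BaseEstimator):
    """Threshold-run seizure detector on regional ΔF/F₀ traces.

    ``fit`` runs detection and classification on a regional DffTrace and
    stores the result in ``seizures_``; ``predict`` returns that list.

    Parameters
    ----------
    reference_region : str
        Region whose trace defines seizure onset/offset.
    threshold : float
        ΔF/F₀ level (%): onset at the first sample strictly above it, offset
        at the first sample at or below it.
    merge_gap : float
        Supra-threshold runs separated by less than this many seconds merge
        into one candidate.
    lookahead : float
        Extra seconds after offset inspected for regional recruitment.
    min_peak_height : float
        Minimum regional peak (% ΔF/F₀) for the half-max propagation timing.
    """

    def __init__(
        self,
        reference_region: str = "midbrain",
        threshold: float = 50.0,
        merge_gap: float = 5.0,
        lookahead: float = 10.0,
        min_peak_height: float = 100.0,
    ):
        self.reference_region = reference_region
        self.threshold = threshold
        self.merge_gap = merge_gap
        self.lookahead = lookahead
        self.min_peak_height = min_peak_height

    def fit(self, region_dff: DffTrace, y=None) -> "SeizureDetector":
        candidates = detect_seizures(
            region_dff,
            reference_region=self.reference_region,
            threshold=self.threshold,
            merge_gap=self.merge_gap,
        )
        seizures = []
        for cand in candidates:
            sz = classify_seizure(
                cand, region_dff, threshold=self.threshold, lookahead=self.lookahead
            )
            if sz.seizure_class == "global":
                try:
                    propagation_halfmax(sz, region_dff, self.min_peak_height)
                except ValueError:
                    pass  # no region reached min peak height; timing left empty
            seizures.append(sz)
        self.seizures_ = seizures
        return self

    def predict(self, region_dff: DffTrace | None = None) -> list[Seizure]:
        if region_dff is not None:
            self.fit(region_dff)
        return self.seizures_


def _region_column(dff: DffTrace, region: str) -> np.ndarray:
    if region in dff.roi_labels:
        return dff.column(region)
    if dff.region_of:
        for roi, reg in dff.region_of.items():
            if reg == region and roi in dff.roi_labels:
                return dff.column(roi)
    raise KeyError(f"region {region!r} not present in trace")


def detect_seizures(
    region_dff: DffTrace,
    reference_region: str = "midbrain",
    threshold: float = 50.0,
    merge_gap: float = 5.0,
) -> list[tuple[float, float]]:
    """Candidate seizures as (onset, offset) pairs in seconds.

    Onset is the time of the first sample where the reference-region ΔF/F₀ is
    strictly greater than the threshold; offset is the time of the first
    subsequent sample at or below it (half-open interval).  Runs separated by
    less than ``merge_gap`` seconds are merged.
    """
    try:
        ref = _region_column(region_dff, reference_region)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    rate = region_dff.sampling_rate
    runs = _find_runs(ref > threshold)
    gap_samples = merge_gap * rate
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < gap_samples:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    return [(start / rate, stop / rate) for start, stop in merged]


def classify_seizure(
    candidate: tuple[float, float],
    all_region_dff: DffTrace,
    threshold: float = 50.0,
    lookahead: float = 10.0,
) -> Seizure:
    """Classify a candidate: global iff the anterior forebrain is recruited
    and the episode lasts more than one minute; local otherwise.

    A region counts as recruited when its ΔF/F₀ exceeds the threshold at any
    point in [onset, offset + lookahead).
    """
    onset, offset = candidate
    rate = all_region_dff.sampling_rate
    i0 = int(round(onset * rate))
    i1 = min(int(round((offset + lookahead) * rate)), all_region_dff.n_samples)
    recruited = set()
    for j, roi in enumerate(all_region_dff.roi_labels):
        region = (all_region_dff.region_of or {}).get(roi, roi)
        if np.any(all_region_dff.dff[i0:i1, j] > threshold):
            recruited.add(region)
    is_global = (
        "anterior_forebrain" in recruited and (offset - onset) > GLOBAL_MIN_DURATION
    )
    return Seizure(
        onset=onset,
        offset=offset,
        recruited_regions=recruited,
        seizure_class="global" if is_global else "local",
    )


def propagation_halfmax(
    seizure: Seizure,
    region_dff: DffTrace,
    min_peak_height: float = 100.0,
    regions: tuple[str, ...] = REGION_ORDER,
    lead: float = 30.0,
) -> Seizure:
    """Time regional recruitment by ictal half-maxima and assign the origin.

    For each region whose in-seizure peak reaches ``min_peak_height``, the
    half-max time is the first upward crossing of max(ΔF/F₀)/2 inside the
    seizure window (linear interpolation between samples).  The window opens
    ``lead`` seconds before the candidate onset: the reference-region
    threshold crossing that defines the onset can lag the origin region's own
    recruitment, so the origin's half-max may precede it.  Times are reported
    relative to the earliest region; that region is the origin, ties broken by
    the fixed anatomical order (hindbrain, midbrain, anterior forebrain) with
    the tie flag set.  Regions below ``min_peak_height`` are excluded and
    flagged; if none qualifies a ValueError is raised.

    The seizure is updated in place and returned.
    """
    rate = region_dff.sampling_rate
    i0 = max(int(round((seizure.onset - lead) * rate)), 0)
    i1 = max(int(round(seizure.offset * rate)), i0 + 2)
    times: dict[str, float] = {}
    excluded: set[str] = set()
    for region in regions:
        try:
            col = _region_column(region_dff, region)
        except KeyError:
            continue
        seg = col[i0:i1]
        peak = float(seg.max())
        if peak < min_peak_height:
            excluded.add(region)
            continue
        level = peak / 2.0
        above = seg >= level
        if not above.any():
            excluded.add(region)
            continue
        k = int(np.argmax(above))
        if k == 0:
            t_cross = 0.0
        else:
            y0, y1 = seg[k - 1], seg[k]
            frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
            t_cross = (k - 1 + frac) / rate
        times[region] = i0 / rate + t_cross
    if not times:
        raise ValueError(
            f"no region reaches the minimum peak height {min_peak_height}% "
            "during the seizure"
        )
    earliest = min(times.values())
    rel = {r: t - earliest for r, t in times.items()}
    at_min = [r for r in regions if r in rel and np.isclose(rel[r], 0.0, atol=1e-9)]
    seizure.halfmax_time = rel
    seizure.origin = at_min[0]
    seizure.origin_tie = len(at_min) > 1
    seizure.excluded_regions = excluded
    if excluded:
        log.info("regions below %g%% excluded from half-max timing: %s",
                 min_peak_height, sorted(excluded))
    return seizure


def basal_activity_sd(
    whole_brain_dff,
    windows: list[tuple[float, float]],
    sampling_rate: float | None = None,
    seizures: list[Seizure] | None = None,
) -> float:
    """Mean over windows of the population SD of whole-brain ΔF/F₀.

    Windows are (start, end) pairs in seconds (120 s by convention).  When a
    seizure list is supplied, any window overlapping a seizure is rejected
    with an error — basal activity is defined between seizures.
    """
    from .events import _rate_of

    x = _as_1d(whole_brain_dff)
    rate = _rate_of(whole_brain_dff, sampling_rate)
    if not windows:
        raise ValueError("at least one window required")
    if seizures:
        for start, end in windows:
            for sz in seizures:
                if start < sz.offset and end > sz.onset:
                    raise ValueError(
                        f"window ({start:g}, {end:g}) overlaps seizure "
                        f"[{sz.onset:g}, {sz.offset:g})"
                    )
    sds = []
    for start, end in windows:
        i0, i1 = int(round(start * rate)), int(round(end * rate))
        seg = x[i0:i1]
        if seg.size < 2:
            raise ValueError(f"window ({start:g}, {end:g}) has fewer than 2 samples")
        sds.append(float(seg.std(ddof=0)))
    return float(np.mean(sds))


def pick_basal_windows(
    duration: float,
    seizures: list[Seizure],
    n_windows: int = 5,
    window_length: float = 120.0,
    margin: float = 120.0,
    mode: str = "earliest",
    seed: int | None = None,
) -> list[tuple[float, float]]:
    """Choose seizure-free windows for basal-activity metrics.

    Admissible starts keep the whole window at least ``margin`` seconds away
    from every seizure.  ``mode='earliest'`` places windows deterministically,
    evenly spaced through the admissible time (reproducible default);
    ``mode='random'`` draws seeded uniform starts, mirroring random placement
    adjusted away from seizures.  Returns fewer windows (with a warning) when
    the recording lacks seizure-free time.
    """
    blocked = [(sz.onset - margin, sz.offset + margin) for sz in seizures]
    blocked.sort()
    free: list[tuple[float, float]] = []
    cursor = 0.0
    for lo, hi in blocked:
        if lo > cursor:
            free.append((cursor, min(lo, duration)))
        cursor = max(cursor, hi)
    if cursor < duration:
        free.append((cursor, duration))
    segments = [(lo, hi) for lo, hi in free if hi - lo >= window_length]
    if not segments:
        log.warning("no admissible basal window; returning none")
        return []
    caps = [int((hi - lo) // window_length) for lo, hi in segments]
    total_cap = sum(caps)
    n_place = min(n_windows, total_cap)
    if n_place < n_windows:
        log.warning("only %d of %d basal windows available", n_place, n_windows)
    # allocate windows to segments proportionally to capacity
    alloc = [0] * len(segments)
    order = sorted(range(len(segments)), key=lambda i: -caps[i])
    i = 0
    for _ in range(n_place):
        while alloc[order[i % len(order)]] >= caps[order[i % len(order)]]:
            i += 1
        alloc[order[i % len(order)]] += 1
        i += 1
    if mode == "random":
        rng = np.random.default_rng(seed)
    windows: list[tuple[float, float]] = []
    for (lo, hi), k in zip(segments, alloc):
        if k == 0:
            continue
        slack = (hi - lo) - k * window_length
        if mode == "random":
            # seeded random slack split between/around the k windows
            gaps = rng.dirichlet(np.ones(k + 1)) * slack
        else:
            gaps = np.full(k + 1, slack / (k + 1))
        start = lo
        for g in gaps[:-1]:
            start += g
            windows.append((start, start + window_length))
            start += window_length
    windows.sort()
    return windows


def glial_seizure_onset(all_cell_dff, sampling_rate: float | None = None) -> list[int]:
    """Onset frames where the all-cell mean ΔF/F₀ first reaches 50%.

    Returns the first index of every maximal run with mean ≥ 50.
    """
    if isinstance(all_cell_dff, DffTrace):
        mean = all_cell_dff.dff.mean(axis=1)
    else:
        arr = np.asarray(all_cell_dff, dtype=float)
        mean = arr.mean(axis=1) if arr.ndim == 2 else arr
    runs = _find_runs(mean >= 50.0)
    return [int(start) for start, _ in runs]
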