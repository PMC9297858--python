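"""Astroglial network metrics over analysis windows.

Given per-cell event lists (from the noise-model detector on 4 Hz-resampled
ΔF/F₀), these functions summarise glial activity in two-minute basal /
preictal / ictal windows and in one-minute windows around light stimuli.  A
cell is *active* in a window if at least one of its events peaks inside it;
summary statistics (mean amplitude, mean AUC) are taken over active cells
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import CalciumEvent
from .seizure import Seizure, pick_basal_windows

__all__ = [
    "WindowSpec",
    "CellWindowMetrics",
    "WindowSummary",
    "window_metrics",
    "periictal_comparison",
    "light_response_comparison",
]

log = logging.getLogger(__name__)

PERIICTAL_WINDOW = 120.0  # s, basal/preictal/ictal
LIGHT_WINDOW = 60.0  # s, pre/post light stimulus

_KIND_LENGTHS = {
    "basal": PERIICTAL_WINDOW,
    "preictal": PERIICTAL_WINDOW,
    "ictal": PERIICTAL_WINDOW,
    "pre_light": LIGHT_WINDOW,
    "post_light": LIGHT_WINDOW,
}


@dataclass(frozen=True)
class WindowSpec:
    """An analysis window [start, end) of a fixed, kind-dependent length."""

    kind: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.kind not in _KIND_LENGTHS:
            raise ValueError(f"unknown window kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        expected = _KIND_LENGTHS[self.kind]
        if not np.isclose(self.end - self.start, expected, rtol=1e-6):
            raise ValueError(
                f"{self.kind} windows must be {expected:g} s long, "
                f"got {self.end - self.start:g}"
            )


@dataclass
class CellWindowMetrics:
    """Per-cell activity inside one window."""

    cell_id: str
    active: bool
    n_events: int
    auc: float
    mean_amplitude: float
    event_durations: list[float] = field(default_factory=list)


@dataclass
class WindowSummary:
    """Population summary of one window (active-cell statistics)."""

    window: WindowSpec
    active_fraction: float
    mean_amplitude: float | None
    mean_auc: float | None
    per_cell: list[CellWindowMetrics] = field(default_factory=list)


def window_metrics(
    cell_events: dict[str, list[CalciumEvent]], window: WindowSpec
) -> WindowSummary:
    """Per-cell metrics and population summary for one window.

    An event belongs to the window when its ``peak_time`` lies in
    [start, end), so each event is counted exactly once even if it straddles
    a boundary.  When no cell is active the amplitude/AUC summaries are None.
    """
    if not cell_events:
        raise ValueError("empty cell set")
    per_cell = []
    for cell_id in sorted(cell_events):
        evs = [
            e for e in cell_events[cell_id] if window.start <= e.peak_time < window.end
        ]
        active = len(evs) >= 1
        per_cell.append(
            CellWindowMetrics(
                cell_id=cell_id,
                active=active,
                n_events=len(evs),
                auc=float(sum(e.auc for e in evs)),
                mean_amplitude=float(np.mean([e.amplitude for e in evs])) if active else 0.0,
                event_durations=[e.halfheight_width for e in evs],
            )
        )
    active_cells = [c for c in per_cell if c.active]
    active_fraction = len(active_cells) / len(per_cell)
    if active_cells:
        mean_amplitude = float(np.mean([c.mean_amplitude for c in active_cells]))
        mean_auc = float(np.mean([c.auc for c in active_cells]))
    else:
        mean_amplitude = mean_auc = None  # undefined without active cells
    return WindowSummary(
        window=window,
        active_fraction=active_fraction,
        mean_amplitude=mean_amplitude,
        mean_auc=mean_auc,
        per_cell=per_cell,
    )


def periictal_comparison(
    cell_events: dict[str, list[CalciumEvent]],
    seizures: list[Seizure],
    duration: float,
    n_basal_windows: int = 6,
    basal_mode: str = "earliest",
    seed: int | None = None,
) -> dict[str, list[WindowSummary]]:
    """Glial metrics in basal, preictal and ictal windows of one fish.

    Preictal is the 120 s ending at each seizure onset, ictal the 120 s
    starting at it.  Basal windows are sampled at least 120 s away from every
    seizure — deterministically evenly spaced by default, or seeded-random
    (``basal_mode='random'``) to mirror random placement adjusted away from
    seizures — and are meant to be averaged per fish.  Without seizures only
    basal metrics are returned.
    """
    out: dict[str, list[WindowSummary]] = {"basal": [], "preictal": [], "ictal": []}
    basal = pick_basal_windows(
        duration,
        seizures,
        n_windows=n_basal_windows,
        window_length=PERIICTAL_WINDOW,
        margin=PERIICTAL_WINDOW,
        mode=basal_mode,
        seed=seed,
    )
    for start, end in basal:
        out["basal"].append(
            window_metrics(cell_events, WindowSpec("basal", start, end))
        )
    for sz in seizures:
        pre = (sz.onset - PERIICTAL_WINDOW, sz.onset)
        ict = (sz.onset, sz.onset + PERIICTAL_WINDOW)
        if pre[0] < 0:
            log.warning("seizure at %.1f s too early for a preictal window", sz.onset)
        else:
            out["preictal"].append(
                window_metrics(cell_events, WindowSpec("preictal", *pre))
            )
        if ict[1] > duration:
            log.warning("seizure at %.1f s too late for an ictal window", sz.onset)
        else:
            out["ictal"].append(
                window_metrics(cell_events, WindowSpec("ictal", *ict))
            )
    return out


def light_response_comparison(
    cell_events: dict[str, list[CalciumEvent]],
    stimulus_onsets: list[float],
    duration: float | None = None,
    pre: float = LIGHT_WINDOW,
    post: float = LIGHT_WINDOW,
) -> list[tuple[WindowSummary, WindowSummary]]:
    """Paired (pre, post) glial summaries around each light stimulus.

    Windows are [onset − pre, onset) and [onset, onset + post) — disjoint and
    tiling the peristimulus minute on each side.  Stimuli too close to a
    recording edge are dropped with a warning.
    """
    pairs = []
    for onset in stimulus_onsets:
        if onset - pre < 0 or (duration is not None and onset + post > duration):
            log.warning("stimulus at %.1f s too close to a recording edge; dropped", onset)
            continue
        pre_sum = window_metrics(
            cell_events, WindowSpec("pre_light", onset - pre, onset)
        )
        post_sum = window_metrics(
            cell_events, WindowSpec("post_light", onset, onset + post)
        )
        pairs.append((pre_sum, post_sum))
    return pairs
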