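"""Locomotor quantification from per-interval tracking records.

ZebraBox-style tracking reports, for every accumulating 5-s interval, the
distance (mm) and the time (s) a larva moved faster than 1 mm/s.  From these
the pipeline derives the active-swimming time ratio, high-distance burst
counts (> 40 mm per 5-s interval), and the velocity of long-lasting bursts
(distance / moving time for intervals with at least 3.5 s of movement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SwimRecord",
    "BehaviorSummary",
    "active_ratio",
    "detect_bursts",
    "long_burst_velocity",
    "artifact_filter",
    "summarize",
    "records_to_frame",
    "records_from_frame",
]

log = logging.getLogger(__name__)

BIN_SECONDS = 5.0


@dataclass
class SwimRecord:
    """Per-larva locomotion record: (distance mm, moving-duration s) per 5-s bin."""

    larva_id: str
    genotype: str
    distances: np.ndarray
    moving_durations: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.moving_durations = np.asarray(self.moving_durations, dtype=float)
        if self.distances.shape != self.moving_durations.shape:
            raise ValueError("distances and moving_durations must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        if np.any((self.moving_durations < 0) | (self.moving_durations > BIN_SECONDS)):
            raise ValueError("moving_durations must lie in [0, 5] s per bin")

    @property
    def n_intervals(self) -> int:
        return self.distances.size


@dataclass
class BehaviorSummary:
    """Derived per-larva statistics."""

    larva_id: str
    genotype: str
    active_ratio: float
    n_bursts: int
    has_burst: bool
    long_burst_velocities: list[float] = field(default_factory=list)


def active_ratio(record: SwimRecord) -> float:
    """Fraction of time spent actively swimming: Σ moving / (5 s · n bins)."""
    if record.n_intervals == 0:
        raise ValueError("empty swim record")
    return float(record.moving_durations.sum() / (BIN_SECONDS * record.n_intervals))


def detect_bursts(record: SwimRecord, threshold: float = 40.0) -> tuple[int, bool]:
    """Count intervals with distance strictly above the burst threshold (mm/5 s)."""
    n = int(np.sum(record.distances > threshold))
    return n, n >= 1


def long_burst_velocity(
    record: SwimRecord,
    min_moving: float = 3.5,
    denominator: str = "moving",
) -> list[float]:
    """Velocity (mm/s) of long-lasting bursts.

    For each interval in which the animal moved at least ``min_moving``
    seconds, velocity = distance / moving time.  ``denominator='bin'``
    divides by the fixed 5-s bin length instead.
    """
    mask = record.moving_durations >= min_moving
    if denominator == "moving":
        with np.errstate(divide="ignore", invalid="ignore"):
            v = record.distances[mask] / record.moving_durations[mask]
    elif denominator == "bin":
        v = record.distances[mask] / BIN_SECONDS
    else:
        raise ValueError("denominator must be 'moving' or 'bin'")
    return [float(x) for x in v]


def artifact_filter(record: SwimRecord, max_velocity: float = 100.0) -> SwimRecord:
    """Zero out intervals implying implausible instantaneous velocity.

    Tracking glitches occasionally register enormous displacements; intervals
    whose implied velocity (distance / max(moving time, 1 sample-free floor))
    exceeds ``max_velocity`` mm/s are zeroed and counted in the log.  The
    default threshold is an arbitrary plausibility bound, far above larval
    swimming speeds.  Idempotent.
    """
    denom = np.maximum(record.moving_durations, 1e-3)
    implied = record.distances / denom
    bad = implied > max_velocity
    if bad.any():
        log.info("artifact filter zeroed %d interval(s)", int(bad.sum()))
    distances = np.where(bad, 0.0, record.distances)
    moving = np.where(bad, 0.0, record.moving_durations)
    return SwimRecord(
        larva_id=record.larva_id,
        genotype=record.genotype,
        distances=distances,
        moving_durations=moving,
    )


def summarize(
    record: SwimRecord,
    burst_threshold: float = 40.0,
    min_moving: float = 3.5,
) -> BehaviorSummary:
    n_bursts, has_burst = detect_bursts(record, burst_threshold)
    return BehaviorSummary(
        larva_id=record.larva_id,
        genotype=record.genotype,
        active_ratio=active_ratio(record),
        n_bursts=n_bursts,
        has_burst=has_burst,
        long_burst_velocities=long_burst_velocity(record, min_moving),
    )


def records_to_frame(records: list[SwimRecord]) -> pd.DataFrame:
    """Long-format table: larva_id, genotype, t_start_s, distance_mm, moving_s."""
    rows = []
    for rec in records:
        for i in range(rec.n_intervals):
            rows.append(
                {
                    "larva_id": rec.larva_id,
                    "genotype": rec.genotype,
                    "t_start_s": i * BIN_SECONDS,
                    "distance_mm": rec.distances[i],
                    "moving_s": rec.moving_durations[i],
                }
            )
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[SwimRecord]:
    required = {"larva_id", "genotype", "t_start_s", "distance_mm", "moving_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    records = []
    for larva_id, grp in df.groupby("larva_id", sort=True):
        grp = grp.sort_values("t_start_s")
        records.append(
            SwimRecord(
                larva_id=str(larva_id),
                genotype=str(grp["genotype"].iloc[0]),
                distances=grp["distance_mm"].to_numpy(),
                moving_durations=grp["moving_s"].to_numpy(),
            )
        )
    return records
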