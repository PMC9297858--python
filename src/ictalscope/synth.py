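"""Synthetic recordings with ground truth, parameterized by genotype.

The generator emulates the statistical structure of the four recording
modalities the pipeline analyses:

* whole-brain / regional neuronal calcium imaging at 4 Hz, with seizures as
  smoothed supra-100% ΔF/F₀ plateaus propagating across regions;
* single-plane glial calcium imaging, with per-cell inter-ictal transients
  and near-synchronous ictal participation;
* ZebraBox-style locomotor records (distance and moving time per 5-s bin);
* paired 10 kHz LFP and 1 Hz glutamate-sensor (iGluSnFR) recordings with
  co-timed events.

Genotype presets encode the published group contrasts: homozygous mutants
carry seizures, reduced basal activity and hypoactive swimming with
occasional high-velocity bursts; heterozygous and wild-type siblings carry
no seizures and higher basal activity.  The basal-fluctuation and behavior
preset constants are calibrated so the expected values of the downstream
summary statistics equal the published group means; see docs/methods.md for
the calibration.

All randomness flows from a single integer seed through named sub-streams,
so outputs are bit-reproducible and stable under unrelated parameter
changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .behavior import SwimRecord
from .traces import TraceMatrix

__all__ = [
    "GENOTYPES",
    "SynthBrainParams",
    "SeizureTruth",
    "GroundTruth",
    "generate_brain_recording",
    "generate_glial_recording",
    "generate_behavior",
    "generate_glu_lfp",
    "make_classification_cohort",
    "make_origin_cohort",
    "make_propagation_set",
    "BEHAVIOR_PRESETS",
    "BASAL_PRESETS",
]

GENOTYPES = ("homozygous_mutant", "heterozygous", "wild_type")

REGIONS = ("anterior_forebrain", "midbrain", "hindbrain")

#: resting fluorescence level, arbitrary camera units
F0_DEFAULT = 100.0

# -- genotype presets ------------------------------------------------------

#: Basal (inter-ictal) activity presets.  ``target_sd`` is the stationary SD
#: of basal ΔF/F₀ (%), set to the published group means of the two-minute
#: windowed SD; ``rate_per_min``/``amp_mean`` shape the transient shot-noise
#: component (mutants: rare small transients; controls: frequent larger
#: ones).  The Gaussian sensor-noise sigma is derived at generation time so
#: that sensor noise + transient shot noise (Campbell's theorem) reaches the
#: target SD.
BASAL_PRESETS: dict[str, dict[str, float]] = {
    "homozygous_mutant": {"target_sd": 0.63, "rate_per_min": 2.0, "amp_mean": 1.5},
    "heterozygous": {"target_sd": 1.54, "rate_per_min": 12.0, "amp_mean": 2.61},
    "wild_type": {"target_sd": 1.44, "rate_per_min": 12.0, "amp_mean": 2.42},
}
_BASAL_AMP_SIGMA_LN = 0.3

#: Behavior presets.  Each 5-s interval is active with probability
#: ``p_move``; active intervals draw a moving duration uniformly in
#: ``mean ± half_width`` seconds with ``mean = 5 · active_ratio / p_move``,
#: so the expected active-time ratio equals ``active_ratio`` (the published
#: group mean).  Per-interval swimming velocity is lognormal with the given
#: mean (mm/s, the published long-burst group mean) independent of duration;
#: the heavier mutant tail produces the occasional >40 mm bursts.
BEHAVIOR_PRESETS: dict[str, dict[str, float]] = {
    "homozygous_mutant": {
        "p_move": 0.10,
        "active_ratio": 0.047,
        "half_width": 1.8,
        "velocity_mean": 7.31,
        "velocity_sigma_ln": 0.5,
    },
    "heterozygous": {
        "p_move": 0.75,
        "active_ratio": 0.444,
        "half_width": 1.8,
        "velocity_mean": 4.86,
        "velocity_sigma_ln": 0.3,
    },
    "wild_type": {
        "p_move": 0.78,
        "active_ratio": 0.476,
        "half_width": 1.8,
        "velocity_mean": 4.83,
        "velocity_sigma_ln": 0.3,
    },
}

#: Glial inter-ictal presets: fraction of cells with any events and
#: per-active-cell event rate (controls more active than mutants).
GLIAL_PRESETS: dict[str, dict[str, float]] = {
    "homozygous_mutant": {"fraction_active": 0.3, "rate_per_min": 0.5},
    "heterozygous": {"fraction_active": 0.7, "rate_per_min": 1.2},
    "wild_type": {"fraction_active": 0.7, "rate_per_min": 1.2},
}
GLIAL_NOISE_SIGMA = 2.0  # % dff, per-cell sensor noise
GLIAL_EVENT_AMP_MEAN = 30.0  # % dff
GLIAL_EVENT_AMP_SIGMA_LN = 0.4

#: Glutamate/LFP presets: mutant surges are larger and longer than
#: PTZ-evoked ones while the LFP deflections are comparable.
GLU_PRESETS: dict[str, dict[str, float]] = {
    "mutant": {"amp_mean": 25.0, "amp_sd": 6.0, "dur_median": 45.0, "dur_sd": 18.0},
    "ptz": {"amp_mean": 12.0, "amp_sd": 3.0, "dur_median": 18.0, "dur_sd": 7.0},
}
LFP_RATE = 10_000.0
LFP_DEFLECTION_MV = 0.4
LFP_NOISE_MV = 0.02
IGLU_RATE = 1.0


def _check_genotype(genotype: str) -> None:
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}, got {genotype!r}")


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Named sub-stream of the single documented PRNG seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass
class SynthBrainParams:
    """Parameters of the synthetic brain recording generator.

    Defaults mirror the recording conditions of the emulated experiments:
    4 Hz regional imaging for 60 min, seizure plateaus of 100-300% ΔF/F₀
    whose half-height widths are lognormal with median 127 s and SD 52 s,
    and forebrain recruitment delays normal with mean 13 s and SD 5.67 s
    (truncated at zero).  ``noise_sigma=None`` derives the Gaussian sensor
    noise from the genotype basal-SD preset (see BASAL_PRESETS).
    """

    sampling_rate: float = 4.0
    duration: float = 3600.0
    regions: tuple[str, ...] = REGIONS
    noise_sigma: float | None = None
    kernel_rise: float = 0.2
    kernel_decay: float = 1.8
    seizure_rate: float = 3.0  # events per hour (mutant)
    n_seizures: int | None = None  # fixed count override
    seizure_amplitude_range: tuple[float, float] = (100.0, 300.0)
    seizure_halfheight_median: float = 127.0
    seizure_halfheight_sd: float = 52.0
    forebrain_delay_mean: float = 13.0
    forebrain_delay_sd: float = 5.67
    global_fraction: float = 0.75
    baseline_drift_amplitude: float = 0.002
    drift_period: float = 500.0
    f0: float = F0_DEFAULT
    basal_rate_per_min: float | None = None  # override genotype preset
    basal_amp_mean: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.seizure_rate < 0:
            raise ValueError("seizure_rate must be non-negative")
        if min(self.seizure_amplitude_range) < 0:
            raise ValueError("seizure amplitudes must be non-negative")
        if not 0 <= self.global_fraction <= 1:
            raise ValueError("global_fraction must lie in [0, 1]")
        if self.seizure_halfheight_median <= 0:
            raise ValueError("seizure_halfheight_median must be positive")


@dataclass
class SeizureTruth:
    onset: float
    offset: float
    delays: dict[str, float]
    seizure_class: str
    origin: str
    amplitude: float


@dataclass
class GroundTruth:
    """Everything the generator injected, for parameter-recovery tests."""

    genotype: str
    seizures: list[SeizureTruth] = field(default_factory=list)
    events: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    bouts: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sz in self.seizures:
            if sz.offset <= sz.onset:
                raise ValueError("seizure offset must exceed onset")
        onsets = [sz.onset for sz in self.seizures]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("seizure onsets must be strictly increasing")

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


# -- building blocks -------------------------------------------------------


def _kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, peak-normalized to 1."""
    if rise <= 0 or decay <= rise:
        raise ValueError("need 0 < kernel_rise < kernel_decay")
    tpk = np.log(decay / rise) / (1.0 / rise - 1.0 / decay)
    peak = np.exp(-tpk / decay) - np.exp(-tpk / rise)
    out = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    return out / peak


def _kernel_l2(rise: float, decay: float) -> float:
    """∫ g(t)² dt of the peak-normalized kernel (closed form)."""
    tpk = np.log(decay / rise) / (1.0 / rise - 1.0 / decay)
    peak = np.exp(-tpk / decay) - np.exp(-tpk / rise)
    raw = decay / 2.0 + rise / 2.0 - 2.0 / (1.0 / rise + 1.0 / decay)
    return raw / peak**2


def _plateau(
    t: np.ndarray, onset: float, width: float, amp: float,
    tau_rise: float = 2.0, tau_fall: float = 5.0,
) -> np.ndarray:
    """Smoothed plateau whose width at half height is exactly ``width``."""
    return amp * 0.5 * (
        np.tanh((t - onset) / tau_rise) - np.tanh((t - onset - width) / tau_fall)
    )


def _lognormal_from_median_sd(
    rng: np.random.Generator, median: float, sd: float, size=None
) -> np.ndarray:
    """Lognormal draws with the given median and standard deviation."""
    ratio2 = (sd / median) ** 2
    w = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * ratio2))
    sigma = np.sqrt(np.log(w))
    return median * np.exp(sigma * rng.standard_normal(size))


def _lognormal_from_mean(
    rng: np.random.Generator, mean: float, sigma_ln: float, size=None
) -> np.ndarray:
    mu = np.log(mean) - 0.5 * sigma_ln**2
    return np.exp(mu + sigma_ln * rng.standard_normal(size))


def _truncnorm_pos(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero (redraw)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0


def _basal_train(
    rng: np.random.Generator,
    t: np.ndarray,
    rate_per_s: float,
    amp_mean: float,
    amp_sigma_ln: float,
    rise: float,
    decay: float,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Poisson transient train on the time grid; returns (dff %, truth)."""
    duration = t[-1] - t[0] + (t[1] - t[0] if t.size > 1 else 0.0)
    dff = np.zeros_like(t)
    truth: list[tuple[float, float]] = []
    if rate_per_s <= 0 or amp_mean <= 0:
        return dff, truth
    n = rng.poisson(rate_per_s * duration)
    if n == 0:
        return dff, truth
    onsets = np.sort(rng.uniform(t[0], t[0] + duration, size=n))
    amps = _lognormal_from_mean(rng, amp_mean, amp_sigma_ln, size=n)
    span = min(10.0 * decay, duration)
    for onset, amp in zip(onsets, amps):
        i0 = np.searchsorted(t, onset)
        i1 = np.searchsorted(t, onset + span)
        dff[i0:i1] += amp * _kernel(t[i0:i1] - onset, rise, decay)
        truth.append((float(onset), float(amp)))
    return dff, truth


def _derived_noise_sigma(params: SynthBrainParams, genotype: str) -> tuple[float, float, float]:
    """(noise_sigma, basal_rate_per_s, basal_amp_mean) for a genotype.

    The sensor-noise sigma is solved from the genotype's target basal SD via
    Campbell's theorem for the transient shot-noise variance
    rate · E[amp²] · ∫g², unless explicitly overridden.
    """
    preset = BASAL_PRESETS[genotype]
    rate_per_min = (
        params.basal_rate_per_min
        if params.basal_rate_per_min is not None
        else preset["rate_per_min"]
    )
    amp_mean = (
        params.basal_amp_mean if params.basal_amp_mean is not None else preset["amp_mean"]
    )
    if params.noise_sigma is not None:
        return params.noise_sigma, rate_per_min / 60.0, amp_mean
    shot_var = (
        (rate_per_min / 60.0)
        * amp_mean**2
        * np.exp(_BASAL_AMP_SIGMA_LN**2)
        * _kernel_l2(params.kernel_rise, params.kernel_decay)
    )
    noise_var = max(preset["target_sd"] ** 2 - shot_var, 0.0)
    return float(np.sqrt(noise_var)), rate_per_min / 60.0, amp_mean


def _draw_seizures(
    rng: np.random.Generator, params: SynthBrainParams, genotype: str
) -> list[SeizureTruth]:
    """Seizure schedule for one fish; controls carry none."""
    if genotype != "homozygous_mutant":
        return []
    if params.n_seizures is not None:
        n = params.n_seizures
    else:
        n = rng.poisson(params.seizure_rate * params.duration / 3600.0)
    seizures: list[SeizureTruth] = []
    occupied: list[tuple[float, float]] = []
    edge = min(200.0, 0.15 * params.duration)
    margin = min(240.0, 0.2 * params.duration)
    for _ in range(n):
        is_global = rng.uniform() < params.global_fraction
        placed = width = None
        for _attempt in range(200):
            if is_global:
                w = float(
                    _lognormal_from_median_sd(
                        rng,
                        params.seizure_halfheight_median,
                        params.seizure_halfheight_sd,
                    )
                )
            else:
                w = float(rng.uniform(15.0, 50.0))
            lo, hi = edge, params.duration - w - edge
            if hi <= lo:
                continue
            onset = float(rng.uniform(lo, hi))
            if all(onset + w + margin < a or onset > b + margin for a, b in occupied):
                placed, width = onset, w
                break
        if placed is None:
            continue
        amp = float(rng.uniform(*params.seizure_amplitude_range))
        origin = "midbrain" if rng.uniform() < 2.0 / 3.0 else "hindbrain"
        second = "hindbrain" if origin == "midbrain" else "midbrain"
        delays = {origin: 0.0, second: _truncnorm_pos(rng, 2.5, 1.5)}
        if is_global:
            delays["anterior_forebrain"] = _truncnorm_pos(
                rng, params.forebrain_delay_mean, params.forebrain_delay_sd
            )
        occupied.append((placed, placed + width))
        seizures.append(
            SeizureTruth(
                onset=placed,
                offset=placed + width,
                delays=delays,
                seizure_class="global" if is_global else "local",
                origin=origin,
                amplitude=amp,
            )
        )
    seizures.sort(key=lambda s: s.onset)
    return seizures


def _render_raw(
    true_dff: np.ndarray,
    t: np.ndarray,
    rng: np.random.Generator,
    f0: float,
    noise_sigma: float,
    drift_amplitude: float,
    drift_period: float,
    drift_phase: float,
) -> np.ndarray:
    """Raw fluorescence F = F₀·(1+drift)·(1+ΔF/F₀/100) + Gaussian noise."""
    drift = drift_amplitude * np.sin(2.0 * np.pi * t / drift_period + drift_phase)
    raw = f0 * (1.0 + drift) * (1.0 + true_dff / 100.0)
    if noise_sigma > 0:
        raw = raw + rng.normal(0.0, noise_sigma / 100.0 * f0, size=t.shape)
    return raw


# -- public generators -----------------------------------------------------


def generate_brain_recording(
    params: SynthBrainParams, genotype: str
) -> tuple[TraceMatrix, GroundTruth]:
    """Synthetic whole-brain + regional neuronal recording.

    Returns a raw-fluorescence TraceMatrix with one column per region plus a
    ``whole_brain`` column, and the full ground truth.  Homozygous mutants
    carry seizures and sparse basal transients; control genotypes carry no
    seizures and a denser basal transient process (inter-ictal hypoactivity
    of the mutant).
    """
    _check_genotype(genotype)
    n = int(round(params.duration * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate
    noise_sigma, basal_rate, basal_amp = _derived_noise_sigma(params, genotype)

    seizures = _draw_seizures(_rng(params.seed, 1), params, genotype)

    roi_labels = list(params.regions) + ["whole_brain"]
    true_dff = np.zeros((n, len(roi_labels)))
    events: dict[str, list[tuple[float, float]]] = {}

    region_seizure = np.zeros((n, len(params.regions)))
    for j, region in enumerate(params.regions):
        for sz in seizures:
            if region not in sz.delays:
                continue
            onset = sz.onset + sz.delays[region]
            region_seizure[:, j] += _plateau(t, onset, sz.offset - sz.onset, sz.amplitude)

    for j, roi in enumerate(roi_labels):
        basal, truth = _basal_train(
            _rng(params.seed, 100 + j),
            t,
            basal_rate,
            basal_amp,
            _BASAL_AMP_SIGMA_LN,
            params.kernel_rise,
            params.kernel_decay,
        )
        events[roi] = truth
        if roi == "whole_brain":
            true_dff[:, j] = basal + region_seizure.mean(axis=1)
        else:
            true_dff[:, j] = basal + region_seizure[:, j]

    drift_phase_rng = _rng(params.seed, 2)
    values = np.empty_like(true_dff)
    for j in range(len(roi_labels)):
        values[:, j] = _render_raw(
            true_dff[:, j],
            t,
            _rng(params.seed, 200 + j),
            params.f0,
            noise_sigma,
            params.baseline_drift_amplitude,
            params.drift_period,
            float(drift_phase_rng.uniform(0.0, 2.0 * np.pi)),
        )
    trace = TraceMatrix(
        time=t,
        values=values,
        sampling_rate=params.sampling_rate,
        roi_labels=roi_labels,
        region_of={r: r for r in roi_labels},
    )
    return trace, GroundTruth(genotype=genotype, seizures=seizures, events=events)


def generate_glial_recording(
    params: SynthBrainParams, n_cells: int, genotype: str
) -> tuple[TraceMatrix, GroundTruth]:
    """Synthetic per-cell glial recording (single imaging plane).

    Inter-ictal per-cell event rate and the fraction of ever-active cells
    follow genotype presets; during injected ictal windows ~95% of cells mount
    large plateaus so the all-cell mean true ΔF/F₀ exceeds 100%.
    """
    _check_genotype(genotype)
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    n = int(round(params.duration * params.sampling_rate))
    t = np.arange(n) / params.sampling_rate
    preset = GLIAL_PRESETS[genotype]
    noise_sigma = (
        params.noise_sigma if params.noise_sigma is not None else GLIAL_NOISE_SIGMA
    )
    seizures = _draw_seizures(_rng(params.seed, 11), params, genotype)
    cell_rng = _rng(params.seed, 12)
    active_mask = cell_rng.uniform(size=n_cells) < preset["fraction_active"]
    basal_rate = (
        params.basal_rate_per_min / 60.0
        if params.basal_rate_per_min is not None
        else preset["rate_per_min"] / 60.0
    )
    roi_labels = [f"cell_{i:03d}" for i in range(n_cells)]
    values = np.empty((n, n_cells))
    events: dict[str, list[tuple[float, float]]] = {}
    # glial transients are slower than neuronal ones
    rise, decay = max(params.kernel_rise, 0.5), max(params.kernel_decay, 4.0)
    for i, roi in enumerate(roi_labels):
        rate = basal_rate if active_mask[i] else 0.0
        dff, truth = _basal_train(
            _rng(params.seed, 1000 + i),
            t,
            rate,
            GLIAL_EVENT_AMP_MEAN,
            GLIAL_EVENT_AMP_SIGMA_LN,
            rise,
            decay,
        )
        sz_rng = _rng(params.seed, 2000 + i)
        for sz in seizures:
            if sz_rng.uniform() < 0.95:  # participation
                amp = float(sz_rng.uniform(150.0, 300.0))
                dff += _plateau(t, sz.onset, sz.offset - sz.onset, amp)
        events[roi] = truth
        values[:, i] = _render_raw(
            dff,
            t,
            _rng(params.seed, 3000 + i),
            params.f0,
            noise_sigma,
            params.baseline_drift_amplitude,
            params.drift_period,
            float(sz_rng.uniform(0.0, 2.0 * np.pi)),
        )
    trace = TraceMatrix(
        time=t, values=values, sampling_rate=params.sampling_rate, roi_labels=roi_labels
    )
    return trace, GroundTruth(genotype=genotype, seizures=seizures, events=events)


def generate_behavior(
    genotype: str,
    n_intervals: int,
    seed: int,
    preset: dict[str, float] | None = None,
) -> tuple[SwimRecord, GroundTruth]:
    """Synthetic per-5-s-interval locomotion record for one larva.

    The preset (see BEHAVIOR_PRESETS) fixes the per-interval movement
    probability, the moving-duration distribution (uniform around the mean
    implied by the target active ratio) and the lognormal velocity
    distribution, so every expected summary statistic is derivable from the
    preset parameters.
    """
    _check_genotype(genotype)
    if n_intervals < 1:
        raise ValueError("n_intervals must be at least 1")
    p = dict(BEHAVIOR_PRESETS[genotype])
    if preset:
        p.update(preset)
    rng = _rng(seed, 21)
    mean_moving = 5.0 * p["active_ratio"] / p["p_move"] if p["p_move"] > 0 else 0.0
    lo = max(mean_moving - p["half_width"], 0.0)
    hi = min(mean_moving + p["half_width"], 5.0)
    moving = np.zeros(n_intervals)
    distance = np.zeros(n_intervals)
    bouts: list[tuple[float, float, float]] = []
    for i in range(n_intervals):
        if p["p_move"] > 0 and rng.uniform() < p["p_move"]:
            dur = float(rng.uniform(lo, hi))
            vel = float(
                _lognormal_from_mean(rng, p["velocity_mean"], p["velocity_sigma_ln"])
            )
            moving[i] = dur
            distance[i] = vel * dur
            bouts.append((i * 5.0, dur, distance[i]))
    record = SwimRecord(
        larva_id=f"larva_{seed}",
        genotype=genotype,
        distances=distance,
        moving_durations=moving,
    )
    return record, GroundTruth(genotype=genotype, bouts=bouts)


def generate_glu_lfp(
    condition: str,
    duration: float,
    seed: int,
    n_events: int | None = None,
    rate_per_hour: float = 12.0,
) -> tuple[TraceMatrix, TraceMatrix, GroundTruth]:
    """Paired LFP (10 kHz) and iGluSnFR (1 Hz) recording with co-timed events.

    Mutant glutamate surges stochastically dominate PTZ-evoked ones in both
    amplitude and half-height duration, while LFP deflection amplitudes are
    comparable between conditions.
    """
    if condition not in GLU_PRESETS:
        raise ValueError(f"condition must be one of {tuple(GLU_PRESETS)}")
    if duration < 120.0:
        raise ValueError("duration must be at least 120 s")
    preset = GLU_PRESETS[condition]
    rng = _rng(seed, 31)
    if n_events is None:
        n_events = int(rng.poisson(rate_per_hour * duration / 3600.0))
    margin = 30.0
    usable = duration - 2 * margin
    if n_events > 0:
        onsets = np.sort(rng.uniform(margin, margin + usable, size=n_events))
        amps = np.maximum(rng.normal(preset["amp_mean"], preset["amp_sd"], n_events), 1.0)
        durs = _lognormal_from_median_sd(
            rng, preset["dur_median"], preset["dur_sd"], size=n_events
        )
    else:
        onsets = np.array([])
        amps = np.array([])
        durs = np.array([])

    t_glu = np.arange(int(round(duration * IGLU_RATE))) / IGLU_RATE
    glu_dff = np.zeros_like(t_glu)
    for onset, amp, dur in zip(onsets, amps, durs):
        glu_dff += _plateau(t_glu, onset, dur, amp, tau_rise=2.0, tau_fall=8.0)
    glu_raw = F0_DEFAULT * (1.0 + glu_dff / 100.0) + rng.normal(
        0.0, 0.5, size=t_glu.shape
    )
    glu = TraceMatrix(
        time=t_glu, values=glu_raw, sampling_rate=IGLU_RATE, roi_labels=["iglusnfr"]
    )

    n_lfp = int(round(duration * LFP_RATE))
    t_lfp = np.arange(n_lfp) / LFP_RATE
    lfp = rng.normal(0.0, LFP_NOISE_MV, size=n_lfp)
    for onset, _amp, dur in zip(onsets, amps, durs):
        # comparable deflections in both conditions: damped 5 Hz burst
        i0 = int(onset * LFP_RATE)
        burst_len = int(min(10.0, dur) * LFP_RATE)
        tb = np.arange(min(burst_len, n_lfp - i0)) / LFP_RATE
        lfp[i0 : i0 + tb.size] += (
            -LFP_DEFLECTION_MV * np.exp(-tb / 3.0) * np.sin(2.0 * np.pi * 5.0 * tb)
        )
    lfp_trace = TraceMatrix(
        time=t_lfp, values=lfp, sampling_rate=LFP_RATE, roi_labels=["lfp_mv"]
    )
    truth = GroundTruth(
        genotype=condition,
        events={"iglusnfr": [(float(o), float(a)) for o, a in zip(onsets, amps)]},
    )
    return lfp_trace, glu, truth


# -- deterministic constructed cohorts -------------------------------------


def make_classification_cohort(
    n_fish: int = 25,
    n_global: int = 12,
    seed: int = 0,
    duration: float = 900.0,
    sampling_rate: float = 4.0,
) -> list[tuple[TraceMatrix, GroundTruth]]:
    """Fixed cohort for the global-seizure classification worked example.

    The first ``n_global`` fish each receive one injected global seizure
    (amplitude 150%, half-height width 120 s, forebrain recruited after 13 s);
    the remaining fish alternate between a local event (40 s, no forebrain)
    and a sub-threshold (40%) event, so no control fish can classify as
    global.
    """
    cohort = []
    for i in range(n_fish):
        params = SynthBrainParams(
            sampling_rate=sampling_rate,
            duration=duration,
            n_seizures=0,
            noise_sigma=1.0,
            baseline_drift_amplitude=0.0,
            basal_rate_per_min=0.0,
            seed=seed * 1000 + i,
        )
        trace, truth = generate_brain_recording(params, "homozygous_mutant")
        t = trace.time
        if i < n_global:
            sz = SeizureTruth(
                onset=300.0,
                offset=420.0,
                delays={"midbrain": 0.0, "hindbrain": 2.0, "anterior_forebrain": 13.0},
                seizure_class="global",
                origin="midbrain",
                amplitude=150.0,
            )
        elif i % 2 == 0:
            sz = SeizureTruth(
                onset=300.0,
                offset=340.0,
                delays={"midbrain": 0.0, "hindbrain": 2.0},
                seizure_class="local",
                origin="midbrain",
                amplitude=150.0,
            )
        else:
            sz = SeizureTruth(
                onset=300.0,
                offset=340.0,
                delays={"midbrain": 0.0, "hindbrain": 2.0},
                seizure_class="local",
                origin="midbrain",
                amplitude=40.0,  # sub-threshold: never crosses 50%
            )
        add = np.zeros_like(trace.values)
        for j, roi in enumerate(trace.roi_labels):
            if roi == "whole_brain":
                parts = [
                    _plateau(t, sz.onset + d, sz.offset - sz.onset, sz.amplitude)
                    for d in sz.delays.values()
                ]
                pad = [np.zeros_like(t)] * (3 - len(parts))
                add[:, j] = np.mean(parts + pad, axis=0)
            elif roi in sz.delays:
                add[:, j] = _plateau(
                    t, sz.onset + sz.delays[roi], sz.offset - sz.onset, sz.amplitude
                )
        trace.values = trace.values * (1.0 + add / 100.0)  # multiplies F0·(1+dff)
        truth.seizures = [sz] if sz.amplitude > 50.0 else []
        cohort.append((trace, truth))
    return cohort


def make_origin_cohort(
    n_seizures: int = 12,
    n_midbrain: int = 8,
    seed: int = 0,
    inter_region_delay: float = 3.0,
    forebrain_delay: float = 13.0,
    duration: float = 400.0,
    sampling_rate: float = 4.0,
) -> list[tuple[TraceMatrix, GroundTruth]]:
    """Single-seizure recordings with fixed origin labels and delays ≥ 2 s.

    The first ``n_midbrain`` seizures originate in the midbrain, the rest in
    the hindbrain; the non-origin posterior region follows after
    ``inter_region_delay`` seconds and the forebrain after
    ``forebrain_delay`` seconds.
    """
    out = []
    for i in range(n_seizures):
        origin = "midbrain" if i < n_midbrain else "hindbrain"
        second = "hindbrain" if origin == "midbrain" else "midbrain"
        delays = {
            origin: 0.0,
            second: inter_region_delay,
            "anterior_forebrain": forebrain_delay,
        }
        out.append(
            _single_seizure_recording(
                seed * 1000 + i,
                delays,
                origin,
                amplitude=150.0,
                width=120.0,
                duration=duration,
                sampling_rate=sampling_rate,
            )
        )
    return out


def make_propagation_set(
    n_seizures: int = 200,
    seed: int = 0,
    forebrain_delay_mean: float = 13.0,
    forebrain_delay_sd: float = 5.67,
    duration: float = 400.0,
    sampling_rate: float = 4.0,
) -> list[tuple[TraceMatrix, GroundTruth]]:
    """Global seizures with forebrain delays ~ Normal(mean, sd) truncated at 0.

    Used to check that the half-max propagation analysis recovers the
    recruitment-delay distribution it was generated from.
    """
    rng = _rng(seed, 41)
    out = []
    for i in range(n_seizures):
        origin = "midbrain" if rng.uniform() < 2.0 / 3.0 else "hindbrain"
        second = "hindbrain" if origin == "midbrain" else "midbrain"
        delays = {
            origin: 0.0,
            second: _truncnorm_pos(rng, 2.5, 1.5),
            "anterior_forebrain": _truncnorm_pos(
                rng, forebrain_delay_mean, forebrain_delay_sd
            ),
        }
        amp = float(rng.uniform(120.0, 300.0))
        out.append(
            _single_seizure_recording(
                seed * 1000 + i,
                delays,
                origin,
                amplitude=amp,
                width=120.0,
                duration=duration,
                sampling_rate=sampling_rate,
            )
        )
    return out


def _single_seizure_recording(
    seed: int,
    delays: dict[str, float],
    origin: str,
    amplitude: float,
    width: float,
    duration: float,
    sampling_rate: float,
) -> tuple[TraceMatrix, GroundTruth]:
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    onset = 100.0
    rng = _rng(seed, 42)
    roi_labels = list(REGIONS) + ["whole_brain"]
    values = np.empty((n, len(roi_labels)))
    parts = {}
    for region in REGIONS:
        parts[region] = _plateau(t, onset + delays.get(region, 0.0), width, amplitude)
    whole = np.mean([parts[r] for r in REGIONS], axis=0)
    for j, roi in enumerate(roi_labels):
        dff = whole if roi == "whole_brain" else parts[roi]
        values[:, j] = _render_raw(
            dff, t, _rng(seed, 300 + j), F0_DEFAULT, 1.0, 0.0, 500.0, 0.0
        )
    trace = TraceMatrix(
        time=t,
        values=values,
        sampling_rate=sampling_rate,
        roi_labels=roi_labels,
        region_of={r: r for r in roi_labels},
    )
    truth = GroundTruth(
        genotype="homozygous_mutant",
        seizures=[
            SeizureTruth(
                onset=onset,
                offset=onset + width,
                delays=delays,
                seizure_class="global",
                origin=origin,
                amplitude=amplitude,
            )
        ],
    )
    return trace, truth
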