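import numpy as np
import pytest

import ictalscope as ic
from ictalscope.seizure import (
    SeizureDetector,
    basal_activity_sd,
    classify_seizure,
    detect_seizures,
    glial_seizure_onset,
    pick_basal_windows,
    propagation_halfmax,
)
from ictalscope.synth import SynthBrainParams, generate_brain_recording

from conftest import make_dff

REGIONS = ["anterior_forebrain", "midbrain", "hindbrain"]


def region_dff_from(fore, mid, hind, rate=4.0):
    return make_dff(np.column_stack([fore, mid, hind]), rate=rate, labels=REGIONS,
                    regions={r: r for r in REGIONS})


def boxcar(n, start, stop, amp, rate=4.0):
    x = np.zeros(n)
    x[int(start * rate) : int(stop * rate)] = amp
    return x


def run_length_oracle(x, threshold, merge_gap_s, rate):
    """Independent threshold-run detector by explicit scan."""
    runs = []
    inside = False
    for i, v in enumerate(x):
        if v > threshold and not inside:
            inside = True
            start = i
        elif v <= threshold and inside:
            inside = False
            runs.append((start, i))
    if inside:
        runs.append((start, len(x)))
    merged = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) / rate < merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s / rate, e / rate) for s, e in merged]


class TestDetectSeizures:
    def test_single_interval_duration(self):
        n = int(200 * 4)
        mid = boxcar(n, 10, 140, 120.0)
        dff = region_dff_from(np.zeros(n), mid, np.zeros(n))
        (onset, offset), = detect_seizures(dff)
        assert onset == pytest.approx(10.0, abs=0.25)
        assert offset - onset == pytest.approx(130.0, abs=0.5)

    def test_never_above_threshold(self):
        n = 800
        dff = region_dff_from(np.zeros(n), np.full(n, 40.0), np.zeros(n))
        assert detect_seizures(dff) == []

    @pytest.mark.parametrize("gap,expected", [(2.0, 1), (10.0, 2)])
    def test_merge_gap_rule(self, gap, expected):
        n = int(400 * 4)
        mid = boxcar(n, 10, 80, 120.0) + boxcar(n, 80 + gap, 180 + gap, 120.0)
        dff = region_dff_from(np.zeros(n), mid, np.zeros(n))
        got = detect_seizures(dff)
        assert len(got) == expected
        oracle = run_length_oracle(mid, 50.0, 5.0, 4.0)
        assert got == pytest.approx(oracle)

    def test_random_patterns_match_run_oracle(self, rng):
        for _ in range(10):
            x = rng.choice([0.0, 120.0], size=600, p=[0.85, 0.15])
            dff = region_dff_from(np.zeros(600), x, np.zeros(600))
            got = detect_seizures(dff, merge_gap=3.0)
            assert got == pytest.approx(run_length_oracle(x, 50.0, 3.0, 4.0))

    def test_missing_reference_region_errors(self):
        dff = make_dff(np.zeros((100, 1)), labels=["hindbrain"])
        with pytest.raises(ValueError, match="midbrain"):
            detect_seizures(dff)


class TestClassifySeizure:
    def test_long_with_forebrain_is_global(self):
        n = int(300 * 4)
        dff = region_dff_from(
            boxcar(n, 20, 150, 120.0), boxcar(n, 10, 140, 120.0),
            boxcar(n, 10, 140, 120.0),
        )
        sz = classify_seizure((10.0, 140.0), dff)
        assert sz.seizure_class == "global"
        assert "anterior_forebrain" in sz.recruited_regions

    def test_short_without_forebrain_is_local(self):
        n = int(300 * 4)
        dff = region_dff_from(
            np.zeros(n), boxcar(n, 10, 50, 120.0), boxcar(n, 10, 50, 120.0)
        )
        assert classify_seizure((10.0, 50.0), dff).seizure_class == "local"

    def test_long_without_forebrain_still_local(self):
        # the rule is conjunctive: duration > 60 s alone is not global
        n = int(300 * 4)
        dff = region_dff_from(
            np.full(n, 20.0), boxcar(n, 10, 80, 120.0), boxcar(n, 10, 80, 120.0)
        )
        assert classify_seizure((10.0, 80.0), dff).seizure_class == "local"

    def test_invariant_to_subthreshold_extra_region(self):
        n = int(300 * 4)
        base = np.column_stack(
            [boxcar(n, 20, 150, 120.0), boxcar(n, 10, 140, 120.0), np.zeros(n)]
        )
        labels = REGIONS + ["extra"]
        with_extra = make_dff(
            np.column_stack([base, np.full(n, 30.0)]), labels=labels,
            regions={r: r for r in labels},
        )
        without = make_dff(base, labels=REGIONS, regions={r: r for r in REGIONS})
        assert (
            classify_seizure((10.0, 140.0), with_extra).seizure_class
            == classify_seizure((10.0, 140.0), without).seizure_class
        )


class TestPropagationHalfmax:
    def _ramped(self, n, onset, amp=150.0, rate=4.0, width=120.0):
        t = np.arange(n) / rate
        return amp * 0.5 * (np.tanh((t - onset) / 2.0) - np.tanh((t - onset - width) / 5.0))

    def test_constructed_delays_recovered(self):
        n = int(400 * 4)
        dff = region_dff_from(
            self._ramped(n, 113.0), self._ramped(n, 103.0), self._ramped(n, 100.0)
        )
        sz = classify_seizure((100.0, 225.0), dff)
        propagation_halfmax(sz, dff)
        assert sz.origin == "hindbrain"
        assert sz.halfmax_time["anterior_forebrain"] == pytest.approx(13.0, abs=0.3)
        assert sz.halfmax_time["midbrain"] == pytest.approx(3.0, abs=0.3)
        assert sz.halfmax_time["hindbrain"] == 0.0

    def test_identical_traces_tie_broken_by_anatomical_order(self):
        n = int(400 * 4)
        x = self._ramped(n, 100.0)
        dff = region_dff_from(x, x, x)
        sz = classify_seizure((100.0, 225.0), dff)
        propagation_halfmax(sz, dff)
        assert sz.origin == "hindbrain"  # fixed order: hindbrain first
        assert sz.origin_tie
        assert all(v == pytest.approx(0.0) for v in sz.halfmax_time.values())

    def test_low_peak_region_excluded(self):
        n = int(400 * 4)
        dff = region_dff_from(
            self._ramped(n, 113.0, amp=80.0), self._ramped(n, 100.0),
            self._ramped(n, 102.0),
        )
        sz = classify_seizure((100.0, 225.0), dff)
        propagation_halfmax(sz, dff)
        assert "anterior_forebrain" in sz.excluded_regions
        assert "anterior_forebrain" not in sz.halfmax_time

    def test_no_region_reaching_min_peak_errors(self):
        n = int(400 * 4)
        dff = region_dff_from(
            self._ramped(n, 100.0, amp=60.0),
            self._ramped(n, 100.0, amp=60.0),
            self._ramped(n, 100.0, amp=60.0),
        )
        sz = classify_seizure((100.0, 225.0), dff)
        with pytest.raises(ValueError, match="peak height"):
            propagation_halfmax(sz, dff)


class TestBasalActivitySd:
    def test_constant_is_zero(self):
        assert basal_activity_sd(np.zeros(4800), [(0.0, 120.0)], 4.0) == 0.0

    def test_alternating_unit_signal(self):
        x = np.tile([1.0, -1.0], 2400)
        assert basal_activity_sd(x, [(0.0, 120.0)], 4.0) == pytest.approx(1.0)

    def test_window_overlapping_seizure_rejected(self):
        from ictalscope.seizure import Seizure

        sz = Seizure(onset=100.0, offset=200.0)
        with pytest.raises(ValueError, match="overlaps"):
            basal_activity_sd(np.zeros(4800), [(150.0, 270.0)], 4.0, seizures=[sz])

    def test_mutant_lower_than_control_over_seeds(self):
        means = {}
        for genotype in ("homozygous_mutant", "wild_type"):
            sds = []
            for seed in range(8):
                params = SynthBrainParams(duration=1800.0, seed=seed, n_seizures=0)
                trace, _ = generate_brain_recording(params, genotype)
                dff = ic.compute_dff(trace, ic.baseline_whole_trace(trace))
                sds.append(
                    basal_activity_sd(
                        dff.column("whole_brain"),
                        [(i * 300.0, i * 300.0 + 120.0) for i in range(5)],
                        dff.sampling_rate,
                    )
                )
            means[genotype] = np.mean(sds)
        assert means["homozygous_mutant"] < means["wild_type"]


class TestPickBasalWindows:
    def test_windows_avoid_seizures_with_margin(self):
        from ictalscope.seizure import Seizure

        seizures = [Seizure(onset=1000.0, offset=1130.0)]
        windows = pick_basal_windows(3600.0, seizures, n_windows=5)
        assert len(windows) == 5
        for start, end in windows:
            assert end - start == pytest.approx(120.0)
            assert end <= 880.0 or start >= 1250.0

    def test_random_mode_reproducible(self):
        from ictalscope.seizure import Seizure

        seizures = [Seizure(onset=1000.0, offset=1130.0)]
        a = pick_basal_windows(3600.0, seizures, mode="random", seed=7)
        b = pick_basal_windows(3600.0, seizures, mode="random", seed=7)
        assert a == b


class TestGlialSeizureOnset:
    def test_constructed_onset_frame(self):
        x = np.zeros((1000, 3))
        x[480:600] = 80.0
        assert glial_seizure_onset(x) == [480]

    def test_never_reaching_fifty_empty(self):
        assert glial_seizure_onset(np.full((500, 4), 30.0)) == []

    def test_matches_run_oracle_on_random_patterns(self, rng):
        for _ in range(10):
            mean = rng.choice([0.0, 80.0], size=400, p=[0.9, 0.1])
            x = np.tile(mean[:, None], (1, 3))
            expected = [s for s, _ in run_length_oracle(mean, 50.0, 0.0, 1.0)]
            expected = [int(s) for s in expected]
            # oracle uses strict >, onset definition here is >= 50: adjust by
            # using a level that cannot be hit exactly
            assert glial_seizure_onset(x) == expected


class TestSeizureDetectorEndToEnd:
    def test_injected_seizures_all_detected(self):
        detected = truth_count = 0
        for seed in range(5):
            params = SynthBrainParams(duration=1800.0, seed=seed, n_seizures=2)
            trace, truth = generate_brain_recording(params, "homozygous_mutant")
            dff = ic.compute_dff(trace, ic.baseline_whole_trace(trace))
            det = SeizureDetector().fit(dff)
            detected += len(det.seizures_)
            truth_count += len(truth.seizures)
        assert detected == truth_count

    def test_global_seizures_all_exceed_one_minute(self):
        params = SynthBrainParams(duration=2400.0, seed=3, n_seizures=3)
        trace, _ = generate_brain_recording(params, "homozygous_mutant")
        dff = ic.compute_dff(trace, ic.baseline_whole_trace(trace))
        for sz in SeizureDetector().fit(dff).seizures_:
            if sz.seizure_class == "global":
                assert sz.duration > 60.0
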