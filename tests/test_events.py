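import numpy as np
import pytest

from ictalscope.events import (
    NoiseEventDetector,
    PeakEventDetector,
    auc,
    detect_events,
    detect_peaks,
    event_triggered_average,
    fit_noise,
)


def brute_force_prominence(x):
    """Exhaustive local-max + prominence oracle (topographic definition)."""
    peaks = []
    for i in range(1, len(x) - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            peaks.append(i)
    out = {}
    for i in peaks:
        # walk left until a higher point or the edge; track the minimum
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        left_base = left_min if j >= 0 else min(x[: i + 1])
        right_min = x[i]
        j = i + 1
        while j < len(x) and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        right_base = right_min if j < len(x) else min(x[i:])
        out[i] = x[i] - max(left_base, right_base)
    return out


class TestFitNoise:
    def test_sigma_recovered_on_gaussian(self, rng):
        x = rng.normal(0.0, 2.0, 100_000)
        nm = fit_noise(x)
        assert nm.sigma == pytest.approx(2.0, rel=0.05)
        assert nm.mu == pytest.approx(0.0, abs=0.05)

    def test_constant_trace_degenerate(self):
        nm = fit_noise(np.full(500, 3.0))
        assert nm.mu == 3.0
        assert nm.sigma == 0.0
        assert nm.degenerate

    def test_robust_to_sparse_boxcar_events(self, rng):
        # 10-sigma boxcars on <5% of samples must not inflate sigma
        x = rng.normal(0.0, 1.0, 20_000)
        for onset in range(500, 20_000, 2500):
            x[onset : onset + 100] += 10.0
        nm = fit_noise(x)
        assert nm.sigma == pytest.approx(1.0, rel=0.10)


class TestDetectEvents:
    def test_flat_zero_trace_no_events(self):
        assert detect_events(np.zeros(500), sampling_rate=4.0) == []

    def test_single_boxcar_recovered(self, rng):
        x = rng.normal(0.0, 1.0, 2400)
        x[1000:1020] += 10.0  # 5 s at 4 Hz, 10 sigma
        evs = [e for e in detect_events(x, sampling_rate=4.0) if e.amplitude > 5.0]
        assert len(evs) == 1
        ev = evs[0]
        assert ev.onset == pytest.approx(250.0, abs=0.25)
        assert ev.offset == pytest.approx(255.0, abs=0.25)
        assert ev.halfheight_width == pytest.approx(5.0, abs=0.5)

    def test_false_positive_occupancy_on_pure_noise(self):
        # one-sided 95% threshold: ~5% of samples supra-threshold, but the
        # 2-sample minimum length keeps event-occupied time below 1%
        occupied = []
        supra = []
        for seed in range(30):
            x = np.random.default_rng(seed).normal(0.0, 1.0, 2400)
            det = NoiseEventDetector().fit(x)
            supra.append(np.mean(x > det.threshold_))
            evs = det.detect(x, sampling_rate=4.0)
            occupied.append(sum(e.duration for e in evs) / 600.0)
        assert np.mean(supra) == pytest.approx(0.05, abs=0.005)
        assert np.mean(occupied) < 0.01

    def test_raising_ci_never_increases_events(self, rng):
        x = rng.normal(0.0, 1.0, 4000)
        x[100:140] += 4.0
        counts = [
            len(NoiseEventDetector(ci_level=ci).fit_detect(x, sampling_rate=4.0))
            for ci in (0.90, 0.95, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_degenerate_noise_on_nonconstant_trace_errors(self):
        det = NoiseEventDetector().fit(np.zeros(500))
        with pytest.raises(ValueError, match="degenerate"):
            det.detect(np.arange(500.0), sampling_rate=4.0)


class TestDetectPeaks:
    def test_monotone_ramp_has_no_peaks(self):
        assert detect_peaks(np.linspace(0, 50, 200), sampling_rate=4.0) == []

    def test_single_triangle(self):
        x = np.concatenate([np.linspace(0, 20, 41), np.linspace(20, 0, 41)[1:]])
        evs = detect_peaks(x, sampling_rate=4.0)
        assert len(evs) == 1
        assert evs[0].amplitude == pytest.approx(20.0)
        # half-height width of a symmetric triangle is half its base
        assert evs[0].halfheight_width == pytest.approx(10.0, abs=0.25)

    def test_two_bumps_prominence_matches_oracle(self):
        # overlapping bumps: the lesser peak's prominence is measured against
        # the saddle between them, the greater peak's against the base
        t = np.linspace(0, 20, 801)
        x = 10.0 * np.exp(-((t - 8) ** 2) / 2) + 9.0 * np.exp(-((t - 12) ** 2) / 2)
        oracle = brute_force_prominence(x)
        proms = sorted(oracle.values())
        evs = detect_peaks(x, min_height=5.0, min_prominence=1.0, sampling_rate=40.0)
        assert len(evs) == 2
        for ev, i in zip(evs, sorted(oracle)):
            assert ev.peak_time == pytest.approx(t[i], abs=0.05)
            assert ev.amplitude == pytest.approx(x[i])
        # sweeping the prominence gate reproduces the oracle's partition
        between = 0.5 * (proms[0] + proms[1])
        assert len(detect_peaks(x, 5.0, between, sampling_rate=40.0)) == 1
        assert len(detect_peaks(x, 5.0, proms[1] + 0.1, sampling_rate=40.0)) == 0

    def test_raising_thresholds_monotone(self, rng):
        x = np.abs(rng.normal(0, 5, 2000))
        for param in ("min_height", "min_prominence"):
            counts = [
                len(detect_peaks(x, sampling_rate=4.0, **{param: v}))
                for v in (2.0, 5.0, 10.0)
            ]
            assert counts == sorted(counts, reverse=True)


class TestAuc:
    def test_constant_segment(self):
        # 1% over 2 s: 9 samples at 4 Hz
        assert auc(np.ones(9), 4.0) == pytest.approx(2.0)

    def test_triangle_half_base_height(self):
        # base 4 s at 4 Hz (17 samples), height 10 -> 0.5*4*10 = 20
        x = np.concatenate([np.linspace(0, 10, 9), np.linspace(10, 0, 9)[1:]])
        assert auc(x, 4.0) == pytest.approx(20.0)

    def test_matches_fine_grid_oracle(self, rng):
        t = np.arange(200) / 4.0
        x = np.interp(t, [0, 10, 20, 30, 50], [0, 5, 1, 8, 0]) + rng.normal(
            0, 0.01, t.size
        )
        fine_t = np.arange(20_000) / 400.0
        fine = np.interp(fine_t, t, x)
        assert auc(x, 4.0) == pytest.approx(np.trapezoid(fine, fine_t), rel=0.005)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0], 4.0)

    def test_additive_over_partition(self, rng):
        x = rng.normal(0, 1, 101)
        whole = auc(x, 4.0)
        left, right = auc(x[:51], 4.0), auc(x[50:], 4.0)
        assert whole == pytest.approx(left + right)


class TestEventTriggeredAverage:
    def test_identical_segments_zero_sem(self):
        x = np.tile(np.array([0, 1, 2, 1.0]), 50)
        rel, mean, sem, n = event_triggered_average(
            x, [8.0, 16.0, 24.0], 1.0, 3.0, sampling_rate=1.0
        )
        assert n == 3
        np.testing.assert_allclose(mean, [1.0, 0.0, 1.0, 2.0])
        np.testing.assert_allclose(sem, 0.0)

    def test_two_segment_mean(self):
        x = np.array([0.0, 2.0, 2.0, 0.0])
        rel, mean, sem, n = event_triggered_average(
            x, [0.0, 2.0], 0.0, 2.0, sampling_rate=1.0
        )
        np.testing.assert_allclose(mean, [1.0, 1.0])

    def test_edge_onsets_dropped(self):
        x = np.zeros(100)
        rel, mean, sem, n = event_triggered_average(
            x, [0.5, 50.0], 5.0, 5.0, sampling_rate=1.0
        )
        assert n == 1

    def test_noisy_template_recovered_within_clt_bound(self, rng):
        template = np.sin(np.linspace(0, np.pi, 40))
        sigma = 0.2  # SNR 5
        n_seg = 50
        x = np.zeros(40 * (n_seg + 2))
        onsets = []
        for k in range(n_seg):
            i = 40 * (k + 1)
            x[i : i + 40] = template
            onsets.append(i / 4.0)
        x += rng.normal(0, sigma, x.size)
        _, mean, _, n = event_triggered_average(x, onsets, 0.0, 10.0, sampling_rate=4.0)
        assert n == n_seg
        assert np.all(np.abs(mean - template) < 3 * sigma / np.sqrt(n_seg))
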