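"""Filtering, baseline estimation, miniature-event detection and summaries."""

import math

import numpy as np
import pytest

from conftest import match_events
from marmodev._util import AnalysisError, ConfigurationError
from marmodev.ephys import (CellSummary, DetectionParams, EventList, LTDSeries,
                            Trace, bandpass_filter, default_params,
                            detect_minis, ei_ratio, estimate_baseline_sd,
                            group_compare, ltd_magnitude, paired_pulse_ratio,
                            phenotype_logfc, summarize_cells)
from marmodev.synthetic import SimConfig, gen_mini_trace

FS = 10_000.0
P3M = default_params("3M", "mEPSC")


def _sine(freq, duration=10.0):
    t = np.arange(int(duration * FS)) / FS
    return Trace(samples=np.sin(2 * np.pi * freq * t), sampling_hz=FS)


class TestBandpass:
    def test_dc_component_removed(self):
        trace = Trace(samples=np.full(int(5 * FS), 50.0), sampling_hz=FS)
        out = bandpass_filter(trace, P3M)
        assert abs(out.samples.mean()) < 1e-6

    def test_passband_tone_preserved(self):
        out = bandpass_filter(_sine(100.0), P3M)
        rms_in = 1.0 / np.sqrt(2)
        rms_out = np.sqrt(np.mean(out.samples ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.10

    def test_subband_tone_suppressed(self):
        out = bandpass_filter(_sine(0.5, duration=20.0), P3M)
        rms_in = 1.0 / np.sqrt(2)
        rms_out = np.sqrt(np.mean(out.samples ** 2))
        assert rms_out < 0.1 * rms_in

    def test_band_edge_beyond_nyquist_rejected(self):
        bad = DetectionParams(amp_thresh_sd=2, area_thresh_sd_ms=3,
                              band_high_hz=6000.0)
        with pytest.raises(ConfigurationError, match="Nyquist"):
            bandpass_filter(_sine(10.0), bad)


class TestBaselineSD:
    def test_recovers_noise_sigma(self):
        rng = np.random.default_rng(0)
        estimates = [estimate_baseline_sd(
            Trace(samples=rng.normal(0, 2.0, int(60 * FS)), sampling_hz=FS),
            P3M) for _ in range(20)]
        assert 1.6 <= np.median(estimates) <= 2.4

    def test_constant_trace_has_zero_sd(self):
        trace = Trace(samples=np.full(int(2 * FS), 7.0), sampling_hz=FS)
        assert estimate_baseline_sd(trace, P3M) == 0.0

    def test_window_avoids_a_single_large_event(self):
        x = np.zeros(int(10 * FS))
        x[50_000:50_200] = -100.0
        trace = Trace(samples=x, sampling_hz=FS)
        assert estimate_baseline_sd(trace, P3M) == 0.0

    def test_short_trace_rejected(self):
        trace = Trace(samples=np.zeros(100), sampling_hz=FS)
        with pytest.raises(AnalysisError, match="short"):
            estimate_baseline_sd(trace, P3M)


class TestDetection:
    @pytest.mark.parametrize("seed", range(4, 9))
    def test_single_large_event_detected_exactly_once(self, seed):
        # 0M thresholds (3 SD, 4.5 SD*ms): a 10x-SD broad event clears both
        cfg = SimConfig(seed=seed, duration_s=10.0, event_rate_hz=0.0,
                        noise_sd_pa=1.0)
        trace, _ = gen_mini_trace(cfg)
        kernel_t = np.arange(0, 0.04, 1 / FS)
        kernel = np.exp(-kernel_t / 5e-3) - np.exp(-kernel_t / 0.5e-3)
        kernel /= kernel.max()
        i0 = int(5.0 * FS)
        trace.samples[i0:i0 + kernel.size] -= 10.0 * kernel  # 10x noise SD
        events = detect_minis(trace, default_params("0M", "mEPSC"))
        assert len(events) == 1
        assert events.events.peak_s.iloc[0] == pytest.approx(5.0, abs=0.005)

    def test_ground_truth_recall_and_precision(self):
        tp = n_det = n_true = 0
        for seed in range(1, 6):
            trace, truth = gen_mini_trace(SimConfig(
                seed=seed, duration_s=60.0, event_rate_hz=1.0,
                amp_mean_pa=10.0, noise_sd_pa=1.25))
            det = detect_minis(trace, P3M)
            tp += match_events(det.events.peak_s.to_numpy(),
                               truth.events.peak_s.to_numpy())
            n_det += len(det)
            n_true += len(truth)
        assert tp / n_true >= 0.9
        assert tp / n_det >= 0.9

    def test_false_positive_rate_on_pure_noise(self):
        trace, _ = gen_mini_trace(SimConfig(
            seed=2, duration_s=60.0, event_rate_hz=0.0, noise_sd_pa=1.25))
        assert len(detect_minis(trace, P3M)) / 60.0 <= 0.2

    def test_raising_thresholds_never_adds_events(self):
        trace, _ = gen_mini_trace(SimConfig(seed=5, duration_s=30.0))
        baseline_count = len(detect_minis(trace, P3M))
        for amp, area in [(2.5, 3.0), (3.0, 3.0), (2.0, 4.5), (2.0, 6.0),
                          (3.0, 9.0)]:
            raised = DetectionParams(amp_thresh_sd=amp,
                                     area_thresh_sd_ms=area)
            assert len(detect_minis(trace, raised)) <= baseline_count

    def test_detection_invariant_to_polarity(self):
        trace, _ = gen_mini_trace(SimConfig(seed=6, duration_s=20.0))
        flipped = Trace(samples=-trace.samples, sampling_hz=trace.sampling_hz,
                        polarity="positive", condition=trace.condition,
                        age=trace.age)
        e1 = detect_minis(trace, P3M).events
        e2 = detect_minis(flipped, P3M).events
        np.testing.assert_allclose(e1.to_numpy(dtype=float),
                                   e2.to_numpy(dtype=float))

    def test_degenerate_baseline_with_signal_errors(self):
        x = np.zeros(int(5 * FS))
        x[25_000] = -30.0  # single impulse: flat baseline, nonzero signal
        trace = Trace(samples=x, sampling_hz=FS)
        with pytest.raises(AnalysisError, match="degenerate"):
            detect_minis(trace, P3M)

    def test_default_threshold_table(self):
        assert (P3M.amp_thresh_sd, P3M.area_thresh_sd_ms) == (2.0, 3.0)
        p0 = default_params("0M", "mIPSC")
        assert (p0.amp_thresh_sd, p0.area_thresh_sd_ms) == (3.0, 9.0)
        with pytest.raises(ConfigurationError):
            default_params("9M", "mEPSC")


class TestSummaries:
    def test_frequency_and_amplitude(self):
        import pandas as pd
        events = EventList(events=pd.DataFrame({
            "onset_s": np.arange(30) * 2.0, "peak_s": np.arange(30) * 2.0,
            "peak_amplitude_pa": [10.0, 20.0, 30.0] * 10,
            "area_pa_ms": np.ones(30)}), trace_duration_s=60.0)
        s = summarize_cells(events)
        assert s.frequency_hz == pytest.approx(0.5)
        assert s.mean_amplitude_pa == pytest.approx(20.0)

    def test_empty_event_list_flags_amplitude(self):
        s = summarize_cells(EventList(events=None, trace_duration_s=60.0))
        assert s.frequency_hz == 0.0
        assert s.amplitude_missing


class TestRatiosAndLTD:
    def test_ei_ratio_values(self):
        assert ei_ratio(2.0, 4.0) == pytest.approx(0.5)
        assert ei_ratio(3.0, 3.0) == pytest.approx(1.0)
        assert math.isnan(ei_ratio(2.0, 0.0))

    def test_ei_ratio_logfc_decomposition(self):
        # logFC of the E/I ratio of group means equals logFC(E) - logFC(I)
        ue_e, vpa_e = [1.0, 1.2, 0.9], [0.6, 0.7, 0.65]
        ue_i, vpa_i = [2.0, 2.1], [2.4, 2.6]
        lhs = phenotype_logfc([np.mean(ue_e) / np.mean(ue_i)],
                              [np.mean(vpa_e) / np.mean(vpa_i)])
        rhs = phenotype_logfc(ue_e, vpa_e) - phenotype_logfc(ue_i, vpa_i)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_ltd_magnitude_against_window_means(self):
        rng = np.random.default_rng(0)
        times = np.arange(-9.5, 40.5, 0.5)
        amps = rng.uniform(50.0, 150.0, times.size)
        series = LTDSeries(times_min=times, amplitudes=amps)
        base = amps[(times > -10) & (times <= 0)].mean()
        post = amps[(times >= 30) & (times <= 40)].mean()
        assert ltd_magnitude(series) == pytest.approx(post / base, abs=1e-12)

    def test_ltd_normalization_is_idempotent_and_scale_free(self):
        times = np.arange(-9.5, 40.5, 0.5)
        amps = np.where(times <= 0, 100.0, 80.0)
        series = LTDSeries(times_min=times, amplitudes=amps)
        assert ltd_magnitude(series) == pytest.approx(0.8)
        scaled = LTDSeries(times_min=times, amplitudes=amps * 37.0)
        assert ltd_magnitude(scaled) == pytest.approx(0.8)

    def test_ltd_requires_window_coverage(self):
        series = LTDSeries(times_min=np.arange(-9.5, 10.0, 0.5),
                           amplitudes=np.ones(39))
        with pytest.raises(AnalysisError, match="post-LFS"):
            ltd_magnitude(series)

    def test_paired_pulse_ratio(self):
        assert paired_pulse_ratio(100.0, 50.0) == pytest.approx(0.5)
        assert paired_pulse_ratio(80.0, 80.0) == pytest.approx(1.0)
        with pytest.raises(AnalysisError):
            paired_pulse_ratio(0.0, 10.0)

    def test_phenotype_logfc_values(self):
        assert phenotype_logfc([1.0], [2.0]) == pytest.approx(1.0)
        assert phenotype_logfc([3.0], [3.0]) == pytest.approx(0.0)
        assert phenotype_logfc([0.5], [0.25]) == pytest.approx(-1.0)
        with pytest.raises(AnalysisError):
            phenotype_logfc([0.0], [1.0])


def _holm_sidak_oracle(p_raw):
    """Step-down Sidak: adjusted_i = 1-(1-p_(i))^(m-i+1), monotone."""
    order = np.argsort(p_raw)
    m = len(p_raw)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - p_raw[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = running
    return adj


class TestGroupCompare:
    def test_identical_groups_give_p_one(self):
        vals = {"0M": ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])}
        out = group_compare(vals)
        assert out.loc["0M", "p_raw"] == pytest.approx(1.0)
        assert out.loc["0M", "p_adj"] == pytest.approx(1.0)

    def test_holm_sidak_oracle_frozen_example(self):
        adj = _holm_sidak_oracle(np.array([0.01, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.029701, 0.059100, 0.059100],
                                   atol=5e-5)

    def test_adjustment_matches_stepdown_oracle(self):
        rng = np.random.default_rng(1)
        vals = {age: (rng.normal(0, 1, 6), rng.normal(d, 1, 6))
                for age, d in zip(("0M", "3M", "6M"), (0.0, 1.5, 3.0))}
        out = group_compare(vals)
        expected = _holm_sidak_oracle(out["p_raw"].to_numpy())
        np.testing.assert_allclose(out["p_adj"].to_numpy(), expected,
                                   rtol=1e-10)

    def test_insufficient_group_flagged_and_excluded(self):
        vals = {"0M": ([1.0], [2.0, 3.0]),
                "3M": ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])}
        out = group_compare(vals)
        assert out.loc["0M", "missing"]
        assert math.isnan(out.loc["0M", "p_adj"])
        # single testable comparison: adjusted equals raw
        assert out.loc["3M", "p_adj"] == pytest.approx(
            out.loc["3M", "p_raw"])
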