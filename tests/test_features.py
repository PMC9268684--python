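"""Unit tests for waveform and spike-train feature extraction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dgephys.errors import DegenerateWaveformError, ParameterError
from dgephys.features import (
    SpikeTrain,
    WaveformTemplate,
    ahp_derivative_metric,
    burst_index,
    extract_features,
    first_derivative,
    isi_histogram,
    mean_firing_rate,
    trough_to_peak_latency,
)
from dgephys.synthetic import WaveformParams, generate_waveform

from conftest import make_train


def _bump_waveform(trough_idx=40, peak_idx=46, n=64, trough=-100.0, peak=40.0):
    """Piecewise-linear trough/peak waveform with extrema at given samples."""
    v = np.zeros(n)
    v[: trough_idx + 1] = np.linspace(0, trough, trough_idx + 1)
    v[trough_idx : peak_idx + 1] = np.linspace(trough, peak, peak_idx - trough_idx + 1)
    v[peak_idx:] = np.linspace(peak, 0, n - peak_idx)
    return WaveformTemplate(v, 20_000.0)


class TestTroughToPeakLatency:
    def test_sample_count_latency(self):
        # trough at sample 40, peak at 46 -> 6 samples x 0.05 ms
        wf = _bump_waveform(40, 46)
        assert trough_to_peak_latency(wf, interpolate=False) == pytest.approx(0.30)

    @pytest.mark.parametrize("ttp", [0.15, 0.25, 0.4, 0.6, 0.8, 1.0])
    def test_generator_ground_truth_recovery(self, ttp):
        wf = generate_waveform(WaveformParams(trough_to_peak_ms=ttp, noise_sd_uv=0.0))
        assert trough_to_peak_latency(wf, interpolate=False) == pytest.approx(ttp, abs=0.05)
        assert trough_to_peak_latency(wf, interpolate=True) == pytest.approx(ttp, abs=0.02)

    def test_monotone_decay_is_degenerate(self):
        wf = WaveformTemplate(np.linspace(0.0, -100.0, 64), 20_000.0)
        with pytest.raises(DegenerateWaveformError):
            trough_to_peak_latency(wf, flip_inverted=False)

    def test_monotone_rise_after_trough_is_degenerate(self):
        v = np.concatenate([np.linspace(0, -100, 20), np.linspace(-100, 50, 44)[1:]])
        with pytest.raises(DegenerateWaveformError):
            trough_to_peak_latency(WaveformTemplate(v, 20_000.0))

    def test_inverted_polarity_flipped_with_warning(self):
        wf = _bump_waveform(40, 46)
        with pytest.warns(UserWarning, match="inverted"):
            lat = trough_to_peak_latency(WaveformTemplate(-wf.samples, 20_000.0), interpolate=False)
        assert lat == pytest.approx(0.30)

    def test_latency_invariant_under_amplitude_scaling(self):
        wf = generate_waveform(WaveformParams(trough_to_peak_ms=0.6, noise_sd_uv=0.0))
        scaled = WaveformTemplate(wf.samples * 3.7, wf.sampling_rate_hz)
        assert trough_to_peak_latency(scaled) == pytest.approx(trough_to_peak_latency(wf))

    def test_too_short_waveform_rejected(self):
        with pytest.raises(ParameterError):
            WaveformTemplate(np.zeros(8), 20_000.0)


class TestFirstDerivative:
    def test_constant_waveform_zero_derivative(self):
        wf = WaveformTemplate(np.full(32, 5.0), 20_000.0)
        assert np.allclose(first_derivative(wf), 0.0)

    def test_linear_ramp_slope(self):
        # 1 uV per sample at 20 kHz = 20 uV/ms
        wf = WaveformTemplate(np.arange(32, dtype=float), 20_000.0)
        assert np.allclose(first_derivative(wf), 20.0)

    def test_linearity_under_scaling(self):
        wf = generate_waveform(WaveformParams(trough_to_peak_ms=0.5, noise_sd_uv=0.0))
        d1 = first_derivative(wf)
        d2 = first_derivative(WaveformTemplate(wf.samples * 2.0, wf.sampling_rate_hz))
        assert np.allclose(d2, 2.0 * d1)


class TestAHPMetric:
    @pytest.mark.parametrize("slope", [40.0, 70.0, 120.0])
    def test_generator_ground_truth_within_5pct(self, slope):
        wf = generate_waveform(
            WaveformParams(trough_to_peak_ms=0.6, ahp_slope_uv_per_ms=slope, noise_sd_uv=0.0)
        )
        assert ahp_derivative_metric(wf) == pytest.approx(slope, rel=0.05)

    def test_flat_tail_gives_zero(self):
        v = np.zeros(64)
        v[: 21] = np.linspace(0, -100, 21)
        v[20 : 31] = np.linspace(-100, 40, 11)
        v[30:] = 40.0  # flat after the peak
        assert ahp_derivative_metric(WaveformTemplate(v, 20_000.0)) == 0.0

    def test_homogeneous_degree_one_in_amplitude(self):
        wf = generate_waveform(WaveformParams(trough_to_peak_ms=0.6, noise_sd_uv=0.0))
        m1 = ahp_derivative_metric(wf)
        m2 = ahp_derivative_metric(WaveformTemplate(wf.samples * 2.0, wf.sampling_rate_hz))
        assert m2 == pytest.approx(2.0 * m1)

    def test_tiny_post_peak_window_degenerate(self):
        v = np.zeros(20)
        v[:10] = np.linspace(0, -100, 10)
        v[9:19] = np.linspace(-100, 40, 10)
        v[19] = 20.0
        with pytest.raises(DegenerateWaveformError):
            ahp_derivative_metric(WaveformTemplate(v, 20_000.0))


class TestISIHistogram:
    def test_direct_counts(self):
        train = make_train([5.2, 5.3, 250.5])
        hist = isi_histogram(train, bin_width_ms=1.0)
        assert hist.counts[5] == 2
        assert hist.counts[250] == 1
        assert hist.counts.sum() == 3

    def test_single_spike_all_zero(self):
        train = SpikeTrain(np.array([0.5]), 10.0)
        assert isi_histogram(train).counts.sum() == 0

    def test_out_of_range_intervals_excluded(self):
        train = make_train([5.0, 400.0, 5.0])
        hist = isi_histogram(train)
        assert hist.counts.sum() == 2

    @given(st.lists(st.floats(min_value=0.5, max_value=500.0), min_size=1, max_size=200))
    def test_total_matches_bruteforce_recount(self, isis):
        train = make_train(isis)
        hist = isi_histogram(train)
        expected = sum(1 for isi in np.diff(train.times_s) * 1000.0 if isi < 300.0)
        assert hist.counts.sum() == expected


class TestBurstIndex:
    def test_hand_counted_window_masses(self):
        # 30 ISIs at 5 ms and 20 at 250 ms: (30/10)/(20/100) = 15
        train = make_train([5.0] * 30 + [250.0] * 20)
        assert burst_index(train) == pytest.approx(15.0)

    def test_both_windows_empty_is_zero(self):
        train = make_train([100.0] * 20)
        assert burst_index(train) == 0.0

    def test_zero_denominator_is_infinite(self):
        train = make_train([4.0] * 400)
        assert burst_index(train) == np.inf

    def test_fewer_than_two_spikes_zero(self):
        assert burst_index(SpikeTrain(np.array([1.0]), 10.0)) == 0.0
        assert burst_index(SpikeTrain(np.array([]), 10.0)) == 0.0

    def test_raw_count_mode(self):
        train = make_train([5.0] * 30 + [250.0] * 20)
        assert burst_index(train, normalize_by_width=False) == pytest.approx(1.5)

    @given(
        st.lists(
            st.one_of(
                st.floats(min_value=1.0, max_value=9.5),
                st.floats(min_value=30.0, max_value=180.0),
                st.floats(min_value=200.5, max_value=299.0),
                st.floats(min_value=320.0, max_value=900.0),
            ),
            min_size=2,
            max_size=300,
        )
    )
    def test_oracle_equivalence_bruteforce_loop(self, isis):
        """Windowed BI equals an explicit loop over successive ISIs, exactly."""
        train = make_train(isis)
        n_early = n_late = 0
        times = train.times_s
        for a, b in zip(times[:-1], times[1:]):
            isi = (b - a) * 1000.0
            if 0.0 <= isi < 10.0:
                n_early += 1
            elif 200.0 <= isi < 300.0:
                n_late += 1
        if n_early == 0:
            expected = 0.0
        elif n_late == 0:
            expected = np.inf
        else:
            expected = (n_early / 10.0) / (n_late / 100.0)
        assert burst_index(train) == expected


class TestMeanFiringRate:
    def test_count_over_duration(self):
        train = SpikeTrain(np.linspace(0.05, 9.95, 100), 10.0)
        assert mean_firing_rate(train) == pytest.approx(10.0)

    def test_empty_train_zero(self):
        assert mean_firing_rate(SpikeTrain(np.array([]), 10.0)) == 0.0

    def test_invalid_duration_rejected(self):
        with pytest.raises(ParameterError):
            SpikeTrain(np.array([1.0]), 0.0)


class TestExtractFeatures:
    def test_generator_unit_within_tolerances(self):
        wp = WaveformParams(trough_to_peak_ms=0.25, ahp_slope_uv_per_ms=90.0, noise_sd_uv=0.0)
        wf = generate_waveform(wp)
        train = make_train([4.0] * 50)
        feats = extract_features(wf, train)
        assert feats.trough_to_peak_ms == pytest.approx(0.25, abs=0.02)
        assert feats.ahp_uv_per_ms == pytest.approx(90.0, rel=0.05)
        assert feats.burst_index == np.inf
        assert "infinite_burst_index" in feats.flags

    def test_single_spike_partial_features(self):
        wf = generate_waveform(WaveformParams(trough_to_peak_ms=0.6, noise_sd_uv=0.0))
        feats = extract_features(wf, SpikeTrain(np.array([1.0]), 10.0))
        assert feats.firing_rate_hz == pytest.approx(0.1)
        assert feats.burst_index == 0.0
        assert "few_spikes" in feats.flags
        assert np.isfinite(feats.trough_to_peak_ms)

    def test_degenerate_waveform_flagged_not_fatal(self):
        wf = WaveformTemplate(np.linspace(0.0, -100.0, 64), 20_000.0)
        feats = extract_features(wf, make_train([10.0] * 5))
        assert "degenerate_waveform" in feats.flags
        assert np.isnan(feats.trough_to_peak_ms)
        assert np.isfinite(feats.firing_rate_hz)
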