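"""Contractility metrics: arithmetic examples, identities, and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirlymph.ampd import PeakTroughSet, detect_peaks_and_troughs
from nirlymph.errors import InvalidInputError, UndefinedMeanError
from nirlymph.metrics import (
    InstantaneousMean,
    contraction_frequency,
    deviation_stats,
    instantaneous_mean,
    measure_cycles,
    normalize_to_baseline,
    pearson_correlation,
    percent_amplitude,
    pumping_score,
    summarize_trace,
    tone_change,
)
from nirlymph.phantom import ContractionWaveformParams, generate_traces
from nirlymph.trace import Trace


def events_at(peaks, troughs):
    return PeakTroughSet(
        peak_indices=np.asarray(peaks, dtype=int),
        trough_indices=np.asarray(troughs, dtype=int),
    )


class TestInstantaneousMean:
    def test_constant_trace(self):
        x = np.full(120, 100.0)
        im = instantaneous_mean(x, events_at([20, 50, 80], [35, 65]))
        np.testing.assert_allclose(im.values, 100.0)

    def test_linear_ramp_interior(self):
        x = np.linspace(0.0, 119.0, 120)
        im = instantaneous_mean(x, events_at([20, 50, 80], [35, 65]))
        hw = im.half_window
        np.testing.assert_allclose(im.values[hw:-hw], x[hw:-hw], atol=1e-9)

    def test_sinusoid_matches_convolution_oracle(self):
        # 1.5-period window: residual oscillation is |sinc(1.5)| ~ 0.205 of
        # the amplitude, i.e. +-2.05 for amplitude 10 (direct evaluation)
        t = np.arange(480)
        x = 100 + 10 * np.sin(2 * np.pi * t / 24)
        ev = detect_peaks_and_troughs(x)
        im = instantaneous_mean(x, ev)
        w = 2 * im.half_window + 1
        oracle = np.convolve(x, np.ones(w) / w, mode="valid")
        np.testing.assert_allclose(im.values[im.half_window : -im.half_window], oracle, rtol=1e-12)
        assert np.abs(oracle - 100).max() < 2.1

    def test_fewer_than_two_peaks_undefined(self):
        with pytest.raises(UndefinedMeanError):
            instantaneous_mean(np.ones(50), events_at([10], []))


class TestMeasureCycles:
    def test_two_cycles_forty_percent(self):
        x = np.full(120, 100.0)
        x[[25, 75]] = 120.0
        x[[50, 100]] = 80.0
        im = InstantaneousMean(values=np.full(120, 100.0), half_window=0)
        cycles = measure_cycles(x, events_at([25, 75], [50, 100]), im)
        assert len(cycles) == 2
        assert all(c.pct_amplitude == pytest.approx(40.0) for c in cycles)

    def test_peak_without_following_trough(self):
        x = np.zeros(60)
        im = InstantaneousMean(values=np.ones(60), half_window=0)
        assert measure_cycles(x, events_at([30], []), im) == []

    def test_edge_cycles_dropped(self):
        x = np.full(120, 100.0)
        im = InstantaneousMean(values=np.full(120, 100.0), half_window=30)
        cycles = measure_cycles(x, events_at([10, 60], [40, 115]), im)
        # only the 60 -> (trough beyond the right margin) pairing survives? no:
        # peak 10 is inside the left margin, trough 115 inside the right one
        assert [(c.peak_index, c.trough_index) for c in cycles] == [(60, 40)] or cycles == []
        # re-check with interior events only
        cycles = measure_cycles(x, events_at([40, 80], [60]), im)
        assert [(c.peak_index, c.trough_index) for c in cycles] == [(40, 60)]

    def test_phantom_depth_recovered_against_generator(self):
        wave = ContractionWaveformParams(depth=0.3, frequency_per_min=6.0)
        trace, _ = generate_traces(wave, "diameter")
        s = summarize_trace(trace)
        assert s.pct_amplitude == pytest.approx(30.0, abs=1.0)


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "n_peaks,duration,expected",
        [(18, 180.0, 6.0), (0, 180.0, 0.0), (13, 120.0, 6.5)],
    )
    def test_frequency(self, n_peaks, duration, expected):
        ev = events_at(np.arange(n_peaks), [])
        assert contraction_frequency(ev, duration) == pytest.approx(expected)

    def test_frequency_rejects_bad_duration(self):
        with pytest.raises(InvalidInputError):
            contraction_frequency(events_at([1], []), 0.0)

    def test_percent_amplitude(self):
        from nirlymph.metrics import CycleMeasurement

        cyc = lambda a: CycleMeasurement(0, 1, 0, 0, 1, a)
        assert percent_amplitude([cyc(40), cyc(40)]) == pytest.approx(40.0)
        assert math.isnan(percent_amplitude([]))
        assert percent_amplitude([cyc(30), cyc(50), cyc(40)]) == pytest.approx(40.0)

    def test_pumping_score(self):
        assert pumping_score(6.5, 40.0) == pytest.approx(260.0)
        assert pumping_score(0.0, math.nan) == 0.0
        assert math.isnan(pumping_score(2.0, math.nan))
        assert pumping_score(10.0, 30.0) == pytest.approx(300.0)

    def test_tone_change(self):
        x = np.linspace(900, 1100, 50)
        assert tone_change(x, x) == pytest.approx(100.0)
        assert tone_change(np.full(10, 1000.0), np.full(10, 656.0)) == pytest.approx(65.6)
        assert tone_change(x, 2 * x) == pytest.approx(200.0)
        with pytest.raises(InvalidInputError):
            tone_change(np.zeros(10), x)

    def test_pearson(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(a, 2 * a + 1) == pytest.approx(1.0)
        assert pearson_correlation(a, -a) == pytest.approx(-1.0)
        assert pearson_correlation(a, np.array([1.0, 3.0, 2.0, 4.0])) == pytest.approx(0.8)
        with pytest.raises(InvalidInputError):
            pearson_correlation(a, np.ones(4))

    def test_deviation_stats(self):
        assert deviation_stats([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)
        mad, rmsd = deviation_stats([1, 2, 3], [2, 2, 5])
        assert mad == pytest.approx(1.0)
        assert rmsd == pytest.approx(math.sqrt(5 / 3))
        assert deviation_stats([10.0], [13.0]) == (3.0, 3.0)
        with pytest.raises(InvalidInputError):
            deviation_stats([1, 2], [1, 2, 3])

    @given(st.integers(0, 2**16))
    def test_rmsd_at_least_mad(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 20))
        mad, rmsd = deviation_stats(a, b)
        assert rmsd >= mad - 1e-12


class TestSummarize:
    def test_phantom_six_per_min_forty_percent(self):
        wave = ContractionWaveformParams(depth=0.4, frequency_per_min=6.0)
        trace, _ = generate_traces(wave, "diameter")
        s = summarize_trace(trace)
        assert s.frequency == pytest.approx(6.0)
        assert s.pct_amplitude == pytest.approx(40.0, abs=1.0)
        assert s.pumping_score == pytest.approx(240.0, abs=6.0)

    def test_constant_trace_is_quiescent(self):
        s = summarize_trace(Trace(np.full(100, 42.0), 2.5))
        assert s.frequency == 0.0
        assert math.isnan(s.pct_amplitude)
        assert s.pumping_score == 0.0
        assert s.mean_level == pytest.approx(42.0)

    def test_disjoint_windows_of_stationary_phantom_agree(self):
        wave = ContractionWaveformParams(depth=0.3, frequency_per_min=6.0)
        trace, _ = generate_traces(wave, "diameter", noise_sigma=0.3, duration=360.0, seed=7)
        s1 = summarize_trace(trace, (0.0, 180.0))
        s2 = summarize_trace(trace, (180.0, 360.0))
        assert s1.frequency == pytest.approx(s2.frequency, abs=0.4)
        assert s1.pct_amplitude == pytest.approx(s2.pct_amplitude, abs=2.0)

    def test_pumping_identity_holds_exactly(self):
        wave = ContractionWaveformParams(depth=0.25, frequency_per_min=8.0)
        trace, _ = generate_traces(wave, "diameter", noise_sigma=0.5, seed=3)
        s = summarize_trace(trace)
        assert s.pumping_score == s.frequency * s.pct_amplitude

    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, factor):
        wave = ContractionWaveformParams(depth=0.3, frequency_per_min=6.0)
        trace, _ = generate_traces(wave, "diameter", noise_sigma=0.4, duration=120.0, seed=11)
        s1 = summarize_trace(trace)
        s2 = summarize_trace(Trace(factor * trace.values, trace.sample_rate))
        assert s2.frequency == s1.frequency
        assert s2.pct_amplitude == pytest.approx(s1.pct_amplitude, rel=1e-9)
        assert s2.pumping_score == pytest.approx(s1.pumping_score, rel=1e-9)

    def test_window_mean_amplitude_mode(self):
        wave = ContractionWaveformParams(depth=0.3, frequency_per_min=6.0)
        trace, _ = generate_traces(wave, "diameter")
        s = summarize_trace(trace, amplitude_mode="window_mean")
        assert s.pct_amplitude == pytest.approx(30.0, abs=2.0)


class TestTreatment:
    def _summary(self, **kw):
        from nirlymph.metrics import ContractilitySummary

        base = dict(
            frequency=6.0, pct_amplitude=40.0, pumping_score=240.0,
            mean_level=100.0, n_cycles=10, window=(0.0, 120.0),
        )
        base.update(kw)
        return ContractilitySummary(**base)

    def test_identical_summaries_are_100_percent(self):
        s = self._summary()
        eff = normalize_to_baseline(s, s)
        assert eff.frequency_pct == eff.amplitude_pct == eff.pumping_pct == eff.tone_pct == 100.0

    def test_frequency_ratio(self):
        eff = normalize_to_baseline(self._summary(), self._summary(frequency=9.0))
        assert eff.frequency_pct == pytest.approx(150.0)

    def test_pumping_ratio(self):
        eff = normalize_to_baseline(
            self._summary(pumping_score=260.0), self._summary(pumping_score=130.0)
        )
        assert eff.pumping_pct == pytest.approx(50.0)

    def test_zero_baseline_metric_flagged_not_fatal(self):
        eff = normalize_to_baseline(
            self._summary(frequency=0.0, pumping_score=0.0), self._summary()
        )
        assert math.isnan(eff.frequency_pct)
        assert eff.tone_pct == pytest.approx(100.0)
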