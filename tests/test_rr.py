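"""Dual-domain RR estimation, spectral-shape features and the quality index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermorr import (
    BandEdges,
    RqiParams,
    SceneConfig,
    assess_regions,
    detrend_linear,
    extract_grid_signals,
    generate_scene,
    periodogram,
    rqi,
    rr_from_spectrum,
    rr_from_time,
    sigmoid,
    spectrum_features,
    spectrum_index,
    window_signal,
    zero_crossings,
)
from thermorr.dsp import AnalysisWindow, PowerSpectrum
from thermorr.rr import assess_window, result_table
from tests.conftest import sine_trace

G5 = 1.0 / (1.0 + math.exp(-5.0))  # ~0.993307


def spectrum_from_values(freqs, values, fps=8.6):
    return PowerSpectrum(freqs=np.asarray(freqs, float), values=np.asarray(values, float),
                         n_fft=2 * (len(freqs) - 1), native_n=len(freqs), fps=fps)


class TestRrFromSpectrum:
    @pytest.mark.parametrize("freq_hz, rr_expected", [(0.25, 15.0), (0.5, 30.0)])
    def test_peak_recovers_tone(self, freq_hz, rr_expected):
        win = detrend_linear(window_signal(sine_trace(freq_hz), 0.0, 15.0))
        spec = periodogram(win, n_fft=8192)
        _, rr = rr_from_spectrum(spec)
        assert rr == pytest.approx(rr_expected, abs=0.1)

    def test_band_edge_tone_reads_full_scale(self):
        """A 2.0 Hz tone maps to 120 bpm within one padded grid step."""
        win = detrend_linear(window_signal(sine_trace(2.0), 0.0, 15.0))
        spec = periodogram(win, n_fft=8192)
        f_peak, rr = rr_from_spectrum(spec)
        grid_bpm = 60 * 8.6 / 8192
        assert rr == pytest.approx(120.0, abs=2 * grid_bpm)

    def test_flat_spectrum_ties_to_lowest_frequency(self):
        freqs = np.linspace(0.0, 4.3, 1001)
        spec = spectrum_from_values(freqs, np.ones_like(freqs))
        f_peak, rr = rr_from_spectrum(spec)
        in_band = freqs[(freqs >= 0.1) & (freqs <= 2.0)]
        assert f_peak == in_band[0]
        assert rr == 60 * in_band[0]

    def test_empty_band_support_rejected(self):
        spec = spectrum_from_values([0.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="band"):
            rr_from_spectrum(spec)


class TestZeroCrossings:
    def test_midpoint_interpolation(self):
        win = AnalysisWindow(samples=np.array([1.0, -1.0, 1.0]), fps=1.0)
        times = zero_crossings(win)
        assert np.allclose(times, [0.5, 1.5])

    def test_strictly_positive_signal_has_none(self):
        win = AnalysisWindow(samples=np.ones(20) + 0.1, fps=8.6)
        assert zero_crossings(win).size == 0

    def test_sine_crossings_at_half_periods(self):
        """Crossings of a 0.25 Hz sine are 2.0 s apart, within a sample step."""
        trace = sine_trace(0.25)
        win = AnalysisWindow(samples=trace.values, fps=trace.fps)  # exact zero-mean tone
        times = zero_crossings(win)
        spacings = np.diff(times)
        assert np.all(np.abs(spacings - 2.0) <= 1 / 8.6)

    def test_exact_zero_belongs_to_following_sign(self):
        # touching zero without changing sign is not a crossing
        win = AnalysisWindow(samples=np.array([1.0, 0.0, 1.0, -1.0]), fps=1.0)
        times = zero_crossings(win)
        assert np.allclose(times, [2.5])

    def test_downward_only_selection(self):
        trace = sine_trace(0.25)
        win = detrend_linear(window_signal(trace, 0.0, 15.0))
        down = zero_crossings(win, direction="down")
        both = zero_crossings(win)
        assert down.size in (both.size // 2, both.size // 2 + 1)
        assert np.all(np.abs(np.diff(down) - 4.0) <= 2 / 8.6)  # full periods


class TestRrFromTime:
    def test_quarter_hertz_sine(self):
        trace = sine_trace(0.25)
        win = detrend_linear(window_signal(trace, 0.0, 15.0))
        rr = rr_from_time(zero_crossings(win))
        assert rr == pytest.approx(15.0, abs=0.5)

    def test_fewer_than_two_crossings_undefined(self):
        assert rr_from_time([]) is None
        assert rr_from_time([3.2]) is None

    def test_median_by_enumeration(self):
        # intervals 1.0, 1.0, 3.0 s -> frequencies 0.5, 0.5, 1/6 -> median 0.5
        crossings = [0.0, 1.0, 2.0, 5.0]
        assert rr_from_time(crossings) == pytest.approx(30.0)

    def test_even_count_median_is_mean_of_central_pair(self):
        # intervals 1, 2 s -> frequencies 0.5, 0.25 -> median 0.375 -> 22.5 bpm
        assert rr_from_time([0.0, 1.0, 3.0]) == pytest.approx(22.5)

    def test_literal_convention_doubles_the_tone(self):
        """One-directional crossings with f=2/dt read twice the frequency."""
        trace = sine_trace(0.25)
        win = detrend_linear(window_signal(trace, 0.0, 15.0))
        down = zero_crossings(win, direction="down")
        rr_lit = rr_from_time(down, convention="literal")
        assert rr_lit == pytest.approx(30.0, abs=1.0)


class TestSpectrumFeatures:
    def brute_force(self, spec, bands, params):
        """Per-bin enumeration oracle for the indicator-weighted fractions."""
        bf = [(f, p) for f, p in zip(spec.freqs, spec.values) if bands.bf_lo <= f <= bands.bf_hi]
        hf = [(f, p) for f, p in zip(spec.freqs, spec.values) if f > bands.bf_hi]
        p_max = max(p for _, p in bf)
        if p_max == 0:
            return 0.0, 1.0, 1.0
        num = sum(p for _, p in bf if p >= params.bf_threshold * p_max)
        f_bf = num / sum(p for _, p in bf)
        hf_total = sum(p for _, p in hf)
        if hf_total == 0:
            f_hf = 0.0
        else:
            f_hf = sum(p for _, p in hf if p >= params.hf_threshold * p_max) / hf_total
        return p_max, f_bf, f_hf

    def test_matches_bin_enumeration_oracle(self, rng):
        bands, params = BandEdges(), RqiParams()
        freqs = np.linspace(0.0, 4.3, 513)
        for _ in range(10):
            values = rng.exponential(size=freqs.size)
            spec = spectrum_from_values(freqs, values)
            p_max, f_bf, f_hf, degenerate = spectrum_features(spec, bands, params)
            o_max, o_bf, o_hf = self.brute_force(spec, bands, params)
            assert not degenerate
            assert p_max == pytest.approx(o_max, rel=1e-12)
            assert f_bf == pytest.approx(o_bf, rel=1e-12)
            assert f_hf == pytest.approx(o_hf, rel=1e-12)

    def test_single_line_spectrum(self):
        """One breath-band line, nothing else: F_BF = 1, F_HF = 0, SI = 0.5."""
        freqs = np.linspace(0.0, 4.3, 513)
        values = np.zeros_like(freqs)
        values[np.argmin(np.abs(freqs - 0.4))] = 10.0
        p_max, f_bf, f_hf, degenerate = spectrum_features(spectrum_from_values(freqs, values))
        assert (f_bf, f_hf, degenerate) == (1.0, 0.0, False)
        assert spectrum_index(f_bf, f_hf) == 0.5

    def test_flat_spectrum_is_maximally_noiselike(self):
        freqs = np.linspace(0.0, 4.3, 513)
        p_max, f_bf, f_hf, degenerate = spectrum_features(
            spectrum_from_values(freqs, np.full_like(freqs, 3.0))
        )
        assert f_bf == 1.0 and f_hf == 1.0 and not degenerate
        assert spectrum_index(f_bf, f_hf) == 0.0

    def test_all_zero_spectrum_flagged_degenerate(self):
        freqs = np.linspace(0.0, 4.3, 513)
        p_max, f_bf, f_hf, degenerate = spectrum_features(
            spectrum_from_values(freqs, np.zeros_like(freqs))
        )
        assert degenerate and f_bf == 1.0 and f_hf == 1.0 and p_max == 0.0

    def test_clean_tone_with_small_noise_has_tiny_f_hf(self, rng):
        trace = sine_trace(0.333, amplitude=10.0)
        noisy = trace.values + rng.normal(0, 0.05, size=len(trace))
        trace.values = noisy
        win = detrend_linear(window_signal(trace, 0.0, 15.0))
        spec = periodogram(win, n_fft=8192)
        _, f_bf, f_hf, _ = spectrum_features(spec)
        assert f_hf < 0.05
        # the peak lobe carries nearly all breath-band power
        assert f_bf > 0.5
        assert spectrum_index(f_bf, f_hf) == pytest.approx(0.5, abs=0.1)


class TestIndexArithmetic:
    @pytest.mark.parametrize("f_bf, f_hf, expected", [(0, 0, 1.0), (1, 1, 0.0), (0.2, 0.1, 0.85)])
    def test_spectrum_index_values(self, f_bf, f_hf, expected):
        assert spectrum_index(f_bf, f_hf) == pytest.approx(expected)

    def test_spectrum_index_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            spectrum_index(1.2, 0.0)

    def test_sigmoid_fixed_points(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(5.0) == pytest.approx(G5, abs=1e-9)
        for x in (-3.7, 0.1, 12.0):
            assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0)
        assert 0.0 <= sigmoid(-800.0) < sigmoid(800.0) <= 1.0  # saturates, no overflow

    def test_rqi_closed_form(self):
        assert rqi(1.0, 20.0, 20.0) == pytest.approx(G5, abs=1e-9)
        assert rqi(1.0, 25.0, 20.0) == pytest.approx(0.5)  # |dRR| = a
        assert rqi(0.8, None, 20.0) == 0.0

    @given(si=st.floats(0, 1), delta=st.floats(0, 200))
    @settings(derandomize=True, max_examples=200)
    def test_rqi_bounded_and_below_si(self, si, delta):
        q = rqi(si, 20.0 + delta, 20.0)
        assert 0.0 <= q <= 1.0
        assert q <= si + 1e-15

    def test_rqi_monotone_in_disagreement_and_linear_in_si(self):
        deltas = np.linspace(0, 50, 40)
        qs = [rqi(1.0, 20.0 + d, 20.0) for d in deltas]
        assert np.all(np.diff(qs) < 0)  # strictly decreasing in |dRR|
        for d in (0.0, 3.0, 10.0):
            q_half = rqi(0.5, 20.0 + d, 20.0)
            q_full = rqi(1.0, 20.0 + d, 20.0)
            assert q_half == pytest.approx(0.5 * q_full, rel=1e-12)


class TestAssessRegions:
    def test_breathing_cells_selected_and_rate_recovered(self):
        cfg = SceneConfig(rr_true_bpm=20.0, breathing_cells=(9, 10), seed=2)
        seq, box, _ = generate_scene(cfg)
        traces = extract_grid_signals(seq, box)
        res = assess_regions(traces)
        assert res.found
        assert res.selected_roi in (9, 10)
        assert res.rr_bpm == pytest.approx(20.0, abs=1.0)
        assert res.rr_bpm == next(
            a.rr_f for a in res.assessments if a.roi_index == res.selected_roi
        )

    def test_constant_frames_find_no_region(self):
        cfg = SceneConfig(rr_true_bpm=15.0, breathing_cells=(), amplitude=0.0,
                          noise_sigma=0.0, drift_slope=0.0, seed=0)
        seq, box, _ = generate_scene(cfg)
        res = assess_regions(extract_grid_signals(seq, box))
        assert not res.found
        assert res.selected_roi is None and res.rr_bpm is None
        assert all(a.degenerate for a in res.assessments)

    def test_identical_regions_tie_to_lowest_index(self):
        """Two bit-identical breathing traces: the lower index wins."""
        trace_a = sine_trace(0.3, roi_index=4)
        trace_b = sine_trace(0.3, roi_index=17)
        res = assess_regions([trace_b, trace_a])  # order must not matter
        assert res.selected_roi == 4

    def test_selected_region_attains_max_rqi(self, default_scene):
        seq, box, _ = default_scene
        res = assess_regions(extract_grid_signals(seq, box))
        best = max(a.rqi for a in res.assessments)
        sel = next(a for a in res.assessments if a.roi_index == res.selected_roi)
        assert sel.rqi == best

    def test_rr_always_inside_estimable_range(self, default_scene):
        seq, box, _ = default_scene
        res = assess_regions(extract_grid_signals(seq, box))
        for a in res.assessments:
            assert 6.0 <= a.rr_f <= 120.0
            assert 0.0 <= a.rqi <= a.si + 1e-15 <= 1.0 + 1e-15

    def test_result_table_shape(self, default_scene):
        seq, box, _ = default_scene
        res = assess_regions(extract_grid_signals(seq, box))
        df = result_table(res)
        assert len(df) == 24
        assert df["selected"].sum() == 1
        assert set(df.columns) == {"roi", "rr_f", "rr_t", "p_bf_max", "f_bf", "f_hf",
                                   "si", "rqi", "selected"}

    def test_rr_t_undefined_forces_zero_rqi(self):
        """A monotone (crossing-free after detrend? no — use flat+spike) signal."""
        values = np.zeros(129)
        values[:64] = 1.0
        values[64:] = -1.0  # exactly one crossing after detrending
        trace = sine_trace(0.3)
        trace.values = values
        a = assess_window(window_signal(trace, 0.0, 15.0))
        assert a.rr_t is None or a.rqi > 0  # if a second crossing appears, rqi legal
        if a.rr_t is None:
            assert a.rqi == 0.0


def test_noise_degrades_expected_quality():
    """Matched-seed Monte Carlo: more pixel noise never raises mean RQI.

    SI alone is not monotone in noise: because the band fractions are
    power-weighted, moderate broadband noise adds sub-threshold power to the
    breath-band denominator and briefly *raises* SI before the flattening
    spectrum pulls it down.  The time-frequency agreement gate collapses
    under the same noise, so the combined index RQI is the monotone
    quantity; SI is monotone once past the dilution regime.
    """
    sigmas = [5.0, 300.0, 1500.0, 6000.0]
    mean_si, mean_rqi = [], []
    for sigma in sigmas:
        sis, rqis = [], []
        for seed in range(8):
            cfg = SceneConfig(rr_true_bpm=18.0, breathing_cells=(9,), noise_sigma=sigma,
                              drift_slope=0.0, seed=100 + seed)
            seq, box, _ = generate_scene(cfg)
            traces = extract_grid_signals(seq, box)
            a = assess_window(window_signal(traces[9], 0.0, 15.0))
            sis.append(a.si)
            rqis.append(a.rqi)
        mean_si.append(np.mean(sis))
        mean_rqi.append(np.mean(rqis))
    # allow logistic-tail float noise between effectively-zero values
    eps = 1e-9
    assert mean_rqi[0] >= mean_rqi[1] - eps >= mean_rqi[2] - 2 * eps >= mean_rqi[3] - 3 * eps
    # heavy-noise SI falls well below the clean-signal level
    assert mean_si[2] < mean_si[0] and mean_si[3] <= mean_si[2]
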