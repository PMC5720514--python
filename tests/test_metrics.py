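"""Spectrum, eta index, classifier rules and tissue calibration."""

import numpy as np
import pytest

from eadsim.metrics import (EtaResult, PropagationFailure, SpectrumSummary,
                            average_spectrum, classify_pattern, eta_index,
                            measure_cv, measure_space_constant)
from eadsim.movie import VoltageMovie
from eadsim.synthetic import ap_trace, oscillator_field


def _movie_from(v, sample_dt=1.0, dx=0.04):
    return VoltageMovie(data=np.asarray(v, np.float32), sample_dt=sample_dt,
                        dx=dx)


class TestAverageSpectrum:
    def test_pure_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(1000.0)
        v = -40.0 + 10.0 * np.sin(2 * np.pi * 5.0 * t / 1000.0)
        movie = _movie_from(np.tile(v[:, None], (1, 16)))
        sp = average_spectrum(movie)
        assert sp.dominant_frequency == pytest.approx(5.0)

    def test_amplitude_scales_linearly_with_signal(self):
        t = np.arange(1000.0)
        v = 8.0 * np.sin(2 * np.pi * 3.0 * t / 1000.0)
        m1 = _movie_from(np.tile(v[:, None], (1, 4)))
        m2 = _movie_from(np.tile(3.0 * v[:, None], (1, 4)))
        s1, s2 = average_spectrum(m1), average_spectrum(m2)
        assert np.allclose(s2.mean_amplitude, 3.0 * s1.mean_amplitude,
                           atol=1e-6)
        assert s1.dominant_frequency == s2.dominant_frequency

    def test_two_tone_alpha_beta_assignment(self):
        # beta is the slower AP-to-AP peak, alpha the faster EAD peak
        t = np.arange(1000.0)
        v = (10.0 * np.sin(2 * np.pi * 2.0 * t / 1000.0)
             + 6.0 * np.sin(2 * np.pi * 4.0 * t / 1000.0))
        sp = average_spectrum(_movie_from(np.tile(v[:, None], (1, 8))))
        assert sp.beta_peak == pytest.approx(2.0)
        assert sp.alpha_peak == pytest.approx(4.0)

    def test_window_below_1s_rejected(self):
        movie = _movie_from(np.zeros((1200, 4)))
        with pytest.raises(ValueError):
            average_spectrum(movie, window=500.0)


class TestEtaIndex:
    def test_five_full_aps_give_eta_five(self):
        assert eta_index(ap_trace(5, 0)).eta == 5.0

    def test_constant_rest_gives_zero(self):
        movie = _movie_from(np.full((1000, 10), -86.0))
        assert eta_index(movie).eta == 0.0

    def test_eads_above_band_do_not_count(self):
        # plateau oscillations stay above -59 mV: only the AP transits count
        assert eta_index(ap_trace(3, 2)).eta == 3.0

    def test_offset_invariance_outside_band(self):
        v = ap_trace(4, 0).data
        e1 = eta_index(_movie_from(v)).eta
        e2 = eta_index(_movie_from(np.where(v > -60, v + 5, v - 5))).eta
        assert e1 == e2 == 4.0

    def test_time_reversal_invariance(self):
        v = ap_trace(4, 1).data
        assert eta_index(_movie_from(v)).eta == \
            eta_index(_movie_from(v[::-1])).eta

    def test_exact_ratio_definition(self):
        res = eta_index(ap_trace(5, 0))
        assert res.eta == res.crossings_total / (2.0 * res.n_nodes)

    def test_dithering_on_the_line_not_double_counted(self):
        # oscillation inside the +/-1 mV hysteresis band is a single transit
        t = np.arange(1000.0)
        v = np.full_like(t, -86.0)
        v[200:800] = -60.0 + 0.9 * np.sin(t[200:800])  # stays inside band
        v[500:520] = 0.0
        e = eta_index(_movie_from(v[:, None]))
        assert e.eta == 1.0


class TestClassifierRules:
    def _spectrum(self, peaks):
        freqs = np.arange(0.0, 20.0)
        low = sorted([p for p in peaks if p[0] <= 6.5],
                     key=lambda p: -p[1])[:2]
        alpha = beta = None
        if len(low) == 2:
            beta, alpha = sorted([low[0][0], low[1][0]])
        elif len(low) == 1:
            alpha = low[0][0]
        return SpectrumSummary(freqs=freqs, mean_amplitude=np.zeros(20),
                               peaks=peaks, alpha_peak=alpha, beta_peak=beta)

    def test_quiescent_movie_is_ee(self):
        movie = _movie_from(np.full((1000, 9), -85.9))
        assert classify_pattern(movie).label == "EE"

    def test_oscillator_field_is_o(self):
        movie = oscillator_field()
        eta = eta_index(movie)
        sp = average_spectrum(movie)
        lab = classify_pattern(movie, sp, eta, decouple_result="phase_wave")
        assert lab.label == "O"
        assert not lab.low_confidence

    def test_beta_dominant_with_positive_eta_is_b(self):
        sp = self._spectrum([(2.0, 1.0), (4.0, 0.5)])
        eta = EtaResult(eta=1.5, crossings_total=30, n_nodes=10,
                        window=(0.0, 1000.0))
        assert classify_pattern(None, sp, eta).label == "B"

    def test_alpha_dominant_with_low_eta_is_a(self):
        sp = self._spectrum([(4.0, 1.0), (2.0, 0.4)])
        eta = EtaResult(eta=0.2, crossings_total=4, n_nodes=10,
                        window=(0.0, 1000.0))
        assert classify_pattern(None, sp, eta).label == "A"

    def test_conflicting_ingredients_flagged(self):
        sp = self._spectrum([(4.0, 1.0), (2.0, 0.4)])  # alpha dominant
        eta = EtaResult(eta=5.0, crossings_total=100, n_nodes=10,
                        window=(0.0, 1000.0))  # but eta says full repol
        lab = classify_pattern(None, sp, eta)
        assert lab.low_confidence

    def test_single_stationary_filament_is_s(self):
        from eadsim.phase import Filament
        fil = Filament(track=[(t, np.array([10.0, 10.0]))
                              for t in range(200, 801)], charge=1)
        assert classify_pattern(None, filaments=[fil]).label == "S"

    def test_single_meandering_filament_is_ms(self):
        from eadsim.phase import Filament
        fil = Filament(track=[(t, np.array([10.0 + 0.02 * t, 10.0]))
                              for t in range(200, 801)], charge=1)
        assert classify_pattern(None, filaments=[fil]).label == "MS"


class TestMeasureCV:
    def test_default_cable_velocity(self, cable_wave_movie):
        cv = measure_cv(cable_wave_movie, 2.0, 6.0)
        assert 55.0 < cv < 85.0

    def test_no_activation_raises(self):
        movie = _movie_from(np.full((500, 200), -86.0), sample_dt=0.1)
        with pytest.raises(PropagationFailure):
            measure_cv(movie, 2.0, 6.0)


class TestSpaceConstant:
    def test_passive_cable_matches_closed_form(self):
        # independent forward-Euler passive cable: lambda = sqrt(D/g)
        d, g, dx = 0.00154, 0.25, 0.04
        n = 200
        v = np.zeros(n)
        i_inj = np.zeros(n)
        i_inj[0] = 1.0
        dt = 0.02
        for _ in range(40000):
            lap = np.zeros(n)
            lap[1:-1] = (v[2:] - 2 * v[1:-1] + v[:-2])
            lap[0] = v[1] - v[0]
            lap[-1] = v[-2] - v[-1]
            v += dt * (-g * v + i_inj + d / dx ** 2 * lap)
        lam_true = np.sqrt(d / g) * 1e4
        dv = v - v[-1]
        mask = (dv >= 0.1 * dv.max()) & (dv <= 0.9 * dv.max())
        x = np.arange(n) * dx
        slope = np.polyfit(x[mask], np.log(dv[mask]), 1)[0]
        lam_fit = -1e4 / slope
        assert lam_fit == pytest.approx(lam_true, rel=0.02)

    def test_lambda_scales_as_sqrt_d(self, cable_grid, default_params):
        lam1 = measure_space_constant(cable_grid, default_params, dl=0.00154)
        lam4 = measure_space_constant(cable_grid, default_params,
                                      dl=4 * 0.00154)
        assert lam4 / lam1 == pytest.approx(2.0, rel=0.05)

    def test_suprathreshold_current_rejected(self, cable_grid,
                                             default_params):
        with pytest.raises(ValueError):
            measure_space_constant(cable_grid, default_params, i_sub=-60.0)
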