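"""Unit and oracle tests of the modified TP06 cell model."""

import sys
from pathlib import Path

import numpy as np
import pytest

from eadsim import (build_params, classify_cell_regime, resting_state,
                    simulate_cell, step_cell)
from eadsim.cell_model import (GCAL_TP06, GKR_TP06, apd90, burst_pace_cell,
                               membrane_currents)

sys.path.insert(0, str(Path(__file__).parent))
from tp06_reference import integrate_reference  # noqa: E402


class TestBuildParams:
    def test_default_model_doubles_gcal_and_halves_f_tau(self):
        p = build_params(1.0, 1.0)
        assert p.g_cal == pytest.approx(2.0 * GCAL_TP06)
        assert p.g_kr == pytest.approx(GKR_TP06)
        assert p.f_tau_scale == 0.5

    def test_sweep_multipliers_scale_the_default(self):
        p = build_params(0.6, 6.5)
        assert p.g_kr == pytest.approx(0.6 * GKR_TP06)
        assert p.g_cal == pytest.approx(2.0 * 6.5 * GCAL_TP06)
        assert "multiplier_convention" in p.meta

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            build_params(-0.1, 1.0)

    def test_out_of_range_multiplier_flagged(self):
        with pytest.warns(UserWarning):
            build_params(1.0, 9.0)

    def test_zero_gcal_gives_no_plateau_reversal(self):
        # without L-type current there is no inward plateau current: the AP
        # repolarizes monotonically and cannot carry EADs
        movie, _ = simulate_cell(build_params(1.0, 0.0), stim_times=[10],
                                 duration=1500, sample_dt=1.0)
        assert classify_cell_regime(movie, window=1400) == "normal"


class TestStepCell:
    def test_rest_is_stable_over_10_ms(self, default_params):
        from eadsim.cell_model import equilibrium_state
        state = equilibrium_state()
        v0 = state.v
        for _ in range(500):
            state = step_cell(state, default_params, dt=0.02)
        assert abs(state.v - v0) < 0.1

    def test_gates_remain_in_unit_interval(self, default_params):
        state = resting_state()
        for k in range(500):
            i_stim = -52.0 if k < 50 else 0.0
            state = step_cell(state, default_params, dt=0.02, i_stim=i_stim)
            for g, val in state.gates.items():
                assert 0.0 <= val <= 1.0, f"gate {g} left [0,1] at step {k}"

    def test_suprathreshold_stimulus_fires_within_5_ms(self, default_params):
        state = resting_state()
        fired = False
        for k in range(250):  # 5 ms
            i_stim = -52.0 if k < 50 else 0.0
            state = step_cell(state, default_params, dt=0.02, i_stim=i_stim)
            if state.v > 10.0:
                fired = True
                break
        assert fired

    def test_invalid_dt_rejected(self, default_params):
        with pytest.raises(ValueError):
            step_cell(resting_state(), default_params, dt=0.0)


class TestSimulateCell:
    def test_rest_stable_over_2_s(self, default_params):
        movie, _ = simulate_cell(default_params, stim_times=[],
                                 duration=2000)
        v = movie.trace(0)
        assert abs(v[-1] - v[0]) < 1.0

    def test_paced_cell_produces_one_ap_per_stimulus(self, default_params):
        movie, _ = simulate_cell(
            default_params, stim_times=np.arange(10.0, 6000.0, 1000.0),
            duration=6000)
        v = movie.trace(0)
        up = np.flatnonzero((v[:-1] < -60) & (v[1:] >= -60))
        down = np.flatnonzero((v[:-1] >= -60) & (v[1:] < -60))
        assert len(up) == 6 and len(down) == 6

    def test_oscillatory_point_never_repolarizes_after_onset(self):
        movie, _, _ = burst_pace_cell(build_params(0.6, 6.5))
        v = movie.trace(0)
        first_up = np.flatnonzero(v > -60)[0]
        # after the oscillation establishes itself the potential stays high
        assert v[first_up + 1000:].min() > -60.0

    def test_ead_point_repolarizes_between_aps(self):
        movie, _, _ = burst_pace_cell(build_params(0.6, 4.0))
        v = movie.trace(0)
        assert v[-2000:].min() < -60.0  # recovers in the free window


class TestOracleEquivalence:
    """Production stepper vs the independent dt = 0.001 ms reference."""

    @pytest.mark.parametrize("gkr,gcal", [(1.0, 1.0), (0.6, 4.0)])
    def test_trace_matches_reference_within_1_mV_rms(self, gkr, gcal):
        ref = integrate_reference(gkr, gcal, 2000.0, 0.001,
                                  np.array([10.0, 1010.0]), -52.0, 1.0, 1000)
        movie, _ = simulate_cell(build_params(gkr, gcal),
                                 stim_times=[10, 1010], duration=2000)
        v = movie.trace(0)
        n = min(len(ref), len(v))
        rms = float(np.sqrt(np.mean((ref[:n] - v[:n]) ** 2)))
        assert rms < 1.0

    def test_oscillatory_point_matches_reference_while_coherent(self):
        # the non-repolarizing EAD oscillation is phase-unstable, so any
        # two integrators decorrelate after several cycles; pointwise RMS
        # is compared over the first 600 ms while trajectories are coherent
        ref = integrate_reference(0.6, 6.5, 2000.0, 0.001,
                                  np.array([10.0]), -52.0, 1.0, 1000)
        movie, _ = simulate_cell(build_params(0.6, 6.5), stim_times=[10],
                                 duration=2000)
        v = movie.trace(0)
        rms = float(np.sqrt(np.mean((ref[:500] - v[:500]) ** 2)))
        assert rms < 1.0
        # both agree on the non-repolarizing character after the upstroke
        assert ref[100:500].min() > -60.0
        assert v[100:500].min() > -60.0

    def test_apd90_matches_reference_within_2_ms(self, default_params):
        stims = np.arange(10.0, 3000.0, 1000.0)
        ref = integrate_reference(1.0, 1.0, 3000.0, 0.001, stims,
                                  -52.0, 1.0, 1000)
        movie, _ = simulate_cell(default_params, stim_times=stims,
                                 duration=3000)
        a_ref = apd90(ref[2000:], 1.0)
        a_prod = apd90(movie.trace(0)[2000:], 1.0)
        assert abs(a_ref - a_prod) < 2.0


class TestRegimeClassification:
    def test_synthetic_normal_aps(self):
        from eadsim.synthetic import ap_trace
        movie = ap_trace(5, 0)
        assert classify_cell_regime(movie) == "normal"

    def test_regime_order_along_gcal(self):
        # at fixed gkr_mult = 0.6 the behaviour after the final stimulus
        # passes normal -> EAD -> non-repolarizing as gcal_mult grows
        labels = []
        for gcal in (1.0, 4.0, 6.5):
            movie, _, stims = burst_pace_cell(build_params(0.6, gcal))
            v = movie.trace(0)
            start = int(stims[-1])
            labels.append(classify_cell_regime((v[start:], 1.0),
                                               window=len(v) - start))
        assert labels == ["normal", "ead_repolarizing",
                          "non_repolarizing_oscillation"]

    def test_short_window_rejected(self):
        from eadsim.synthetic import ap_trace
        with pytest.raises(ValueError):
            classify_cell_regime(ap_trace(2, 0, duration=500.0), window=500)


def test_current_breakdown_sums_to_i_ion(default_params):
    state = resting_state()
    cb = membrane_currents(state, default_params)
    parts = (cb.i_na + cb.i_k1 + cb.i_to + cb.i_kr + cb.i_ks + cb.i_cal
             + cb.i_naca + cb.i_nak + cb.i_pca + cb.i_pk + cb.i_bca
             + cb.i_bna)
    assert cb.i_ion == pytest.approx(parts, rel=1e-12)
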