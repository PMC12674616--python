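"""Pump current law, co-expression rule, tuning, and the voltage-dependent
pump."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import electrocyte as ec
from electrocyte.constants import faraday_volume
from electrocyte.pump import (apply_coexpression, coexpressed_leak_conductance,
                              pump_current_concentration, tune_baseline_pump)
from electrocyte.simulate import rheobase
from electrocyte.stimulus import StimulusProtocol


class TestConcentrationPump:
    def test_baseline_returns_baseline_exactly(self, default_params):
        p = default_params.replace(I_pump0=1.73)
        assert pump_current_concentration(p.Na_in0, p.K_out0, p) == 1.73

    def test_saturates_at_four_times_baseline(self, default_params):
        p = default_params.replace(I_pump0=2.0)
        sat = pump_current_concentration(p.Na_in0 + 50.0, p.K_out0 + 50.0, p)
        assert sat == pytest.approx(8.0, rel=1e-6)

    def test_sodium_scale_point(self, default_params):
        # +na_scale mM of sodium: 4/((1+e^-1) * 2) times baseline
        p = default_params.replace(I_pump0=1.0)
        val = pump_current_concentration(p.Na_in0 + 3.0, p.K_out0, p)
        assert val == pytest.approx(4.0 / ((1.0 + math.exp(-1.0)) * 2.0))
        assert val == pytest.approx(1.4621, abs=1e-4)

    @settings(max_examples=60, deadline=None)
    @given(na=st.floats(5.0, 40.0), ko=st.floats(0.5, 10.0),
           dna=st.floats(0.01, 5.0), dko=st.floats(0.01, 5.0))
    def test_strictly_increasing_and_bounded(self, default_params,
                                             na, ko, dna, dko):
        p = default_params.replace(I_pump0=1.0)
        v0 = pump_current_concentration(na, ko, p)
        assert 0.0 < v0 < 4.0
        assert pump_current_concentration(na + dna, ko, p) > v0
        assert pump_current_concentration(na, ko + dko, p) > v0


class TestCoexpression:
    def test_published_operating_point(self):
        # 1.888 uA across (55.2 - (-76)) mV is 14.39 uS
        g = coexpressed_leak_conductance(1.888, -76.0, 55.2)
        assert g == pytest.approx(1.888 / 131.2 * 1e3, rel=1e-12)
        assert g == pytest.approx(14.39, abs=0.01)

    def test_zero_pump_zero_leak(self):
        assert coexpressed_leak_conductance(0.0, -76.0, 55.2) == 0.0

    def test_linearity_in_pump_current(self):
        g1 = coexpressed_leak_conductance(1.0, -76.0, 55.2)
        g2 = coexpressed_leak_conductance(2.0, -76.0, 55.2)
        assert g2 == pytest.approx(2.0 * g1)

    def test_degenerate_onset_raises(self):
        with pytest.raises(ValueError):
            coexpressed_leak_conductance(1.0, 55.2, 55.2)


class TestTuning:
    def test_sodium_free_cell_needs_no_pump(self, default_params):
        dead = default_params.replace(g_NaT_max=0.0, g_NaP_max=0.0,
                                      g_AChRNa=0.0)
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.0)
        tuned, diag = tune_baseline_pump(dead, pro)
        assert diag["I_pump0"] == pytest.approx(0.0, abs=1e-3)

    def test_convergence_and_residual(self, tuned_strong):
        _, diag = tuned_strong
        x, target, residual = diag["history"][-1]
        assert abs(residual) < 1e-3  # 1 nA
        assert diag["I_pump0"] > 0.5

    def test_period_averaged_sodium_drift_below_one_nanoamp(
            self, tuned_strong, drive_013):
        tuned, _ = tuned_strong
        tr = ec.integrate(tuned, drive_013, duration=500.0, stride=10)
        half = len(tr.t) // 2
        drift = abs(tr.Na_in[-1] - tr.Na_in[half]) / (tr.t[-1] - tr.t[half])
        assert drift < 1e-3 / faraday_volume(tuned.omega_in)

    def test_leak_carries_one_third_of_sodium_charge(self,
                                                     tuned_strong_trace):
        rep = ec.pump_load_per_ap(tuned_strong_trace)
        assert rep.nal_inward_fraction == pytest.approx(1.0 / 3.0, abs=0.05)


class TestVoltageDependentPump:
    def test_pump_equals_half_of_scaled_potassium_currents(self):
        params = ec.preset("electrocyte-voltage-pump")
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.10)
        tr = ec.integrate(params, pro, duration=50.0, stride=1, frozen=True)
        cur = tr.currents()
        half_k = 0.5 * (cur["I_K"] + cur["I_KL"])
        np.testing.assert_allclose(cur["I_pump"], half_k, rtol=1e-12,
                                   atol=1e-15)

    def test_waveform_identical_to_pump_free_full_k_model(self):
        """2/3-K + voltage-dependent pump vs full-K without pump: the
        voltage traces agree bit for bit at frozen concentrations."""
        params = ec.preset("electrocyte-voltage-pump")
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.13)
        tr_pump = ec.integrate(params, pro, duration=80.0, stride=1,
                               frozen=True)
        tr_free = ec.integrate(params.replace(pump_mode="none"), pro,
                               duration=80.0, stride=1, frozen=True)
        assert np.array_equal(tr_pump.v, tr_free.v)
        assert np.array_equal(tr_pump.n, tr_free.n)

    def test_live_concentrations_preserve_waveform(self):
        """Near-perfect homeostasis: starting from its concentration
        steady state, the live voltage-dependent-pump run keeps the
        firing rate and spike shape of the frozen pump-free model over
        100 ms (pointwise voltage RMS is not meaningful here because any
        sub-ppm period difference dephases two ~600 Hz oscillators)."""
        params = ec.preset("electrocyte-voltage-pump")
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.10)
        na_ss, _ = ec.steady_state_concentration(params, pro)
        state = ec.initial_state(params, na_in=na_ss)
        live = ec.integrate(params, pro, duration=100.0, stride=2,
                            state=state)
        # reference: pump-free model frozen at the same concentrations
        ref_params = params.replace(pump_mode="none", Na_in0=na_ss)
        ref = ec.integrate(ref_params, pro, duration=100.0, stride=2,
                           frozen=True)
        r_live = len(live.spike_times)
        r_ref = len(ref.spike_times)
        assert abs(r_live - r_ref) <= 1
        # the live pump runs ~2-3% above the potassium third (the residual
        # concentration modulation that holds [Na+]in at its steady state),
        # which trims the spike amplitude by a comparable fraction
        a_live = ec.ap_metrics(live)["amplitude"]
        a_ref = ec.ap_metrics(ref)["amplitude"]
        assert a_live == pytest.approx(a_ref, rel=0.03)

    def test_stoichiometry_exact(self, tuned_strong_trace):
        """Cumulative Na:K transport is 3:2 to machine precision."""
        rep = ec.pump_load_per_ap(tuned_strong_trace)
        assert rep.na_pumped_per_ap == 1.5 * rep.k_pumped_per_ap


class TestRheobaseInvariance:
    def test_coexpression_pins_firing_onset(self, strong_params):
        """Over baseline pump currents up to ~2.5 uA, co-expression holds
        the rheobase within 5% of the pump-free value (onset voltage
        calibrated for these kinetics), whereas the uncompensated shift
        equals the pump current itself."""
        r0 = rheobase(strong_params, bracket=(0.0, 1.0))
        von = -79.0  # measured firing-onset voltage of this preset
        for i0 in (0.5, 1.5, 2.5):
            co = apply_coexpression(strong_params.replace(v_onset=von), i0,
                                    pump_mode="fixed")
            r = rheobase(co, bracket=(0.0, 2.0), tol=5e-4)
            assert abs(r - r0) < 0.05 * r0
        # contrast: without co-expression the onset shifts by ~I_pump0
        bare = strong_params.replace(I_pump0=2.5, pump_mode="fixed")
        r_bare = rheobase(bare, bracket=(0.0, 5.0), tol=5e-3)
        assert r_bare - r0 == pytest.approx(2.5, rel=0.1)
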