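"""Integrator, spike detection, tuning curves, and calibration routines."""

import numpy as np
import pytest

import electrocyte as ec
from electrocyte.simulate import (IntegrationError, detect_spikes, fi_curve,
                                  integrate)
from electrocyte.stimulus import StimulusProtocol


class TestIntegrate:
    def test_zero_duration_returns_initial_sample(self, default_params):
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.1)
        tr = integrate(default_params, pro, duration=0.0)
        assert len(tr.t) == 1
        assert tr.v[0] == -85.0

    def test_bit_identical_reruns(self, default_params):
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.13)
        a = integrate(default_params, pro, duration=40.0, stride=1)
        b = integrate(default_params, pro, duration=40.0, stride=1)
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.Na_in, b.Na_in)

    def test_resume_matches_single_run(self, default_params):
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.13)
        whole = integrate(default_params, pro, duration=40.0, stride=1,
                          frozen=True)
        first = integrate(default_params, pro, duration=20.0, stride=1,
                          frozen=True)
        second = integrate(default_params, pro, duration=20.0, stride=1,
                           frozen=True, state=first.final_state)
        assert second.v[-1] == whole.v[-1]

    def test_pump_input_shift_identity(self, default_params):
        """A constant pump current P under input I gives a bit-identical
        voltage trace to no pump under input I - P (frozen concentrations,
        no co-expressed leak)."""
        P = 0.15
        I = 0.55
        with_pump = default_params.replace(I_pump0=P, pump_mode="fixed")
        pro_a = StimulusProtocol(kind="constant_current", amplitude=I)
        pro_b = StimulusProtocol(kind="constant_current", amplitude=I - P)
        a = integrate(with_pump, pro_a, duration=100.0, stride=1,
                      frozen=True)
        b = integrate(default_params, pro_b, duration=100.0, stride=1,
                      frozen=True)
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.m, b.m)

    def test_first_order_convergence(self, default_params):
        """Forward Euler: halving dt roughly halves the error against a
        fine-step reference over a smooth subthreshold segment."""
        pro = StimulusProtocol(kind="constant_current", amplitude=0.15)
        ref = integrate(default_params, pro, duration=10.0, dt=0.000125,
                        stride=80, frozen=True).v[-1]
        e1 = abs(integrate(default_params, pro, duration=10.0, dt=0.002,
                           stride=1, frozen=True).v[-1] - ref)
        e2 = abs(integrate(default_params, pro, duration=10.0, dt=0.001,
                           stride=1, frozen=True).v[-1] - ref)
        assert e1 / e2 == pytest.approx(2.0, rel=0.35)

    def test_blowup_reports_failing_step(self, default_params):
        bad = default_params.replace(C=1e-5)  # far below the stability bound
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.13)
        with pytest.raises(IntegrationError, match="step"):
            integrate(bad, pro, duration=10.0, frozen=True)

    def test_invalid_arguments(self, default_params):
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.1)
        with pytest.raises(ValueError):
            integrate(default_params, pro, duration=10.0, dt=0.0)
        with pytest.raises(ValueError):
            integrate(default_params, pro, duration=-1.0)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0.0, 100.0, 0.01)
        assert len(detect_spikes((t, np.full_like(t, -80.0)))) == 0

    def test_sawtooth_counts_peaks(self):
        # ten 2 ms sawtooth pulses of 20 mV rising above threshold
        t = np.arange(0.0, 20.0, 0.001)
        v = -80.0 + 20.0 * (t % 2.0) / 2.0
        spikes = detect_spikes((t, v))
        assert len(spikes) == 10

    def test_tonic_rate_matches_pacemaker(self, default_params):
        pro = StimulusProtocol(kind="pacemaker", r_pn0=400.0)
        tr = integrate(default_params, pro, duration=100.0, stride=5,
                       frozen=True)
        assert len(tr.spike_times) == pytest.approx(40, abs=1)


class TestFICurve:
    def test_monotone_on_grid(self, default_params):
        rates = fi_curve(default_params, [0.0, 0.3, 0.5, 0.8],
                         duration=300.0)
        assert rates[0] == 0.0
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 400.0

    def test_pump_translates_curve_along_input_axis(self, default_params):
        """f(I) with pump P equals f(I - P) without pump (exactly, by the
        shift identity of the integrator)."""
        P = 0.2
        grid = np.array([0.35, 0.55, 0.75])
        base = fi_curve(default_params, grid, duration=300.0)
        shifted = fi_curve(default_params.replace(I_pump0=P,
                                                  pump_mode="fixed"),
                           grid + P, duration=300.0)
        np.testing.assert_array_equal(base, shifted)


class TestCalibration:
    def test_noop_when_already_on_target(self, default_params):
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.13)
        out = ec.calibrate_spike_amplitude(default_params, pro, target=13.0,
                                           tol=0.1)
        assert out.g_NaT_max == default_params.g_NaT_max

    def test_amplitude_monotone_in_sodium_conductance(self, default_params):
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.13)
        amps = []
        for g in (0.0, 40.0, 120.0):
            tr = integrate(default_params.replace(g_NaT_max=g), pro,
                           duration=300.0, stride=5, frozen=True)
            amps.append(ec.ap_metrics(tr)["amplitude"])
        assert amps[0] < amps[1] < amps[2]

    def test_unreachable_target_raises(self, default_params):
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.13)
        with pytest.raises(ValueError):
            ec.calibrate_spike_amplitude(default_params, pro, target=500.0,
                                         bracket=(0.0, 100.0))


class TestSteadyState:
    def test_looser_tolerance_never_runs_longer(self):
        params = ec.preset("electrocyte-voltage-pump")
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.10)
        tol = 5e-7
        _, d1 = ec.steady_state_concentration(params, pro, tolerance=tol,
                                              chunk=250.0)
        _, d2 = ec.steady_state_concentration(params, pro, tolerance=2 * tol,
                                              chunk=250.0)
        assert d2["time_ms"] <= d1["time_ms"]


class TestTraceExport:
    def test_csv_and_spike_files(self, default_params, tmp_path):
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.13)
        tr = integrate(default_params, pro, duration=50.0, stride=10,
                       frozen=True)
        csv = tmp_path / "trace.csv"
        tr.to_csv(csv)
        import pandas as pd
        frame = pd.read_csv(csv)
        assert list(frame.columns)[:3] == ["t", "v", "m"]
        assert len(frame) == len(tr.t)
        spikes = tmp_path / "spikes.txt"
        tr.save_spike_times(spikes)
        loaded = ec.load_spike_times(spikes)
        np.testing.assert_allclose(loaded, tr.spike_times, atol=1e-5)

    def test_hdf5_roundtrip(self, default_params, tmp_path):
        import h5py
        pro = StimulusProtocol(kind="constant_drive", amplitude=0.13)
        tr = integrate(default_params, pro, duration=20.0, stride=10,
                       frozen=True)
        path = tmp_path / "trace.h5"
        tr.to_hdf5(path)
        with h5py.File(path) as f:
            np.testing.assert_array_equal(f["v"][:], tr.v)
            assert f.attrs["dt"] == tr.dt
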