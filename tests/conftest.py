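"""Shared fixtures.

Pump tuning and long simulations are expensive, so tuned models and fixture
runs are session-scoped; everything downstream of them is deterministic.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import electrocyte as ec
from electrocyte.stimulus import StimulusProtocol


@pytest.fixture(scope="session")
def default_params():
    return ec.preset("electrocyte-default")


@pytest.fixture(scope="session")
def strong_params():
    return ec.preset("electrocyte-strong-synapse")


@pytest.fixture(scope="session")
def drive_013():
    return StimulusProtocol(kind="constant_drive", amplitude=0.13)


@pytest.fixture(scope="session")
def tuned_strong(strong_params, drive_013):
    """Strong-synapse model with pump tuned at constant drive 0.13."""
    tuned, diag = ec.tune_baseline_pump(strong_params, drive_013)
    return tuned, diag


@pytest.fixture(scope="session")
def tuned_strong_trace(tuned_strong, drive_013):
    tuned, _ = tuned_strong
    return ec.integrate(tuned, drive_013, duration=400.0, stride=2,
                        frozen=True)


@pytest.fixture(scope="session")
def electroneutral_reference(strong_params, drive_013):
    """Matched reference: pump transports ions but carries no net current.

    Tuned by the same one-third-of-sodium-load rule, iterated on
    electroneutral runs (no co-expressed leak is needed because there is no
    pump current to balance).
    """
    x = 0.5
    for _ in range(60):
        work = strong_params.replace(I_pump0=x, pump_mode="fixed")
        tr = ec.integrate(work, drive_013, duration=300.0, stride=2,
                          frozen=True, electroneutral=True)
        sp = tr.spike_times
        cur = tr.currents()
        sel = (tr.t >= sp[-2]) & (tr.t < sp[-1])
        na = (cur["I_NaT"] + cur["I_NaP"] + cur["I_NaL"]
              + cur["I_AChRNa"])[sel].mean()
        target = -na / 3.0
        if abs(x - target) < 1e-3:
            break
        x = target
    work = strong_params.replace(I_pump0=x, pump_mode="fixed")
    return ec.integrate(work, drive_013, duration=400.0, stride=2,
                        frozen=True, electroneutral=True)


@pytest.fixture(scope="session")
def chirp_metrics():
    """Reduced-scale (3 chirps) fixture runs, unbuffered and buffered."""
    unb = ec.run_experiment(ec.generate_fixture("fig4_chirps", n_events=3))
    buf = ec.run_experiment(
        ec.generate_fixture("fig4_chirps_buffered", n_events=3))
    return unb, buf


@pytest.fixture(scope="session")
def rise_metrics():
    """Reduced-scale (3 rises) fixture runs at weak and strong coupling."""
    weak = ec.run_experiment(ec.generate_fixture("fig5_rises_weak",
                                                 n_events=3))
    strong = ec.run_experiment(ec.generate_fixture("fig5_rises_strong",
                                                   n_events=3))
    return weak, strong
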