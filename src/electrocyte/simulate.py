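"""Time-stepping engine, spike detection, tuning curves, and calibration.

The integrator is fixed-step forward Euler at dt = 0.001 ms (the reference
scheme for this model class); there is no randomness anywhere in the model,
so two runs with identical configuration produce bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel
from .model_core import gate_steady_state, nernst
from .params import ModelParameters
from .stimulus import StimulusProtocol, pacemaker_reset_times

_STIM_CODE = {"constant_current": _kernel.STIM_CONST_CURRENT,
              "constant_drive": _kernel.STIM_CONST_DRIVE,
              "pacemaker": _kernel.STIM_PACEMAKER}


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationTrace:
    """Stride-decimated record of a simulation.

    ``q_pump`` is the cumulative pump charge (uA*ms = nC) and ``K_in_book``
    the book-kept intracellular potassium (integrated alongside the closure
    state) — both are exact Euler accumulators, not post-hoc integrals.
    """

    dt: float
    stride: int
    params: ModelParameters
    protocol: StimulusProtocol
    t: np.ndarray
    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    Na_in: np.ndarray
    drive: np.ndarray
    I_pump: np.ndarray
    q_pump: np.ndarray
    K_in_book: np.ndarray
    flags: dict
    final_state: dict
    pacemaker_times: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    _spikes: np.ndarray | None = None
    _currents: dict | None = None

    @property
    def duration(self) -> float:
        return self.t[-1] - self.t[0]

    @property
    def spike_times(self) -> np.ndarray:
        if self._spikes is None:
            self._spikes = detect_spikes(self)
        return self._spikes

    def currents(self) -> dict:
        """Per-sample current breakdown, re-evaluated with the kernel."""
        if self._currents is None:
            out = _kernel.eval_records(
                self.params.pack(), self.v, self.m, self.h, self.n,
                self.Na_in, self.drive,
                self.flags["stim_mode"], self.flags["pump_mode"],
                self.flags["frozen"], self.flags["buffered"],
                self.flags["electroneutral"], self.flags["clamp_negative"],
                self.flags["vdep_mod"])
            keys = ("I_NaT", "I_NaP", "I_NaL", "I_K", "I_KL", "I_AChRNa",
                    "I_AChRK", "I_stim", "I_pump", "E_Na", "E_K")
            self._currents = dict(zip(keys, out))
        return self._currents

    # -- export --------------------------------------------------------
    def to_frame(self):
        import pandas as pd
        cols = {"t": self.t, "v": self.v, "m": self.m, "h": self.h,
                "n": self.n, "Na_in": self.Na_in, "drive": self.drive,
                "I_pump": self.I_pump, "q_pump": self.q_pump,
                "K_in_book": self.K_in_book}
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            for name in ("t", "v", "m", "h", "n", "Na_in", "drive",
                         "I_pump", "q_pump", "K_in_book"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["dt"] = self.dt
            f.attrs["stride"] = self.stride
            for k, v in self.metadata.items():
                f.attrs[k] = v

    def save_spike_times(self, path) -> None:
        np.savetxt(path, self.spike_times, fmt="%.6f")


def initial_state(params: ModelParameters, v0: float = -85.0,
                  na_in: float | None = None) -> dict:
    """Gates at steady state for v0; sodium at baseline unless overridden."""
    m_inf, h_inf, n_inf, *_ = gate_steady_state(v0, params)
    return {"v": v0, "m": m_inf, "h": h_inf, "n": n_inf,
            "na": params.Na_in0 if na_in is None else na_in,
            "k_book": params.K_in0, "q_pump": 0.0, "t": 0.0}


def integrate(params: ModelParameters, protocol: StimulusProtocol,
              duration: float, dt: float = 0.001, stride: int = 1,
              frozen: bool = False, buffered: bool = False,
              electroneutral: bool = False,
              state: dict | None = None) -> SimulationTrace:
    """Forward-Euler integration of the full model under a protocol.

    Parameters
    ----------
    duration : ms.  ``duration=0`` returns a trace holding only the
        initial sample.
    frozen : hold concentrations at baseline (instantaneous-rate regime).
    buffered : pin [K+]out at baseline (extracellular potassium buffer).
    electroneutral : remove the pump current from the voltage equation
        while keeping its ion transport (the efficiency reference case).
    state : resume from a previous trace's ``final_state``.
    """
    if dt <= 0 or duration < 0:
        raise ValueError("need dt > 0 and duration >= 0")
    n_steps = int(round(duration / dt))
    if state is None:
        state = initial_state(params)

    stim_mode = _STIM_CODE[protocol.kind]
    if stim_mode == _kernel.STIM_PACEMAKER:
        resets = pacemaker_reset_times(
            protocol, state["t"] + duration + 1.0)
        # sentinel so the interval lookup never walks off the end
        resets = np.append(resets, resets[-1] + 1e12)
    else:
        resets = np.zeros(1)

    n_rec = n_steps // stride + 1
    rec = {name: np.empty(n_rec) for name in
           ("t", "v", "m", "h", "n", "na", "drive", "pump", "qpump",
            "kbook")}

    out = _kernel.run_loop(
        params.pack(), n_steps, dt, stride,
        state["v"], state["m"], state["h"], state["n"], state["na"],
        state["k_book"], state["q_pump"], state["t"],
        stim_mode, float(protocol.amplitude), resets,
        params.pump_mode_code(), frozen, buffered, electroneutral,
        params.clamp_negative_pump, params.vdep_concentration_modulation,
        rec["t"], rec["v"], rec["m"], rec["h"], rec["n"], rec["na"],
        rec["drive"], rec["pump"], rec["qpump"], rec["kbook"])
    (status, fail_step, v, m, h, n, na, k_book, q_pump, _j, n_recorded) = out

    if status == _kernel.STATUS_NONFINITE:
        raise IntegrationError(
            f"non-finite membrane voltage at step {fail_step} "
            f"(t = {state['t'] + fail_step * dt:.3f} ms)")
    if status == _kernel.STATUS_BAD_POOL:
        raise IntegrationError(
            f"concentration pool became non-positive at step {fail_step} "
            f"(t = {state['t'] + fail_step * dt:.3f} ms, Na_in = {na:.4f} mM)")

    sl = slice(0, n_recorded)
    flags = {"stim_mode": stim_mode,
             "pump_mode": params.pump_mode_code(),
             "frozen": frozen, "buffered": buffered,
             "electroneutral": electroneutral,
             "clamp_negative": params.clamp_negative_pump,
             "vdep_mod": params.vdep_concentration_modulation}
    trace = SimulationTrace(
        dt=dt, stride=stride, params=params, protocol=protocol,
        t=rec["t"][sl], v=rec["v"][sl], m=rec["m"][sl], h=rec["h"][sl],
        n=rec["n"][sl], Na_in=rec["na"][sl], drive=rec["drive"][sl],
        I_pump=rec["pump"][sl], q_pump=rec["qpump"][sl],
        K_in_book=rec["kbook"][sl], flags=flags,
        final_state={"v": v, "m": m, "h": h, "n": n, "na": na,
                     "k_book": k_book, "q_pump": q_pump,
                     "t": state["t"] + n_steps * dt},
        pacemaker_times=(resets[:-1][resets[:-1] <= state["t"] + duration]
                         if stim_mode == _kernel.STIM_PACEMAKER else None),
        metadata={"params_hash": params.content_hash(),
                  "protocol": protocol.kind, "dt": dt, "stride": stride},
    )
    return trace


def detect_spikes(trace: SimulationTrace | tuple,
                  threshold_fraction: float = 0.5,
                  refractory: float = 0.5,
                  min_amplitude: float = 2.0) -> np.ndarray:
    """Upward threshold crossings with a refractory lockout.

    The threshold is ``baseline + threshold_fraction * (peak - baseline)``
    with the baseline taken as the 5th percentile of the trace and the peak
    as its maximum; a flat or near-flat trace yields no spikes.
    Deterministic.
    """
    if isinstance(trace, SimulationTrace):
        t, v = trace.t, trace.v
    else:
        t, v = trace
    if len(v) == 0:
        return np.empty(0)
    # estimate levels from the later part of the trace so the start-up
    # transient (first spike from rest) cannot inflate the threshold
    tail = v[len(v) // 4:] if len(v) >= 8 else v
    base = np.percentile(tail, 5.0)
    peak = np.percentile(tail, 99.9)
    if peak - base < min_amplitude:
        return np.empty(0)
    thr = base + threshold_fraction * (peak - base)
    above = v >= thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if len(crossings) == 0:
        return np.empty(0)
    times = t[crossings]
    kept = [times[0]]
    for ti in times[1:]:
        if ti - kept[-1] >= refractory:
            kept.append(ti)
    return np.asarray(kept)


def firing_rate(trace: SimulationTrace, t_start: float | None = None,
                t_end: float | None = None) -> float:
    """Mean firing rate (Hz) of trace spikes within [t_start, t_end]."""
    s = trace.spike_times
    t0 = trace.t[0] if t_start is None else t_start
    t1 = trace.t[-1] if t_end is None else t_end
    n = int(np.sum((s >= t0) & (s <= t1)))
    return n / ((t1 - t0) * 1e-3)


def fi_curve(params: ModelParameters, inputs, mode: str = "current",
             frozen: bool = True, duration: float = 500.0,
             dt: float = 0.001, stride: int = 10) -> np.ndarray:
    """Steady-state firing rate (Hz) for each input on the grid.

    ``mode="current"`` interprets inputs as constant currents (uA),
    ``mode="drive"`` as constant dimensionless synaptic drives.  Rates are
    measured over the last half of the run (transients at these firing
    rates decay well within the first half); instantaneous-rate curves use
    frozen concentrations, matching the convention for tuning curves of
    this model.
    """
    kind = "constant_current" if mode == "current" else "constant_drive"
    rates = np.empty(len(inputs))
    for i, amp in enumerate(inputs):
        pro = StimulusProtocol(kind=kind, amplitude=float(amp))
        trace = integrate(params, pro, duration=duration, dt=dt,
                          stride=stride, frozen=frozen)
        rates[i] = firing_rate(trace, t_start=duration / 2.0)
    return rates


def rheobase(params: ModelParameters, bracket=(0.0, 5.0),
             tol: float = 1e-3, duration: float = 300.0,
             dt: float = 0.001) -> float:
    """Minimal constant current (uA) eliciting sustained firing (bisection)."""
    lo, hi = bracket

    def fires(amp):
        pro = StimulusProtocol(kind="constant_current", amplitude=amp)
        trace = integrate(params, pro, duration=duration, dt=dt, stride=10,
                          frozen=True)
        return firing_rate(trace, t_start=duration / 2.0) > 0.0

    if fires(lo):
        return lo
    # walk up in coarse steps first: the firing range of this model class
    # is an interval, so probing only the top of the bracket can miss it
    n_probe = 20
    step = (hi - lo) / n_probe
    top = None
    for i in range(1, n_probe + 1):
        if fires(lo + i * step):
            top = lo + i * step
            lo = lo + (i - 1) * step
            break
    if top is None:
        raise ValueError(f"no firing found in {bracket} uA; widen the bracket")
    hi = top
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


def calibrate_spike_amplitude(params: ModelParameters,
                              protocol: StimulusProtocol | None = None,
                              target: float = 13.0,
                              tol: float = 0.1,
                              bracket: tuple = (0.0, 2000.0),
                              duration: float = 300.0,
                              dt: float = 0.001,
                              max_iter: int = 60) -> ModelParameters:
    """Bisect g_NaT_max until the mean spike amplitude matches ``target``.

    Amplitude (peak minus preceding trough, mV) is monotone increasing in
    g_NaT_max over the working bracket; returns parameters with the tuned
    conductance.  Raises if the target is unreachable inside the bracket.
    """
    from .analysis import ap_metrics

    if protocol is None:
        protocol = StimulusProtocol(kind="constant_drive", amplitude=0.13)

    def amplitude(g):
        work = params.replace(g_NaT_max=g)
        trace = integrate(work, protocol, duration=duration, dt=dt,
                          stride=5, frozen=True)
        if len(trace.spike_times) < 4:
            return 0.0
        metrics = ap_metrics(trace)
        return metrics["amplitude"]

    a0 = amplitude(params.g_NaT_max)
    if abs(a0 - target) <= tol:
        return params

    lo, hi = bracket
    alo, ahi = amplitude(lo), amplitude(hi)
    if not (alo <= target <= ahi):
        raise ValueError(
            f"target amplitude {target} mV unreachable in bracket "
            f"{bracket} (amplitudes {alo:.2f}..{ahi:.2f} mV)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        am = amplitude(mid)
        if abs(am - target) <= tol:
            return params.replace(g_NaT_max=mid)
        if am < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("amplitude calibration did not converge "
                       f"(last bracket {lo:.2f}..{hi:.2f} uS)")


def steady_state_concentration(params: ModelParameters,
                               protocol: StimulusProtocol,
                               tolerance: float | None = None,
                               chunk: float = 500.0,
                               max_time: float = 60000.0,
                               dt: float = 0.001,
                               buffered: bool = False) -> tuple[float, dict]:
    """Run with live concentrations until [Na+]in stops drifting.

    ``tolerance`` is the period-averaged |d[Na+]in/dt| bound in mM/ms;
    the default corresponds to a 1 nA residual sodium current.  Returns the
    terminal [Na+]in (for use as the t=0 concentration of subsequent runs)
    and diagnostics.
    """
    from .constants import faraday_volume
    if tolerance is None:
        tolerance = 1e-3 / faraday_volume(params.omega_in)  # 1 nA worth
    state = None
    t_done = 0.0
    drift = math.inf
    history = []
    while t_done < max_time:
        trace = integrate(params, protocol, duration=chunk, dt=dt,
                          stride=50, buffered=buffered, state=state)
        state = trace.final_state
        drift = abs(trace.Na_in[-1] - trace.Na_in[0]) / chunk
        history.append((t_done, state["na"], drift))
        t_done += chunk
        if drift < tolerance:
            return state["na"], {"time_ms": t_done, "drift": drift,
                                 "history": history}
    raise RuntimeError(
        f"no concentration steady state within {max_time} ms; last drift "
        f"{drift:.3e} mM/ms vs tolerance {tolerance:.3e}")
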