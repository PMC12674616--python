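"""Drive protocols: constant current, constant drive, pacemaker waveforms.

The pacemaker nucleus is not modeled explicitly; only the synaptic
conductance waveform it gates is.  The dimensionless drive follows a
piecewise pulse of the time ``t_pn`` since the last pacemaker spike (linear
ramp to 0.05 ms, unit plateau to 0.25 ms, exponential decay, tau = 0.1 ms),
and ``t_pn`` resets at the pacemaker rate.  Two communication signals
modulate the reset clock:

* chirps (type A): resets are suppressed for ``n_periods_suppressed``
  pacemaker periods, so the drive decays freely — a pause in the discharge;
* frequency rises: the instantaneous rate jumps by ``r_rise`` and decays
  exponentially (``tau_rise``) back to baseline; the reset clock integrates
  the instantaneous rate (phase accumulator), which reduces exactly to the
  fixed-period rule at constant rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._kernel import syn_clamp_scalar

RAMP_MS = 0.05
PLATEAU_MS = 0.25
DECAY_TAU_MS = 0.1


@dataclass
class ChirpEvent:
    """Cessation of pacemaker firing for n periods, starting near t_start."""
    t_start: float                 # ms
    n_periods_suppressed: int = 20

    def __post_init__(self) -> None:
        if self.n_periods_suppressed < 1:
            raise ValueError("n_periods_suppressed must be >= 1")


@dataclass
class RiseEvent:
    """Abrupt rate elevation decaying exponentially back to baseline."""
    t_start: float        # ms
    r_rise: float = 40.0  # Hz
    tau_rise: float = 1.0  # s

    def __post_init__(self) -> None:
        if self.tau_rise <= 0:
            raise ValueError("tau_rise must be > 0")


@dataclass
class StimulusProtocol:
    """Tagged union of the three drive kinds.

    ``amplitude`` is a current in uA for ``constant_current`` and a
    dimensionless drive for ``constant_drive``; ``r_pn0`` is the baseline
    pacemaker rate in Hz for ``pacemaker``.
    """

    kind: str
    amplitude: float = 0.0
    r_pn0: float = 0.0
    schedule: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("constant_current", "constant_drive", "pacemaker"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "pacemaker":
            if self.r_pn0 <= 0:
                raise ValueError("pacemaker rate must be > 0")
            starts = [e.t_start for e in self.schedule]
            if any(b < a for a, b in zip(starts, starts[1:])):
                raise ValueError("schedule event times must be non-decreasing")
            kinds = {type(e) for e in self.schedule}
            if kinds == {ChirpEvent, RiseEvent}:
                raise ValueError("cannot mix chirp and rise events")

    # -- IO ------------------------------------------------------------
    def to_dict(self) -> dict:
        events = []
        for e in self.schedule:
            if isinstance(e, ChirpEvent):
                events.append({"type": "chirp", "t_start": e.t_start,
                               "n_periods_suppressed": e.n_periods_suppressed})
            else:
                events.append({"type": "rise", "t_start": e.t_start,
                               "r_rise": e.r_rise, "tau_rise": e.tau_rise})
        return {"kind": self.kind, "amplitude": self.amplitude,
                "r_pn0": self.r_pn0, "schedule": events}

    @classmethod
    def from_dict(cls, data: dict) -> "StimulusProtocol":
        events = []
        for e in data.get("schedule", []):
            etype = e.get("type")
            if etype == "chirp":
                events.append(ChirpEvent(
                    t_start=e["t_start"],
                    n_periods_suppressed=e.get("n_periods_suppressed", 20)))
            elif etype == "rise":
                events.append(RiseEvent(
                    t_start=e["t_start"], r_rise=e.get("r_rise", 40.0),
                    tau_rise=e.get("tau_rise", 1.0)))
            else:
                raise ValueError(f"unknown schedule event type {etype!r}")
        return cls(kind=data["kind"], amplitude=data.get("amplitude", 0.0),
                   r_pn0=data.get("r_pn0", 0.0), schedule=events)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "StimulusProtocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def syn_clamp(t_pn: float) -> float:
    """Dimensionless synaptic drive at time t_pn (ms) since pacemaker spike."""
    if t_pn < 0:
        raise ValueError("t_pn must be >= 0")
    return syn_clamp_scalar(t_pn)


def frequency_rise_rate(t_rise: float, r_rise: float, tau_rise: float,
                        r_pn0: float) -> float:
    """Instantaneous pacemaker rate (Hz) at t_rise ms after rise onset."""
    if tau_rise <= 0:
        raise ValueError("tau_rise must be > 0")
    return r_rise * math.exp(-t_rise / (tau_rise * 1e3)) + r_pn0


def mean_drive(r_pn: float) -> float:
    """Closed-form time average of the drive over one pacemaker period.

    Ramp area + plateau area + truncated-exponential area divided by the
    period 1/r_pn; 0.13 at 400 Hz, 0.10 at 300 Hz (two-decimal rounding).
    """
    if r_pn < 0:
        raise ValueError("r_pn must be >= 0")
    if r_pn == 0.0:
        return 0.0
    period = 1e3 / r_pn  # ms
    if period <= RAMP_MS:
        area = period * period / (2.0 * RAMP_MS)
    elif period <= PLATEAU_MS:
        area = RAMP_MS / 2.0 + (period - RAMP_MS)
    else:
        area = (RAMP_MS / 2.0 + (PLATEAU_MS - RAMP_MS)
                + DECAY_TAU_MS * (1.0 - math.exp(-(period - PLATEAU_MS)
                                                 / DECAY_TAU_MS)))
    return area / period


def pacemaker_reset_times(protocol: StimulusProtocol, duration: float,
                          phase_dt: float = 0.01) -> np.ndarray:
    """Times (ms) at which t_pn resets, covering [0, duration].

    Constant-rate and chirp schedules are generated analytically; rise
    schedules integrate the instantaneous rate on a fine grid and place a
    reset at each unit crossing of the accumulated phase (the accumulator
    reduces exactly to the fixed-period rule at constant rate).
    """
    if protocol.kind != "pacemaker":
        raise ValueError("reset times are defined for pacemaker protocols")
    has_rise = any(isinstance(e, RiseEvent) for e in protocol.schedule)
    if has_rise:
        return _reset_times_rises(protocol, duration, phase_dt)
    return _reset_times_chirps(protocol, duration)


def _reset_times_chirps(protocol: StimulusProtocol,
                        duration: float) -> np.ndarray:
    period = 1e3 / protocol.r_pn0
    events = list(protocol.schedule)
    resets = [0.0]
    t = 0.0
    k = 0
    while t <= duration:
        if k < len(events) and t >= events[k].t_start:
            gap = events[k].n_periods_suppressed * period
            k += 1
        else:
            gap = period
        t += gap
        resets.append(t)
    return np.asarray(resets)


def _reset_times_rises(protocol: StimulusProtocol, duration: float,
                       phase_dt: float) -> np.ndarray:
    grid = np.arange(0.0, duration + phase_dt, phase_dt)
    rate = np.full(grid.shape, protocol.r_pn0, dtype=float)
    # the most recent rise overrides any incomplete predecessor
    for ev in protocol.schedule:
        sel = grid >= ev.t_start
        rate[sel] = (ev.r_rise
                     * np.exp(-(grid[sel] - ev.t_start) / (ev.tau_rise * 1e3))
                     + protocol.r_pn0)
    phase = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * phase_dt * 1e-3)])
    n_cross = int(np.floor(phase[-1]))
    targets = np.arange(0.0, n_cross + 1.0)
    resets = np.interp(targets, phase, grid)
    return resets


def pacemaker_phase(t: float, protocol: StimulusProtocol) -> float:
    """t_pn (ms): elapsed time at ``t`` since the last pacemaker reset."""
    if t < 0:
        raise ValueError("t must be >= 0")
    resets = pacemaker_reset_times(protocol, t + 1.0)
    j = int(np.searchsorted(resets, t, side="right") - 1)
    return t - resets[j]


def pacemaker_spike_times(protocol: StimulusProtocol,
                          duration: float) -> np.ndarray:
    """Pacemaker spike times within [0, duration] (= the reset times)."""
    resets = pacemaker_reset_times(protocol, duration)
    return resets[resets <= duration]
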