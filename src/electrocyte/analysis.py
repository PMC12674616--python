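"""Entrainment quantification, pump-load/energy accounting, AP morphology.

The entrainment index is the mean resultant length of electrocyte spike
phases measured within pacemaker inter-spike intervals,

    theta_k = (t_e_k - t_p_j) / (t_p_{j+1} - t_p_j),
    R_bar   = | sum_k exp(i 2 pi theta_k) | / n,

with 1 meaning perfect phase-locking and 0 no phase preference.
Electrocyte spikes before the first or after the last pacemaker spike have
no bracketing interval and are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .constants import FARADAY


class UndefinedResultError(ValueError):
    """The requested statistic is undefined for these inputs."""


@dataclass
class EntrainmentResult:
    phases: np.ndarray          # in [0, 1)
    R_bar: float | None         # None when no phases are available
    n_pacemaker: int
    n_electrocyte: int

    @property
    def defined(self) -> bool:
        return self.R_bar is not None


@dataclass
class EnergyReport:
    """Per-action-potential transport and efficiency bookkeeping.

    Na and K amounts derive from the single accumulated pump charge, so
    their 3:2 ratio is exact.  ``efficiency_ratio`` compares the sodium
    pumped per AP against a matched electroneutral reference (pump current
    absent from the voltage equation, transport intact, no compensatory
    leak); values above 1 mean the electrogenic pump costs more.
    """

    n_spikes: int
    pump_charge_per_ap: float        # nC
    na_pumped_per_ap: float          # nmol
    k_pumped_per_ap: float           # nmol
    nal_inward_fraction: float | None = None
    efficiency_ratio: float | None = None


def entrainment_index(pn_spikes, e_spikes) -> EntrainmentResult:
    """Mean resultant length of electrocyte phases in pacemaker intervals.

    Requires at least two pacemaker spikes; with zero usable electrocyte
    spikes the index is flagged undefined (``R_bar = None``), not zero.
    """
    pn = np.asarray(pn_spikes, dtype=float)
    es = np.asarray(e_spikes, dtype=float)
    if pn.ndim != 1 or len(pn) < 2:
        raise UndefinedResultError(
            "entrainment needs >= 2 pacemaker spikes")
    if np.any(np.diff(pn) <= 0) or (len(es) > 1 and np.any(np.diff(es) < 0)):
        raise ValueError("spike time lists must be sorted")
    inside = (es > pn[0]) & (es < pn[-1])
    es_in = es[inside]
    if len(es_in) == 0:
        return EntrainmentResult(phases=np.empty(0), R_bar=None,
                                 n_pacemaker=len(pn), n_electrocyte=0)
    j = np.searchsorted(pn, es_in, side="right") - 1
    phases = (es_in - pn[j]) / (pn[j + 1] - pn[j])
    z = np.exp(1j * 2.0 * np.pi * phases)
    r_bar = float(np.abs(np.sum(z)) / len(z))
    return EntrainmentResult(phases=phases, R_bar=r_bar,
                             n_pacemaker=len(pn), n_electrocyte=len(es_in))


def windowed_entrainment(pn_spikes, e_spikes, windows) -> list:
    """Entrainment index per (t0, t1) analysis window (ms)."""
    pn = np.asarray(pn_spikes, dtype=float)
    es = np.asarray(e_spikes, dtype=float)
    out = []
    for (t0, t1) in windows:
        pw = pn[(pn >= t0) & (pn <= t1)]
        ew = es[(es >= t0) & (es <= t1)]
        if len(pw) < 2:
            out.append(EntrainmentResult(np.empty(0), None, len(pw), 0))
        else:
            out.append(entrainment_index(pw, ew))
    return out


def ap_metrics(trace) -> dict:
    """Amplitude (peak - preceding trough), width at half amplitude (ms),
    and onset voltage (maximal curvature before the upstroke) of the mean
    action potential in a trace."""
    # analyze the steady part only: the start-up transient from rest is not
    # a representative action potential
    skip = len(trace.v) // 4
    v = trace.v[skip:]
    t = trace.t[skip:]
    spikes = trace.spike_times
    if len(spikes) < 1:
        raise UndefinedResultError("ap_metrics needs at least one spike")
    base = np.percentile(v, 5.0)
    vmax = float(np.percentile(v, 99.9))
    half = base + 0.5 * (vmax - base)
    min_dist = max(1, int(0.5 / (trace.dt * trace.stride)))
    peaks, _ = find_peaks(v, height=half, distance=min_dist)
    if len(peaks) < 1:
        raise UndefinedResultError("no peaks above the half-range threshold")

    amplitudes = []
    widths = []
    onsets = []
    prev = 0
    for pk in peaks:
        seg = v[prev:pk + 1]
        trough_idx = prev + int(np.argmin(seg))
        trough = v[trough_idx]
        amp = v[pk] - trough
        amplitudes.append(amp)
        half_level = trough + 0.5 * amp
        above = v >= half_level
        li = pk
        while li > 0 and above[li - 1]:
            li -= 1
        ri = pk
        while ri < len(v) - 1 and above[ri + 1]:
            ri += 1
        widths.append(t[min(ri, len(t) - 1)] - t[li])
        upstroke = v[trough_idx:pk + 1]
        if len(upstroke) >= 5:
            curv = np.diff(upstroke, 2)
            onsets.append(upstroke[1 + int(np.argmax(curv))])
        prev = pk
    return {"amplitude": float(np.mean(amplitudes)),
            "width": float(np.mean(widths)),
            "onset_voltage": float(np.mean(onsets)) if onsets else math.nan,
            "n_spikes": len(peaks)}


def pump_load_per_ap(trace, reference_trace=None) -> EnergyReport:
    """Ion transport by the pump per action potential.

    Integrates the pump current between the first and last spike of the
    trace (using the exact cumulative pump-charge accumulator) and divides
    by the number of inter-spike periods.  With a matched electroneutral
    reference trace the efficiency ratio (this trace's sodium load per AP
    over the reference's) is filled in.
    """
    spikes = trace.spike_times
    if len(spikes) < 2:
        raise UndefinedResultError("pump load needs >= 2 spikes")
    q0 = float(np.interp(spikes[0], trace.t, trace.q_pump))
    q1 = float(np.interp(spikes[-1], trace.t, trace.q_pump))
    n_periods = len(spikes) - 1
    q_per_ap = (q1 - q0) / n_periods
    mol_per_ap = q_per_ap / FARADAY  # single conversion so Na:K is 3:2 exact
    na_per_ap = 3.0 * mol_per_ap
    k_per_ap = 2.0 * mol_per_ap

    cur = trace.currents()
    sel = (trace.t >= spikes[0]) & (trace.t <= spikes[-1])
    na_parts = {k: np.mean(np.clip(cur[k][sel], None, 0.0))
                for k in ("I_NaT", "I_NaP", "I_NaL", "I_AChRNa")}
    inward_total = sum(na_parts.values())
    nal_fraction = (na_parts["I_NaL"] / inward_total
                    if inward_total < 0 else None)

    efficiency = None
    if reference_trace is not None:
        ref = pump_load_per_ap(reference_trace)
        if ref.na_pumped_per_ap > 0:
            efficiency = na_per_ap / ref.na_pumped_per_ap
    return EnergyReport(n_spikes=len(spikes), pump_charge_per_ap=q_per_ap,
                        na_pumped_per_ap=na_per_ap, k_pumped_per_ap=k_per_ap,
                        nal_inward_fraction=nal_fraction,
                        efficiency_ratio=efficiency)


def load_spike_times(path) -> np.ndarray:
    """Read a plain-text spike list (one time in ms per line)."""
    return np.loadtxt(Path(path), ndmin=1)


def save_spike_times(path, spikes) -> None:
    np.savetxt(Path(path), np.asarray(spikes), fmt="%.6f")
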