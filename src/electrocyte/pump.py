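"""The electrogenic Na+/K+-ATPase.

The pump exchanges three intracellular Na+ for two extracellular K+ per
cycle, producing one net outward elementary charge — its current therefore
appears with its own term in the master equation and with factors 3 and 2
in the sodium and potassium concentration ODEs.  Three layers are modeled:

* a concentration-dependent current (sigmoidal in [Na+]in and [K+]out,
  saturating at four times the baseline),
* the co-expression rule that scales a compensatory sodium leak conductance
  with the baseline pump current so that rheobase is pump-invariant,
* an idealized voltage-dependent pump whose current copies one third of the
  potassium-current dynamics, allowing the potassium conductances to be
  reduced to 2/3 with unchanged action-potential shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .params import ModelParameters


@dataclass
class PumpState:
    """Baseline setting plus cumulative transport bookkeeping.

    Cumulative amounts are derived from a single accumulated charge
    ``q_pump = integral of I_pump dt`` (uA*ms = nC), so the 3:2
    Na-extruded : K-imported stoichiometry holds to machine precision by
    construction.
    """

    I_pump0: float
    mode: str = "concentration"
    I_pump: float = 0.0          # instantaneous current, uA
    q_pump: float = 0.0          # cumulative pump charge, nC

    @property
    def na_extruded_nmol(self) -> float:
        from .constants import FARADAY
        return 3.0 * (self.q_pump / FARADAY)  # nC / (C/mol) = nmol

    @property
    def k_imported_nmol(self) -> float:
        from .constants import FARADAY
        return 2.0 * (self.q_pump / FARADAY)


def pump_current_concentration(Na_in: float, K_out: float,
                               params: ModelParameters) -> float:
    """Concentration-dependent pump current (uA).

    ``4 I_pump0 / ((1 + exp((Na_in0 - Na_in)/na_scale))
    (1 + exp((K_out0 - K_out)/k_scale)))`` — equals ``I_pump0`` exactly at
    baseline, saturates at ``4 I_pump0``, strictly increasing in both
    arguments.
    """
    return _kernel.pump_concentration_scalar(Na_in, K_out, params.pack())


def coexpressed_leak_conductance(I_pump0: float, v_onset: float,
                                 E_Na: float) -> float:
    """Sodium leak conductance (uS) co-expressed with the pump.

    ``g_NaL = I_pump0 / (E_Na - v_onset)`` (written with the positive
    denominator so the conductance is non-negative): at ``v = v_onset`` the
    leak's inward current magnitude equals the baseline pump current, which
    pins the firing onset of the co-expressed cell to that of the pump-free
    cell.
    """
    if E_Na == v_onset:
        raise ValueError("degenerate co-expression: E_Na equals v_onset")
    if I_pump0 < 0:
        raise ValueError("I_pump0 must be >= 0")
    g_ms = I_pump0 / (E_Na - v_onset)   # uA/mV = mS
    return g_ms * 1e3                   # -> uS


def pump_current_voltage_dependent(state, ions, params: ModelParameters,
                                   apply_modulation: bool | None = None) -> float:
    """Idealized voltage-dependent pump current (uA).

    Baseline term ``(1/3)(g_KL + g_K_max n^4)(v - E_K)``; the concentration
    modulation of the sigmoidal pump law is applied multiplicatively around
    it when ``apply_modulation`` (default: the parameter flag) is set.
    """
    p = params.pack()
    from .params import _P_G_K, _P_G_KL
    n4 = state.n ** 4
    pb = (p[_P_G_KL] * (state.v - ions.E_K) / 3.0
          + p[_P_G_K] * n4 * (state.v - ions.E_K) / 3.0)
    mod = params.vdep_concentration_modulation if apply_modulation is None \
        else apply_modulation
    if mod:
        pb *= _kernel.pump_modulation_scalar(ions.Na_in, ions.K_out, p)
    if params.clamp_negative_pump and pb < 0.0:
        pb = 0.0
    return pb


def apply_coexpression(params: ModelParameters, I_pump0: float,
                       pump_mode: str = "concentration") -> ModelParameters:
    """Return parameters with the pump set and g_NaL from the rule above."""
    from .model_core import nernst
    e_na = nernst(params.Na_in0, params.Na_out0, params.T,
                  convention=params.nernst_convention)
    g_nal = coexpressed_leak_conductance(I_pump0, params.v_onset, e_na)
    return params.replace(I_pump0=I_pump0, g_NaL=g_nal, pump_mode=pump_mode)


def tune_baseline_pump(params: ModelParameters, protocol,
                       coexpress: bool = True,
                       damping: float = 0.5,
                       tol: float = 1e-3,
                       max_iter: int = 100,
                       duration: float = 400.0,
                       dt: float = 0.001,
                       I_pump0_init: float = 0.1,
                       calibrate_amplitude_to: float | None = None):
    """Tune the baseline pump current to the cell's sodium load.

    Finds the fixed point ``I_pump0 = (1/3) sum of period-averaged sodium
    currents`` (transient, persistent, leak, and synaptic sodium) in the
    tonic firing regime under ``protocol``, iterating because the
    co-expressed g_NaL itself depends on ``I_pump0``.  Damped fixed-point
    iteration; converged when the residual is below ``tol`` (uA; default
    1 nA).

    Returns ``(tuned_params, diagnostics)`` where ``tuned_params`` carries
    the converged ``I_pump0`` (and matching ``g_NaL`` if co-expressed) and
    diagnostics holds the iteration history.
    """
    from .simulate import integrate  # local import to avoid a cycle

    x = float(I_pump0_init)
    history = []
    converged = False
    work = params
    for it in range(max_iter):
        if coexpress:
            work = apply_coexpression(params, x)
        else:
            work = params.replace(I_pump0=x)
        if calibrate_amplitude_to is not None:
            from .simulate import calibrate_spike_amplitude
            work = calibrate_spike_amplitude(
                work, protocol, target=calibrate_amplitude_to)
        trace = integrate(work, protocol, duration=duration, dt=dt,
                          frozen=True)
        spikes = trace.spike_times
        cur = trace.currents()
        na_all = (cur["I_NaT"] + cur["I_NaP"] + cur["I_NaL"]
                  + cur["I_AChRNa"])
        if len(spikes) < 6:
            if np.max(np.abs(na_all[trace.t > duration / 2])) < tol:
                # degenerate sodium-free cell: zero load, zero pump
                target = 0.0
            elif x > 0 and it + 1 < max_iter:
                # the trial pump current silenced the cell: back off
                x *= 0.5
                if x < 1e-6:
                    raise RuntimeError(
                        "pump tuning: cell does not fire tonically under "
                        "this protocol even without a pump current")
                continue
            else:
                raise RuntimeError(
                    f"pump tuning requires tonic firing; got {len(spikes)} "
                    f"spikes in {duration} ms at I_pump0={x:.4f} uA")
        else:
            # averaging window: the last complete spiking period
            t0, t1 = spikes[-2], spikes[-1]
            sel = (trace.t >= t0) & (trace.t < t1)
            target = -np.mean(na_all[sel]) / 3.0
        residual = x - target
        history.append((x, target, residual))
        if abs(residual) < tol:
            converged = True
            break
        # secant step on f(x) = target(x) - x (the co-expressed leak gives
        # the map a gain of ~1/3, so plain damped iteration is slow);
        # fall back to a damped step when the secant is ill-conditioned
        x_new = None
        f1 = -residual
        # partner point must be well separated or the slope estimate is
        # dominated by the spike-period discretization noise of target(x)
        partners = [h for h in history[:-1]
                    if abs(h[0] - x) > max(0.02 * abs(x), 1e-3)]
        if partners:
            x0, t0, r0 = min(partners, key=lambda h: abs(h[2]))
            f0 = -r0
            if f1 != f0:
                cand = x - f1 * (x - x0) / (f1 - f0)
                if 0.0 <= cand <= max(4.0 * x, 1.0):
                    x_new = cand
        if x_new is None or abs(x_new - x) < 0.25 * abs(residual):
            x_new = x * (1.0 - damping) + damping * target
        x = max(x_new, 0.0)
    if not converged:
        raise RuntimeError(
            "pump tuning did not converge within "
            f"{max_iter} iterations; history tail: {history[-3:]}")
    if coexpress:
        work = apply_coexpression(params, x)
    else:
        work = params.replace(I_pump0=x)
    diagnostics = {"iterations": len(history), "history": history,
                   "I_pump0": x, "g_NaL": work.g_NaL}
    return work, diagnostics
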