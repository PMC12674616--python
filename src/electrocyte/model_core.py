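"""Membrane voltage dynamics, channel and synaptic currents, Nernst potentials.

The master equation of the model is

    C dv/dt = -I_NaT - I_NaP - I_K - I_L - I_pump + I_stim(t),

with the leak split into a potassium leak and a co-expressed sodium leak,
``I_L = I_NaL + I_KL``, so that every current in the equation is carried by
exactly one ion species (or by the pump).  Positive channel/pump current
hyperpolarizes; positive ``I_stim`` depolarizes.

The synaptic (cholinergic receptor) currents are gated by the dimensionless
pacemaker drive: ``I_stim = eps * syn_clamp * (-I_AChRNa - I_AChRK)``.  In
the :class:`CurrentBreakdown` the AChR entries are the ion-resolved currents
actually flowing (already scaled by ``eps * syn_clamp``), so that
``I_stim = -I_AChRNa - I_AChRK`` and the species bookkeeping closes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import _kernel
from .constants import rt_over_f_mv
from .ion_dynamics import IonState, closure_update
from .params import ModelParameters


@dataclass
class MembraneState:
    """Voltage and gating state at time t (gates dimensionless in [0, 1])."""

    v: float            # mV
    m: float = 0.0      # transient-Na activation
    h: float = 1.0      # transient-Na inactivation
    p: float = 0.0      # persistent-Na activation (instantaneous)
    n: float = 0.0      # K activation (enters as n^4)
    t: float = 0.0      # ms

    def __post_init__(self) -> None:
        for g in ("m", "h", "p", "n"):
            x = getattr(self, g)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {g}={x} outside [0, 1]")


@dataclass
class CurrentBreakdown:
    """Signed currents (uA) of one instant, one entry per membrane pathway."""

    I_NaT: float = 0.0
    I_NaP: float = 0.0
    I_NaL: float = 0.0
    I_AChRNa: float = 0.0   # eps*syn-scaled sodium AChR current
    I_K: float = 0.0
    I_KL: float = 0.0
    I_AChRK: float = 0.0    # eps*syn-scaled potassium AChR current
    I_pump: float = 0.0
    I_stim: float = 0.0

    @property
    def sodium_total(self) -> float:
        return self.I_NaT + self.I_NaP + self.I_NaL + self.I_AChRNa

    @property
    def potassium_total(self) -> float:
        return self.I_K + self.I_KL + self.I_AChRK


def nernst(c_in: float, c_out: float, T: float, z: int = 1,
           convention: str = "out_over_in") -> float:
    """Nernst reversal potential in mV.

    The default convention, ``(RT/zF) ln(c_out/c_in)``, yields the
    physiological +55 mV sodium reversal for 13.5 mM in / 120 mM out at
    293.15 K; ``"in_over_out"`` evaluates the mirrored form.
    """
    if c_in <= 0 or c_out <= 0:
        raise ValueError(f"concentrations must be > 0 (got {c_in}, {c_out})")
    if T <= 0:
        raise ValueError(f"temperature must be > 0 K (got {T})")
    if z == 0:
        raise ValueError("valence must be nonzero")
    sign = 1.0 if convention == "out_over_in" else -1.0
    if convention not in ("out_over_in", "in_over_out"):
        raise ValueError(f"unknown convention {convention!r}")
    return sign * rt_over_f_mv(T) / z * math.log(c_out / c_in)


def gate_steady_state(v: float, params: ModelParameters):
    """(m_inf, h_inf, n_inf, tau_m, tau_h, tau_n) at voltage v."""
    am, bm, ah, bh, an, bn = _kernel.gate_rates(
        v, params.phi, params.v_shift, params.phi_m, params.phi_h,
        params.phi_n, params.m_vshift, params.h_vshift, params.n_vshift)
    return (am / (am + bm), ah / (ah + bh), an / (an + bn),
            1.0 / (am + bm), 1.0 / (ah + bh), 1.0 / (an + bn))


def persistent_activation(v: float, params: ModelParameters) -> float:
    """Instantaneous persistent-sodium activation p_inf(v)."""
    return _kernel.p_inf(v, params.p_vhalf, params.p_slope)


def channel_currents(state: MembraneState, ions: IonState,
                     params: ModelParameters,
                     drive: float = 0.0) -> CurrentBreakdown:
    """All membrane currents at one instant under dimensionless drive.

    In the ideal voltage-dependent pump mode the reported voltage-gated and
    leak potassium currents are scaled to 2/3 of their full-conductance
    values, the removed third being carried by the pump.
    """
    if drive < 0:
        raise ValueError("drive must be >= 0")
    pump_mode = params.pump_mode_code()
    out = _kernel.step_eval(
        state.v, state.m, state.h, state.n, ions.Na_in, drive, 0.0,
        params.pack(), _kernel.STIM_CONST_DRIVE, pump_mode,
        False, ions.buffered, False, params.clamp_negative_pump,
        params.vdep_concentration_modulation)
    (i_nat, i_nap, i_nal, i_k, i_kl, i_sna, i_sk, i_stim, i_pump,
     *_rest) = out
    return CurrentBreakdown(I_NaT=i_nat, I_NaP=i_nap, I_NaL=i_nal,
                            I_AChRNa=i_sna, I_K=i_k, I_KL=i_kl,
                            I_AChRK=i_sk, I_pump=i_pump, I_stim=i_stim)


def membrane_derivative(state: MembraneState, currents: CurrentBreakdown,
                        params: ModelParameters) -> float:
    """dv/dt (mV/ms) of the master equation from a current breakdown."""
    s = (currents.I_NaT + currents.I_NaP + currents.I_NaL
         + currents.I_K + currents.I_KL)
    return ((currents.I_stim - currents.I_pump) - s) / params.C


def resting_state(params: ModelParameters, v0: float = -85.0,
                  na_in: float | None = None) -> tuple[MembraneState, IonState]:
    """Initial condition: gates at steady state for ``v0``, pools at closure."""
    m_inf, h_inf, n_inf, *_ = gate_steady_state(v0, params)
    na = params.Na_in0 if na_in is None else na_in
    ions = closure_update(na, params)
    state = MembraneState(v=v0, m=m_inf, h=h_inf,
                          p=persistent_activation(v0, params), n=n_inf)
    return state, ions
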