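"""Numba kernel: per-step model evaluation and the forward-Euler loop.

Everything numerical lives here so that the Python-facing operations in
:mod:`model_core`, :mod:`pump`, :mod:`ion_dynamics` and the integrator in
:mod:`simulate` evaluate literally the same compiled expressions — the
per-step current partition test and the bit-identity oracles depend on it.

Floating-point structure (deliberate, do not "simplify"):

* The voltage update is ``dv/dt = ((I_stim - I_pump_extra) - S)/C`` with a
  single subtraction forming the net external term.  A constant pump ``P``
  under input ``I`` therefore produces bit-identical voltage traces to a
  pump-free run under input ``I - P`` (frozen concentrations, g_NaL = 0).
* In the ideal voltage-dependent pump mode the potassium currents enter
  ``S`` at full conductance and the pump appears only through
  ``I_pump_extra = I_pump - I_pump_base`` with ``I_pump_base = K_total/3``.
  At baseline concentration modulation (exactly 1.0) the extra term is
  exactly 0.0, so the voltage trace is bit-identical to the pump-free
  full-conductance-potassium model, which is the claimed equivalence.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import (
    _P_C, _P_G_NAT, _P_G_NAP, _P_G_K, _P_G_KL, _P_G_NAL, _P_G_ACHR_NA,
    _P_G_ACHR_K, _P_EPSILON, _P_RTF, _P_FW, _P_VOL_RATIO, _P_NA_IN0,
    _P_K_IN0, _P_NA_OUT0, _P_K_OUT0, _P_I_PUMP0, _P_V_ONSET, _P_NA_SCALE,
    _P_K_SCALE, _P_PHI, _P_V_SHIFT, _P_P_VHALF, _P_P_SLOPE, _P_NERNST_SIGN,
    _P_NAP_H, _P_PHI_M, _P_PHI_H, _P_PHI_N, _P_SHIFT_M, _P_SHIFT_H,
    _P_SHIFT_N,
)

# stimulus modes
STIM_CONST_CURRENT = 0
STIM_CONST_DRIVE = 1
STIM_PACEMAKER = 2

# pump modes (indices into params.PUMP_MODES)
PUMP_NONE = 0
PUMP_FIXED = 1
PUMP_CONCENTRATION = 2
PUMP_VOLTAGE = 3

# integrate() status codes
STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_BAD_POOL = 2


@njit(cache=True)
def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 patched."""
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True)
def gate_rates(v, phi, v_shift, phi_m, phi_h, phi_n,
               sh_m, sh_h, sh_n):
    """HH-form opening/closing rates (1/ms) for m, h, n at voltage v (mV).

    Classic squid-style rate functions shifted along the voltage axis
    (``v_shift`` globally, ``sh_*`` per gate), sped up globally by ``phi``
    and per-gate by the ``phi_*`` multipliers — the configurable stand-in
    for the unpublished base-model kinetics.  The per-gate multipliers set
    the timescale separation (fast activation, slower recovery) that
    shapes the tonic high-frequency limit cycle; the per-gate shifts place
    the activation windows relative to the firing threshold.
    """
    um = v - v_shift - sh_m
    uh = v - v_shift - sh_h
    un = v - v_shift - sh_n
    fm = phi * phi_m
    fh = phi * phi_h
    fn = phi * phi_n
    am = fm * 0.1 * _vtrap(um + 40.0, 10.0)
    bm = fm * 4.0 * math.exp(-(um + 65.0) / 18.0)
    ah = fh * 0.07 * math.exp(-(uh + 65.0) / 20.0)
    bh = fh * 1.0 / (1.0 + math.exp(-(uh + 35.0) / 10.0))
    an = fn * 0.01 * _vtrap(un + 55.0, 10.0)
    bn = fn * 0.125 * math.exp(-(un + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def p_inf(v, p_vhalf, p_slope):
    """Instantaneous persistent-sodium activation."""
    return 1.0 / (1.0 + math.exp(-(v - p_vhalf) / p_slope))


@njit(cache=True)
def syn_clamp_scalar(t_pn):
    """Dimensionless pacemaker-gated synaptic conductance waveform.

    Piecewise in the time since the last pacemaker spike: linear ramp to
    0.05 ms, unit plateau to 0.25 ms, exponential decay (tau = 0.1 ms).
    """
    if t_pn <= 0.05:
        return t_pn / 0.05
    if t_pn <= 0.25:
        return 1.0
    return math.exp(-(t_pn - 0.25) / 0.1)


@njit(cache=True)
def nernst_mv(rtf, sign, z, c_in, c_out):
    """Reversal potential in mV; sign=+1 is the ln(out/in) convention."""
    return sign * rtf / z * math.log(c_out / c_in)


@njit(cache=True)
def ion_pools(na_in, p):
    """Algebraic closure: derived pools from the single state [Na+]in."""
    d = na_in - p[_P_NA_IN0]
    na_out = p[_P_NA_OUT0] - p[_P_VOL_RATIO] * d
    k_in = p[_P_K_IN0] - d
    k_out = p[_P_K_OUT0] + p[_P_VOL_RATIO] * d
    return na_out, k_in, k_out


@njit(cache=True)
def pump_concentration_scalar(na_in, k_out, p):
    """Concentration-dependent Na+/K+-ATPase current (uA).

    4*I_pump0 / ((1 + exp((Na_in0 - Na_in)/na_scale))
                 * (1 + exp((K_out0 - K_out)/k_scale)));
    equals I_pump0 exactly at baseline and saturates at 4*I_pump0.
    """
    ena = math.exp((p[_P_NA_IN0] - na_in) / p[_P_NA_SCALE])
    eko = math.exp((p[_P_K_OUT0] - k_out) / p[_P_K_SCALE])
    return 4.0 * p[_P_I_PUMP0] / ((1.0 + ena) * (1.0 + eko))


@njit(cache=True)
def pump_modulation_scalar(na_in, k_out, p):
    """Concentration modulation factor (== 1.0 exactly at baseline)."""
    ena = math.exp((p[_P_NA_IN0] - na_in) / p[_P_NA_SCALE])
    eko = math.exp((p[_P_K_OUT0] - k_out) / p[_P_K_SCALE])
    return 4.0 / ((1.0 + ena) * (1.0 + eko))


@njit(cache=True)
def step_eval(v, m, h, n, na_in, syn, i_ext, p,
              stim_mode, pump_mode, frozen, buffered, electroneutral,
              clamp_negative, vdep_mod):
    """Evaluate every current and state derivative at one instant.

    Returns
    -------
    (i_nat, i_nap, i_nal, i_k, i_kl, i_stim_na, i_stim_k, i_stim, i_pump,
     dvdt, dna, dk, dm, dh, dn, e_na, e_k)

    ``i_k``/``i_kl`` are the reported potassium channel currents (scaled to
    2/3 in the voltage-dependent pump mode); ``dk`` is the bookkeeping
    intracellular-potassium rate (Eq. 9 analogue) used by the conservation
    identity; ``i_stim_na``/``i_stim_k`` are the ion-resolved synaptic
    currents eps*syn*I_AChR already carrying their channel sign.
    """
    # --- concentrations & reversals ---------------------------------------
    na_c = p[_P_NA_IN0] if frozen else na_in
    na_out, k_in, k_out = ion_pools(na_c, p)
    if buffered:
        k_out = p[_P_K_OUT0]
    e_na = nernst_mv(p[_P_RTF], p[_P_NERNST_SIGN], 1.0, na_c, na_out)
    e_k = nernst_mv(p[_P_RTF], p[_P_NERNST_SIGN], 1.0, k_in, k_out)

    # --- channel currents --------------------------------------------------
    dv_na = v - e_na
    dv_k = v - e_k
    i_nat = p[_P_G_NAT] * (m * m * m) * h * dv_na
    pg = p_inf(v, p[_P_P_VHALF], p[_P_P_SLOPE])
    if p[_P_NAP_H] != 0.0:
        pg *= h
    i_nap = p[_P_G_NAP] * pg * dv_na
    i_nal = p[_P_G_NAL] * dv_na
    i_k_full = p[_P_G_K] * (n * n * n * n) * dv_k
    i_kl_full = p[_P_G_KL] * dv_k

    # --- stimulus ----------------------------------------------------------
    if stim_mode == STIM_CONST_CURRENT:
        i_stim_na = 0.0
        i_stim_k = 0.0
        i_stim = i_ext
    else:
        i_stim_na = p[_P_EPSILON] * syn * (p[_P_G_ACHR_NA] * dv_na)
        i_stim_k = p[_P_EPSILON] * syn * (p[_P_G_ACHR_K] * dv_k)
        i_stim = -i_stim_na - i_stim_k

    # --- pump --------------------------------------------------------------
    if pump_mode == PUMP_NONE:
        i_pump = 0.0
        pump_extra = 0.0
        i_k = i_k_full
        i_kl = i_kl_full
    elif pump_mode == PUMP_FIXED:
        i_pump = p[_P_I_PUMP0]
        pump_extra = i_pump
        i_k = i_k_full
        i_kl = i_kl_full
    elif pump_mode == PUMP_CONCENTRATION:
        i_pump = pump_concentration_scalar(na_c, k_out, p)
        pump_extra = i_pump
        i_k = i_k_full
        i_kl = i_kl_full
    else:  # PUMP_VOLTAGE
        pb_k = i_k_full / 3.0
        pb_kl = i_kl_full / 3.0
        pb = pb_k + pb_kl
        mod = pump_modulation_scalar(na_c, k_out, p) if vdep_mod else 1.0
        i_pump = pb * mod
        if clamp_negative and i_pump < 0.0:
            i_pump = 0.0
        pump_extra = i_pump - pb  # exactly 0.0 at baseline modulation
        i_k = i_k_full - pb_k     # reported 2/3-scaled channel currents
        i_kl = i_kl_full - pb_kl

    if electroneutral:
        pump_extra = 0.0  # pump keeps moving ions but carries no net charge

    # --- derivatives -------------------------------------------------------
    s_total = i_nat + i_nap + i_nal + i_k_full + i_kl_full
    dvdt = ((i_stim - pump_extra) - s_total) / p[_P_C]

    fw = p[_P_FW]
    dna = (-(i_nat + i_nap + i_nal + i_stim_na) - 3.0 * i_pump) / fw
    dk = (-(i_k + i_kl + i_stim_k) + 2.0 * i_pump) / fw

    am, bm, ah, bh, an, bn = gate_rates(v, p[_P_PHI], p[_P_V_SHIFT],
                                        p[_P_PHI_M], p[_P_PHI_H], p[_P_PHI_N],
                                        p[_P_SHIFT_M], p[_P_SHIFT_H],
                                        p[_P_SHIFT_N])
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n

    return (i_nat, i_nap, i_nal, i_k, i_kl, i_stim_na, i_stim_k, i_stim,
            i_pump, dvdt, dna, dk, dm, dh, dn, e_na, e_k)


@njit(cache=True)
def run_loop(p, n_steps, dt, stride,
             v0, m0, h0, n0, na0, k_book0, q_pump0, t0,
             stim_mode, stim_amp, reset_times,
             pump_mode, frozen, buffered, electroneutral, clamp_negative,
             vdep_mod,
             rec_t, rec_v, rec_m, rec_h, rec_n, rec_na, rec_drive,
             rec_pump, rec_qpump, rec_kbook):
    """Forward-Euler loop.  Records every ``stride`` steps (incl. step 0).

    Returns (status, fail_step, v, m, h, n, na, k_book, q_pump, reset_idx,
    n_recorded).
    """
    v = v0
    m = m0
    h = h0
    n = n0
    na = na0
    k_book = k_book0
    q_pump = q_pump0
    # concentration bookkeeping integrates deltas from the entry values so
    # that tiny per-step increments are not rounded against the large
    # absolute baselines (13.5 / 89 mM) - the charge-mass identity is
    # checked at 1e-8 relative accuracy
    na_acc = 0.0
    kb_acc = 0.0

    j = 0  # pacemaker interval index
    n_reset = reset_times.shape[0]
    rec_i = 0

    for step in range(n_steps + 1):
        t = t0 + step * dt

        if stim_mode == STIM_PACEMAKER:
            while j + 1 < n_reset and t >= reset_times[j + 1]:
                j += 1
            syn = syn_clamp_scalar(t - reset_times[j])
            i_ext = 0.0
        elif stim_mode == STIM_CONST_DRIVE:
            syn = stim_amp
            i_ext = 0.0
        else:
            syn = 0.0
            i_ext = stim_amp

        (i_nat, i_nap, i_nal, i_k, i_kl, i_sna, i_sk, i_stim, i_pump,
         dvdt, dna, dk, dm, dh, dn, e_na, e_k) = step_eval(
            v, m, h, n, na, syn, i_ext, p,
            stim_mode, pump_mode, frozen, buffered, electroneutral,
            clamp_negative, vdep_mod)

        if step % stride == 0:
            rec_t[rec_i] = t
            rec_v[rec_i] = v
            rec_m[rec_i] = m
            rec_h[rec_i] = h
            rec_n[rec_i] = n
            rec_na[rec_i] = na
            rec_drive[rec_i] = syn if stim_mode != STIM_CONST_CURRENT else i_ext
            rec_pump[rec_i] = i_pump
            rec_qpump[rec_i] = q_pump
            rec_kbook[rec_i] = k_book
            rec_i += 1

        if step == n_steps:
            break

        # forward-Euler update; gates clamped to [0, 1] (the clamp only
        # engages at extreme voltages where the rate exponentials exceed
        # the step-size stability bound, e.g. strong hyperpolarizing probes)
        v = v + dt * dvdt
        m = min(max(m + dt * dm, 0.0), 1.0)
        h = min(max(h + dt * dh, 0.0), 1.0)
        n = min(max(n + dt * dn, 0.0), 1.0)
        if not frozen:
            na_acc = na_acc + dt * dna
            na = na0 + na_acc
        kb_acc = kb_acc + dt * dk
        k_book = k_book0 + kb_acc
        q_pump = q_pump + dt * i_pump

        if not math.isfinite(v):
            return (STATUS_NONFINITE, step + 1, v, m, h, n, na, k_book,
                    q_pump, j, rec_i)
        if not frozen:
            na_out, k_in, k_out = ion_pools(na, p)
            if buffered:
                k_out = p[_P_K_OUT0]
            if na <= 0.0 or na_out <= 0.0 or k_in <= 0.0 or k_out <= 0.0:
                return (STATUS_BAD_POOL, step + 1, v, m, h, n, na, k_book,
                        q_pump, j, rec_i)

    return (STATUS_OK, -1, v, m, h, n, na, k_book, q_pump, j, rec_i)


@njit(cache=True)
def eval_records(p, v, m, h, n, na, drive,
                 stim_mode, pump_mode, frozen, buffered, electroneutral,
                 clamp_negative, vdep_mod):
    """Re-evaluate the current breakdown on recorded samples.

    Calls the same per-step evaluation as the integrator, so post-hoc
    current traces are exactly what the integrator used at those samples.
    Returns 11 arrays: I_NaT, I_NaP, I_NaL, I_K, I_KL, I_AChRNa, I_AChRK,
    I_stim, I_pump, E_Na, E_K.
    """
    nrec = v.shape[0]
    i_nat = np.empty(nrec)
    i_nap = np.empty(nrec)
    i_nal = np.empty(nrec)
    i_k = np.empty(nrec)
    i_kl = np.empty(nrec)
    i_sna = np.empty(nrec)
    i_sk = np.empty(nrec)
    i_stim = np.empty(nrec)
    i_pump = np.empty(nrec)
    e_na = np.empty(nrec)
    e_k = np.empty(nrec)
    for i in range(nrec):
        if stim_mode == STIM_CONST_CURRENT:
            syn = 0.0
            i_ext = drive[i]
        else:
            syn = drive[i]
            i_ext = 0.0
        out = step_eval(v[i], m[i], h[i], n[i], na[i], syn, i_ext, p,
                        stim_mode, pump_mode, frozen, buffered,
                        electroneutral, clamp_negative, vdep_mod)
        i_nat[i] = out[0]
        i_nap[i] = out[1]
        i_nal[i] = out[2]
        i_k[i] = out[3]
        i_kl[i] = out[4]
        i_sna[i] = out[5]
        i_sk[i] = out[6]
        i_stim[i] = out[7]
        i_pump[i] = out[8]
        e_na[i] = out[15]
        e_k[i] = out[16]
    return (i_nat, i_nap, i_nal, i_k, i_kl, i_sna, i_sk, i_stim, i_pump,
            e_na, e_k)
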