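"""Ion-concentration dynamics: one ODE state and an algebraic closure.

Only intracellular sodium is integrated.  Because the membrane couples the
species through ``C dv/dt = F*omega_in*(d[Na]in/dt + d[K]in/dt)`` and the
prefactor ``C/(F*omega_in)`` is tiny, macroscopic intracellular changes obey
``d[Na]in ~ -d[K]in``, which the model enforces exactly by deriving

    [K+]in  = [K+]in0  - ([Na+]in - [Na+]in0)
    [Na+]out = [Na+]out0 - (omega_in/omega_out) ([Na+]in - [Na+]in0)
    [K+]out  = [K+]out0  + (omega_in/omega_out) ([Na+]in - [Na+]in0)

from the single state variable.  An instantaneous, infinite-capacity
extracellular potassium buffer optionally pins ``[K+]out`` at its baseline
while ``[K+]in`` still follows the closure.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _kernel
from .params import _P_NERNST_SIGN, _P_RTF, ModelParameters


@dataclass
class IonState:
    """Concentration pools (mM) and derived reversal potentials (mV)."""

    Na_in: float
    Na_out: float
    K_in: float
    K_out: float
    E_Na: float
    E_K: float
    buffered: bool = False


class PoolError(ValueError):
    """A derived concentration pool became non-positive."""


def closure_update(Na_in: float, params: ModelParameters,
                   buffered: bool = False) -> IonState:
    """Derive all pools and reversal potentials from [Na+]in."""
    p = params.pack()
    na_out, k_in, k_out = _kernel.ion_pools(Na_in, p)
    if buffered:
        k_out = params.K_out0
    pools = {"Na_in": Na_in, "Na_out": na_out, "K_in": k_in, "K_out": k_out}
    bad = {k: v for k, v in pools.items() if v <= 0.0}
    if bad:
        raise PoolError(f"non-positive concentration pool(s): {bad} "
                        f"(Na_in={Na_in} mM)")
    sign = p[_P_NERNST_SIGN]
    rtf = p[_P_RTF]
    e_na = _kernel.nernst_mv(rtf, sign, 1.0, Na_in, na_out)
    e_k = _kernel.nernst_mv(rtf, sign, 1.0, k_in, k_out)
    return IonState(Na_in=Na_in, Na_out=na_out, K_in=k_in, K_out=k_out,
                    E_Na=e_na, E_K=e_k, buffered=buffered)


def sodium_concentration_rate(currents, params: ModelParameters) -> float:
    """d[Na+]in/dt in mM/ms from a :class:`CurrentBreakdown`.

    (-I_NaT - I_NaP - I_NaL - I_AChRNa(scaled) - 3 I_pump) / (F omega_in).
    """
    fw = _kernel_fw(params)
    return (-(currents.I_NaT + currents.I_NaP + currents.I_NaL
              + currents.I_AChRNa) - 3.0 * currents.I_pump) / fw


def potassium_concentration_rate(currents, params: ModelParameters) -> float:
    """Bookkeeping d[K+]in/dt in mM/ms (the derived species' ODE analogue).

    Used by the charge-mass consistency diagnostics; the integrated state
    itself follows the algebraic closure.
    """
    fw = _kernel_fw(params)
    return (-(currents.I_K + currents.I_KL + currents.I_AChRK)
            + 2.0 * currents.I_pump) / fw


def _kernel_fw(params: ModelParameters) -> float:
    from .constants import faraday_volume
    return faraday_volume(params.omega_in)
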