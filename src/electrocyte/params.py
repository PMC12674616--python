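"""Model parameters, presets, and parameter-file IO.

``ModelParameters`` carries every tunable of the electrocyte model: maximal
conductances, capacitance, cell geometry, baseline ion concentrations, the
Na+/K+-ATPase settings, the synaptic strength ``epsilon``, and the gating
kinetics of the underlying excitable-membrane model.  The pump/concentration
layer of the model is generic; the gating kinetics are a configurable
Hodgkin-Huxley-form default calibrated for tonic 200-600 Hz firing with
~13 mV spikes (see the shipped ``electrocyte-default`` preset).

Parameters are stored in the units they are usually quoted in (uS, uF, mM,
mm^3, K, uA, mV); :func:`ModelParameters.pack` converts them once into the
internal unit system of :mod:`electrocyte.constants` for the integrator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .constants import US_TO_MS, faraday_volume, rt_over_f_mv

PUMP_MODES = ("none", "fixed", "concentration", "voltage")
NERNST_CONVENTIONS = ("out_over_in", "in_over_out")

# Indices into the packed float64 parameter vector consumed by the kernel.
_P_C = 0
_P_G_NAT = 1
_P_G_NAP = 2
_P_G_K = 3
_P_G_KL = 4
_P_G_NAL = 5
_P_G_ACHR_NA = 6
_P_G_ACHR_K = 7
_P_EPSILON = 8
_P_RTF = 9
_P_FW = 10
_P_VOL_RATIO = 11
_P_NA_IN0 = 12
_P_K_IN0 = 13
_P_NA_OUT0 = 14
_P_K_OUT0 = 15
_P_I_PUMP0 = 16
_P_V_ONSET = 17
_P_NA_SCALE = 18
_P_K_SCALE = 19
_P_PHI = 20
_P_V_SHIFT = 21
_P_P_VHALF = 22
_P_P_SLOPE = 23
_P_NERNST_SIGN = 24
_P_NAP_H = 25
_P_PHI_M = 26
_P_PHI_H = 27
_P_PHI_N = 28
_P_SHIFT_M = 29
_P_SHIFT_H = 30
_P_SHIFT_N = 31
_PACK_LEN = 32


@dataclass
class ModelParameters:
    """Full parameter set of the electrocyte model.

    Conductances in uS, capacitance in uF, concentrations in mM, volume in
    mm^3, temperature in K, currents in uA, voltages in mV.
    """

    # Membrane and channels
    C: float = 0.01                # uF
    g_NaT_max: float = 14.65       # uS, transient Na (m^3 h)
    g_NaP_max: float = 13.0        # uS, persistent Na (instantaneous p_inf)
    g_K_max: float = 478.0         # uS, delayed rectifier (n^4)
    g_KL: float = 3.0              # uS, potassium leak
    g_NaL: float = 0.0             # uS, co-expressed sodium leak
    g_AChRNa: float = 52.0         # uS, cholinergic receptor Na component
    g_AChRK: float = 39.0          # uS, cholinergic receptor K component
    epsilon: float = 1.0           # dimensionless synaptic strength

    # Geometry / environment
    T: float = 293.15              # K
    omega_in: float = 0.434        # mm^3 intracellular volume
    vol_ratio: float = 2.0         # omega_in / omega_out

    # Baseline (t = 0 and pump set-point) concentrations, mM
    Na_in0: float = 13.5
    K_in0: float = 89.0
    Na_out0: float = 120.0
    K_out0: float = 2.16

    # Na+/K+-ATPase
    I_pump0: float = 0.0           # uA baseline pump current
    pump_mode: str = "none"        # none | fixed | concentration | voltage
    na_scale: float = 3.0          # mM, pump Na sensitivity scale
    k_scale: float = 1.0           # mM, pump K sensitivity scale
    v_onset: float = -76.0         # mV, voltage just before firing onset
    clamp_negative_pump: bool = False
    vdep_concentration_modulation: bool = True

    # Gating kinetics (HH-form defaults; configurable, not printed in any
    # single reference)
    phi: float = 6.0               # global rate speed factor
    phi_m: float = 1.0             # extra speed multiplier, m gate
    phi_h: float = 1.0             # extra speed multiplier, h gate
    phi_n: float = 0.85            # extra speed multiplier, n gate
    v_shift: float = -15.0         # mV shift of all rate functions
    m_vshift: float = 0.0          # additional shift, m gate only
    h_vshift: float = 0.0          # additional shift, h gate only
    n_vshift: float = 0.0          # additional shift, n gate only
    p_vhalf: float = -62.0         # mV half-activation of persistent Na
    p_slope: float = 4.25          # mV slope of persistent Na activation
    nap_inactivation: bool = False  # multiply p by h if True

    nernst_convention: str = "out_over_in"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in ("g_NaT_max", "g_NaP_max", "g_K_max", "g_KL", "g_NaL",
                     "g_AChRNa", "g_AChRK"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name in ("C", "omega_in", "vol_ratio", "T", "Na_in0", "K_in0",
                     "Na_out0", "K_out0", "na_scale", "k_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.pump_mode not in PUMP_MODES:
            raise ValueError(
                f"pump_mode must be one of {PUMP_MODES}, got {self.pump_mode!r}")
        if self.nernst_convention not in NERNST_CONVENTIONS:
            raise ValueError(
                f"nernst_convention must be one of {NERNST_CONVENTIONS}")

    # -- derived ------------------------------------------------------------
    def replace(self, **changes) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def pack(self) -> np.ndarray:
        """Pack into the float64 vector consumed by the numba kernel.

        Conductances are converted uS -> mS here (the single conversion
        point), so kernel currents come out in uA for voltages in mV.
        """
        p = np.empty(_PACK_LEN, dtype=np.float64)
        p[_P_C] = self.C
        p[_P_G_NAT] = self.g_NaT_max * US_TO_MS
        p[_P_G_NAP] = self.g_NaP_max * US_TO_MS
        p[_P_G_K] = self.g_K_max * US_TO_MS
        p[_P_G_KL] = self.g_KL * US_TO_MS
        p[_P_G_NAL] = self.g_NaL * US_TO_MS
        p[_P_G_ACHR_NA] = self.g_AChRNa * US_TO_MS
        p[_P_G_ACHR_K] = self.g_AChRK * US_TO_MS
        p[_P_EPSILON] = self.epsilon
        p[_P_RTF] = rt_over_f_mv(self.T)
        p[_P_FW] = faraday_volume(self.omega_in)
        p[_P_VOL_RATIO] = self.vol_ratio
        p[_P_NA_IN0] = self.Na_in0
        p[_P_K_IN0] = self.K_in0
        p[_P_NA_OUT0] = self.Na_out0
        p[_P_K_OUT0] = self.K_out0
        p[_P_I_PUMP0] = self.I_pump0
        p[_P_V_ONSET] = self.v_onset
        p[_P_NA_SCALE] = self.na_scale
        p[_P_K_SCALE] = self.k_scale
        p[_P_PHI] = self.phi
        p[_P_V_SHIFT] = self.v_shift
        p[_P_P_VHALF] = self.p_vhalf
        p[_P_P_SLOPE] = self.p_slope
        p[_P_NERNST_SIGN] = 1.0 if self.nernst_convention == "out_over_in" else -1.0
        p[_P_NAP_H] = 1.0 if self.nap_inactivation else 0.0
        p[_P_PHI_M] = self.phi_m
        p[_P_PHI_H] = self.phi_h
        p[_P_PHI_N] = self.phi_n
        p[_P_SHIFT_M] = self.m_vshift
        p[_P_SHIFT_H] = self.h_vshift
        p[_P_SHIFT_N] = self.n_vshift
        return p

    def pump_mode_code(self) -> int:
        return PUMP_MODES.index(self.pump_mode)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- IO -----------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(
                f"unknown parameter keys: {sorted(unknown)}; known keys are "
                f"{sorted(known)}")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} is not a mapping")
        return cls.from_dict(data)


_PRESETS: dict[str, dict] = {
    # Graded-spike kinetics: small (~13 mV) limit-cycle action potentials
    # under constant drive, calibrated so spike amplitude is 13.0 mV at
    # syn_clamp = 0.13.  Used for amplitude calibration and tuning-curve
    # work.
    "electrocyte-default": {},
    # Robust strong-persistent-Na kinetics: low rheobase (~2% of the tuned
    # baseline pump current, mirroring the 47 nA vs 1.9-4.1 uA proportions
    # of the published electrocyte model), wide firing range, strong
    # pacemaker synapse.  Used for pump-tuned energy analyses and the
    # chirp protocol.
    "electrocyte-strong-synapse": dict(
        C=0.05, g_NaT_max=0.0, g_NaP_max=125.0, g_K_max=4500.0, g_KL=17.0,
        g_AChRNa=260.0, g_AChRK=195.0, n_vshift=8.0),
    # Same membrane with a much weaker pacemaker synapse: entrains 1:1 at
    # baseline but with a slim margin, so pump-current growth during
    # frequency rises produces missing spikes at epsilon = 0.5.
    "electrocyte-weak-synapse": dict(
        C=0.05, g_NaT_max=0.0, g_NaP_max=125.0, g_K_max=4500.0, g_KL=17.0,
        g_AChRNa=35.1, g_AChRK=26.325, n_vshift=8.0),
    # Same membrane with a smaller potassium component in the mixed
    # cholinergic receptor, so the synaptic potassium flux the
    # voltage-dependent pump cannot sense stays small and the
    # concentration steady state lands within ~0.2% of baseline.
    "electrocyte-voltage-pump": dict(
        C=0.05, g_NaT_max=0.0, g_NaP_max=125.0, g_K_max=4500.0, g_KL=17.0,
        g_AChRNa=260.0, g_AChRK=50.0, n_vshift=8.0, pump_mode="voltage"),
}


def preset(name: str = "electrocyte-default") -> ModelParameters:
    """Return a named parameter preset.

    Every preset shares the published electrocyte constants (baseline
    concentrations, temperature, cell volume, v_onset, epsilon) and
    differs only in the membrane kinetics/synapse configuration, in the
    spirit of the per-protocol tuned parameter sets of the reference
    study.
    """
    try:
        return ModelParameters(**_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{sorted(_PRESETS)}") from None
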