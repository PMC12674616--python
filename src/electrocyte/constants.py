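"""Physical constants and the package's internal unit system.

All model arithmetic uses one consistent unit system:

==============  =========
quantity        unit
==============  =========
voltage         mV
time            ms
current         uA
conductance     uS (converted to mS = uA/mV at the single point of use)
capacitance     uF
concentration   mM
volume          mm^3
temperature     K
==============  =========

With these units, ``g [uS] * v [mV] = I [nA]``, so conductances are scaled by
``US_TO_MS`` (1e-3) exactly once, when parameters are packed for the
integrator.  Likewise a current ``I [uA]`` divided by ``F * omega [mm^3]``
is a concentration rate in mM/ms because 1 mm^3 = 1e-6 L and 1 uA = 1e-6 A
cancel.  Keeping every conversion here prevents silent factor-of-1000 errors.
"""

# CODATA 2018
FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)

US_TO_MS = 1e-3  # uS -> mS (= uA/mV)
V_TO_MV = 1e3

UA_TO_NA = 1e3
NA_TO_UA = 1e-3


def rt_over_f_mv(temperature_k: float) -> float:
    """R*T/F in millivolts (z = 1)."""
    return GAS_CONSTANT * temperature_k / FARADAY * V_TO_MV


def faraday_volume(omega_in_mm3: float) -> float:
    """F * omega_in such that I [uA] / (F * omega) is a rate in mM/ms."""
    return FARADAY * omega_in_mm3
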