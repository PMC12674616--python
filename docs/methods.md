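# Model and methods

## The system

The electrocyte of the weakly electric fish *Eigenmannia virescens* is an
excitable cell that fires one action potential per input pulse from an
upstream pacemaker nucleus, at 200–600 Hz, continuously, for the lifetime
of the animal.  The summed firing of the electric organ's electrocytes is
the electric organ discharge (EOD).  At these rates the Na+/K+-ATPase
activity required for ionic homeostasis produces a pump current of the
same order as the action-potential currents, and because the pump
exchanges 3 Na+ out for 2 K+ in, that current is net outward
(hyperpolarizing).  This package implements a conductance-based point
model of that situation: an excitable membrane, an explicit electrogenic
pump, dynamic ion concentrations with Nernst reversal potentials, and the
pacemaker communication protocols (chirps and frequency rises) whose
entrainment consequences the model quantifies.

## Membrane equations

The master equation is

    C dv/dt = -I_NaT - I_NaP - I_K - I_L - I_pump + I_stim(t),

with the leak split into a potassium leak and a sodium leak,
`I_L = I_NaL + I_KL`, so that every term is carried by exactly one ion
species (or by the pump):

    I_NaT = g_NaT_max m^3 h (v - E_Na)      transient sodium
    I_NaP = g_NaP_max p_inf(v) (v - E_Na)   persistent sodium (instantaneous)
    I_K   = g_K_max n^4 (v - E_K)           delayed rectifier
    I_KL  = g_KL (v - E_K),  I_NaL = g_NaL (v - E_Na)
    I_stim = eps * syn_clamp(t) * (-I_AChRNa - I_AChRK)

The cholinergic receptor currents are conductances to the sodium and
potassium reversals gated by the dimensionless pacemaker drive
`syn_clamp`, so the synaptic sodium and potassium fluxes can be tracked
per species.  Positive channel/pump current hyperpolarizes; positive
`I_stim` depolarizes.

Reversal potentials follow the Nernst equation.  The implementation
defaults to `E = (RT/zF) ln([X]out/[X]in)`, the convention that yields the
physiological +55 mV sodium reversal for 13.5 mM in / 120 mM out at
293.15 K (and E_K = −93.9 mV for 89 / 2.16 mM); the mirrored convention is
available via the `nernst_convention` parameter.

## Ion-concentration dynamics

Only intracellular sodium is integrated:

    d[Na+]in/dt = (-I_NaT - I_NaP - I_NaL - eps*syn*I_AChRNa - 3 I_pump) / (F w_in)

with `w_in = 0.434 mm^3` the cell volume.  Because
`C dv/dt = F w_in (d[Na]in/dt + d[K]in/dt)` and the prefactor
`C/(F w_in)` is ~1e-6, macroscopic intracellular changes obey
`d[Na]in ≈ -d[K]in`; the model enforces this exactly by deriving the other
three pools algebraically from [Na+]in (volume ratio `w_in/w_out = 2`):

    [K+]in  = 89   - ([Na+]in - 13.5)
    [Na+]out = 120 - 2 ([Na+]in - 13.5)
    [K+]out  = 2.16 + 2 ([Na+]in - 13.5)

An instantaneous, infinite-capacity extracellular potassium buffer can pin
`[K+]out` at baseline while `[K+]in` still follows the closure.  A
bookkeeping intracellular-potassium rate (the analogue of the eliminated
ODE) is integrated alongside so the charge–mass identity can be verified
numerically; the test suite checks it to 1e-8 relative accuracy.

## The pump

Concentration dependence (sigmoidal in the two pools the pump senses):

    I_pump = 4 I_pump0 / [(1 + exp(([Na]in0 - [Na]in)/3)) (1 + exp([K]out0 - [K]out))]

equal to `I_pump0` exactly at baseline and saturating at `4 I_pump0`.
The baseline is tuned to the cell's own sodium load: in tonic firing,
`I_pump0 = (1/3) * sum of period-averaged sodium currents`, iterated
(secant steps with a damped fallback, since the co-expressed leak feeds
back on the load) to a residual below 1 nA.

Co-expression rule: the compensatory sodium leak scales with the pump,
`g_NaL = I_pump0 / (E_Na - v_onset)`, so that at the firing-onset voltage
the leak's inward current cancels the pump current and rheobase is
approximately pump-invariant.  The denominator is written with `E_Na`
first so the conductance is non-negative (the mirrored form would be
negative for any onset below E_Na).

Idealized voltage-dependent pump: the baseline pump current is replaced by
`(1/3)(g_KL + g_K_max n^4)(v - E_K)` while the potassium conductances are
scaled to 2/3.  The integrator computes the potassium total once and takes
the pump as exactly one third of it, so at baseline concentration
modulation the voltage trace is bit-identical to the pump-free
full-conductance model — the equivalence is exact by construction, not
approximate.  The concentration modulation (the sigmoid above, normalized
to 1 at baseline) is applied multiplicatively around the voltage-dependent
baseline by default; both compositions are exposed because the reference
formulation does not pin this down.  A configuration flag can clamp the
pump at zero when `(v - E_K) < 0` (a physical pump does not run backward
on voltage alone); it is off by default so the equivalence statement stays
exact.

## Gating kinetics (this package's stand-in)

The upstream electrocyte model's rate functions are not published in the
source we implement, so the kinetics here are classic Hodgkin–Huxley-form
rate functions with configurable global/per-gate voltage shifts and speed
multipliers, plus a Boltzmann `p_inf` for the persistent sodium channel.
All claims used as the package's acceptance surface are either analytic
(drive averages, Nernst values, pump saturation, the bit-identity
equivalences) or robust to the exact parameterization (one-third
redundancy, efficiency loss, pump adaptation, entrainment degradation),
which is what makes a stand-in legitimate.

Two kinetic regimes are shipped as presets, mirroring the per-protocol
tuned parameter sets of the reference study:

* `electrocyte-default` — graded-spike kinetics.  The persistent-Na /
  delayed-rectifier pair forms a small limit cycle near the upper end of
  its oscillation window; the transient sodium conductance then sets the
  spike amplitude continuously, so `calibrate_spike_amplitude` can bisect
  `g_NaT_max` to the 13 mV operating amplitude (at constant drive 0.13 the
  shipped value gives 13.0 mV).  Tonic range ≈ 460–650 Hz over drives
  0.095–0.20.
* `electrocyte-strong-synapse` / `-weak-synapse` / `-voltage-pump` — a
  robust strong-persistent-Na membrane (C = 0.05 uF, g_NaP = 125 uS,
  g_K = 4.5 mS, K-activation shifted +8 mV) whose rheobase (~0.1 uA) is a
  few percent of its tuned pump current (~4.8 uA at drive 0.13), matching
  the proportions of the published model (47 nA vs 1.9–4.1 uA).  That
  ratio — not any absolute conductance — is what the chirp/rise
  phenomenology depends on: the pump decline accumulated over a few
  chirps must be able to cross the silent cell's distance to threshold.
  The three variants differ only in the cholinergic receptor
  conductances: strong (260/195 uS Na/K) for chirps and the energy
  analyses, weak (35.1/26.3 uS) so that 1:1 entrainment at 260 Hz is
  secure at baseline but has a slim margin that pump growth erodes at
  eps = 0.5, and a small-K receptor variant (260/50 uS) for the
  voltage-dependent-pump runs so that the synaptic potassium flux the
  pump cannot sense stays small and the concentration steady state lands
  within ~0.2% of baseline (13.522 mM vs 13.5, analogous to the published
  13.517).

The absolute conductance/capacitance scale was chosen so the tuned pump
currents land on the published scale (3.95 uA at the 600 Hz pacemaker
baseline, 1.16–1.18 uA at 260 Hz); scaling all conductances and C
together leaves the voltage dynamics invariant but sets the ion-flux
magnitudes, and with the physical cell volume fixed at 0.434 mm^3 it
thereby sets the speed of the concentration feedback.

`v_onset` defaults to the published −76 mV.  The measured voltage just
below firing onset of the strong-synapse preset is −82 mV, and the value
that best flattens rheobase against the pump for these kinetics is
−79 mV; the rheobase-invariance test passes that calibrated value
explicitly, the same measured-vs-used distinction the reference model
makes (−81 measured, −76 used).

## Stimulus protocols

The pacemaker is not modeled explicitly; its effect is the drive waveform
`syn_clamp(t_pn)`: linear ramp to 1 over 0.05 ms, plateau to 0.25 ms,
exponential decay with tau = 0.1 ms, where `t_pn` resets at the pacemaker
rate.  Closed-form period averages: 0.13 at 400 Hz, 0.10 at 300 Hz.

* Chirps (type A): `t_pn` resets are suppressed for 20 pacemaker periods.
  The fixture uses a 600 Hz baseline with 100 ms firing epochs between
  chirps, repeated 10 times (reducible for desk-scale runs).
* Frequency rises: the instantaneous rate is
  `r_rise exp(-t_rise/tau_rise) + r_pn0` (40 Hz, tau = 1 s, baseline
  260 Hz), initiated every 2 s, 10 times.  The reset clock integrates the
  instantaneous rate (phase accumulator), which reduces exactly to the
  fixed-period rule at constant rate; a new rise restarts the decay clock
  (override, not superposition — the reference text does not specify,
  and override matches "initiated every 2 s" most simply).

## Numerics

Forward Euler at dt = 0.001 ms for all states on one shared grid (the
reference scheme for this model family); concentrations are integrated as
deltas from their entry values so that nano-molar per-step increments are
not rounded against the 13.5/89 mM baselines.  Gates are clamped to
[0, 1]; the clamp only engages at extreme voltages (e.g. strong
hyperpolarizing probe currents) where the rate exponentials exceed the
step-size stability bound.  There is no randomness anywhere in the model:
identical configurations produce bit-identical traces.

Deliberate floating-point structure in the integrator: the net external
term is formed as a single subtraction `I_stim - I_pump`, so a constant
pump P under input I is bit-identical to no pump under input I − P; and
the voltage-dependent pump enters the voltage update only through an
`I_pump - K_total/3` excess that is exactly zero at baseline modulation.
These two identities are the package's exact regression oracles.

Spike detection: upward crossings of `baseline + 0.5 * (peak - baseline)`
with a 0.5 ms refractory lockout, levels estimated from the later part of
the trace so the start-up transient cannot inflate the threshold.
Tuning curves discard the first half of a 500 ms run.  The pump-tuning
average uses the last complete inter-spike period.

## Desk-scale problem sizes

The full printed protocols (10 chirps ≈ 1.5 s of model time; 10 rises ≈
26 s) run in tens of seconds; the test suite exercises the same protocols
at 3 events, where every qualitative signature is already expressed: the
binned pump current declines monotonically across chirps, spikes invade
the suppressed windows by the third chirp but not the first, potassium
buffering abolishes them, the pump current grows monotonically across
rises, and the entrainment index at eps = 0.5 ends below both its own
first-rise value and the eps = 1 index.

## What the fixtures do and do not show

The fixtures emulate the study conditions (protocol rates, event
schedules, drive levels, baseline concentrations, pump law) with this
package's own membrane kinetics.  Quantities that depend only on the
pump/concentration layer — drive averages, saturation, stoichiometry,
the one-third redundancy and ~1/3 efficiency loss, the equivalence
identities — are parameterization-independent.  Quantities tied to the
unpublished base-model kinetics (absolute rheobase, tuned conductances,
exact spike shapes, the precise chirp index at which window spikes first
appear) are implementation-relative here and are tested as qualitative
signatures, not numeric oracles.

## Known limitations

* Single compartment; no electrocyte morphology or axial spread.
* No calcium or chloride fluxes; the receptor current carries Na and K
  only.
* The potassium buffer is instantaneous and infinite; no transient buffer
  kinetics, no osmotic volume changes.
* No temperature or ATP dependence of the pump; no mechanistic
  Albers–Post cycle.
* The co-expression rule is linear in `I_pump0`; for these kinetics it
  pins rheobase to <5% only up to ~2.5 uA of baseline pump current
  (the residual grows to tens of percent of the — still tiny — rheobase
  at 4–8 uA, versus an uncompensated shift equal to the full pump
  current).
* Fixed-step forward Euler: first-order accurate; halving dt is verified
  to roughly halve the voltage error, but no adaptive error control.
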