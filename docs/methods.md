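# Methods

## Model

The mossy fiber is represented as an unbranched chain of cylindrical
sections — soma, then eleven axonal cylinders with ten *en passant* boutons
interleaved — each split into segments at 1 μm⁻¹ (defaults: 10 + 11×100 +
10×4 = 1150 segments). Geometry that the source morphology leaves open is
fixed by convention: the soma and each bouton are cylinders with length
equal to diameter (10 μm and 4 μm), so the lateral area of the cylinder
approximates the surface of the equivalent sphere. The boutons are
in-line, so the chain ends with an axonal cylinder and the "distal" zone
(10th bouton) really does have axon on both sides.

Passive parameters are uniform: C_m = 1 μF cm⁻², R_m = 10 000 Ω cm²
(leak conductance 0.1 mS cm⁻²), R_i = 110 Ω cm. Na⁺ conductance is
50 mS cm⁻² on axons and boutons and 10 mS cm⁻² on the soma; K⁺ is
36 mS cm⁻² everywhere; E_Na = +50 mV, E_K = −85 mV. The leak reversal e_l
is set to the −80 mV resting potential everywhere. Because voltage-gated
channels carry some current at −80 mV, the true resting potential sits a
couple of millivolts off e_l (≈ −82.9 mV under the generic kinetics); this
offset is accepted, and `balance_leak_reversal` is provided for analyses
that need an exact equilibrium. Local depolarization — the stand-in for
extracellular K⁺ accumulation around a stretch of axon — is applied by
setting e_l of a named zone (distal / middle / proximal: a bouton plus the
two flanking axonal cylinders; uniform: boutons 2–10 with axons 2–11) to a
target value. Extracellular K⁺ itself is not modelled.

## Numerical integration

One step of size dt (default 0.1 ms; 0.01 ms for dV/dt-sensitive
analyses):

1. every gate advances by the exact exponential update
   x ← x∞ + (x − x∞)·exp(−dt/τ), with x∞ and τ evaluated at the pre-step
   voltage (staggered scheme);
2. the voltage advances by one backward-Euler step: with gates frozen the
   ionic current is linear in V, so the update is a single symmetric
   tridiagonal solve (LAPACK `dgtsv`). Axial coupling between adjacent
   segments i, j is 1/(ρᵢ/2 + ρⱼ/2) with ρ = R_i·L/(πd²/4), which handles
   the axon↔bouton diameter steps consistently. Chain ends are sealed.

Backward Euler is unconditionally stable — no protocol diverges at the
coarse 0.1 ms step — and first-order accurate; the validation suite checks
the expected error halving under dt halving, agreement with the analytic
RC charging curve within 1 % at dt = 0.01 ms, agreement of the steady-state
sealed-end cable profile with cosh((L−x)/λ)/cosh(L/λ) within 0.5 %, and an
AP peak-time shift < 0.2 ms between dt = 0.1 ms and a dt = 0.001 ms
reference (measured: 0.04 ms). Divergence (non-finite or |V| > 1000 mV)
aborts with the offending time and segment rather than propagating NaNs.

For speed, the solver samples each gate's x∞ and exp(−dt/τ) once on a
0.05 mV grid over [−150, 100] mV and linearly interpolates during
stepping (interpolation error ~10⁻⁶ on x∞, far below the oracle
tolerances); `gate_mode="exact"` evaluates the closed forms each step and
is used in the test that verifies machine-precision current balance at an
equilibrated rest. Output is recorded at every integration step, so
derivative analyses operate on the native grid. Runs are bit-deterministic
for identical configurations.

Equilibration before the first pulse (t_pre) is 200 ms; the post-stimulus
observation window (t_post) defaults to 2000 ms. Both are package choices
(the settling procedure and total simulated time of the original study are
not published); tests and drivers shorten them where only the stimulated
phase matters.

## Channel kinetics

Gates are declared in configuration (YAML), either as forward/backward
rates α(V), β(V) from closed-form families (exponential, sigmoid, linoid —
the linoid uses its removable-singularity limit A·k at V = V₀), as direct
x∞(V)/τ(V) curves, or as tabulated curves with linear interpolation.
No temperature scaling is applied; rates are used as given.

The shipped `generic` profile is an engine-testing kinetics set: the
classic squid-axon Na⁺ (m³h) and delayed-rectifier K⁺ (n⁴)
parameterizations shifted by −15 mV so that the gates sit at their usual
resting operating point at −80 mV, plus a Kv1.4-style slow inactivation
gate h on the K⁺ channel (x∞ midpoint −70 mV, slope 6 mV, τ ≈ 20 ms when
depolarized and ≈ 440 ms at rest). Those inactivation time scales bracket
the inter-spike intervals of 20–100 Hz trains, so inactivation accumulates
across a train — the mechanism behind use-dependent spike broadening and,
with local depolarization, the ectopic afterdischarge. K⁺-channel variants
are constructed from the profile: pure inactivating, pure non-inactivating
(the same n⁴ without the h gate), or a mixture splitting the total
36 mS cm⁻² exactly (e.g. 90 % / 10 %).

The `paper` profile is a deliberately empty slot: the rate constants of
the mossy-fiber-bouton channel set (`hhmfb.mod`) and the Kv1.4 inactivating
K⁺ model (`KIn.mod`) are published in ModelDB (accession 128079; complete
model deposit 2018003) but not in print, and they are not guessed here.
Transcribing them into `profiles/paper.yaml` enables quantitative
reproduction of the published trace metrics without touching code; until
then every run with `--kinetics paper` fails fast with a pointer to the
slot. Consequences of using the generic profile instead are quantitative,
not structural: the qualitative contrasts reproduce (no afterdischarge at
uniform −80 mV rest; afterdischarge with the distal zone at −70 mV;
abolished with non-inactivating K⁺; restored in the 90/10 mixture only at
−60 mV), but thresholds, frequencies and half-durations differ from the
published values, and the generic squid n-gate's substantial resting
activation makes the *active* steady-state zone potentials sit closer to
E_K than the published ones (the passive zone potentials, a pure
morphology/leak property, come out within ~1 mV of them). The generic
Na⁺ kinetics also conduct slowly along the 0.2 μm axon (~10 ms over the
full length), so during 50 Hz trains the soma→bouton delay is comparable
to the inter-pulse interval; the propagation-order driver therefore
estimates lags by cross-correlation (train phase: first pulse cycle only,
to avoid period aliasing) rather than nearest-peak matching.

## Protocols

Each published panel is a named, pure-data preset: pulse amplitude 0.2 nA,
width 2 ms, trains of 50×50 Hz, 60×20 Hz, 50×100 Hz (and the sub-threshold
40×50, 50×20, 40×100 controls), zone and target (−70 / −60 / −75 mV),
channel variant, optional g_Na override (50→60 mS cm⁻²), and dt
(0.01 ms for the derivative panels). Injection is at the centre segment of
the soma; recording sites default to the centre of the soma and the 10th
bouton (plus the 6th for the bi-directional-propagation presets).

## Trace analysis conventions

The published figures come with no detector definitions, so the package
fixes them once:

* **Spike detection** — upward crossings of −20 mV separated by ≥ 2 ms;
  the threshold is above every depolarized baseline used (≥ −60 mV) and
  below all spike peaks. Peak = maximum before the next downward crossing;
  baseline = minimum V in the 5 ms before the crossing (so broadened
  late-train spikes riding on depolarization are measured consistently).
* **Half-duration** — width at baseline + ½(peak − baseline), linear
  interpolation on both flanks; undefined (NaN + flag) if the falling
  flank never returns before the next event. Invariant under affine
  transforms of V.
* **Afterdischarge** — present if ≥ 3 spikes occur later than 50 ms after
  the end of the last pulse (the guard excludes a single rebound spike);
  frequency = (N−1)/(t_last − t_first). The estimator behind the published
  frequencies is unstated; this one is the natural event-span rate.
* **dV/dt / IS-SD** — central differences; ≥ 2 prominent rising-phase
  maxima of dV/dt flag the IS-SD inflection of an antidromically invading
  somatic spike (intended for dt = 0.01 ms traces).
* **Latency order** — per-spike grouping across sites by nearest peak time
  within ±5 ms, deterministic earlier-event tie-break, unmatched events
  reported as propagation failures.

Metrics quoted to 0.01 ms precision can shift by about one sample under
alternative baseline/estimator conventions.

## Synthetic fixtures

All randomness lives in the fixture generator; the simulator is
deterministic. Fixtures are a flat baseline plus analytic spike templates
(triangular, Gaussian, bi-exponential) at prescribed times with optional
seeded Gaussian noise; the per-spike truth (time, peak, half-width) comes
from the template's closed form (the bi-exponential FWHM by root-finding
on the analytic expression), never from measuring the trace. They exercise
every analysis operation (recovery within one sample at zero noise; zero
detection errors at 1 mV noise on 100 mV spikes across 100 seeds) and
provide the passive analytic references (RC step, cable attenuation) for
the solver oracles. What fixtures do **not** emulate: real AP waveform
biophysics, baseline drift, or correlated noise — passing fixture tests
validates the analysis chain's arithmetic, not its robustness to
electrophysiological artefacts.

## Problem sizes

The validation suite and the acceptance script run the full 1150-segment
cell for the 50-pulse trains (≈ 13 000–32 000 steps at dt = 0.1 ms), a
single-AP convergence check at dt = 0.001 ms over an 80 ms window, a
401-segment passive cable to steady state, and 100 noisy fixtures; the
fine-dt (0.01 ms) derivative analyses in `analysis/03` default to a 500 ms
post-stimulus window.

## Known limitations

* No branched morphology, dendrites, synapses, extracellular space, or
  explicit K⁺ dynamics (depolarization is a leak-reversal shift only).
* Backward Euler's numerical damping slightly broadens fast spikes at
  dt = 0.1 ms (hence the convergence oracle); Crank–Nicolson is not
  offered because its oscillatory artefacts at coarse dt are worse for
  this use.
* The generic kinetics profile is for engine validation and qualitative
  mechanism studies; quantitative comparison to the published numbers
  requires transcribing the ModelDB rate constants into the `paper`
  profile slot.
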