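# mossyfiber

Compartmental simulation of hippocampal mossy-fiber axons: how a small,
local depolarization of the axon — standing in for activity-dependent
extracellular K⁺ accumulation — combines with repetitive stimulation to
trigger **ectopic, antidromically propagating afterdischarge**, and why the
**inactivating property of axonal K⁺ channels (Kv1.4-like)** is required
for it.

The package is for computational neuroscientists who want a small,
dependency-light, fully testable re-implementation of this experiment
family: a deterministic cable-equation solver, declarative
Hodgkin–Huxley channel kinetics, the complete table of stimulation
protocols, and the trace analyses (spike detection, half-duration,
afterdischarge statistics, latency ordering, dV/dt features) used to read
the simulations out.

## The model

The granule-cell axon is an unbranched chain

```
soma — axon₁ — bouton₁ — axon₂ — … — bouton₁₀ — axon₁₁
```

with a 10 μm soma, eleven 100 μm × 0.2 μm axonal cylinders and ten 4 μm
*en passant* boutons, discretized at 1 segment/μm (1150 segments).
Passive membrane: C_m = 1 μF cm⁻², R_m = 10 000 Ω cm², R_i = 110 Ω cm,
leak reversal e_l = −80 mV. Active conductances: Na⁺ 50 mS cm⁻² on
axons/boutons and 10 mS cm⁻² on the soma (E_Na = +50 mV), K⁺ 36 mS cm⁻²
everywhere (E_K = −85 mV). Each segment obeys the cable equation

```
C_m dV/dt = −g_L(V−e_l) − g_Na m³h(V−E_Na) − g_K n⁴(h_K)(V−E_K) + axial + I_inj
```

integrated by backward Euler with staggered exact-exponential gate updates
(tridiagonal solve per step; unconditionally stable at the standard
dt = 0.1 ms). Local depolarization is modelled by shifting e_l inside a
named zone (e.g. the 10th bouton and the axons on both sides); spikes are
evoked by somatic current pulses (2 ms, 0.2 nA) in trains such as
50 × 50 Hz.

Channel kinetics are **data, not code**: gates are declared in YAML
(α/β or x∞/τ closed forms, or tabulated curves). The shipped `generic`
profile is a squid-type HH Na⁺/K⁺ set shifted to a −80 mV rest plus a
Kv1.4-style slow inactivation gate on the K⁺ channel. A `paper` profile
slot is reserved for rate constants transcribed from the ModelDB deposits
of the original mossy-fiber bouton model (accession 128079: `hhmfb.mod`,
`KIn.mod`; model deposit 2018003) — see
`src/mossyfiber/profiles/paper.yaml`; quantitative reproduction of the
published trace metrics requires that transcription, and the constants are
deliberately not guessed here.

## Worked example

```python
import mossyfiber as mf

model = mf.build_mossy_fiber()              # 22 sections, 1150 segments
prot  = mf.preset("fig1b")                  # 50 × 50 Hz, distal zone at −70 mV
traces = mf.run(model, prot)                # deterministic TraceSet
report = mf.analyze_traceset(traces)
print(report["afterdischarge"])
```

With the shipped `generic` kinetics this prints

```
{'present': True, 'n_spikes': 4, 'first_spike_ms': 1250.2,
 'last_spike_ms': 1350.1, 'frequency_hz': 30.03}
```

i.e. after the last of the 50 pulses (train ends at 1182 ms) the distal
axon keeps firing: 4 spikes at ≈ 30 Hz recorded at the 10th bouton. The
same protocol **without** the depolarized zone (`preset("fig1a")`) produces
no post-stimulus spikes, and replacing the K⁺ channel with its
non-inactivating variant (`preset("fig3c")`) abolishes the afterdischarge
again — the cumulative-inactivation mechanism at the heart of the study.
Use-dependent broadening is visible in the same run: the somatic
half-duration grows from 1.34 ms (first spike of the train) by a factor
1.10 with inactivating K⁺ channels, but only 1.03 with non-inactivating
ones.

The same pipeline is scriptable from the shell:

```
mossyfiber list-presets
mossyfiber run fig1b --out out/          # traces (CSV+HDF5), analysis JSON, manifest
mossyfiber analyze out/fig1b_traces.h5
mossyfiber sweep grid.yaml --base fig1b  # afterdischarge over a parameter grid
```

The numbered drivers under `analysis/` (engine validation, induction
matrix, propagation order, channel variants, depolarization-site survey)
run the full experiment set and write their tables to `results/`.

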