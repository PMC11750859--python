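# Generic engine-testing kinetics profile.
#
# Na+ (m^3 h) and delayed-rectifier K+ (n^4) are the classic squid-axon
# Hodgkin-Huxley parameterizations, uniformly shifted by -15 mV so the gates
# sit at their usual resting operating point at a -80 mV resting potential.
# The inactivating K+ channel adds a Kv1.4-style slow inactivation gate h:
# it inactivates with tau ~= 20 ms at spike potentials and recovers with
# tau ~= 440 ms at rest, so inactivation accumulates across a 20-100 Hz
# train (cumulative inactivation -> use-dependent spike broadening).
#
# Rates in 1/ms, voltages in mV, tau in ms.  Conductance densities and
# reversals are supplied by the morphology / variant layer, not here.
name: generic
channels:
  na:
    reversal_mv: 50.0
    density_key: na
    gates:
      m:
        exponent: 3
        alpha: {family: linoid, A: 0.1, V0: -55.0, k: 10.0}
        beta: {family: exponential, A: 4.0, V0: -80.0, k: -18.0}
      h:
        exponent: 1
        alpha: {family: exponential, A: 0.07, V0: -80.0, k: -20.0}
        beta: {family: sigmoid, A: 1.0, V0: -50.0, k: 10.0}
  k_inactivating:
    reversal_mv: -85.0
    density_key: k
    gates:
      n:
        exponent: 4
        alpha: {family: linoid, A: 0.01, V0: -70.0, k: 10.0}
        beta: {family: exponential, A: 0.125, V0: -80.0, k: -80.0}
      h:
        exponent: 1
        xinf: {family: sigmoid, V0: -70.0, k: -6.0}
        tau: {family: const_plus_sigmoid, base: 20.0, amp: 420.0, V0: -60.0, k: 10.0}
  k_noninactivating:
    reversal_mv: -85.0
    density_key: k
    gates:
      n:
        exponent: 4
        alpha: {family: linoid, A: 0.01, V0: -70.0, k: 10.0}
        beta: {family: exponential, A: 0.125, V0: -80.0, k: -80.0}
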