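# wcplast

Noise-modulated multistable synaptic plasticity in networks of driven
Wilson–Cowan units.

## The problem

Periodic stimulation changes synaptic strength in a way that depends on the
stimulation frequency, the resonance of the stimulated circuit, and — the
focus here — the intensity of background noise. `wcplast` implements a
rate-based model of this interaction for computational neuroscientists who
want to simulate and analyse it: interacting Wilson–Cowan units coupled by an
activity-dependent excitatory synapse, with homeostatic scaling keeping mean
rates at a set point, a common sinusoidal drive, and per-unit Gaussian white
noise of controlled intensity. Its headline phenomenon is that the plastic
weight between driven units does not settle to a single value: over a band of
drive frequencies and at low noise it lands in one of three discrete states
("low", "mid", "high"), and raising the noise intensity first biases and then
abolishes this tri-stability.

## The model

Each unit holds an excitatory and an inhibitory population with fractional
firing rates `E_i, I_i ∈ [0, 1]`:

    τ_E dE_i/dt = −E_i + S(W_EE·E_i − W_EI·I_i + E_0 + Σ_j w_ij·E_j
                           + f(t) + z·ξ_i(t) − S_E,i)
    τ_I dI_i/dt = −I_i + S(W_IE·E_i + W_II·I_i + I_0 + Σ_j u_ij·E_j − S_I,i)

with logistic gain `S(x) = 1/(1+exp(−m(x−n)))`, shared sinusoidal drive
`f(t)` (amplitude 0.5, onset jittered within 1 s), and independent unit-
variance white noise `ξ_i` scaled by `z`. Excitatory inter-unit weights are
plastic with a thresholded Hebbian rule,

    τ_h dw_ij/dt = −w_ij + γ·E_i·E_j·Θ(E_i·E_j − h),

so a synapse strengthens only while the instantaneous rate product exceeds
the coincidence threshold `h` and decays exponentially otherwise. Slow
variables `S_E, S_I` subtract from each population's input in proportion to
the integrated deviation of its rate from the set point (`E_∞ = I_∞ = 0.2`),
preventing runaway excitation and pinning long-run mean rates.

Integration is explicit fixed-step Euler–Maruyama (dt = 1 ms), with the
white-noise sample entering the excitatory sigmoid argument as `z·ξ/√dt`
(see `docs/methods.md` for the convention and its consequences). The
analysis layer provides band-passed instantaneous phases, the complex
phase-locking value, the Kuramoto order parameter, sliding-window
coarse-grained weights and truncated correlations, state classification,
and attractor counting by gap clustering.

## Worked example

`examples/tristability.py` runs 30 independent trials at the multistable
working point (resonance 12 Hz, drive 48 Hz, z = 0.0015) and clusters the
trial-final weights:

```
trials: 30   clusters found: 3
  center 0.0097  (9 trials)
  center 0.0263  (9 trials)
  center 0.0607  (12 trials)
state counts: {'low': 6, 'mid': 9, 'high': 9, 'unclassified': 6}
```

The three cluster centers are the discrete attractors of the synaptic
weight; which one a trial reaches depends only on its noise realisation.
`examples/phase_states.py` shows what the states mean dynamically — in a
single long run the units are anti-phase while the weight is "low"
(circular-mean Δφ ≈ ±π), in quadrature in "mid" (≈ ±π/2), in phase in
"high" (≈ 0), and phase-locked (PLV ≈ 0.99) inside every state.
`examples/noise_collapse.py` scans z and shows the collapse to a single
state near the mid-level weight, and `examples/ten_unit_network.py` shows
coherent high-weight subnetworks forming and reorganising in a fully
connected ten-unit network.

A thin CLI wraps the same machinery (`wcplast simulate|sweep|noise-curve|
state-analysis|ten-unit`); every run writes a JSON manifest from which its
numbers can be regenerated exactly.

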