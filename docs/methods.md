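# Methods

## Model

A network of N Wilson–Cowan units, each an excitatory/inhibitory population
pair with logistic gain `S(x) = 1/(1+e^{−m(x−n)})`. Within a unit the
excitatory population excites the inhibitory one (gain `W_IE`) and the
inhibitory population feeds back onto the excitatory sigmoid argument with
inhibitory sign (`−W_EI·I`); with the default gains (`W_EE=23, W_EI=15,
W_IE=35, W_II=0, m=1, n=4, E_0=0.5, I_0=−5`) the unit is a stable nonlinear
oscillator. Note the sign: the inhibitory coupling must enter negatively —
with `+W_EI·I` the unit saturates at `E = 1` and produces no dynamics at
all; the parameter value is the magnitude of an inhibitory gain.

Between units, excitatory→excitatory weights `w_ij` (row receives from
column) are plastic; excitatory→inhibitory weights `u_ij = 0.1` are fixed.
The plasticity rule

    τ_h dw/dt = −w + γ E_i E_j Θ(E_i E_j − h),   τ_h = 2.5 s, γ = 1, h = 0.04

is Hebbian with a coincidence threshold: the weight grows toward
`γ·E_i·E_j` only while the instantaneous product exceeds `h` (both
populations above ~50% more often than not), and decays with time constant
`τ_h` otherwise. `Θ(0) = 0` exactly, so a product sitting exactly at
threshold decays. Homeostatic variables integrate rate deviations from the
set points (`τ_SE dS_E/dt = E − E_∞` and analogously for I, with
`E_∞ = I_∞ = 0.2`, `τ_SE = 1 s`, `τ_SI = 2 s`) and are subtracted inside
the corresponding sigmoid argument. This is a slow negative feedback: any
run much longer than `τ_SE` has window-averaged `E ≈ 0.2` regardless of
drive and noise, which the test suite asserts to ±0.02.

Two topologies are built in: the two-unit unidirectional circuit (unit 1
receives `w_12`, `u_12` from unit 2; nothing flows back) and the all-to-all
network with every off-diagonal weight initialised to `w_init = 0.15` and
`u = 0.1`. Self-connections do not exist (zero diagonals, enforced).

## Drive, noise, integration

All units receive the same sinusoid `f(t) = A sin(2πf_d(t−t_0))`, zero
before its onset `t_0`, which is drawn uniformly in the first second of the
run to wash out phase interactions between onset and the endogenous
oscillation. "Height 0.5" is read as peak amplitude `A = 0.5` (not
peak-to-peak); both the amplitude and the jitter window are configurable.
The drive and the noise enter the excitatory argument only.

Integration is explicit Euler–Maruyama with fixed `dt = 1 ms`. Each unit
draws one fresh `N(0,1)` sample per step. The default convention
(`noise_mode="ito"`) injects `z·ξ/√dt` into the sigmoid argument — the
standard discrete reading of a white-noise process with intensity z. The
alternative `noise_mode="per_step"` injects `z·ξ` without the `√dt`
factor. The conventions differ by a factor `1/√dt ≈ 31.6` in effective
per-step noise, and the choice is consequential: under the per-step
convention the tri-stable weight structure survives to `z ≈ 0.05` and a
single run at `z = 0.0015` never switches states, whereas under the Itô
convention the same run switches spontaneously between all three states
(as the single-run analyses here show) and tri-stability collapses at
`z ≈ 0.002–0.003`. All defaults, tests and the acceptance script use the
Itô convention. Any reported critical-noise value is therefore tied to
this convention; under a different normalisation of the noise stream the
z axis rescales globally (the relative structure — tri-stability at low z,
a collapse threshold, abolition at high z — is unaffected).

Initial conditions for `E, I, S_E, S_I` are all zeros; the discarded
transient (`n_discard`, default 1e5 steps) absorbs this choice, which is
configurable only through the code because nothing downstream was found to
depend on it. A non-finite population value aborts the run with the step
index rather than clipping, since divergence always indicates a mis-set
parameter. Weights are recorded every 100 steps by default (full rate by
setting `record_weights_every=1`); activity at full rate.

The integrator hot loop is a numba kernel; a pure-numpy single-step
reference (`wcplast.model.step`) implements the identical update order and
the test suite checks the two paths agree to 1e-12 over noisy runs and
that fixed seeds give bit-identical trajectories. Convergence is first
order in dt, verified by Richardson comparison against a fine-step run.

## Resonance

The time-constant pairs exposed by `time_constants_for_resonance` —
4 Hz → (0.017, 0.013), 8 Hz → (0.024, 0.014), 12 Hz → (0.011, 0.007),
23 Hz → (0.014, 0.006) — define the model's standard operating points and
are used by all experiments. `estimate_resonance` measures a pair's
drive-response resonance directly: it drives a single uncoupled unit with a
weak sinusoid over a frequency grid and returns the frequency of maximal
steady-state response at the drive frequency. Measured this way the four
tabulated pairs peak near 9, 11, 19 and 28 Hz respectively — higher than
their nominal labels, though in the same order. The labels should be read
as names for the operating points, not as measured resonances of this
implementation; phenomena tied to "multiples of the resonance" (such as
the onset of multistability near twice the resonance) occur at the
corresponding multiples of the measured peak, i.e. at ~3–4× the nominal
label.

## Analysis

Phases: 4th-order Butterworth band-pass at `f_r ± 5 Hz`, applied
forward-backward (zero phase), then the analytic-signal angle. Three time
constants of the filter bandwidth (300 samples at the default band) are
trimmed at each end as edge margin. Phase differences are wrapped to
(−π, π] before histogramming; histogram bins are π/50 wide.

Synchrony: the complex phase-locking value (mean unit phasor of the phase
difference; modulus PLV, argument Φ) between unit pairs, and the Kuramoto
order parameter `r(t)` across the network.

Coarse-graining: sliding windows of 10,000 steps with stride 1,000 (the
stride is a package choice; results are insensitive to it). Per window:
the mean weight `w̄`, the truncated correlation
`γC_Δ = γ·mean(E_i E_j Θ(E_i E_j − h))`, PLV and Φ. Averaging the
plasticity ODE over a window long against τ_h and short against the
correlation's own drift gives the quasi-steady prediction `w̄ = γC_Δ`; in
simulation the two windowed series agree to a median relative difference
of ~1–5%, asserted <10% in the tests.

States: `w̄ < 0.01` is "low", `0.025 < w̄ < 0.0275` "mid", `w̄ > 0.06`
"high"; values in the gaps are "unclassified" and excluded from per-state
statistics (windows straddling a state switch land there). Trial-final
weights are clustered by sorting and splitting at gaps > 0.0075 (half the
distance between the low cutoff and the mid band); clusters agree with a
brute-force pairwise-linkage oracle by construction and by test.

Sweeps: the multistable band of a drive-frequency sweep is the longest
contiguous run of grid points whose trial-final weights form ≥3 clusters;
the collapse frequency is the first grid point after that run. Isolated
single-point blips beyond the band (straggler trials caught mid-transition)
are thereby excluded; taking instead the highest ≥3-cluster point inflates
the collapse estimate to the grid edge at realistic trial counts. The
critical noise of a z scan is the smallest grid z whose cluster count
drops below 3, reported with the grid spacing as its resolution.

## Study protocols and problem sizes

Two-unit ensembles run 5×10⁵ steps (500 s) per trial; ensemble sizes of
30–50 trials per grid cell are the package defaults for sweeps (100-trial
grids remain a flag away). The single-run state analysis uses 10⁶ steps
discarding 3×10⁵; the ten-unit study 2×10⁶ steps discarding 1×10⁵. Trial k
of a cell is seeded `base_seed + k`, so every table is reproducible from
its manifest.

The ten-unit study defaults to z = 0.003. Under the Itô noise convention
this is the intermediate regime in which the network switches spontaneously
between weight states and transient high-weight subnetworks form and
reorganise; at z ≲ 0.002 the network freezes into one global high-weight
component and at z ≳ 0.005 high weights never form. Within-component
coherence is reported both on raw traces and on the band-passed traces;
raw 1-kHz traces carry the per-step noise jitter and cap at Pearson
r ≈ 0.85–0.95 even for perfectly phase-locked units, while band-passed
traces of a tight subnetwork correlate above 0.95.

## What the simulations do and do not show

All data in this package are generated by the model itself; there is no
empirical recording anywhere in the pipeline. The model emulates mean-field
population rates with instantaneous transmission, a single shared drive and
statistically independent noise per unit. It does not emulate spike timing,
conduction delays, heterogeneous units, or structured (correlated) noise —
so passing tests demonstrate the internal consistency of the rate-model
phenomenology (tri-stability, noise-controlled state probabilities,
state-dependent phase locking, subnetwork reorganisation), not predictions
about any particular biological preparation.

## Known limitations

- The noise z axis is convention-bound (see above); quantitative z
  thresholds transfer across implementations only up to the global scale.
- The fixed-step explicit integrator is first-order; dt = 1 ms is part of
  the model definition here, and the per-step noise convention makes the
  noise term dt-dependent by design.
- Gap clustering of trial finals is sensitive to trials caught
  mid-transition at the protocol horizon; at noise levels with frequent
  spontaneous switching the cluster count of a finite ensemble fluctuates
  even when all three states are clearly populated.
- `estimate_resonance` characterises a deterministic single unit; it is a
  measurement procedure, not a calibration that re-tunes the tabulated
  operating points.
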