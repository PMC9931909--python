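"""State-dependent synchrony in a single long run.

One long two-unit run at the multistable working point visits all three
weight states in succession.  The script windows the run, classifies each
window by its coarse-grained weight, and prints per-state statistics: the
phase-locking value (PLV ~ 1 inside any stable state), the circular mean of
the inter-unit phase difference (anti-phase in "low", quadrature in "mid",
in-phase in "high"), and the agreement between the windowed weight and its
quasi-steady prediction gamma * C_Delta.
"""

import numpy as np

from wcplast import (
    ModelParams, RunSettings, WindowSpec,
    bandpass_phase, classify_windows, coarse_weight, cplv,
    truncated_correlation, window_starts,
)
from wcplast.model import simulate

settings = RunSettings(
    n_steps=1_000_000, n_discard=300_000, f_r=12.0, f_d=48.0, z=0.0015,
    record_activity_every=1, record_weights_every=1,
)
traj = simulate(settings, ModelParams.for_resonance(12), seed=1)
k = traj.n_discard_samples
E1, E2 = traj.E_series[k:, 0], traj.E_series[k:, 1]
w = traj.W_series[k:, 0, 1]

win = WindowSpec(window_len=10_000, stride=1_000)
w_bar = coarse_weight(w, win)
gC = truncated_correlation(E1, E2, traj.params, win)
labels = classify_windows(w_bar)

ph1 = bandpass_phase(E1, 12.0, settings.dt)
ph2 = bandpass_phase(E2, 12.0, settings.dt)
starts = window_starts(E1.size, win)
dphi = np.angle(np.exp(1j * (ph1.phases - ph2.phases)))

rel = np.abs(w_bar - gC) / np.maximum(w_bar, 1e-12)
print(f"windows: {len(starts)}; median |w_bar - gamma*C| / w_bar = {np.median(rel):.3f}")
for state in ("low", "mid", "high"):
    idx = np.where(labels == state)[0]
    if idx.size == 0:
        print(f"{state:>5}: no windows")
        continue
    plvs = [cplv(ph1.phases[s:s + win.window_len],
                 ph2.phases[s:s + win.window_len])[0] for s in starts[idx]]
    pooled = np.concatenate([dphi[s:s + win.window_len] for s in starts[idx]])
    circ_mean = np.angle(np.mean(np.exp(1j * pooled)))
    print(f"{state:>5}: {idx.size:4d} windows  median PLV {np.median(plvs):.3f}  "
          f"circular-mean dphi {circ_mean:+.2f} rad")
# Typical output: low -> dphi ~ +/-pi (anti-phase), mid -> ~ +/-pi/2,
# high -> ~ 0, all with PLV close to 1.
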