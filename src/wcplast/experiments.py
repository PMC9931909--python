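"""Ensemble experiments: frequency sweeps, noise-response curves, ten-unit runs.

Every experiment is a deterministic function of its spec and base seed:
trial k of a cell uses seed ``base_seed + k``, so any reported number can be
regenerated from the logged metadata alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import (
    AttractorClusters,
    WindowSpec,
    bandpass_phase,
    classify_state,
    count_attractors,
    kuramoto_order,
    state_probabilities,
)
from .model import ModelParams, RunSettings, simulate
from .params import time_constants_for_resonance

__all__ = [
    "SweepSpec",
    "TrialEnsemble",
    "SubnetworkPartition",
    "TenUnitResult",
    "run_ensemble",
    "sweep_fd",
    "multistable_band",
    "noise_response",
    "high_weight_components",
    "ten_unit_study",
]


@dataclass
class SweepSpec:
    """Grid specification for ensemble sweeps over (f_d, z).

    ``settings`` is the per-trial template; its ``f_d`` and ``z`` are
    overridden cell by cell.  Trial k of any cell uses ``base_seed + k``.
    """

    f_r: float = 12.0
    f_d_grid: tuple[float, ...] = (48.0,)
    z_grid: tuple[float, ...] = (0.0015,)
    n_trials: int = 100
    base_seed: int = 0
    settings: RunSettings = field(default_factory=RunSettings)

    def __post_init__(self) -> None:
        if not self.f_d_grid or not self.z_grid:
            raise ValueError("f_d_grid and z_grid must be non-empty")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def params(self) -> ModelParams:
        return ModelParams.for_resonance(self.f_r)


@dataclass
class TrialEnsemble:
    """Final weights and labels for the trials of one (f_r, f_d, z) cell."""

    f_r: float
    f_d: float
    z: float
    final_weights: np.ndarray
    labels: np.ndarray
    seeds: np.ndarray
    failed_seeds: np.ndarray

    @property
    def clusters(self) -> AttractorClusters:
        return count_attractors(self.final_weights)

    def probabilities(self) -> dict[str, float]:
        return state_probabilities(self.labels)


def run_ensemble(spec: SweepSpec, f_d: float, z: float) -> TrialEnsemble:
    """Run ``n_trials`` seeded trials of one cell, collecting final weights.

    The final weight of a two-unit trial is w_12 at the last recorded step;
    for larger topologies the mean off-diagonal plastic weight is used.  A
    trial whose state diverges is skipped and its seed reported in
    ``failed_seeds``; the rest of the cell proceeds.
    """
    params = spec.params()
    settings = replace(
        spec.settings, f_d=float(f_d), z=float(z), f_r=spec.f_r,
        record_activity_every=max(spec.settings.record_activity_every, 1000),
    )
    finals, seeds, failed = [], [], []
    for k in range(spec.n_trials):
        seed = spec.base_seed + k
        try:
            traj = simulate(settings, params, seed=seed)
        except RuntimeError:
            failed.append(seed)
            continue
        Wf = traj.final_weights
        if settings.topology == "two_unit_unidirectional":
            finals.append(Wf[0, 1])
        else:
            off = ~np.eye(Wf.shape[0], dtype=bool)
            finals.append(Wf[off].mean())
        seeds.append(seed)
    finals = np.asarray(finals)
    return TrialEnsemble(
        f_r=spec.f_r, f_d=float(f_d), z=float(z),
        final_weights=finals,
        labels=np.array([classify_state(v) for v in finals]),
        seeds=np.asarray(seeds, dtype=int),
        failed_seeds=np.asarray(failed, dtype=int),
    )


def multistable_band(
    f_d_values: np.ndarray, n_clusters: np.ndarray, threshold: int = 3
) -> tuple[float, float] | None:
    """Longest contiguous run of grid points with >= ``threshold`` clusters.

    Returns ``(onset_f_d, collapse_f_d)`` where onset is the first grid point
    of the run and collapse the first grid point after it (``inf`` when the
    run reaches the grid end), or ``None`` if no point reaches the threshold.
    Isolated above-threshold blips outside the main band -- straggler trials
    caught mid-transition -- do not extend it.
    """
    f_d_values = np.asarray(f_d_values, dtype=float)
    n_clusters = np.asarray(n_clusters)
    above = n_clusters >= threshold
    if not above.any():
        return None
    best_start, best_len = 0, 0
    i = 0
    while i < above.size:
        if above[i]:
            j = i
            while j < above.size and above[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    end = best_start + best_len
    collapse = f_d_values[end] if end < f_d_values.size else np.inf
    return float(f_d_values[best_start]), float(collapse)


def sweep_fd(spec: SweepSpec) -> tuple[pd.DataFrame, dict]:
    """Full (f_d, z) grid of ensembles.

    Returns a table with one row per cell (cluster count, cluster centers,
    state probabilities) and a summary dict holding, per z, the detected
    multistable band (see :func:`multistable_band`) plus the bistable cells.
    """
    rows = []
    ensembles: dict[tuple[float, float], TrialEnsemble] = {}
    for z in spec.z_grid:
        for f_d in spec.f_d_grid:
            ens = run_ensemble(spec, f_d, z)
            ensembles[(f_d, z)] = ens
            cl = ens.clusters if len(ens.final_weights) >= 10 else None
            probs = (
                ens.probabilities()
                if set(ens.labels) & {"low", "mid", "high"}
                else {"low": np.nan, "mid": np.nan, "high": np.nan, "n_unclassified": len(ens.labels)}
            )
            rows.append({
                "f_r": spec.f_r, "f_d": f_d, "z": z,
                "n_trials": len(ens.final_weights),
                "n_clusters": cl.n_clusters if cl is not None else np.nan,
                "cluster_centers": cl.centers.round(5).tolist() if cl is not None else [],
                "p_low": probs["low"], "p_mid": probs["mid"], "p_high": probs["high"],
                "n_unclassified": probs["n_unclassified"],
                "w_mean": ens.final_weights.mean(),
            })
    table = pd.DataFrame(rows)
    summary: dict = {"bands": {}, "bistable_cells": {}}
    for z in spec.z_grid:
        sub = table[table.z == z].sort_values("f_d")
        band = multistable_band(sub.f_d.to_numpy(), sub.n_clusters.to_numpy())
        summary["bands"][z] = band
        summary["bistable_cells"][z] = sub.loc[sub.n_clusters == 2, "f_d"].tolist()
    summary["ensembles"] = ensembles
    return table, summary


def noise_response(
    spec: SweepSpec, f_d: float, w_bins: np.ndarray | None = None
) -> tuple[pd.DataFrame, dict]:
    """Noise-response curve at fixed drive frequency.

    For each z on the grid: the normalised histogram P(w|z) of trial-final
    weights over a fixed w binning, the trial-mean weight, per-state
    probabilities, and the gap-cluster count.  The summary reports the
    critical-noise estimate: the smallest grid z whose cluster count drops
    below 3, with the grid spacing as its resolution.
    """
    if w_bins is None:
        w_bins = np.linspace(0.0, 0.1, 51)
    rows = []
    hists = {}
    for z in spec.z_grid:
        ens = run_ensemble(spec, f_d, z)
        cl = ens.clusters if len(ens.final_weights) >= 10 else None
        counts, _ = np.histogram(ens.final_weights, bins=w_bins)
        hists[z] = counts / max(counts.sum(), 1)
        probs = ens.probabilities() if set(ens.labels) & {"low", "mid", "high"} else {
            "low": np.nan, "mid": np.nan, "high": np.nan, "n_unclassified": len(ens.labels)}
        rows.append({
            "z": z, "f_d": f_d, "f_r": spec.f_r,
            "w_mean": ens.final_weights.mean(),
            "n_clusters": cl.n_clusters if cl is not None else np.nan,
            "p_low": probs["low"], "p_mid": probs["mid"], "p_high": probs["high"],
            "n_unclassified": probs["n_unclassified"],
        })
    table = pd.DataFrame(rows).sort_values("z").reset_index(drop=True)
    below = table.loc[table.n_clusters < 3, "z"]
    z_critical = float(below.iloc[0]) if len(below) else None
    return table, {"z_critical": z_critical, "P_w_given_z": hists, "w_bins": w_bins}


@dataclass
class SubnetworkPartition:
    """Units linked by above-threshold weights within one inspection window.

    ``within_corr`` is the minimum pairwise Pearson correlation of the raw
    excitatory rate series across all components' unit pairs in the window;
    ``within_corr_band`` the same on the band-passed (resonance +/- 5 Hz)
    traces, which isolates the oscillatory component the units synchronise
    on from the per-step noise jitter.  Both are None when no component
    exists in the window.
    """

    t_start: float
    t_stop: float
    components: list[list[int]]
    singletons: list[int]
    mean_weights: np.ndarray
    within_corr: float | None = None
    within_corr_band: float | None = None


def high_weight_components(
    W: np.ndarray, threshold: float = 0.06
) -> tuple[list[list[int]], list[int]]:
    """Connected components of the graph of links with w above threshold.

    A link counts if either direction exceeds the threshold.  Units with no
    high link are returned separately as singletons.
    """
    N = W.shape[0]
    adj = (W > threshold) | (W.T > threshold)
    seen = np.zeros(N, dtype=bool)
    comps: list[list[int]] = []
    singles: list[int] = []
    for s in range(N):
        if seen[s]:
            continue
        stack, comp = [s], []
        while stack:
            v = stack.pop()
            if seen[v]:
                continue
            seen[v] = True
            comp.append(v)
            stack.extend(int(u) for u in np.where(adj[v])[0] if not seen[u])
        if len(comp) > 1:
            comps.append(sorted(comp))
        else:
            singles.append(s)
    return comps, singles


@dataclass
class TenUnitResult:
    """Output of the all-to-all network study."""

    settings: RunSettings
    seed: int
    partitions: list[SubnetworkPartition]
    r_series: dict[float, np.ndarray]
    snapshot_times: np.ndarray


def ten_unit_study(
    settings: RunSettings | None = None,
    seed: int = 0,
    snapshot_every: float = 5.0,
    snapshot_len: float = 1.0,
    threshold: float = 0.06,
) -> TenUnitResult:
    """All-to-all network run with transient-subnetwork bookkeeping.

    Simulates the fully connected network, then every ``snapshot_every``
    seconds averages the weight matrix over a ``snapshot_len``-second window,
    partitions units into components linked by above-threshold weights, and
    computes the within-window Kuramoto coherence r(t) from the band-passed
    phases of all units.

    The default protocol is 2e6 steps at dt=1 ms with the first 1e5
    discarded, f_r = 12 Hz, f_d = 48 Hz and z = 0.003 -- the intermediate
    noise level at which the network switches spontaneously between weight
    states under the package's noise convention.
    """
    if settings is None:
        settings = RunSettings(
            n_units=10, topology="all_to_all", f_r=12.0, f_d=48.0, z=0.003,
            n_steps=2_000_000, n_discard=100_000,
            record_activity_every=1, record_weights_every=100,
        )
    if settings.topology != "all_to_all":
        raise ValueError("ten_unit_study requires all_to_all topology")
    traj = simulate(settings, seed=seed)

    dt = settings.dt
    w_dt = dt * settings.record_weights_every
    snap_w = int(round(snapshot_len / w_dt))      # weight samples per window
    snap_a = int(round(snapshot_len / dt))        # activity samples per window
    step_w = int(round(snapshot_every / w_dt))
    first = settings.n_discard // settings.record_weights_every

    phases = np.array([
        bandpass_phase(traj.E_series[:, i], settings.f_r, dt).phases
        for i in range(settings.n_units)
    ])
    from scipy import signal as _signal

    sos = _signal.butter(
        4, [settings.f_r - 5.0, settings.f_r + 5.0],
        btype="bandpass", fs=1.0 / dt, output="sos",
    )
    E_band = _signal.sosfiltfilt(sos, traj.E_series, axis=0)

    partitions: list[SubnetworkPartition] = []
    r_series: dict[float, np.ndarray] = {}
    times = []
    for s in range(first, traj.W_series.shape[0] - snap_w, step_w):
        t_start = traj.W_times[s]
        Wm = traj.W_series[s:s + snap_w].mean(axis=0)
        comps, singles = high_weight_components(Wm, threshold)
        a0 = int(round(t_start / dt))
        wcorr = wcorr_band = None
        if comps:
            mins, mins_b = [], []
            seg = traj.E_series[a0:a0 + snap_a]
            seg_b = E_band[a0:a0 + snap_a]
            for comp in comps:
                iu = np.triu_indices(len(comp), 1)
                mins.append(np.corrcoef(seg[:, comp].T)[iu].min())
                mins_b.append(np.corrcoef(seg_b[:, comp].T)[iu].min())
            wcorr = float(min(mins))
            wcorr_band = float(min(mins_b))
        partitions.append(SubnetworkPartition(
            t_start=float(t_start), t_stop=float(t_start + snapshot_len),
            components=comps, singletons=singles, mean_weights=Wm,
            within_corr=wcorr, within_corr_band=wcorr_band,
        ))
        r, _ = kuramoto_order(phases[:, a0:a0 + snap_a])
        r_series[float(t_start)] = r
        times.append(t_start)
    return TenUnitResult(
        settings=settings, seed=seed, partitions=partitions,
        r_series=r_series, snapshot_times=np.asarray(times),
    )
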