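"""Measurement layer: phases, synchrony, coarse-grained weights, states.

The standard workflow: band-pass each excitatory rate series
+/- 5 Hz around the unit resonance, extract instantaneous phases via the
analytic signal, compute the complex phase-locking value between unit pairs
and the Kuramoto order parameter across the network, and relate the
coarse-grained synaptic weight ``w_bar`` (sliding-window mean of w) to the
truncated activity correlation

    gamma * C_Delta = gamma * mean( E_i E_j Theta(E_i E_j - h) )

which is its predicted quasi-steady value.  Trial-final weights are grouped
into attractor clusters by one-dimensional gap clustering and mapped to the
"low" / "mid" / "high" states by fixed cutoffs on ``w_bar``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .params import ModelParams

__all__ = [
    "PhaseSeries",
    "WindowSpec",
    "AttractorClusters",
    "STATE_CUTOFFS",
    "bandpass_phase",
    "cplv",
    "kuramoto_order",
    "window_starts",
    "windowed_mean",
    "truncated_correlation",
    "coarse_weight",
    "asymptotic_weight",
    "classify_state",
    "classify_windows",
    "count_attractors",
    "state_probabilities",
    "phase_difference_histogram",
]

#: w_bar cutoffs delimiting the three stable weight states.
STATE_CUTOFFS = {"low": 0.01, "mid": (0.025, 0.0275), "high": 0.06}


@dataclass
class PhaseSeries:
    """Instantaneous phase of one band-passed series.

    ``valid`` is the slice unaffected by filter and Hilbert edge effects
    (three time constants of the filter bandwidth trimmed at each end).
    """

    phases: np.ndarray
    band: tuple[float, float]
    valid: slice

    @property
    def valid_phases(self) -> np.ndarray:
        return self.phases[self.valid]


@dataclass
class WindowSpec:
    """Sliding-window bookkeeping: length and stride in integration steps."""

    window_len: int = 10_000
    stride: int = 1_000

    def __post_init__(self) -> None:
        if self.window_len < 1 or self.stride < 1:
            raise ValueError("window_len and stride must be >= 1")


def bandpass_phase(
    x: np.ndarray, f_r: float, dt: float, half_width: float = 5.0
) -> PhaseSeries:
    """Zero-phase band-pass (f_r +/- half_width, 4th-order Butterworth applied
    forward-backward) followed by analytic-signal phase extraction."""
    x = np.asarray(x, dtype=float)
    fs = 1.0 / dt
    lo, hi = f_r - half_width, f_r + half_width
    if lo <= 0 or hi >= fs / 2:
        raise ValueError(
            f"band ({lo:.1f}, {hi:.1f}) Hz outside (0, Nyquist={fs / 2:.1f}) Hz"
        )
    bandwidth = hi - lo
    margin = int(np.ceil(3.0 * fs / bandwidth))
    if x.size <= 2 * margin:
        raise ValueError(
            f"series of {x.size} samples too short for edge margin {margin}"
        )
    sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = _signal.sosfiltfilt(sos, x)
    phases = np.angle(_signal.hilbert(filtered))
    return PhaseSeries(phases=phases, band=(lo, hi), valid=slice(margin, x.size - margin))


def _overlap(a: PhaseSeries, b: PhaseSeries) -> slice:
    start = max(a.valid.start, b.valid.start)
    stop = min(a.valid.stop, b.valid.stop)
    if stop <= start:
        raise ValueError("phase series have no overlapping valid range")
    return slice(start, stop)


def cplv(phi1: PhaseSeries | np.ndarray, phi2: PhaseSeries | np.ndarray) -> tuple[float, float]:
    """Complex phase-locking value of the phase difference.

    Returns ``(PLV, Phi)``: the modulus and argument of the mean unit phasor
    of ``phi1 - phi2``.  PLV is 1 for perfectly locked signals and of order
    ``1/sqrt(N)`` for independent phases.
    """
    if isinstance(phi1, PhaseSeries) and isinstance(phi2, PhaseSeries):
        sl = _overlap(phi1, phi2)
        d = phi1.phases[sl] - phi2.phases[sl]
    else:
        p1 = phi1.phases if isinstance(phi1, PhaseSeries) else np.asarray(phi1)
        p2 = phi2.phases if isinstance(phi2, PhaseSeries) else np.asarray(phi2)
        if p1.size != p2.size:
            raise ValueError("phase series lengths differ")
        d = p1 - p2
    if d.size == 0:
        raise ValueError("empty phase overlap")
    z = np.mean(np.exp(1j * d))
    return float(np.abs(z)), float(np.angle(z))


def kuramoto_order(phases: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kuramoto order parameter of a ``(K, T)`` phase matrix.

    Returns per-time-point modulus ``r(t)`` (1 = full synchrony, 0 =
    incoherence) and mean phase ``psi(t)`` of the ensemble phasor average.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if phases.shape[0] < 2:
        raise ValueError("need at least K=2 oscillators")
    z = np.mean(np.exp(1j * phases), axis=0)
    return np.abs(z), np.angle(z)


def window_starts(n: int, spec: WindowSpec) -> np.ndarray:
    """Start indices of all windows fully inside a series of length n."""
    if spec.window_len > n:
        raise ValueError(f"window of {spec.window_len} longer than series of {n}")
    return np.arange(0, n - spec.window_len + 1, spec.stride)


def windowed_mean(x: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Sliding-window mean of a 1-D series (cumulative-sum implementation)."""
    x = np.asarray(x, dtype=float)
    starts = window_starts(x.size, spec)
    c = np.concatenate(([0.0], np.cumsum(x)))
    return (c[starts + spec.window_len] - c[starts]) / spec.window_len


def truncated_correlation(
    E1: np.ndarray, E2: np.ndarray, params: ModelParams, window: WindowSpec
) -> np.ndarray:
    """Per-window ``gamma * mean(E1 E2 Theta(E1 E2 - h))`` (strict threshold)."""
    E1 = np.asarray(E1, dtype=float)
    E2 = np.asarray(E2, dtype=float)
    if E1.size != E2.size:
        raise ValueError("series lengths differ")
    prod = E1 * E2
    return params.gamma * windowed_mean(np.where(prod > params.h, prod, 0.0), window)


def coarse_weight(w: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Per-window mean of the weight series (the coarse-grained weight w_bar)."""
    return windowed_mean(w, window)


def asymptotic_weight(C: float, params: ModelParams) -> float:
    """Quasi-steady coarse-grained weight ``gamma * C`` for a held correlation C."""
    if C < 0:
        raise ValueError("C must be >= 0")
    return params.gamma * C


def classify_state(w_bar: float) -> str:
    """Map a coarse-grained weight to "low"/"mid"/"high"/"unclassified"."""
    if w_bar < STATE_CUTOFFS["low"]:
        return "low"
    lo, hi = STATE_CUTOFFS["mid"]
    if lo < w_bar < hi:
        return "mid"
    if w_bar > STATE_CUTOFFS["high"]:
        return "high"
    return "unclassified"


def classify_windows(w_bar: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_state` over an array of w_bar values."""
    return np.array([classify_state(float(v)) for v in np.asarray(w_bar).ravel()])


@dataclass
class AttractorClusters:
    """Gap-clustering result over trial-final weights."""

    n_clusters: int
    centers: np.ndarray
    occupancies: np.ndarray
    gap_min: float

    def count(self, min_occupancy: int = 1) -> int:
        """Cluster count ignoring clusters smaller than ``min_occupancy``."""
        return int(np.sum(self.occupancies >= min_occupancy))


def count_attractors(
    final_weights: np.ndarray, gap_min: float = 0.0075, min_trials: int = 10
) -> AttractorClusters:
    """One-dimensional gap clustering of trial-final weights.

    Sorts the values and splits wherever the gap between consecutive values
    strictly exceeds ``gap_min`` (half the distance between the "low" and
    "mid" cutoff bands by default).  Deterministic: the same input always
    yields the same clusters.
    """
    v = np.sort(np.asarray(final_weights, dtype=float).ravel())
    if v.size < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {v.size}")
    breaks = np.where(np.diff(v) > gap_min)[0]
    edges = np.concatenate(([0], breaks + 1, [v.size]))
    centers = np.array([v[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    occ = np.diff(edges)
    return AttractorClusters(
        n_clusters=centers.size, centers=centers, occupancies=occ, gap_min=gap_min
    )


def state_probabilities(labels: np.ndarray) -> dict[str, float]:
    """Relative frequency of each state over the classified trials.

    "mid" aggregates any sub-branches the caller has already labelled "mid".
    Unclassified trials are excluded from the normalisation and reported
    under ``"n_unclassified"``.
    """
    labels = np.asarray(labels)
    counts = Counter(labels.tolist())
    n_cls = sum(counts[s] for s in ("low", "mid", "high"))
    if n_cls == 0:
        raise ValueError("no classified trials")
    out = {s: counts[s] / n_cls for s in ("low", "mid", "high")}
    out["n_unclassified"] = float(labels.size - n_cls)
    return out


def phase_difference_histogram(
    phi1: PhaseSeries,
    phi2: PhaseSeries,
    labels: np.ndarray,
    window: WindowSpec,
    bin_width: float = np.pi / 50,
) -> dict[str, dict]:
    """Per-state densities of the phase difference and of the cPLV phase.

    ``labels`` assigns a state to each sliding window (as from
    :func:`classify_windows` on the windowed weight).  For every state the
    instantaneous phase differences of all its windows are pooled into a
    density over (-pi, pi], and the per-window cPLV arguments Phi into a
    second density.  Both normalise to unit integral; states with no windows
    are flagged ``empty``.
    """
    sl = _overlap(phi1, phi2)
    dphi_full = phi1.phases - phi2.phases
    nbins = int(round(2 * np.pi / bin_width))
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    starts = window_starts(phi1.phases.size, window)
    if starts.size != np.asarray(labels).size:
        raise ValueError("labels must align with the sliding windows")

    out: dict[str, dict] = {}
    for state in ("low", "mid", "high"):
        idx = np.where(np.asarray(labels) == state)[0]
        dphis = []
        Phis = []
        for i in idx:
            a, b = starts[i], starts[i] + window.window_len
            a, b = max(a, sl.start), min(b, sl.stop)
            if b <= a:
                continue
            seg = dphi_full[a:b]
            dphis.append(seg)
            z = np.mean(np.exp(1j * seg))
            Phis.append(np.angle(z))
        if not dphis:
            out[state] = {"empty": True}
            continue
        wrapped = np.angle(np.exp(1j * np.concatenate(dphis)))
        dens_dphi, _ = np.histogram(wrapped, bins=edges, density=True)
        dens_phi, _ = np.histogram(np.asarray(Phis), bins=edges, density=True)
        out[state] = {
            "empty": False,
            "bin_centers": 0.5 * (edges[:-1] + edges[1:]),
            "dphi_density": dens_dphi,
            "phi_density": dens_phi,
            "n_windows": int(len(Phis)),
        }
    return out
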