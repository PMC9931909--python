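"""Wilson-Cowan network with Hebbian plasticity and homeostatic scaling.

Each unit holds an excitatory (E) and inhibitory (I) population whose
fractional firing rates follow

    tau_E dE_i/dt = -E_i + S(W_EE E_i - W_EI I_i + E0 + sum_j w_ij E_j
                             + f(t) + z xi_i(t) - S_E,i)
    tau_I dI_i/dt = -I_i + S(W_IE E_i + W_II I_i + I0 + sum_j u_ij E_j - S_I,i)

with the logistic gain ``S``.  Excitatory inter-unit weights are plastic,

    tau_h dw_ij/dt = -w_ij + gamma E_i E_j Theta(E_i E_j - h),

i.e. they grow only while the instantaneous rate product exceeds the
coincidence threshold ``h`` and decay exponentially otherwise.  Slow
homeostatic variables ``S_E, S_I`` integrate the deviation of each rate from
its set point and are subtracted from the population input, pinning the
long-run mean rates at ``E_inf`` / ``I_inf``.

Integration is explicit fixed-step Euler-Maruyama: one fresh N(0,1) sample
per unit per step enters the excitatory sigmoid argument, scaled by
``z/sqrt(dt)`` by default (see :class:`~wcplast.params.RunSettings`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import integrate_network
from .drive import make_drive
from .params import DriveSpec, ModelParams, RunSettings

__all__ = [
    "NetworkState",
    "Trajectory",
    "sigmoid",
    "wc_drift",
    "plasticity_drift",
    "homeostatic_drift",
    "step",
    "simulate",
    "estimate_resonance",
]


def sigmoid(x, m: float = 1.0, n: float = 4.0):
    """Logistic gain ``1 / (1 + exp(-m (x - n)))``, saturating without overflow."""
    return 0.5 * (1.0 + np.tanh(0.5 * m * (np.asarray(x, dtype=float) - n)))


@dataclass
class NetworkState:
    """Instantaneous state of an N-unit network.

    ``W`` holds the plastic excitatory inter-unit weights (row i receives
    from column j), ``U`` the fixed inhibitory ones; both have zero diagonal
    (no self-connections).  ``plastic`` marks which entries of W evolve.
    """

    E: np.ndarray
    I: np.ndarray
    S_E: np.ndarray
    S_I: np.ndarray
    W: np.ndarray
    U: np.ndarray
    plastic: np.ndarray
    t: float = 0.0

    @classmethod
    def initial(cls, settings: RunSettings, params: ModelParams) -> "NetworkState":
        """All-zero populations with topology-defined weight matrices."""
        N = settings.n_units
        W = np.zeros((N, N))
        U = np.zeros((N, N))
        plastic = np.zeros((N, N), dtype=bool)
        if settings.topology == "two_unit_unidirectional":
            # unit 1 receives from unit 2 (indices 0 <- 1)
            W[0, 1] = params.w_init
            U[0, 1] = params.u_fixed
            plastic[0, 1] = True
        else:  # all_to_all
            W[:] = params.w_init
            U[:] = params.u_fixed
            np.fill_diagonal(W, 0.0)
            np.fill_diagonal(U, 0.0)
            plastic = ~np.eye(N, dtype=bool)
        zeros = np.zeros(N)
        return cls(zeros.copy(), zeros.copy(), zeros.copy(), zeros.copy(), W, U, plastic)

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.E.copy(), self.I.copy(), self.S_E.copy(), self.S_I.copy(),
            self.W.copy(), self.U.copy(), self.plastic.copy(), self.t,
        )


@dataclass
class Trajectory:
    """Recorded time series of one simulation.

    Activity is sampled every ``settings.record_activity_every`` steps and
    weights every ``settings.record_weights_every`` steps, each sample taken
    *after* the corresponding step.  ``n_discard`` flags the transient
    prefix; the ``post_*`` helpers return the analysed tail.
    """

    times: np.ndarray          # activity sample times (s)
    E_series: np.ndarray       # (n_samples, N)
    I_series: np.ndarray       # (n_samples, N)
    W_times: np.ndarray        # weight sample times (s)
    W_series: np.ndarray       # (n_w_samples, N, N)
    drive_series: np.ndarray   # full-rate drive f(t)
    drive_onset: float         # realized jitter t0 (s)
    seed: int
    params: ModelParams
    settings: RunSettings
    final_state: NetworkState

    @property
    def n_discard_samples(self) -> int:
        return self.settings.n_discard // self.settings.record_activity_every

    def post_transient(self) -> tuple[np.ndarray, np.ndarray]:
        """(E_series, I_series) restricted to the retained tail."""
        k = self.n_discard_samples
        return self.E_series[k:], self.I_series[k:]

    def post_transient_weights(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.settings.n_discard // self.settings.record_weights_every
        return self.W_times[k:], self.W_series[k:]

    @property
    def final_weights(self) -> np.ndarray:
        return self.W_series[-1]


def wc_drift(
    state: NetworkState,
    params: ModelParams,
    drive: float = 0.0,
    noise_sample: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic population drifts (dE/dt, dI/dt) at the current state.

    ``noise_sample`` must already carry the full per-step scaling; drive and
    noise enter the excitatory argument only.
    """
    p = params
    argE = (p.W_EE * state.E - p.W_EI * state.I + p.E0 + state.W @ state.E
            + drive + np.asarray(noise_sample) - state.S_E)
    argI = p.W_IE * state.E + p.W_II * state.I + p.I0 + state.U @ state.E - state.S_I
    dE = (-state.E + sigmoid(argE, p.m, p.n)) / p.tau_E
    dI = (-state.I + sigmoid(argI, p.m, p.n)) / p.tau_I
    return dE, dI


def plasticity_drift(w: float, E_i: float, E_j: float, params: ModelParams) -> float:
    """Hebbian-with-threshold weight drift dw/dt.

    Zero Hebbian term at or below threshold (Theta(0) = 0), so an inactive
    synapse decays as ``-w / tau_h``.
    """
    p = E_i * E_j
    hebb = params.gamma * p if p > params.h else 0.0
    return (-w + hebb) / params.tau_h


def homeostatic_drift(
    E_i: np.ndarray | float, I_i: np.ndarray | float, params: ModelParams
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Scaling-variable drifts ``((E - E_inf)/tau_SE, (I - I_inf)/tau_SI)``."""
    return (
        (np.asarray(E_i) - params.E_inf) / params.tau_SE,
        (np.asarray(I_i) - params.I_inf) / params.tau_SI,
    )


def _z_step(settings: RunSettings) -> float:
    if settings.noise_mode == "ito":
        return settings.z / np.sqrt(settings.dt)
    return settings.z


def step(
    state: NetworkState,
    settings: RunSettings,
    params: ModelParams,
    rng: np.random.Generator,
    drive: float = 0.0,
) -> NetworkState:
    """One explicit Euler-Maruyama step (pure-numpy reference path).

    Draws one N(0,1) sample per unit, scales it per ``settings.noise_mode``
    and advances populations, plastic weights and homeostatic variables by
    ``dt``.  The numba kernel used by :func:`simulate` follows the identical
    update order; the test suite checks the two stay in agreement.
    """
    out = state.copy()
    xi = rng.standard_normal(len(state.E)) * _z_step(settings)
    dE, dI = wc_drift(state, params, drive=drive, noise_sample=xi)
    dt = settings.dt
    prod = np.outer(state.E, state.E)
    hebb = np.where(prod > params.h, params.gamma * prod, 0.0)
    out.W = state.W + np.where(
        state.plastic, dt * (-state.W + hebb) / params.tau_h, 0.0
    )
    dSE, dSI = homeostatic_drift(state.E, state.I, params)
    out.E = state.E + dt * dE
    out.I = state.I + dt * dI
    out.S_E = state.S_E + dt * dSE
    out.S_I = state.S_I + dt * dSI
    out.t = state.t + dt
    if not (np.all(np.isfinite(out.E)) and np.all(np.isfinite(out.I))):
        raise RuntimeError(f"non-finite state at t={out.t:.6f}s")
    return out


def simulate(
    settings: RunSettings,
    params: ModelParams | None = None,
    seed: int = 0,
) -> Trajectory:
    """Run one trial and record its trajectory.

    If ``params`` is omitted it is built from the resonance table for
    ``settings.f_r``.  The trial RNG (seeded with ``seed``) first draws the
    drive onset jitter, then feeds the per-step noise; reruns with the same
    seed and settings are bit-identical.
    """
    if params is None:
        params = ModelParams.for_resonance(settings.f_r)
    st = NetworkState.initial(settings, params)
    rng = np.random.default_rng(seed)
    drive, t0 = make_drive(settings.drive, settings.n_steps, settings.dt, rng)

    ae, we = settings.record_activity_every, settings.record_weights_every
    n_act = settings.n_steps // ae
    n_w = settings.n_steps // we
    N = settings.n_units
    rec_E = np.empty((n_act, N))
    rec_I = np.empty((n_act, N))
    rec_W = np.empty((n_w, N, N))

    p = params
    bad = integrate_network(
        st.E, st.I, st.S_E, st.S_I, st.W, st.U, st.plastic,
        drive, settings.dt, _z_step(settings),
        p.W_EE, p.W_EI, p.W_IE, p.W_II, p.m, p.n, p.E0, p.I0,
        p.tau_E, p.tau_I, p.tau_h, p.gamma, p.h, p.E_inf, p.I_inf,
        p.tau_SE, p.tau_SI,
        settings.n_steps, rng, rec_E, rec_I, rec_W, ae, we,
    )
    if bad >= 0:
        raise RuntimeError(
            f"non-finite population state detected at step {bad} "
            f"(t={bad * settings.dt:.3f}s); check parameters"
        )
    st.t = settings.n_steps * settings.dt
    times = (np.arange(1, n_act + 1) * ae) * settings.dt
    w_times = (np.arange(1, n_w + 1) * we) * settings.dt
    return Trajectory(
        times=times, E_series=rec_E, I_series=rec_I,
        W_times=w_times, W_series=rec_W,
        drive_series=drive, drive_onset=t0, seed=seed,
        params=params, settings=settings, final_state=st,
    )


def estimate_resonance(
    params: ModelParams,
    tau_E: float | None = None,
    tau_I: float | None = None,
    f_grid: np.ndarray | None = None,
    drive_amplitude: float = 0.1,
    settle: float = 3.0,
    measure: float = 3.0,
    dt: float = 0.001,
) -> float:
    """Drive-response resonance of a single unit with the given time constants.

    Runs the deterministic model (z=0, no onset jitter) for each frequency on
    ``f_grid``, measures the amplitude of the steady-state E response at the
    drive frequency (fundamental Fourier component over the last ``measure``
    seconds) of an uncoupled unit, and returns the grid frequency of maximal
    response.  Raises if the response peaks at the grid boundary, i.e. the
    grid does not bracket the peak.
    """
    if tau_E is not None or tau_I is not None:
        params = params.replace(
            tau_E=tau_E if tau_E is not None else params.tau_E,
            tau_I=tau_I if tau_I is not None else params.tau_I,
        )
    if f_grid is None:
        f_grid = np.arange(1.0, 40.5, 0.5)
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.size < 3:
        raise ValueError("f_grid must contain at least 3 frequencies")

    n_steps = int(round((settle + measure) / dt))
    n_meas = int(round(measure / dt))
    amps = np.empty(f_grid.size)
    for k, fd in enumerate(f_grid):
        settings = RunSettings(
            n_units=2, f_d=float(fd), z=0.0, n_steps=n_steps,
            n_discard=n_steps - n_meas, dt=dt,
            topology="two_unit_unidirectional",
            drive_amplitude=drive_amplitude, jitter_window=0.0,
            record_activity_every=1,
        )
        traj = simulate(settings, params, seed=0)
        x = traj.E_series[-n_meas:, 1]  # unit 2 receives no coupling
        t = np.arange(n_meas) * dt
        amps[k] = 2.0 * np.abs(np.mean((x - x.mean()) * np.exp(-2j * np.pi * fd * t)))
    peak = int(np.argmax(amps))
    if peak in (0, f_grid.size - 1):
        raise ValueError(
            f"response maximal at the edge of the scan grid ({f_grid[peak]:.1f} Hz); "
            "extend f_grid to bracket the resonance"
        )
    return float(f_grid[peak])
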