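"""Unit dynamics, plasticity and integrator contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from wcplast import (
    ModelParams,
    NetworkState,
    RunSettings,
    estimate_resonance,
    homeostatic_drift,
    plasticity_drift,
    sigmoid,
    simulate,
    step,
    time_constants_for_resonance,
    wc_drift,
)
from wcplast.drive import make_drive


class TestSigmoid:
    def test_half_at_offset(self):
        assert sigmoid(4.0, m=1.0, n=4.0) == pytest.approx(0.5)

    @given(a=st.floats(-30, 30), m=st.floats(0.1, 5), n=st.floats(-5, 5))
    @hyp_settings(derandomize=True)
    def test_symmetry_about_offset(self, a, m, n):
        assert sigmoid(n + a, m, n) + sigmoid(n - a, m, n) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_at_zero(self):
        assert sigmoid(0.0, 1.0, 4.0) == pytest.approx(1.0 / (1.0 + math.e**4), rel=1e-12)

    def test_saturates_without_overflow(self):
        assert sigmoid(1e4) == 1.0
        assert sigmoid(-1e4) == 0.0

    @given(x=st.floats(-20, 20))
    @hyp_settings(derandomize=True)
    def test_strictly_increasing(self, x):
        assert sigmoid(x + 1e-3) > sigmoid(x)


class TestDrifts:
    def test_rest_state_drift_closed_form(self, params):
        st_ = NetworkState.initial(RunSettings(), params)
        dE, dI = wc_drift(st_, params)
        # at E=I=S=0 only the background inputs remain in the arguments
        expect_E = (1.0 / (1.0 + math.exp(-(0.5 - 4.0)))) / 0.011
        expect_I = (1.0 / (1.0 + math.exp(-(-5.0 - 4.0)))) / 0.007
        assert dE == pytest.approx([expect_E] * 2, rel=1e-10)
        assert dI == pytest.approx([expect_I] * 2, rel=1e-10)

    def test_fixed_point_has_zero_drift(self, params):
        st_ = NetworkState.initial(RunSettings(), params)
        st_.E[:] = 0.3
        arg = params.W_EE * 0.3 - params.W_EI * 0.0 + params.E0
        arg_vec = arg + st_.W @ st_.E
        st_.E[0] = sigmoid(arg + st_.W[0] @ st_.E, params.m, params.n)
        # recompute: set each unit's E to the sigmoid of its own argument
        for _ in range(200):
            target = sigmoid(
                params.W_EE * st_.E - params.W_EI * st_.I + params.E0 + st_.W @ st_.E,
                params.m, params.n,
            )
            st_.E = target
        dE, _ = wc_drift(st_, params)
        assert np.allclose(dE, 0.0, atol=1e-6)

    def test_coupling_enters_excitatory_argument(self, params):
        st_ = NetworkState.initial(RunSettings(), params)
        st_.E[1] = 0.4  # unit 1 receives w_12 * E_2 = 0.15 * 0.4 = 0.06
        dE, _ = wc_drift(st_, params)
        base = params.E0
        expect = (-0.0 + sigmoid(base + 0.06, params.m, params.n)) / params.tau_E
        assert dE[0] == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize(
        "w,Ei,Ej,expect",
        [
            (0.15, 0.5, 0.5, (-0.15 + 0.25) / 2.5),
            (0.1, 0.1, 0.1, -0.1 / 2.5),        # product 0.01 < h: pure decay
            (0.0, 0.0, 0.0, 0.0),
        ],
    )
    def test_plasticity_drift_examples(self, params, w, Ei, Ej, expect):
        assert plasticity_drift(w, Ei, Ej, params) == pytest.approx(expect, abs=1e-15)

    def test_threshold_equality_gives_pure_decay(self):
        # Theta(0) = 0: at product exactly equal to h the Hebbian term is off
        # (h=0.25 and rates of 0.5 are exactly representable in binary)
        params = ModelParams(h=0.25)
        assert plasticity_drift(0.1, 0.5, 0.5, params) == pytest.approx(-0.1 / 2.5)

    def test_plasticity_fixed_point_is_gamma_c(self, params):
        c = 0.25
        assert plasticity_drift(params.gamma * c, 0.5, 0.5, params) == pytest.approx(0.0)

    def test_plasticity_transient_matches_closed_form(self, params):
        # held product c > h: w(t) = w0 e^{-t/tau_h} + gamma c (1 - e^{-t/tau_h})
        w, dt, c = 0.15, 1e-4, 0.25
        for _ in range(int(params.tau_h / dt)):
            w += dt * plasticity_drift(w, 0.5, 0.5, params)
        expect = 0.15 * math.exp(-1) + c * (1 - math.exp(-1))
        assert expect == pytest.approx(0.2132, abs=5e-4)
        assert w == pytest.approx(expect, rel=1e-3)

    @pytest.mark.parametrize(
        "E,I,expect",
        [(0.2, 0.2, (0.0, 0.0)), (0.7, 0.2, (0.5, 0.0)), (0.2, 0.0, (0.0, -0.1))],
    )
    def test_homeostatic_drift_examples(self, params, E, I, expect):
        dSE, dSI = homeostatic_drift(E, I, params)
        assert (dSE, dSI) == pytest.approx(expect)


class TestStep:
    def test_single_step_hand_oracle(self, params):
        """One deterministic Euler step from a hand-chosen state, checked against
        arithmetic done with plain python floats."""
        settings = RunSettings(z=0.0, n_steps=10, n_discard=0)
        st_ = NetworkState.initial(settings, params)
        st_.E[:] = (0.1, 0.3)
        st_.I[:] = (0.05, 0.2)
        st_.S_E[:] = 0.01
        st_.S_I[:] = 0.02
        out = step(st_, settings, params, np.random.default_rng(0), drive=0.2)

        def S(x):
            return 1.0 / (1.0 + math.exp(-(x - 4.0)))

        # unit 1: argE = 23*0.1 - 15*0.05 + 0.5 + 0.15*0.3 + 0.2 - 0.01
        argE1 = 23 * 0.1 - 15 * 0.05 + 0.5 + 0.15 * 0.3 + 0.2 - 0.01
        e1 = 0.1 + 0.001 * (-0.1 + S(argE1)) / 0.011
        argI1 = 35 * 0.1 + 0.0 - 5.0 + 0.1 * 0.3 - 0.02
        i1 = 0.05 + 0.001 * (-0.05 + S(argI1)) / 0.007
        w12 = 0.15 + 0.001 * (-0.15) / 2.5  # product 0.03 < h -> pure decay
        assert out.E[0] == pytest.approx(e1, rel=1e-12)
        assert out.I[0] == pytest.approx(i1, rel=1e-12)
        assert out.W[0, 1] == pytest.approx(w12, rel=1e-12)
        assert out.S_E[0] == pytest.approx(0.01 + 0.001 * (0.1 - 0.2) / 1.0, rel=1e-12)
        assert out.S_I[0] == pytest.approx(0.02 + 0.001 * (0.05 - 0.2) / 2.0, rel=1e-12)

    def test_reference_step_matches_kernel_path(self, params):
        """The numpy single-step reference and the compiled integrator agree
        sample for sample over a noisy run."""
        settings = RunSettings(
            n_steps=200, n_discard=0, z=0.0015,
            record_activity_every=1, record_weights_every=1,
        )
        traj = simulate(settings, params, seed=7)

        rng = np.random.default_rng(7)
        drive, _ = make_drive(settings.drive, settings.n_steps, settings.dt, rng)
        st_ = NetworkState.initial(settings, params)
        E_ref = np.empty_like(traj.E_series)
        W_ref = np.empty_like(traj.W_series)
        for t in range(settings.n_steps):
            st_ = step(st_, settings, params, rng, drive=drive[t])
            E_ref[t] = st_.E
            W_ref[t] = st_.W
        assert np.allclose(E_ref, traj.E_series, atol=1e-12)
        assert np.allclose(W_ref, traj.W_series, atol=1e-12)

    def test_first_order_convergence_in_dt(self, params):
        """Halving dt roughly halves the terminal-state error (explicit Euler)."""
        def terminal(dt):
            n = int(round(0.5 / dt))
            settings = RunSettings(
                n_steps=n, n_discard=0, z=0.0, dt=dt, jitter_window=0.0,
                record_activity_every=n, record_weights_every=n,
            )
            return simulate(settings, params, seed=0).E_series[-1]

        ref = terminal(0.000125)
        e1 = np.abs(terminal(0.001) - ref).max()
        e2 = np.abs(terminal(0.0005) - ref).max()
        assert e2 < e1
        assert e1 / e2 == pytest.approx(2.0, rel=0.5)


class TestSimulate:
    def test_topology_initialisation(self, params):
        two = NetworkState.initial(RunSettings(), params)
        assert two.W[0, 1] == 0.15 and two.U[0, 1] == 0.1
        assert two.W[1, 0] == 0.0 and two.U[1, 0] == 0.0
        ten = NetworkState.initial(
            RunSettings(n_units=10, topology="all_to_all"), params
        )
        assert np.all(np.diag(ten.W) == 0) and np.all(np.diag(ten.U) == 0)
        off = ~np.eye(10, dtype=bool)
        assert np.all(ten.W[off] == 0.15) and np.all(ten.U[off] == 0.1)

    def test_series_lengths_and_determinism(self, params, short_settings):
        t1 = simulate(short_settings, params, seed=3)
        t2 = simulate(short_settings, params, seed=3)
        assert t1.E_series.shape == (short_settings.n_steps, 2)
        assert t1.W_series.shape[0] == short_settings.n_steps // 10
        assert np.array_equal(t1.E_series, t2.E_series)
        assert np.array_equal(t1.W_series, t2.W_series)
        assert t1.drive_onset == t2.drive_onset

    def test_forward_invariance_of_rates(self, params):
        settings = RunSettings(n_steps=50_000, n_discard=0, z=0.0015)
        traj = simulate(settings, params, seed=5)
        assert traj.E_series.min() > -0.05 and traj.E_series.max() < 1.05
        assert traj.I_series.min() > -0.05 and traj.I_series.max() < 1.05

    def test_weights_stay_nonnegative(self, params):
        settings = RunSettings(n_steps=100_000, n_discard=0, z=0.003)
        traj = simulate(settings, params, seed=11)
        assert traj.W_series.min() >= 0.0

    def test_subthreshold_weight_decay_matches_exponential(self):
        """With an unreachable coincidence threshold the weight follows
        w(t) = w0 exp(-t/tau_h) to within 1% over 5 s."""
        params = ModelParams.for_resonance(12, h=2.0)  # product <= 1 < h always
        settings = RunSettings(
            n_steps=5_000, n_discard=0, z=0.0015, record_weights_every=100,
        )
        traj = simulate(settings, params, seed=1)
        w = traj.W_series[:, 0, 1]
        expect = 0.15 * np.exp(-traj.W_times / params.tau_h)
        assert np.max(np.abs(w - expect) / expect) < 0.01

    def test_homeostasis_pins_mean_rate(self, params):
        settings = RunSettings(n_steps=60_000, n_discard=20_000, z=0.0015)
        traj = simulate(settings, params, seed=9)
        E, _ = traj.post_transient()
        assert abs(E[:, 0].mean() - 0.2) < 0.02
        assert abs(E[:, 1].mean() - 0.2) < 0.02

    def test_nonfinite_state_aborts_with_step_index(self, params):
        bad = params.replace(tau_E=1e-9)  # absurd stiffness forces divergence
        settings = RunSettings(n_steps=5_000, n_discard=0, z=0.0)
        with pytest.raises(RuntimeError, match="step"):
            simulate(settings, bad, seed=0)


class TestResonance:
    def test_lookup_table(self):
        assert time_constants_for_resonance(4) == (0.017, 0.013)
        assert time_constants_for_resonance(23) == (0.014, 0.006)
        with pytest.raises(ValueError, match="estimate_resonance"):
            time_constants_for_resonance(10)

    def test_estimate_orders_tabulated_pairs(self, params):
        """The drive-response peak frequency increases across the tabulated
        pairs in the order of their nominal labels."""
        grid = np.arange(2.0, 40.0, 1.0)
        peaks = [
            estimate_resonance(ModelParams.for_resonance(f), f_grid=grid)
            for f in (4, 8, 12, 23)
        ]
        assert peaks == sorted(peaks)
        assert all(2.0 < p < 40.0 for p in peaks)

    def test_grid_excluding_peak_errors(self, params):
        with pytest.raises(ValueError, match="grid"):
            estimate_resonance(params, f_grid=np.arange(1.0, 5.0, 1.0))
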