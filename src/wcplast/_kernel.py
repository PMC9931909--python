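"""Numba kernel for the fixed-step Euler-Maruyama integration.

The kernel advances all populations, homeostatic variables and plastic
weights of an N-unit network.  It is the single hot loop of the package;
everything else is bookkeeping.  A pure-numpy single-step reference lives in
:mod:`wcplast.model` and the test suite checks the two paths agree.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def integrate_network(
    E, I, S_E, S_I, W, U, plastic, drive, dt, z_step,
    W_EE, W_EI, W_IE, W_II, m, n, E0, I0,
    tau_E, tau_I, tau_h, gamma, h, E_inf, I_inf, tau_SE, tau_SI,
    n_steps, rng,
    rec_E, rec_I, rec_W, act_every, w_every,
):
    """Advance the network ``n_steps`` steps in place.

    ``z_step`` is the per-step noise standard deviation (already includes any
    1/sqrt(dt) factor).  One fresh N(0,1) draw per unit per step enters the
    excitatory sigmoid argument.  State is recorded *after* each step at the
    requested decimations, so the last sample of every series is the final
    state whenever the decimation divides ``n_steps``.

    Returns -1 on success, or the index of the first step at which a
    non-finite population value was detected.
    """
    N = E.shape[0]
    newE = np.empty(N)
    newI = np.empty(N)
    ra = 0
    rw = 0
    for t in range(n_steps):
        d = drive[t]
        for i in range(N):
            coupE = 0.0
            coupI = 0.0
            for j in range(N):
                coupE += W[i, j] * E[j]
                coupI += U[i, j] * E[j]
            xi = rng.standard_normal()
            argE = (W_EE * E[i] - W_EI * I[i] + E0 + coupE + d
                    + z_step * xi - S_E[i])
            argI = W_IE * E[i] + W_II * I[i] + I0 + coupI - S_I[i]
            sE = 1.0 / (1.0 + np.exp(-m * (argE - n)))
            sI = 1.0 / (1.0 + np.exp(-m * (argI - n)))
            newE[i] = E[i] + dt * (-E[i] + sE) / tau_E
            newI[i] = I[i] + dt * (-I[i] + sI) / tau_I
        # plasticity and homeostasis use the pre-update rates (explicit Euler)
        for i in range(N):
            for j in range(N):
                if plastic[i, j]:
                    p = E[i] * E[j]
                    hebb = gamma * p if p > h else 0.0
                    W[i, j] += dt * (-W[i, j] + hebb) / tau_h
        for i in range(N):
            S_E[i] += dt * (E[i] - E_inf) / tau_SE
            S_I[i] += dt * (I[i] - I_inf) / tau_SI
            E[i] = newE[i]
            I[i] = newI[i]
        if (t + 1) % act_every == 0:
            for i in range(N):
                rec_E[ra, i] = E[i]
                rec_I[ra, i] = I[i]
            ra += 1
        if (t + 1) % w_every == 0:
            for i in range(N):
                for j in range(N):
                    rec_W[rw, i, j] = W[i, j]
            rw += 1
        if (t + 1) % 1000 == 0:
            ok = True
            for i in range(N):
                if not (np.isfinite(E[i]) and np.isfinite(I[i])):
                    ok = False
            if not ok:
                return t
    return -1
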