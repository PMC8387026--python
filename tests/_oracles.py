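"""Independent brute-force integrators used as oracles by the test suite.

The Euler oracle integrates all three states (u, N, C) independently with a
naive fixed step, sharing no code with the package's adaptive integrator.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def euler_photocycle(k_act, k_unf, k_rec, k_exp0, k_exp_lit, k_imp,
                     intensity, u0, n0, c0, dt, n_steps, record_every):
    """Fixed-step explicit Euler under constant light; records every
    ``record_every`` steps (including step 0)."""
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, 3))
    u, n, c = u0, n0, c0
    j = 0
    for i in range(n_steps + 1):
        if i % record_every == 0:
            out[j, 0] = u
            out[j, 1] = n
            out[j, 2] = c
            j += 1
        du = (k_act * intensity + k_unf) * (1.0 - u) - k_rec * u
        dn = k_imp * c - (k_exp0 + k_exp_lit * u) * n
        u += dt * du
        n += dt * dn
        c -= dt * dn
    return out[:j]


def euler_trace(params, intensity, initial, t_end, n_steps, n_records):
    """Convenience wrapper returning (times, u, N, C) arrays."""
    dt = t_end / n_steps
    record_every = n_steps // n_records
    n_steps = record_every * n_records  # make the grid exact
    out = euler_photocycle(params.k_act, params.k_unf, params.k_rec,
                           params.k_exp0, params.k_exp_lit, params.k_imp,
                           intensity, *initial, dt, n_steps, record_every)
    times = np.arange(out.shape[0]) * (dt * record_every)
    return times, out[:, 0], out[:, 1], out[:, 2]
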