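"""Numba kernels for the mean-field integrator and the lattice simulator.

The mean-field drift is a cubic polynomial in the strong fraction x; kernels
take its coefficients (ascending order) and step with explicit Euler. Status
codes: 0 = saturated, 1 = step budget exhausted, 2 = left [0, 1].
"""

import numba
import numpy as np


@numba.njit(cache=True)
def _drift_eval(c0, c1, c2, c3, x):
    return c0 + x * (c1 + x * (c2 + x * c3))


@numba.njit(cache=True)
def euler_path(c0, c1, c2, c3, x0, dt, n_steps, stride, out_x):
    """Fixed-length Euler integration recording every `stride` steps.

    Returns (status, n_recorded). out_x must have room for
    n_steps // stride + 2 entries; the final state is always recorded.
    """
    x = x0
    out_x[0] = x
    n_rec = 1
    for k in range(1, n_steps + 1):
        x = x + dt * _drift_eval(c0, c1, c2, c3, x)
        if x < 0.0 or x > 1.0:
            return 2, n_rec
        if k % stride == 0:
            out_x[n_rec] = x
            n_rec += 1
    if n_steps % stride != 0:
        out_x[n_rec] = x
        n_rec += 1
    return 0, n_rec


@numba.njit(cache=True)
def euler_saturate(c0, c1, c2, c3, x0, dt, tol, max_steps, stride,
                   out_step, out_x):
    """Euler integration until |dx/dt| < tol (saturation).

    Records (step index, x) every `stride` steps plus the initial and final
    points. Returns (status, n_steps_taken, x_end, n_recorded). The step at
    which the saturation test first passes is not taken: elapsed time is
    n_steps_taken * dt.
    """
    x = x0
    out_step[0] = 0
    out_x[0] = x
    n_rec = 1
    for k in range(max_steps):
        f = _drift_eval(c0, c1, c2, c3, x)
        if abs(f) < tol:
            if out_step[n_rec - 1] != k:
                out_step[n_rec] = k
                out_x[n_rec] = x
                n_rec += 1
            return 0, k, x, n_rec
        x = x + dt * f
        if x < 0.0 or x > 1.0:
            return 2, k + 1, x, n_rec
        if (k + 1) % stride == 0:
            out_step[n_rec] = k + 1
            out_x[n_rec] = x
            n_rec += 1
    if out_step[n_rec - 1] != max_steps:
        out_step[n_rec] = max_steps
        out_x[n_rec] = x
        n_rec += 1
    return 1, max_steps, x, n_rec


@numba.njit(cache=True)
def lattice_sweep_block(states, idx, u_left, u_right, alpha, beta):
    """Apply a block of random-sequential single-synapse updates in place.

    states: int8 array, 1 = strong, 0 = weak, periodic chain.
    idx[k]: candidate synapse for update k; u_left/u_right: uniforms deciding
    whether the flanking neurons fire. Each flanking neuron fires with
    probability alpha (beta) when its *other* adjacent synapse is strong
    (weak); the candidate synapse itself never enters the firing probability.
    """
    n = states.shape[0]
    for k in range(idx.shape[0]):
        i = idx[k]
        lt = states[i - 1 if i > 0 else n - 1]
        rt = states[i + 1 if i < n - 1 else 0]
        if lt == rt:
            continue  # unpolarized regardless of activations
        p_l = alpha if lt == 1 else beta
        p_r = alpha if rt == 1 else beta
        fires_l = u_left[k] < p_l
        fires_r = u_right[k] < p_r
        if fires_l == fires_r:
            continue  # both or neither fire: zero polarity
        if (fires_l and lt == 1) or (fires_r and rt == 1):
            states[i] = 1  # only the strong-adjacent neuron fired
        else:
            states[i] = 0  # only the weak-adjacent neuron fired
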