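"""Compiled integration kernel (numba). Mirrors the reference path in
``dynamics`` op for op; the cross-engine equivalence test keeps them honest."""

import numpy as np

try:
    from numba import njit

    NUMBA_AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    NUMBA_AVAILABLE = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def run_steps(u, sigma, step0, n_steps, stride,
              x_centers, t_x, t_y, height, ring_length,
              amp, k, xs, alpha, pref, mob_diag,
              k_t, dt, noise, group, turn_ratio, u_out, s_out):
    """Advance the chain ``n_steps`` steps in place (Heun drift + EM noise).

    ``noise`` holds pre-drawn standard normals, shape (n_steps, N) (empty
    when k_t == 0). Samples land in ``u_out``/``s_out`` whenever the global
    step index is a multiple of ``stride``. Returns 0 on success, 1 if a
    bead overran its trap vertex.
    """
    n = u.shape[0]
    m = np.empty((n, n))
    forces = np.empty(n)
    forces1 = np.empty(n)
    u_pred = np.empty(n)
    half_l = 0.5 * ring_length
    h2 = height * height
    noise_amp = np.sqrt(2.0 * k_t * dt) if k_t > 0.0 else 0.0

    for s in range(n_steps):
        # track-projected wall mobility with minimum image along x
        for i in range(n):
            m[i, i] = mob_diag
            for j in range(i + 1, n):
                if group[i] >= 0 and group[i] != group[j]:
                    m[i, j] = 0.0
                    m[j, i] = 0.0
                    continue
                dx = x_centers[j] - x_centers[i] + (u[j] - u[i]) * t_x
                dx = dx - ring_length * np.floor(dx / ring_length)
                if dx > half_l:
                    dx -= ring_length
                dy = (u[j] - u[i]) * t_y
                r2 = dx * dx + dy * dy
                r = np.sqrt(r2)
                big_r2 = r2 + 4.0 * h2
                big_r = np.sqrt(big_r2)
                rt = dx * t_x + dy * t_y
                rt2 = rt * rt
                g = pref * (
                    1.0 / r + rt2 / (r2 * r)
                    - 1.0 / big_r - rt2 / (big_r2 * big_r)
                    - 2.0 * h2 * (1.0 / (big_r2 * big_r)
                                  - 3.0 * rt2 / (big_r2 * big_r2 * big_r))
                )
                m[i, j] = g
                m[j, i] = g

        for i in range(n):
            vertex = sigma[i] * (0.5 * amp[i] + xs[i])
            rv = vertex - u[i]
            mag = alpha * k[i] * np.abs(rv) ** (alpha - 1.0)
            forces[i] = mag if rv > 0.0 else -mag

        du = np.dot(m, forces)
        for i in range(n):
            u_pred[i] = u[i] + dt * du[i]
        for i in range(n):
            vertex = sigma[i] * (0.5 * amp[i] + xs[i])
            rv = vertex - u_pred[i]
            mag = alpha * k[i] * np.abs(rv) ** (alpha - 1.0)
            forces1[i] = mag if rv > 0.0 else -mag
        du1 = np.dot(m, forces1)
        for i in range(n):
            u[i] += 0.5 * dt * (du[i] + du1[i])

        if noise_amp > 0.0:
            chol = np.linalg.cholesky(m)
            dw = np.dot(chol, noise[s])
            for i in range(n):
                u[i] += noise_amp * dw[i]

        for i in range(n):
            if np.abs(u[i]) > 0.5 * amp[i] + xs[i]:
                return 1
            overshoot = sigma[i] * u[i] - 0.5 * amp[i]
            if overshoot >= 0.0:
                u[i] = sigma[i] * (0.5 * amp[i] - overshoot * turn_ratio[i])
                sigma[i] = -sigma[i]

        g_step = step0 + s + 1
        if g_step % stride == 0:
            row = g_step // stride
            for i in range(n):
                u_out[row, i] = u[i]
                s_out[row, i] = np.int8(sigma[i])

    return 0
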