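"""Low-level RK4 integration kernels for the coupled neural/hemodynamic system.

The hot loop is JIT-compiled with numba when available; a pure-Python build
of the same source is used otherwise (set ``DCMFILL_NO_NUMBA=1`` to force it).
State layout per node: (z, s, f, v, q).  Hemodynamic parameter columns:
(tau, alpha_grubb, E0, V0, tau_s, tau_f, epsilon).
"""

from __future__ import annotations

import os

import numpy as np

try:  # pragma: no cover - exercised implicitly
    if os.environ.get("DCMFILL_NO_NUMBA"):
        raise ImportError
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


# hemodynamic parameter column indices
TAU, ALPHA_G, E0, V0, TAU_S, TAU_F, EPS = range(7)


@njit(cache=True)
def _derivs(z, s, f, v, q, u_t, A, B, C, alpha, hemo,
            dz, ds, df, dv, dq):
    n = z.shape[0]
    m = u_t.shape[0]
    for i in range(n):
        acc = 0.0
        for k in range(n):
            coef = alpha * A[i, k]
            for j in range(m):
                coef += u_t[j] * B[j, i, k]
            acc += coef * z[k]
        for j in range(m):
            acc += C[i, j] * u_t[j]
        dz[i] = acc

        tau = hemo[i, 0]
        ag = hemo[i, 1]
        e0 = hemo[i, 2]
        tau_s = hemo[i, 4]
        tau_f = hemo[i, 5]
        eps = hemo[i, 6]
        fi = f[i]
        vi = v[i]
        ds[i] = eps * z[i] - s[i] / tau_s - (fi - 1.0) / tau_f
        df[i] = s[i]
        vout = vi ** (1.0 / ag)
        dv[i] = (fi - vout) / tau
        ex = (1.0 - (1.0 - e0) ** (1.0 / fi)) / e0
        dq[i] = (fi * ex - vout * q[i] / vi) / tau


@njit(cache=True)
def rk4_integrate(A, B, C, alpha, u, dt, hemo, n_steps):
    """Integrate the coupled system from rest over ``n_steps`` RK4 steps.

    ``u`` is held piecewise-constant over each step.  Returns
    (z_traj, y_traj, bad_step) where trajectories have ``n_steps + 1`` rows
    (including the initial state) and ``bad_step`` is the first step index at
    which the state became non-finite, or -1 on success.
    """
    n = A.shape[0]
    z = np.zeros(n)
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)

    z_traj = np.empty((n_steps + 1, n))
    y_traj = np.empty((n_steps + 1, n))

    k1 = np.empty((5, n))
    k2 = np.empty((5, n))
    k3 = np.empty((5, n))
    k4 = np.empty((5, n))
    zt = np.empty(n)
    st = np.empty(n)
    ft = np.empty(n)
    vt = np.empty(n)
    qt = np.empty(n)

    for i in range(n):
        z_traj[0, i] = 0.0
        e0 = hemo[i, 2]
        v0 = hemo[i, 3]
        y_traj[0, i] = 0.0 * e0 * v0  # rest -> 0

    for step in range(n_steps):
        u_t = u[step]
        _derivs(z, s, f, v, q, u_t, A, B, C, alpha, hemo,
                k1[0], k1[1], k1[2], k1[3], k1[4])
        for i in range(n):
            zt[i] = z[i] + 0.5 * dt * k1[0, i]
            st[i] = s[i] + 0.5 * dt * k1[1, i]
            ft[i] = f[i] + 0.5 * dt * k1[2, i]
            vt[i] = v[i] + 0.5 * dt * k1[3, i]
            qt[i] = q[i] + 0.5 * dt * k1[4, i]
        _derivs(zt, st, ft, vt, qt, u_t, A, B, C, alpha, hemo,
                k2[0], k2[1], k2[2], k2[3], k2[4])
        for i in range(n):
            zt[i] = z[i] + 0.5 * dt * k2[0, i]
            st[i] = s[i] + 0.5 * dt * k2[1, i]
            ft[i] = f[i] + 0.5 * dt * k2[2, i]
            vt[i] = v[i] + 0.5 * dt * k2[3, i]
            qt[i] = q[i] + 0.5 * dt * k2[4, i]
        _derivs(zt, st, ft, vt, qt, u_t, A, B, C, alpha, hemo,
                k3[0], k3[1], k3[2], k3[3], k3[4])
        for i in range(n):
            zt[i] = z[i] + dt * k3[0, i]
            st[i] = s[i] + dt * k3[1, i]
            ft[i] = f[i] + dt * k3[2, i]
            vt[i] = v[i] + dt * k3[3, i]
            qt[i] = q[i] + dt * k3[4, i]
        _derivs(zt, st, ft, vt, qt, u_t, A, B, C, alpha, hemo,
                k4[0], k4[1], k4[2], k4[3], k4[4])

        total = 0.0
        for i in range(n):
            z[i] += dt / 6.0 * (k1[0, i] + 2.0 * k2[0, i] + 2.0 * k3[0, i] + k4[0, i])
            s[i] += dt / 6.0 * (k1[1, i] + 2.0 * k2[1, i] + 2.0 * k3[1, i] + k4[1, i])
            f[i] += dt / 6.0 * (k1[2, i] + 2.0 * k2[2, i] + 2.0 * k3[2, i] + k4[2, i])
            v[i] += dt / 6.0 * (k1[3, i] + 2.0 * k2[3, i] + 2.0 * k3[3, i] + k4[3, i])
            q[i] += dt / 6.0 * (k1[4, i] + 2.0 * k2[4, i] + 2.0 * k3[4, i] + k4[4, i])
            total += z[i] + s[i] + f[i] + v[i] + q[i]
            if f[i] <= 0.0 or v[i] <= 0.0:
                return z_traj, y_traj, step + 1

        if not np.isfinite(total):
            return z_traj, y_traj, step + 1

        for i in range(n):
            z_traj[step + 1, i] = z[i]
            e0 = hemo[i, 2]
            v0 = hemo[i, 3]
            kk1 = 7.0 * e0
            kk2 = 2.0
            kk3 = 2.0 * e0 - 0.2
            y_traj[step + 1, i] = 100.0 * v0 * (
                kk1 * (1.0 - q[i])
                + kk2 * (1.0 - q[i] / v[i])
                + kk3 * (1.0 - v[i])
            )
    return z_traj, y_traj, -1


@njit(cache=True)
def euler_integrate(A, B, C, alpha, u, dt, hemo, n_steps):
    """Forward-Euler reference integrator (used as a convergence oracle)."""
    n = A.shape[0]
    z = np.zeros(n)
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    z_traj = np.empty((n_steps + 1, n))
    y_traj = np.empty((n_steps + 1, n))
    d = np.empty((5, n))
    for i in range(n):
        z_traj[0, i] = 0.0
        y_traj[0, i] = 0.0
    for step in range(n_steps):
        _derivs(z, s, f, v, q, u[step], A, B, C, alpha, hemo,
                d[0], d[1], d[2], d[3], d[4])
        for i in range(n):
            z[i] += dt * d[0, i]
            s[i] += dt * d[1, i]
            f[i] += dt * d[2, i]
            v[i] += dt * d[3, i]
            q[i] += dt * d[4, i]
        for i in range(n):
            z_traj[step + 1, i] = z[i]
            e0 = hemo[i, 2]
            v0 = hemo[i, 3]
            y_traj[step + 1, i] = 100.0 * v0 * (
                7.0 * e0 * (1.0 - q[i])
                + 2.0 * (1.0 - q[i] / v[i])
                + (2.0 * e0 - 0.2) * (1.0 - v[i])
            )
    return z_traj, y_traj, -1
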