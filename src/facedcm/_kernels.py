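"""Numba-compiled core of the batched RK4 integrator.

Mirrors the arithmetic of :func:`facedcm.forward.integrate_batch` exactly;
imported lazily so the package works (more slowly) without numba.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speed-up
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _rhs(z, s, f, lv, lq, A_eff, Cu, kappa, gamma, inv_tau, inv_alpha,
         E0, log1mE0, dz, ds, df, dlv, dlq):
    P, n = z.shape
    for p in range(P):
        for i in range(n):
            zi = min(max(z[p, i], -50.0), 50.0)
            si = min(max(s[p, i], -100.0), 100.0)
            fi = min(max(f[p, i], -100.0), 100.0)
            lvi = min(max(lv[p, i], -5.0), 5.0)
            lqi = min(max(lq[p, i], -10.0), 5.0)
            acc = Cu[p, i]
            for j in range(n):
                zj = min(max(z[p, j], -50.0), 50.0)
                acc += A_eff[p, i, j] * zj
            dz[p, i] = acc
            ds[p, i] = zi - kappa[p, i] * si - gamma[p, i] * (fi - 1.0)
            df[p, i] = si
            fr = fi if fi > 1e-2 else 1e-2
            fv = np.exp(lvi * inv_alpha[p, i])
            a = (fr - fv) * inv_tau[p, i] * np.exp(-lvi)
            E = 1.0 - np.exp(log1mE0[p, i] / fr)
            b = (fr * E / E0[p, i] * np.exp(-lqi)
                 - fv * np.exp(-lvi)) * inv_tau[p, i]
            dlv[p, i] = min(max(a, -1e3), 1e3)
            dlq[p, i] = min(max(b, -1e3), 1e3)


@njit(cache=True)
def rk4_integrate(A, B, C, kappa, gamma, inv_tau, inv_alpha, E0, log1mE0,
                  V0, u, dt, bins_per_scan, n_scans, driving_scale):
    P, n, _ = A.shape
    m = B.shape[1]
    T = n_scans * bins_per_scan

    z = np.zeros((P, n))
    s = np.zeros((P, n))
    f = np.ones((P, n))
    lv = np.zeros((P, n))
    lq = np.zeros((P, n))
    y = np.zeros((P, n_scans, n))

    A_eff = np.empty((P, n, n))
    Cu = np.empty((P, n))
    dz1 = np.empty((P, n)); ds1 = np.empty((P, n)); df1 = np.empty((P, n))
    dlv1 = np.empty((P, n)); dlq1 = np.empty((P, n))
    dz2 = np.empty((P, n)); ds2 = np.empty((P, n)); df2 = np.empty((P, n))
    dlv2 = np.empty((P, n)); dlq2 = np.empty((P, n))
    dz3 = np.empty((P, n)); ds3 = np.empty((P, n)); df3 = np.empty((P, n))
    dlv3 = np.empty((P, n)); dlq3 = np.empty((P, n))
    dz4 = np.empty((P, n)); ds4 = np.empty((P, n)); df4 = np.empty((P, n))
    dlv4 = np.empty((P, n)); dlq4 = np.empty((P, n))
    tz = np.empty((P, n)); ts = np.empty((P, n)); tf = np.empty((P, n))
    tlv = np.empty((P, n)); tlq = np.empty((P, n))

    u_prev_valid = False
    for t_idx in range(T):
        # refresh input-dependent terms when u changes (piecewise constant)
        changed = not u_prev_valid
        if u_prev_valid:
            for k in range(m):
                if u[k, t_idx] != u[k, t_idx - 1]:
                    changed = True
                    break
        if changed:
            for p in range(P):
                for i in range(n):
                    acc = 0.0
                    for k in range(m):
                        acc += C[p, i, k] * u[k, t_idx]
                    Cu[p, i] = driving_scale * acc
                    for j in range(n):
                        a = A[p, i, j]
                        for k in range(m):
                            if u[k, t_idx] != 0.0:
                                a += u[k, t_idx] * B[p, k, i, j]
                        A_eff[p, i, j] = a
            u_prev_valid = True

        if t_idx % bins_per_scan == 0:
            sc = t_idx // bins_per_scan
            for p in range(P):
                for i in range(n):
                    vv = np.exp(lv[p, i])
                    qq = np.exp(lq[p, i])
                    k1c = 7.0 * E0[p, i]
                    k3c = 2.0 * E0[p, i] - 0.2
                    y[p, sc, i] = 100.0 * V0[p, i] * (
                        k1c * (1.0 - qq) + 2.0 * (1.0 - qq / vv)
                        + k3c * (1.0 - vv))

        _rhs(z, s, f, lv, lq, A_eff, Cu, kappa, gamma, inv_tau, inv_alpha,
             E0, log1mE0, dz1, ds1, df1, dlv1, dlq1)
        half = 0.5 * dt
        for p in range(P):
            for i in range(n):
                tz[p, i] = z[p, i] + half * dz1[p, i]
                ts[p, i] = s[p, i] + half * ds1[p, i]
                tf[p, i] = f[p, i] + half * df1[p, i]
                tlv[p, i] = lv[p, i] + half * dlv1[p, i]
                tlq[p, i] = lq[p, i] + half * dlq1[p, i]
        _rhs(tz, ts, tf, tlv, tlq, A_eff, Cu, kappa, gamma, inv_tau,
             inv_alpha, E0, log1mE0, dz2, ds2, df2, dlv2, dlq2)
        for p in range(P):
            for i in range(n):
                tz[p, i] = z[p, i] + half * dz2[p, i]
                ts[p, i] = s[p, i] + half * ds2[p, i]
                tf[p, i] = f[p, i] + half * df2[p, i]
                tlv[p, i] = lv[p, i] + half * dlv2[p, i]
                tlq[p, i] = lq[p, i] + half * dlq2[p, i]
        _rhs(tz, ts, tf, tlv, tlq, A_eff, Cu, kappa, gamma, inv_tau,
             inv_alpha, E0, log1mE0, dz3, ds3, df3, dlv3, dlq3)
        for p in range(P):
            for i in range(n):
                tz[p, i] = z[p, i] + dt * dz3[p, i]
                ts[p, i] = s[p, i] + dt * ds3[p, i]
                tf[p, i] = f[p, i] + dt * df3[p, i]
                tlv[p, i] = lv[p, i] + dt * dlv3[p, i]
                tlq[p, i] = lq[p, i] + dt * dlq3[p, i]
        _rhs(tz, ts, tf, tlv, tlq, A_eff, Cu, kappa, gamma, inv_tau,
             inv_alpha, E0, log1mE0, dz4, ds4, df4, dlv4, dlq4)
        sixth = dt / 6.0
        for p in range(P):
            for i in range(n):
                z[p, i] = min(max(z[p, i] + sixth * (
                    dz1[p, i] + 2.0 * dz2[p, i] + 2.0 * dz3[p, i]
                    + dz4[p, i]), -50.0), 50.0)
                s[p, i] = min(max(s[p, i] + sixth * (
                    ds1[p, i] + 2.0 * ds2[p, i] + 2.0 * ds3[p, i]
                    + ds4[p, i]), -100.0), 100.0)
                f[p, i] = min(max(f[p, i] + sixth * (
                    df1[p, i] + 2.0 * df2[p, i] + 2.0 * df3[p, i]
                    + df4[p, i]), -100.0), 100.0)
                lv[p, i] = min(max(lv[p, i] + sixth * (
                    dlv1[p, i] + 2.0 * dlv2[p, i] + 2.0 * dlv3[p, i]
                    + dlv4[p, i]), -5.0), 5.0)
                lq[p, i] = min(max(lq[p, i] + sixth * (
                    dlq1[p, i] + 2.0 * dlq2[p, i] + 2.0 * dlq3[p, i]
                    + dlq4[p, i]), -10.0), 5.0)
    return y
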