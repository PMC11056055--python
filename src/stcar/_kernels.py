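"""Compiled log-posterior gradient kernels for the centered parameterization.

These mirror, operation for operation, the pure-numpy ``_logp_and_grad_py``
methods of the model classes in :mod:`stcar.models`, fused into single
functions to remove per-call overhead inside leapfrog loops.  The numpy
methods remain the reference implementation; the test suite asserts the two
paths agree to near machine precision on random states.

Each kernel takes the unconstrained parameter vector plus the precomputed
data arrays and returns ``(logp, grad)``; a non-finite state returns
``(-inf, zeros)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ETA_BOUND = 200.0
LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=False, fastmath=False)
def _tail_scalar(t):
    """(value, dvalue/dt) of logit^{-1}; numerically safe at both tails."""
    if t >= 0.0:
        e = np.exp(-t)
        r = 1.0 / (1.0 + e)
    else:
        e = np.exp(t)
        r = e / (1.0 + e)
    return r


@njit(cache=False, fastmath=False)
def _car_unit(phi, rho, k2, L, d):
    """CAR log density pieces: returns (logp, grho, gk2) and writes gphi."""
    n = phi.shape[0]
    u = np.dot(L, phi)
    pl = 0.0
    pp = 0.0
    for i in range(n):
        pl += phi[i] * u[i]
        pp += phi[i] * phi[i]
    lq = 0.0
    gr = 0.0
    for i in range(n):
        qi = rho * d[i] + 1.0 - rho
        lq += np.log(qi)
        gr += (d[i] - 1.0) / qi
    qf = rho * pl + (1.0 - rho) * pp
    logp = 0.5 * lq - 0.5 * n * (LOG2PI + np.log(k2)) - 0.5 * qf / k2
    grho = 0.5 * gr - 0.5 * (pl - pp) / k2
    gk2 = -0.5 * n / k2 + 0.5 * qf / (k2 * k2)
    gphi = -(rho * u + (1.0 - rho) * phi) / k2
    return logp, grho, gk2, gphi


@njit(cache=False, fastmath=False)
def _poisson_ll(eta, y, maskf, lgam):
    """Masked Poisson log likelihood and residual (y - mu) * mask."""
    N, T = eta.shape
    ll = -lgam
    resid = np.empty((N, T))
    ok = True
    for i in range(N):
        for t in range(T):
            e = eta[i, t]
            if np.abs(e) > _ETA_BOUND:
                ok = False
            mu = np.exp(e)
            m = maskf[i, t]
            ll += m * (y[i, t] * e - mu)
            resid[i, t] = (y[i, t] - mu) * m
    return ll, resid, ok


@njit(cache=False, fastmath=False)
def _eta_base(beta, Xf, offset, N, T):
    xb = np.dot(Xf, beta)
    eta = np.empty((N, T))
    for i in range(N):
        for t in range(T):
            eta[i, t] = offset[i, t] + xb[i * T + t]
    return eta


@njit(cache=False, fastmath=False)
def spam_kernel(theta, N, T, p, Xf, y, offset, maskf, lgam,
                Ls, ds, Lt, dt, shp, scl, ig_const, include_lik):
    dim = theta.shape[0]
    grad = np.zeros(dim)
    beta = theta[0:p]
    a = theta[p:p + N]
    b = theta[p + N:p + N + T]
    c = theta[p + N + T:p + N + T + N * T]
    off = p + N + T + N * T
    r_s = _tail_scalar(theta[off])
    r_T = _tail_scalar(theta[off + 1])
    if r_s >= 1.0 or r_T >= 1.0 or r_s <= 0.0 or r_T <= 0.0:
        return -np.inf, grad
    s_s = theta[off + 2]; s_T = theta[off + 3]; s_I = theta[off + 4]
    v_s = np.exp(s_s); v_T = np.exp(s_T); v_I = np.exp(s_I)
    if v_s == 0.0 or v_T == 0.0 or v_I == 0.0 or not (
        np.isfinite(v_s) and np.isfinite(v_T) and np.isfinite(v_I)
    ):
        return -np.inf, grad

    logp = (np.log(r_s) + np.log1p(-r_s) + np.log(r_T) + np.log1p(-r_T)
            + 3.0 * ig_const - shp * (s_s + s_T + s_I)
            - scl * (1.0 / v_s + 1.0 / v_T + 1.0 / v_I))

    lpa, gra, gva, ga = _car_unit(a, r_s, v_s, Ls, ds)
    lpb, grb, gvb, gb = _car_unit(b, r_T, v_T, Lt, dt)
    cc = 0.0
    for i in range(N * T):
        cc += c[i] * c[i]
    logp += lpa + lpb - 0.5 * N * T * (LOG2PI + np.log(v_I)) - 0.5 * cc / v_I
    grad[p:p + N] = ga
    grad[p + N:p + N + T] = gb
    for i in range(N * T):
        grad[p + N + T + i] = -c[i] / v_I
    grad[off] = gra * r_s * (1.0 - r_s) + (1.0 - 2.0 * r_s)
    grad[off + 1] = grb * r_T * (1.0 - r_T) + (1.0 - 2.0 * r_T)
    grad[off + 2] = gva * v_s - shp + scl / v_s
    grad[off + 3] = gvb * v_T - shp + scl / v_T
    grad[off + 4] = (-0.5 * N * T + 0.5 * cc / v_I) - shp + scl / v_I

    if include_lik:
        eta = _eta_base(beta, Xf, offset, N, T)
        for i in range(N):
            for t in range(T):
                eta[i, t] += a[i] + b[t] + c[i * T + t]
        ll, resid, ok = _poisson_ll(eta, y, maskf, lgam)
        if not ok or not np.isfinite(ll):
            return -np.inf, np.zeros(dim)
        logp += ll
        for i in range(N):
            ra = 0.0
            for t in range(T):
                r = resid[i, t]
                ra += r
                grad[p + N + t] += r
                grad[p + N + T + i * T + t] += r
            grad[p + i] += ra
        rf = resid.reshape(N * T)
        for j in range(p):
            g = 0.0
            for k in range(N * T):
                g += Xf[k, j] * rf[k]
            grad[j] += g
    return logp, grad


@njit(cache=False, fastmath=False)
def spltm_kernel(theta, N, T, p, Xf, y, offset, maskf, lgam,
                 Ls, ds, score, shp, scl, ig_const, include_lik):
    dim = theta.shape[0]
    grad = np.zeros(dim)
    beta = theta[0:p]
    om1 = theta[p]
    om2 = theta[p + 1]
    a = theta[p + 2:p + 2 + N]
    b = theta[p + 2 + N:p + 2 + 2 * N]
    off = p + 2 + 2 * N
    r_int = _tail_scalar(theta[off])
    r_slo = _tail_scalar(theta[off + 1])
    if r_int >= 1.0 or r_slo >= 1.0 or r_int <= 0.0 or r_slo <= 0.0:
        return -np.inf, grad
    s_int = theta[off + 2]; s_slo = theta[off + 3]
    v_int = np.exp(s_int); v_slo = np.exp(s_slo)
    if v_int == 0.0 or v_slo == 0.0 or not (
        np.isfinite(v_int) and np.isfinite(v_slo)
    ):
        return -np.inf, grad

    logp = (np.log(r_int) + np.log1p(-r_int) + np.log(r_slo) + np.log1p(-r_slo)
            + 2.0 * ig_const - shp * (s_int + s_slo)
            - scl * (1.0 / v_int + 1.0 / v_slo))

    lpa, gra, gva, ga = _car_unit(a, r_int, v_int, Ls, ds)
    lpb, grb, gvb, gb = _car_unit(b, r_slo, v_slo, Ls, ds)
    logp += lpa + lpb
    grad[p + 2:p + 2 + N] = ga
    grad[p + 2 + N:p + 2 + 2 * N] = gb
    grad[off] = gra * r_int * (1.0 - r_int) + (1.0 - 2.0 * r_int)
    grad[off + 1] = grb * r_slo * (1.0 - r_slo) + (1.0 - 2.0 * r_slo)
    grad[off + 2] = gva * v_int - shp + scl / v_int
    grad[off + 3] = gvb * v_slo - shp + scl / v_slo

    if include_lik:
        eta = _eta_base(beta, Xf, offset, N, T)
        for i in range(N):
            for t in range(T):
                eta[i, t] += om1 + a[i] + (om2 + b[i]) * score[t]
        ll, resid, ok = _poisson_ll(eta, y, maskf, lgam)
        if not ok or not np.isfinite(ll):
            return -np.inf, np.zeros(dim)
        logp += ll
        g1 = 0.0
        g2 = 0.0
        for i in range(N):
            ra = 0.0
            rs = 0.0
            for t in range(T):
                r = resid[i, t]
                ra += r
                rs += r * score[t]
            g1 += ra
            g2 += rs
            grad[p + 2 + i] += ra
            grad[p + 2 + N + i] += rs
        grad[p] += g1
        grad[p + 1] += g2
        rf = resid.reshape(N * T)
        for j in range(p):
            g = 0.0
            for k in range(N * T):
                g += Xf[k, j] * rf[k]
            grad[j] += g
    return logp, grad


@njit(cache=False, fastmath=False)
def stsm_kernel(theta, N, T, p, Xf, y, offset, maskf, lgam,
                Ls, ds, Lt, dt, shp, scl, ig_const, include_lik):
    dim = theta.shape[0]
    grad = np.zeros(dim)
    beta = theta[0:p]
    A = theta[p:p + N * T].reshape(N, T)
    b = theta[p + N * T:p + N * T + T]
    off = p + N * T + T
    r_s = _tail_scalar(theta[off])
    r_T = _tail_scalar(theta[off + 1])
    if r_s >= 1.0 or r_T >= 1.0 or r_s <= 0.0 or r_T <= 0.0:
        return -np.inf, grad
    s_t = theta[off + 2:off + 2 + T]
    v_t = np.exp(s_t)
    s_b = theta[off + 2 + T]
    v_b = np.exp(s_b)
    if v_b == 0.0 or not np.isfinite(v_b):
        return -np.inf, grad
    for t in range(T):
        if v_t[t] == 0.0 or not np.isfinite(v_t[t]):
            return -np.inf, grad

    logp = (np.log(r_s) + np.log1p(-r_s) + np.log(r_T) + np.log1p(-r_T)
            + (T + 1.0) * ig_const - shp * s_b - scl / v_b)
    for t in range(T):
        logp += -shp * s_t[t] - scl / v_t[t]

    U = np.dot(Ls, A)
    lq = 0.0
    grq = 0.0
    for i in range(N):
        qi = r_s * ds[i] + 1.0 - r_s
        lq += np.log(qi)
        grq += (ds[i] - 1.0) / qi
    gr_s = T * 0.5 * grq
    for t in range(T):
        pl = 0.0
        pp = 0.0
        for i in range(N):
            pl += A[i, t] * U[i, t]
            pp += A[i, t] * A[i, t]
        qf = r_s * pl + (1.0 - r_s) * pp
        logp += -0.5 * N * (LOG2PI + np.log(v_t[t])) - 0.5 * qf / v_t[t]
        gr_s += -0.5 * (pl - pp) / v_t[t]
        grad[off + 2 + t] = (-0.5 * N + 0.5 * qf / v_t[t]) - shp + scl / v_t[t]
        for i in range(N):
            grad[p + i * T + t] = -(r_s * U[i, t] + (1.0 - r_s) * A[i, t]) / v_t[t]
    logp += T * 0.5 * lq

    lpb, grb, gvb, gb = _car_unit(b, r_T, v_b, Lt, dt)
    logp += lpb
    grad[p + N * T:p + N * T + T] = gb
    grad[off] = gr_s * r_s * (1.0 - r_s) + (1.0 - 2.0 * r_s)
    grad[off + 1] = grb * r_T * (1.0 - r_T) + (1.0 - 2.0 * r_T)
    grad[off + 2 + T] = gvb * v_b - shp + scl / v_b

    if include_lik:
        eta = _eta_base(beta, Xf, offset, N, T)
        for i in range(N):
            for t in range(T):
                eta[i, t] += A[i, t] + b[t]
        ll, resid, ok = _poisson_ll(eta, y, maskf, lgam)
        if not ok or not np.isfinite(ll):
            return -np.inf, np.zeros(dim)
        logp += ll
        for i in range(N):
            for t in range(T):
                r = resid[i, t]
                grad[p + i * T + t] += r
                grad[p + N * T + t] += r
        rf = resid.reshape(N * T)
        for j in range(p):
            g = 0.0
            for k in range(N * T):
                g += Xf[k, j] * rf[k]
            grad[j] += g
    return logp, grad


@njit(cache=False, fastmath=False)
def tms_kernel(theta, N, T, p, Xf, y, offset, maskf, lgam,
               Ls, ds, shp, scl, ig_const, include_lik):
    dim = theta.shape[0]
    grad = np.zeros(dim)
    beta = theta[0:p]
    A = theta[p:p + N * T].reshape(N, T)
    off = p + N * T
    r_s = _tail_scalar(theta[off])
    r_T = _tail_scalar(theta[off + 1])
    if r_s >= 1.0 or r_T >= 1.0 or r_s <= 0.0 or r_T <= 0.0:
        return -np.inf, grad
    s_k = theta[off + 2]
    k2 = np.exp(s_k)
    if k2 == 0.0 or not np.isfinite(k2):
        return -np.inf, grad

    logp = (np.log(r_s) + np.log1p(-r_s) + np.log(r_T) + np.log1p(-r_T)
            + ig_const - shp * s_k - scl / k2)

    E = np.empty((N, T))
    for i in range(N):
        E[i, 0] = A[i, 0]
        for t in range(1, T):
            E[i, t] = A[i, t] - r_T * A[i, t - 1]
    U = np.dot(Ls, E)
    pl = 0.0
    pp = 0.0
    QE = np.empty((N, T))
    for i in range(N):
        for t in range(T):
            pl += E[i, t] * U[i, t]
            pp += E[i, t] * E[i, t]
            QE[i, t] = r_s * U[i, t] + (1.0 - r_s) * E[i, t]
    lq = 0.0
    grq = 0.0
    for i in range(N):
        qi = r_s * ds[i] + 1.0 - r_s
        lq += np.log(qi)
        grq += (ds[i] - 1.0) / qi
    qf = r_s * pl + (1.0 - r_s) * pp
    logp += T * 0.5 * lq - 0.5 * N * T * (LOG2PI + np.log(k2)) - 0.5 * qf / k2

    gr_T = 0.0
    for i in range(N):
        for t in range(T):
            g = -QE[i, t] / k2
            if t < T - 1:
                g += r_T * QE[i, t + 1] / k2
            grad[p + i * T + t] = g
            if t > 0:
                gr_T += QE[i, t] * A[i, t - 1] / k2
    grad[off + 1] = gr_T * r_T * (1.0 - r_T) + (1.0 - 2.0 * r_T)
    gr_s = T * 0.5 * grq - 0.5 * (pl - pp) / k2
    grad[off] = gr_s * r_s * (1.0 - r_s) + (1.0 - 2.0 * r_s)
    grad[off + 2] = (-0.5 * N * T + 0.5 * qf / k2) - shp + scl / k2

    if include_lik:
        eta = _eta_base(beta, Xf, offset, N, T)
        for i in range(N):
            for t in range(T):
                eta[i, t] += A[i, t]
        ll, resid, ok = _poisson_ll(eta, y, maskf, lgam)
        if not ok or not np.isfinite(ll):
            return -np.inf, np.zeros(dim)
        logp += ll
        for i in range(N):
            for t in range(T):
                grad[p + i * T + t] += resid[i, t]
        rf = resid.reshape(N * T)
        for j in range(p):
            g = 0.0
            for k in range(N * T):
                g += Xf[k, j] * rf[k]
            grad[j] += g
    return logp, grad
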