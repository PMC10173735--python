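"""Compiled numerics: Dormand-Prince 5(4) integration of the model ODEs.

The public simulator (:func:`ctldyn.model.simulate`) integrates with
scipy's stiff-capable LSODA.  Likelihood optimisation, grid search and
posterior sampling need hundreds of thousands of solves, so the same
right-hand sides are compiled here with numba behind an adaptive
embedded Runge-Kutta driver.  Agreement between the two paths is
asserted in the test suite.

Parameter vectors follow :data:`ctldyn.params.PARAM_ORDER`; states are
``(S, G, E, I, P, PL, L, H)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Parameter indices (PARAM_ORDER)
_S0, _SE, _DE, _DI, _KGS, _KSG, _KI, _KE = 0, 1, 2, 3, 4, 5, 6, 7
_KA, _KEX, _KL, _KT, _KP, _DL, _DT, _DP, _DPL = 8, 9, 10, 11, 12, 13, 14, 15, 16

STATUS_OK = 0
STATUS_MAX_STEPS = 1
STATUS_STEP_UNDERFLOW = 2
STATUS_OVERFLOW = 3

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
    [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
    [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
    [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
    [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
    [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
])
_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                -92097 / 339200, 187 / 2100, 1 / 40])

_BIG = 1e12


@njit(cache=True)
def rhs_full_vec(t, y, p, dy):
    """Full-model right-hand side; infiltration is active for t >= 0."""
    S = y[0] if y[0] > 0.0 else 0.0
    G = y[1] if y[1] > 0.0 else 0.0
    E = y[2] if y[2] > 0.0 else 0.0
    I = y[3] if y[3] > 0.0 else 0.0
    P = y[4] if y[4] > 0.0 else 0.0
    PL = y[5] if y[5] > 0.0 else 0.0
    L = y[6] if y[6] > 0.0 else 0.0
    H = y[7] if y[7] > 0.0 else 0.0
    V = S + G

    if E > 0.0 and V > 0.0:
        R = p[_KL] * L / E + p[_KT] * H / E + p[_KP] * (P / E) * (PL / V)
    else:
        R = 0.0
    alpha = 1.0 / (1.0 + p[_KEX] * R)

    if V > 0.0:
        af = 1.0 / (1.0 + p[_KI] * I / V)
        kill = alpha * p[_KE] * E
        frac_s = S / V
        frac_g = G / V
        induct = E * (1.0 + p[_KA] * I / V)
    else:
        af = 1.0
        kill = 0.0
        frac_s = 0.0
        frac_g = 0.0
        induct = E

    dy[0] = p[_KGS] * G * af - p[_KSG] * S - kill * frac_s
    dy[1] = -p[_KGS] * G * af + 2.0 * p[_KSG] * S - kill * frac_g
    s0_eff = p[_S0] if t >= 0.0 else 0.0
    dy[2] = s0_eff * V + alpha * p[_SE] * E - p[_DE] * E
    dy[3] = alpha * E - p[_DI] * I
    dy[4] = induct - p[_DP] * P
    dy[5] = induct - p[_DPL] * PL
    dy[6] = induct - p[_DL] * L
    dy[7] = induct - p[_DT] * H


@njit(cache=True)
def _interp_clamped(t, tk, vk):
    """Piecewise-linear interpolation, clamped to the first/last knot."""
    n = tk.shape[0]
    if t <= tk[0]:
        return vk[0]
    if t >= tk[n - 1]:
        return vk[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tk[mid] <= t:
            lo = mid
        else:
            hi = mid
    w = (t - tk[lo]) / (tk[hi] - tk[lo])
    return vk[lo] * (1.0 - w) + vk[hi] * w


@njit(cache=True)
def rhs_forced_vec(t, y, ke, ki, kgs, ksg, tE, vE, tI, vI, dy):
    """Two-state tumor RHS with CTL and IFNG trajectories as inputs."""
    S = y[0] if y[0] > 0.0 else 0.0
    G = y[1] if y[1] > 0.0 else 0.0
    V = S + G
    E = _interp_clamped(t, tE, vE)
    I = _interp_clamped(t, tI, vI)
    if V > 0.0:
        af = 1.0 / (1.0 + ki * I / V)
        kill = ke * E
        frac_s = S / V
        frac_g = G / V
    else:
        af = 1.0
        kill = 0.0
        frac_s = 0.0
        frac_g = 0.0
    dy[0] = kgs * G * af - ksg * S - kill * frac_s
    dy[1] = -kgs * G * af + 2.0 * ksg * S - kill * frac_g


@njit(cache=True)
def _error_norm(err, y0, y1, rtol, atol, n):
    s = 0.0
    for i in range(n):
        ymax = abs(y0[i]) if abs(y0[i]) > abs(y1[i]) else abs(y1[i])
        sc = atol + rtol * ymax
        e = err[i] / sc
        s += e * e
    return np.sqrt(s / n)


@njit(cache=True)
def integrate_full(p, y0, t0, t_eval, rtol, atol, max_steps):
    """Integrate the full model from t0, sampling at t_eval (sorted, > t0).

    Steps are clipped so that t = 0 (start of CTL infiltration) and every
    requested output time are hit exactly.  Returns ``(out, status)``
    with ``out`` of shape ``(len(t_eval), 8)``.
    """
    n = 8
    n_eval = t_eval.shape[0]
    out = np.empty((n_eval, n))
    y = y0.copy()
    t = t0
    k = np.empty((7, n))
    dy = np.empty(n)
    ytmp = np.empty(n)
    y5 = np.empty(n)
    err = np.empty(n)

    ieval = 0
    while ieval < n_eval and t_eval[ieval] <= t:
        out[ieval] = y
        ieval += 1
    if ieval >= n_eval:
        return out, STATUS_OK

    t_end = t_eval[n_eval - 1]
    h = (t_end - t) / 100.0
    if h <= 0.0:
        return out, STATUS_OK

    rhs_full_vec(t, y, p, dy)
    k[0] = dy
    steps = 0
    while t < t_end:
        steps += 1
        if steps > max_steps:
            return out, STATUS_MAX_STEPS
        # do not step across t=0 (infiltration switch) or an output time
        h_lim = t_eval[ieval] - t
        if t < 0.0 and t + h > 0.0:
            h_lim = min(h_lim, -t)
        if h > h_lim:
            h_use = h_lim
        else:
            h_use = h

        for s in range(1, 7):
            for i in range(n):
                acc = 0.0
                for j in range(s):
                    acc += _A[s, j] * k[j, i]
                ytmp[i] = y[i] + h_use * acc
            rhs_full_vec(t + _C[s] * h_use, ytmp, p, dy)
            k[s] = dy

        ok = True
        for i in range(n):
            acc5 = 0.0
            acc4 = 0.0
            for s in range(7):
                acc5 += _B5[s] * k[s, i]
                acc4 += _B4[s] * k[s, i]
            y5[i] = y[i] + h_use * acc5
            err[i] = h_use * (acc5 - acc4)
            if not np.isfinite(y5[i]) or abs(y5[i]) > _BIG:
                ok = False
        if not ok:
            h *= 0.25
            if h < 1e-13:
                return out, STATUS_OVERFLOW
            continue

        enorm = _error_norm(err, y, y5, rtol, atol, n)
        if enorm <= 1.0:
            t = t + h_use
            for i in range(n):
                # clamp solver-scale negative undershoots
                y[i] = y5[i] if y5[i] > 0.0 else 0.0
            rhs_full_vec(t, y, p, dy)
            k[0] = dy
            while ieval < n_eval and t >= t_eval[ieval] - 1e-12:
                out[ieval] = y
                ieval += 1
            if ieval >= n_eval:
                return out, STATUS_OK
        fac = 0.9 * enorm ** (-0.2) if enorm > 0.0 else 5.0
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h = h_use * fac
        if h < 1e-13:
            return out, STATUS_STEP_UNDERFLOW
    return out, STATUS_OK


@njit(cache=True)
def integrate_forced(ke, ki, kgs, ksg, y0, t0, t_eval, tE, vE, tI, vI,
                     rtol, atol, max_steps):
    """Integrate the input-forced two-state tumor model."""
    n = 2
    n_eval = t_eval.shape[0]
    out = np.empty((n_eval, n))
    y = y0.copy()
    t = t0
    k = np.empty((7, n))
    dy = np.empty(n)
    ytmp = np.empty(n)
    y5 = np.empty(n)
    err = np.empty(n)

    ieval = 0
    while ieval < n_eval and t_eval[ieval] <= t:
        out[ieval] = y
        ieval += 1
    if ieval >= n_eval:
        return out, STATUS_OK

    t_end = t_eval[n_eval - 1]
    h = (t_end - t) / 100.0
    rhs_forced_vec(t, y, ke, ki, kgs, ksg, tE, vE, tI, vI, dy)
    k[0] = dy
    steps = 0
    while t < t_end:
        steps += 1
        if steps > max_steps:
            return out, STATUS_MAX_STEPS
        h_lim = t_eval[ieval] - t
        h_use = h_lim if h > h_lim else h

        for s in range(1, 7):
            for i in range(n):
                acc = 0.0
                for j in range(s):
                    acc += _A[s, j] * k[j, i]
                ytmp[i] = y[i] + h_use * acc
            rhs_forced_vec(t + _C[s] * h_use, ytmp, ke, ki, kgs, ksg,
                           tE, vE, tI, vI, dy)
            k[s] = dy

        ok = True
        for i in range(n):
            acc5 = 0.0
            acc4 = 0.0
            for s in range(7):
                acc5 += _B5[s] * k[s, i]
                acc4 += _B4[s] * k[s, i]
            y5[i] = y[i] + h_use * acc5
            err[i] = h_use * (acc5 - acc4)
            if not np.isfinite(y5[i]) or abs(y5[i]) > _BIG:
                ok = False
        if not ok:
            h *= 0.25
            if h < 1e-13:
                return out, STATUS_OVERFLOW
            continue

        enorm = _error_norm(err, y, y5, rtol, atol, n)
        if enorm <= 1.0:
            t = t + h_use
            for i in range(n):
                y[i] = y5[i] if y5[i] > 0.0 else 0.0
            rhs_forced_vec(t, y, ke, ki, kgs, ksg, tE, vE, tI, vI, dy)
            k[0] = dy
            while ieval < n_eval and t >= t_eval[ieval] - 1e-12:
                out[ieval] = y
                ieval += 1
            if ieval >= n_eval:
                return out, STATUS_OK
        fac = 0.9 * enorm ** (-0.2) if enorm > 0.0 else 5.0
        if fac < 0.2:
            fac = 0.2
        elif fac > 5.0:
            fac = 5.0
        h = h_use * fac
        if h < 1e-13:
            return out, STATUS_STEP_UNDERFLOW
    return out, STATUS_OK


@njit(cache=True)
def forced_loglik(ke, ki, kgs, ksg, y0, t0, t_eval, tE, vE, tI, vI,
                  gr_i0, gr_i1, gr_dt, gr_mean, gr_sd,
                  ratio_idx, ratio_mean, ratio_sd, rtol, atol):
    """Gaussian log likelihood of the forced model at one (ke, ki).

    Growth-rate observations reference volumes at ``t_eval`` indices
    ``gr_i0``/``gr_i1``; ratio observations reference index ``ratio_idx``.
    """
    out, status = integrate_forced(ke, ki, kgs, ksg, y0, t0, t_eval,
                                   tE, vE, tI, vI, rtol, atol, 100000)
    if status != STATUS_OK:
        return -1e12
    ll = 0.0
    for m in range(gr_i0.shape[0]):
        v0 = out[gr_i0[m], 0] + out[gr_i0[m], 1]
        v1 = out[gr_i1[m], 0] + out[gr_i1[m], 1]
        if v0 <= 0.0 or v1 <= 0.0:
            return -1e12
        pred = np.log(v1 / v0) / gr_dt[m]
        r = (pred - gr_mean[m]) / gr_sd[m]
        ll -= 0.5 * r * r
    for m in range(ratio_idx.shape[0]):
        g = out[ratio_idx[m], 1]
        if g <= 0.0:
            return -1e12
        pred = out[ratio_idx[m], 0] / g
        r = (pred - ratio_mean[m]) / ratio_sd[m]
        ll -= 0.5 * r * r
    return ll


@njit(cache=True)
def grid_loglik_surface(ke_grid, ki_grid, kgs, ksg, y0, t0, t_eval,
                        tE, vE, tI, vI,
                        gr_i0, gr_i1, gr_dt, gr_mean, gr_sd,
                        ratio_idx, ratio_mean, ratio_sd, rtol, atol):
    """Exhaustive log-likelihood surface over a (ke, ki) grid."""
    n_ke = ke_grid.shape[0]
    n_ki = ki_grid.shape[0]
    surface = np.empty((n_ke, n_ki))
    for a in range(n_ke):
        for b in range(n_ki):
            surface[a, b] = forced_loglik(
                ke_grid[a], ki_grid[b], kgs, ksg, y0, t0, t_eval,
                tE, vE, tI, vI, gr_i0, gr_i1, gr_dt, gr_mean, gr_sd,
                ratio_idx, ratio_mean, ratio_sd, rtol, atol)
    return surface
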