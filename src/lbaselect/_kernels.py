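"""Numba kernels for the LBA race likelihood.

Single-accumulator first-passage density/CDF use the standard linear
ballistic accumulator closed forms, renormalized for a drift-rate
distribution truncated to positive values (division by Phi(v/sv), the
probability that the accumulator has a positive drift and therefore
finishes). Condition parameters arrive as a (2, 7) matrix per draw with
columns [v_c, v_e, sv_c, sv_e, A, b, t0].
"""

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)


@njit(cache=True, fastmath=True, inline="always")
def _npdf(x):
    return math.exp(-0.5 * x * x) * _INV_SQRT2PI


@njit(cache=True, fastmath=True, inline="always")
def _ncdf(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True, fastmath=True)
def node_pdf(t, b, A, v, sv):
    """First-passage density at decision time t, drift truncated to (0, inf)."""
    if t <= 0.0:
        return 0.0
    denom = _ncdf(v / sv)
    if denom < 1e-300:
        denom = 1e-300
    if A < 1e-12:
        # degenerate start point: finishing time is b / drift
        z = (b / t - v) / sv
        f = _npdf(z) * b / (sv * t * t)
    else:
        ts = t * sv
        z1 = (b - A - t * v) / ts
        z2 = (b - t * v) / ts
        f = (-v * _ncdf(z1) + sv * _npdf(z1) + v * _ncdf(z2) - sv * _npdf(z2)) / A
    f /= denom
    return f if f > 0.0 else 0.0


@njit(cache=True, fastmath=True)
def node_cdf(t, b, A, v, sv):
    """First-passage CDF at decision time t, drift truncated to (0, inf)."""
    if t <= 0.0:
        return 0.0
    denom = _ncdf(v / sv)
    if denom < 1e-300:
        denom = 1e-300
    if A < 1e-12:
        F = _ncdf((v - b / t) / sv)
    else:
        ts = t * sv
        z1 = (b - A - t * v) / ts
        z2 = (b - t * v) / ts
        F = (1.0
             + (b - A - t * v) / A * _ncdf(z1)
             - (b - t * v) / A * _ncdf(z2)
             + ts / A * (_npdf(z1) - _npdf(z2)))
    F /= denom
    if F < 0.0:
        return 0.0
    if F > 1.0:
        return 1.0
    return F


@njit(cache=True, fastmath=True, inline="always")
def _node_pdf_raw(t, b, A, v, sv):
    # untruncated-drift first-passage density (caller divides by Phi(v/sv))
    if A < 1e-12:
        z = (b / t - v) / sv
        return _npdf(z) * b / (sv * t * t)
    ts = t * sv
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    return (-v * _ncdf(z1) + sv * _npdf(z1) + v * _ncdf(z2) - sv * _npdf(z2)) / A


@njit(cache=True, fastmath=True, inline="always")
def _node_cdf_raw(t, b, A, v, sv):
    if A < 1e-12:
        return _ncdf((v - b / t) / sv)
    ts = t * sv
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    return (1.0
            + (b - A - t * v) / A * _ncdf(z1)
            - (b - t * v) / A * _ncdf(z2)
            + ts / A * (_npdf(z1) - _npdf(z2)))


@njit(cache=True, fastmath=True, inline="always")
def _trial_logdens(rt, correct, p, den_c, den_e, floor):
    # p: (7,) row [v_c, v_e, sv_c, sv_e, A, b, t0]; den_* = Phi(v/sv) per node
    t = rt - p[6]
    if t <= 0.0:
        return math.log(floor)
    if correct:
        f = _node_pdf_raw(t, p[5], p[4], p[0], p[2]) / den_c
        F = _node_cdf_raw(t, p[5], p[4], p[1], p[3]) / den_e
    else:
        f = _node_pdf_raw(t, p[5], p[4], p[1], p[3]) / den_e
        F = _node_cdf_raw(t, p[5], p[4], p[0], p[2]) / den_c
    if f < 0.0:
        f = 0.0
    if F < 0.0:
        F = 0.0
    elif F > 1.0:
        F = 1.0
    d = f * (1.0 - F)
    if d < floor:
        d = floor
    return math.log(d)


@njit(cache=True, fastmath=True, inline="always")
def _denominators(cond_params, c):
    den = np.empty((2, 2))
    for cond in range(2):
        p = cond_params[c, cond]
        for node in range(2):
            d = _ncdf(p[node] / p[node + 2])
            den[cond, node] = d if d > 1e-300 else 1e-300
    return den


@njit(cache=True, fastmath=True)
def loglik_chains(cond_params, rt, cond0, correct, floor):
    """Total log-likelihood for each of C parameter draws.

    cond_params: (C, 2, 7); rt: (n,); cond0: (n,) 0-based condition index;
    correct: (n,) boolean. Returns (C,).
    """
    C = cond_params.shape[0]
    n = rt.shape[0]
    out = np.empty(C)
    for c in range(C):
        den = _denominators(cond_params, c)
        s = 0.0
        for i in range(n):
            cond = cond0[i]
            s += _trial_logdens(
                rt[i], correct[i], cond_params[c, cond],
                den[cond, 0], den[cond, 1], floor,
            )
        out[c] = s
    return out


@njit(cache=True, fastmath=True)
def per_trial_loglik(cond_params, rt, cond0, correct, floor):
    """Per-trial log-likelihood matrix for C parameter draws: (C, n)."""
    C = cond_params.shape[0]
    n = rt.shape[0]
    out = np.empty((C, n))
    for c in range(C):
        den = _denominators(cond_params, c)
        for i in range(n):
            cond = cond0[i]
            out[c, i] = _trial_logdens(
                rt[i], correct[i], cond_params[c, cond],
                den[cond, 0], den[cond, 1], floor,
            )
    return out
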