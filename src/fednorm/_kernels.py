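"""Compiled inner loops for the hierarchical likelihood.

The per-observation accumulation (residuals, per-batch gradient sums)
dominates sampling cost; these numba kernels replace the equivalent
vectorized numpy path (kept in ``_model`` as a fallback) and return
bit-compatible quantities up to floating-point summation order.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def homoscedastic_accumulate(phi, y, bidx, theta, inv_s2):
    """Per-batch gradient sums G = sum phi_i r_i / s_b^2 and residual
    sums of squares, in one pass over the (batch-sorted) rows."""
    n, k = phi.shape
    B = theta.shape[0]
    G = np.zeros((B, k))
    ssr = np.zeros(B)
    for i in range(n):
        b = bidx[i]
        mu = 0.0
        for j in range(k):
            mu += phi[i, j] * theta[b, j]
        r = y[i] - mu
        w = r * inv_s2[b]
        for j in range(k):
            G[b, j] += phi[i, j] * w
        ssr[b] += r * r
    return G, ssr


@njit(cache=True)
def heteroscedastic_accumulate(phi, y, bidx, theta, theta_s):
    """Log likelihood (up to the 2*pi constant) and per-batch gradient
    sums for the mean and softplus-noise coefficient blocks."""
    n, k = phi.shape
    B = theta.shape[0]
    G = np.zeros((B, k))
    Gs = np.zeros((B, k))
    ll = 0.0
    for i in range(n):
        b = bidx[i]
        mu = 0.0
        u = 0.0
        for j in range(k):
            mu += phi[i, j] * theta[b, j]
            u += phi[i, j] * theta_s[b, j]
        if u > 30.0:
            s = u
        elif u < -700.0:
            s = 1e-300
        else:
            s = np.log1p(np.exp(u))
            if s < 1e-300:
                s = 1e-300
        r = y[i] - mu
        z = r / s
        ll += -np.log(s) - 0.5 * z * z
        w = r / (s * s)
        sig = 1.0 / (1.0 + np.exp(-u))
        du = sig * (-1.0 / s + (r * r) / (s * s * s))
        for j in range(k):
            G[b, j] += phi[i, j] * w
            Gs[b, j] += phi[i, j] * du
    return ll, G, Gs
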