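"""Numba-compiled inner loops for FG-CNN training.

These fuse the per-batch elementwise work (convolution, batch-norm
normalization, LeakyReLU, pairwise max-pool and their gradients) into single
passes; the public layer functions in :mod:`emgknee.fgcnn` keep plain NumPy
semantics and serve as the independent reference the tests compare against.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def conv_same_fwd(x, W, b, pl):
    """'same' cross-correlation.  x: (B, L, Din); W: (K, Din, Dout)."""
    B, L, Din = x.shape
    K, _, Dout = W.shape
    z = np.empty((B, L, Dout), x.dtype)
    for bi in range(B):
        for l in range(L):
            for o in range(Dout):
                z[bi, l, o] = b[o]
    # k outer with precomputed valid range: branch-free inner loops
    for k in range(K):
        lo = max(0, pl - k)
        hi = min(L, L + pl - k)
        for bi in range(B):
            for l in range(lo, hi):
                src = l + k - pl
                for d in range(Din):
                    xv = x[bi, src, d]
                    for o in range(Dout):
                        z[bi, l, o] += xv * W[k, d, o]
    return z


@njit(cache=True, fastmath=True)
def conv_same_bwd(dz, x, W, pl, need_dx):
    """Gradients of conv_same_fwd w.r.t. input, kernels and bias."""
    B, L, Din = x.shape
    K, _, Dout = W.shape
    dx = np.zeros((B, L, Din), x.dtype)
    dW = np.zeros((K, Din, Dout), x.dtype)
    db = np.zeros(Dout, x.dtype)
    for bi in range(B):
        for l in range(L):
            for o in range(Dout):
                db[o] += dz[bi, l, o]
    for k in range(K):
        lo = max(0, pl - k)
        hi = min(L, L + pl - k)
        for bi in range(B):
            for l in range(lo, hi):
                src = l + k - pl
                for d in range(Din):
                    xv = x[bi, src, d]
                    for o in range(Dout):
                        dW[k, d, o] += xv * dz[bi, l, o]
                if need_dx:
                    for d in range(Din):
                        s = 0.0
                        for o in range(Dout):
                            s += W[k, d, o] * dz[bi, l, o]
                        dx[bi, src, d] += s
    return dx, dW, db


@njit(cache=True)
def bn_stats(z):
    """Per-channel mean and biased variance over batch and length axes."""
    B, L, D = z.shape
    m = B * L
    mu = np.zeros(D)
    var = np.zeros(D)
    for bi in range(B):
        for l in range(L):
            for d in range(D):
                mu[d] += z[bi, l, d]
    for d in range(D):
        mu[d] /= m
    for bi in range(B):
        for l in range(L):
            for d in range(D):
                t = z[bi, l, d] - mu[d]
                var[d] += t * t
    for d in range(D):
        var[d] /= m
    return mu, var


@njit(cache=True, fastmath=True)
def bn_leaky_pool_fwd(z, mu, ivar, gamma, beta, slope):
    """Fused BN-normalize -> affine -> LeakyReLU -> pairwise max-pool.

    Returns (pooled, xhat, zbn, take_first); ties in the pool route to the
    earlier sample.
    """
    B, L, D = z.shape
    Lp = L // 2
    xhat = np.empty((B, L, D), z.dtype)
    zbn = np.empty((B, L, D), z.dtype)
    pooled = np.empty((B, Lp, D), z.dtype)
    take_first = np.empty((B, Lp, D), dtype=np.bool_)
    for bi in range(B):
        for l in range(L):
            for d in range(D):
                xh = (z[bi, l, d] - mu[d]) * ivar[d]
                xhat[bi, l, d] = xh
                zbn[bi, l, d] = gamma[d] * xh + beta[d]
        for i in range(Lp):
            for d in range(D):
                a = zbn[bi, 2 * i, d]
                bv = zbn[bi, 2 * i + 1, d]
                if a <= 0.0:
                    a *= slope
                if bv <= 0.0:
                    bv *= slope
                first = a >= bv
                take_first[bi, i, d] = first
                pooled[bi, i, d] = a if first else bv
    return pooled, xhat, zbn, take_first


@njit(cache=True, fastmath=True)
def bn_leaky_pool_bwd(dout, xhat, zbn, take_first, gamma, slope, ivar):
    """Gradients through the fused stage; returns (dz, dgamma, dbeta, dslope)."""
    B, L, D = xhat.shape
    Lp = L // 2
    m = B * L
    dgamma = np.zeros(D, xhat.dtype)
    dbeta = np.zeros(D, xhat.dtype)
    dslope = xhat.dtype.type(0.0)
    dxhat = np.zeros((B, L, D), xhat.dtype)
    s1 = np.zeros(D, xhat.dtype)  # sum of dxhat
    s2 = np.zeros(D, xhat.dtype)  # sum of dxhat * xhat
    for bi in range(B):
        for i in range(Lp):
            for d in range(D):
                g = dout[bi, i, d]
                l = 2 * i if take_first[bi, i, d] else 2 * i + 1
                v = zbn[bi, l, d]
                if v > 0.0:
                    dz_act = g
                else:
                    dz_act = g * slope
                    dslope += g * v
                dgamma[d] += dz_act * xhat[bi, l, d]
                dbeta[d] += dz_act
                dxh = dz_act * gamma[d]
                dxhat[bi, l, d] = dxh
                s1[d] += dxh
                s2[d] += dxh * xhat[bi, l, d]
    dz = np.empty((B, L, D), xhat.dtype)
    for bi in range(B):
        for l in range(L):
            for d in range(D):
                dz[bi, l, d] = (ivar[d] / m) * (
                    m * dxhat[bi, l, d] - s1[d] - xhat[bi, l, d] * s2[d]
                )
    return dz, dgamma, dbeta, dslope


@njit(cache=True)
def adam_flat(w, g, s, r, t, lr, beta1, beta2, eps):
    """Fused bias-corrected Adam step over flattened parameters (in place)."""
    c1 = w.dtype.type(1.0 - beta1 ** t)
    c2 = w.dtype.type(1.0 - beta2 ** t)
    lr = w.dtype.type(lr)
    beta1 = w.dtype.type(beta1)
    beta2 = w.dtype.type(beta2)
    eps = w.dtype.type(eps)
    one = w.dtype.type(1.0)
    for i in range(w.size):
        s[i] = beta1 * s[i] + (one - beta1) * g[i]
        r[i] = beta2 * r[i] + (one - beta2) * g[i] * g[i]
        w[i] -= lr * (s[i] / c1) / (np.sqrt(r[i] / c2) + eps)
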