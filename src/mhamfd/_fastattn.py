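"""Fused kernels for the masked attention softmax.

The score matrix of one relation is ``e[k, i, j] = LeakyReLU(a[k, i] +
b[k, j])`` softmax-normalised over each target's attended set.  Building it
with numpy takes ~10 full passes over a (heads, n, n) block; these numba
kernels do the forward and the exact backward in one pass each, recomputing
the cheap pre-activation instead of storing intermediates.  A numpy fallback
keeps the module importable without numba.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every forward pass
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False, fastmath=True)
def _alpha_forward_nb(a, b, mask, slope, out):  # pragma: no cover - numba
    K, n = a.shape
    for k in range(K):
        for i in range(n):
            m = -np.inf
            for j in range(n):
                if mask[i, j]:
                    u = a[k, i] + b[k, j]
                    e = u if u > 0.0 else slope * u
                    if e > m:
                        m = e
            if m == -np.inf:
                continue
            s = 0.0
            for j in range(n):
                if mask[i, j]:
                    u = a[k, i] + b[k, j]
                    e = u if u > 0.0 else slope * u
                    v = np.exp(e - m)
                    out[k, i, j] = v
                    s += v
                else:
                    out[k, i, j] = 0.0
            for j in range(n):
                out[k, i, j] /= s


@njit(cache=False, fastmath=True)
def _alpha_backward_nb(a, b, mask, slope, alpha, g, da, db):  # pragma: no cover
    K, n = a.shape
    for k in range(K):
        for i in range(n):
            dot = 0.0
            for j in range(n):
                dot += g[k, i, j] * alpha[k, i, j]
            for j in range(n):
                if mask[i, j]:
                    u = a[k, i] + b[k, j]
                    lg = 1.0 if u > 0.0 else slope
                    du = alpha[k, i, j] * (g[k, i, j] - dot) * lg
                    da[k, i] += du
                    db[k, j] += du


def alpha_forward(
    a: np.ndarray, b: np.ndarray, mask: np.ndarray, slope: float
) -> np.ndarray:
    """Masked attention weights: softmax_j(LeakyReLU(a[k,i] + b[k,j]))."""
    if HAVE_NUMBA:
        out = np.empty((a.shape[0], a.shape[1], b.shape[1]), dtype=a.dtype)
        out[...] = 0.0
        _alpha_forward_nb(a, b, mask, a.dtype.type(slope), out)
        return out
    e = a[:, :, None] + b[:, None, :]
    e = np.where(e > 0, e, slope * e)
    neg = np.where(mask, e, -np.inf)
    m = neg.max(axis=-1, keepdims=True)
    m[~np.isfinite(m)] = 0.0
    p = np.exp(neg - m)
    p[~np.isfinite(p)] = 0.0
    denom = p.sum(axis=-1, keepdims=True)
    denom[denom == 0.0] = 1.0
    return (p / denom).astype(a.dtype)


def alpha_backward(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray,
    slope: float,
    alpha: np.ndarray,
    g: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the masked attention weights w.r.t. the score vectors."""
    if HAVE_NUMBA:
        da = np.zeros_like(a)
        db = np.zeros_like(b)
        _alpha_backward_nb(a, b, mask, a.dtype.type(slope), alpha, g, da, db)
        return da, db
    t = alpha * (g - (g * alpha).sum(axis=-1, keepdims=True))
    u = a[:, :, None] + b[:, None, :]
    du = np.where(mask, t * np.where(u > 0, 1.0, slope), 0.0)
    return du.sum(axis=2).astype(a.dtype), du.sum(axis=1).astype(b.dtype)
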