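"""Fused numeric kernels for the hot inner loops.

Plain NumPy spends most of its time on temporaries in the rank-j Gram
contraction of the pursuit and in the complex soft-threshold; these kernels
fuse the loops.  Everything has a pure-NumPy fallback so the package works
without a JIT compiler.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=False)
def _gram_update_jit(W, v, sel, G, d, out):  # pragma: no cover - compiled
    j, k, M = W.shape[0], W.shape[1], W.shape[2]
    for kk in range(k):
        for m in range(M):
            out[kk, m] = G[kk, sel[m]]
    for r in range(j):
        for kk in range(k):
            for m in range(M):
                out[kk, m] -= W[r, kk, m] * v[r, m]
    for kk in range(k):
        for m in range(M):
            out[kk, m] /= d[m]
    return out


def gram_update(W: np.ndarray, v: np.ndarray, sel: np.ndarray,
                G: np.ndarray, d: np.ndarray) -> np.ndarray:
    """``w_j = (G[:, sel] - sum_r W[r] * v[r]) / d`` without temporaries."""
    k, M = G.shape[0], sel.shape[0]
    if HAVE_NUMBA:
        out = np.empty((k, M), dtype=np.complex128)
        return _gram_update_jit(
            np.ascontiguousarray(W), np.ascontiguousarray(v), sel, G, d, out
        )
    acc = G[:, sel].copy()
    for r in range(W.shape[0]):
        acc -= W[r] * v[r]
    return acc / d


@njit(cache=True)
def omp_columns_jit(h0, G, Gdiag, xnorm2, delta, max_atoms):  # pragma: no cover - compiled
    """Per-column greedy pursuit in the Gram domain.

    For each patch column: select the unused atom with the largest residual
    correlation, extend the Cholesky factor of the support Gram matrix,
    update the residual correlations through the auxiliary rows
    ``w_j = (G[:, sel] - sum_r w_r v_r)/d`` and the residual energy through
    ``|c_j|^2``; stop at the tolerance, the atom cap, or a numerically
    dependent support.  Returns supports, least-squares coefficients, support
    sizes and final squared residuals.
    """
    k, M = h0.shape
    Q = np.full((max_atoms, M), -1, dtype=np.int64)
    coefs = np.zeros((max_atoms, M), dtype=np.complex128)
    nat = np.zeros(M, dtype=np.int64)
    res_out = np.empty(M, dtype=np.float64)

    h = np.empty(k, dtype=np.complex128)
    tmp = np.empty(k, dtype=np.complex128)
    used = np.zeros(k, dtype=np.bool_)
    L = np.zeros((max_atoms, max_atoms), dtype=np.complex128)
    Wc = np.zeros((max_atoms, k), dtype=np.complex128)
    c = np.zeros(max_atoms, dtype=np.complex128)
    v = np.zeros(max_atoms, dtype=np.complex128)
    sup = np.zeros(max_atoms, dtype=np.int64)

    for m in range(M):
        res = xnorm2[m]
        for i in range(k):
            h[i] = h0[i, m]
            used[i] = False
        j = 0
        while res > delta and j < max_atoms:
            best = -1.0
            sel = -1
            for i in range(k):
                if not used[i]:
                    a = abs(h[i])
                    if a > best:
                        best = a
                        sel = i
            if sel < 0:
                break
            for r in range(j):
                acc = G[sup[r], sel]
                for t in range(r):
                    acc -= L[r, t] * v[t]
                v[r] = acc / L[r, r]
            d2 = Gdiag[sel]
            for r in range(j):
                d2 -= v[r].real * v[r].real + v[r].imag * v[r].imag
            lim = Gdiag[sel] if Gdiag[sel] > 1.0 else 1.0
            if d2 <= 1e-12 * lim:
                break  # numerically dependent atom: freeze this patch
            d = np.sqrt(d2)
            accc = h0[sel, m]
            for r in range(j):
                accc -= v[r].conjugate() * c[r]
            cj = accc / d
            for i in range(k):
                tmp[i] = G[i, sel]
            for r in range(j):
                vr = v[r]
                Wr = Wc[r]
                for i in range(k):
                    tmp[i] -= Wr[i] * vr
            Wj = Wc[j]
            for i in range(k):
                wji = tmp[i] / d
                Wj[i] = wji
                h[i] -= wji * cj
            for r in range(j):
                L[j, r] = v[r].conjugate()
            L[j, j] = d
            c[j] = cj
            sup[j] = sel
            used[sel] = True
            res -= cj.real * cj.real + cj.imag * cj.imag
            j += 1
        for r in range(j - 1, -1, -1):
            acc = c[r]
            for t in range(r + 1, j):
                acc -= L[t, r].conjugate() * coefs[t, m]
            coefs[r, m] = acc / L[r, r].conjugate()
        for r in range(j):
            Q[r, m] = sup[r]
        nat[m] = j
        res_out[m] = res if res > 0.0 else 0.0
    return Q, coefs, nat, res_out


@njit(cache=True)
def reconstruct_jit(D, supports, coefs):  # pragma: no cover - compiled
    w2 = D.shape[0]
    max_atoms, N = supports.shape
    out = np.zeros((w2, N), dtype=np.complex128)
    for m in range(N):
        for r in range(max_atoms):
            q = supports[r, m]
            if q < 0:
                break
            cr = coefs[r, m]
            for i in range(w2):
                out[i, m] += D[i, q] * cr
    return out


@njit(cache=True)
def _soft_threshold_jit(v, kappa, out):  # pragma: no cover - compiled
    n = v.size
    vf = v.reshape(n)
    of = out.reshape(n)
    for i in range(n):
        mag = abs(vf[i])
        if mag > kappa:
            of[i] = vf[i] * ((mag - kappa) / mag)
        else:
            of[i] = 0.0
    return out


def soft_threshold(v: np.ndarray, kappa: float) -> np.ndarray:
    """Complex soft-threshold ``max(|v|-kappa, 0) * v/|v|``."""
    v = np.asarray(v)
    if HAVE_NUMBA and v.dtype == np.complex128:
        out = np.empty_like(v)
        _soft_threshold_jit(np.ascontiguousarray(v), float(kappa), out)
        return out
    mag = np.abs(v)
    shrink = np.maximum(mag - kappa, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(mag > 0, shrink * v / np.where(mag > 0, mag, 1.0), 0.0)
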