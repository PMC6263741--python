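"""Complex-domain orthogonal matching pursuit and its tolerance calibration.

Each patch is approximated as a sparse linear combination of dictionary
atoms: greedily select the atom most correlated with the residual, refit the
coefficients by least squares on the selected support, and stop once the
squared residual drops below a tolerance ``delta`` (or an atom cap is hit).

``delta`` is calibrated statistically: if the coding residual is circular
complex Gaussian with per-pixel standard deviation ``sigma_x``, then
``||r||^2 / (sigma_x^2/2)`` is chi-square with ``2 w^2`` degrees of freedom,
so ``delta = (sigma_x^2/2) * F^{-1}_{chi2(2w^2)}(mu)`` keeps a fraction
``mu`` of pure-noise patches below threshold.  ``sigma_x`` itself is
estimated from first-order horizontal/vertical differences of the image with
a robust (MAD) scale estimator.

The pursuit is implemented in batch form over many patches at once using a
precomputed Gram matrix and progressive Cholesky updates, which is what makes
per-iteration coding of thousands of overlapping patches affordable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from ._kernels import HAVE_NUMBA, gram_update, omp_columns_jit, reconstruct_jit

__all__ = [
    "SparseCode",
    "estimate_noise_std",
    "omp_tolerance",
    "omp",
    "batch_omp",
    "code_patches",
    "reconstruct",
]

_MAD_SCALE = 1.4826  # MAD -> std for Gaussian data


@dataclass(frozen=True)
class SparseCode:
    """Support and coefficients of one patch's sparse code."""

    support: tuple[int, ...]
    coefficients: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if len(set(self.support)) != len(self.support):
            raise ValueError("support indices must be unique")
        if any(j < 0 or j >= self.k for j in self.support):
            raise ValueError("support index out of range")

    def dense(self) -> np.ndarray:
        alpha = np.zeros(self.k, dtype=complex)
        alpha[list(self.support)] = self.coefficients
        return alpha


def estimate_noise_std(x: np.ndarray) -> float:
    """Robust per-pixel complex noise standard deviation of an image.

    Pools horizontal and vertical first differences (differencing removes the
    smooth signal, doubling the noise variance, hence the final 1/sqrt(2)),
    applies a median-absolute-deviation scale estimate separately to the real
    and imaginary parts, and combines them in quadrature.  The returned value
    is the standard deviation of the full complex perturbation,
    ``sqrt(E|n|^2)``.
    """
    x = np.asarray(x)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("noise estimation requires a 2-D image with at least 2 rows/cols")
    d = np.concatenate([np.diff(x, axis=0).ravel(), np.diff(x, axis=1).ravel()])

    def _mad(v: np.ndarray) -> float:
        return _MAD_SCALE * float(np.median(np.abs(v - np.median(v))))

    s_re = _mad(d.real)
    s_im = _mad(d.imag) if np.iscomplexobj(x) else 0.0
    return float(np.hypot(s_re, s_im) / np.sqrt(2.0))


def omp_tolerance(sigma_x: float, w: int, mu: float = 0.96) -> float:
    """Chi-square-quantile residual tolerance for a ``w x w`` complex patch."""
    if not 0.0 < mu < 1.0:
        raise ValueError("quantile mu must lie in (0, 1)")
    if sigma_x < 0:
        raise ValueError("sigma_x must be nonnegative")
    return float(0.5 * sigma_x**2 * chi2.ppf(mu, 2 * w * w))


def _back_substitute(Lb: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Solve ``L^H a = c`` for each patch; Lb is (M, j, j), cb is (j, M)."""
    j = cb.shape[0]
    a = np.zeros_like(cb)
    for m in range(j - 1, -1, -1):
        acc = cb[m]
        if m < j - 1:
            acc = acc - np.sum(Lb[:, m + 1 :, m].conj() * a[m + 1 :, :].T, axis=1)
        a[m] = acc / Lb[:, m, m].conj()
    return a


def batch_omp(
    X: np.ndarray,
    D: np.ndarray,
    delta: float,
    max_atoms: int,
    chunk: int = 2048,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Greedy pursuit over all columns of ``X`` simultaneously.

    Returns ``(supports, coefficients, n_atoms, residual_sq)`` where
    ``supports``/``coefficients`` are ``(max_atoms, N)`` arrays (unused slots
    hold -1 / 0) and ``residual_sq`` is the squared coding error per patch.
    Atom selection maximizes ``|d_j^H r|`` with ties broken by lowest index;
    coefficients are the least-squares fit on the selected support,
    maintained through a progressively updated Cholesky factor of the support
    Gram matrix.
    """
    X = np.asarray(X, dtype=complex)
    D = np.asarray(D, dtype=complex)
    if D.ndim != 2 or D.shape[1] == 0:
        raise ValueError("dictionary must be a nonempty (w^2, k) matrix")
    if X.shape[0] != D.shape[0]:
        raise ValueError("patch and atom dimensions differ")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    w2, N = X.shape
    k = D.shape[1]
    max_atoms = min(max_atoms, k, w2)

    G = np.ascontiguousarray(D.conj().T @ D)
    Gdiag = np.ascontiguousarray(G.diagonal().real)

    if HAVE_NUMBA:
        h0 = D.conj().T @ X
        xnorm2 = np.real(np.einsum("ij,ij->j", X.conj(), X))
        Q, al, n, r2 = omp_columns_jit(
            np.ascontiguousarray(h0), G, Gdiag, xnorm2, float(delta), max_atoms
        )
        return Q.astype(np.intp), al, n.astype(np.intp), r2

    supports = np.full((max_atoms, N), -1, dtype=np.intp)
    coefs = np.zeros((max_atoms, N), dtype=complex)
    n_atoms = np.zeros(N, dtype=np.intp)
    res2_all = np.empty(N, dtype=float)

    for lo in range(0, N, chunk):
        sl = slice(lo, min(lo + chunk, N))
        Q, al, n, r2 = _omp_chunk(X[:, sl], D, G, Gdiag, delta, max_atoms)
        supports[:, sl] = Q
        coefs[:, sl] = al
        n_atoms[sl] = n
        res2_all[sl] = r2
    return supports, coefs, n_atoms, res2_all


def _omp_chunk(
    Xc: np.ndarray,
    D: np.ndarray,
    G: np.ndarray,
    Gdiag: np.ndarray,
    delta: float,
    max_atoms: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    # Gram-domain pursuit: with L the Cholesky factor of the support Gram
    # matrix, track c = L^{-1} h0_Q (so the residual energy drops by |c_j|^2
    # at each selection) and W = G[:, Q] L^{-H} (so the residual correlations
    # update rank-one, h <- h - w_j c_j).  Nothing of size w^2 appears inside
    # the loop.
    k = G.shape[0]
    M = Xc.shape[1]
    h0 = D.conj().T @ Xc  # residual correlations at alpha = 0
    h = h0.copy()
    res2 = np.real(np.einsum("ij,ij->j", Xc.conj(), Xc))

    L = np.zeros((M, max_atoms, max_atoms), dtype=complex)
    W = np.zeros((max_atoms, k, M), dtype=complex)
    c = np.zeros((max_atoms, M), dtype=complex)  # forward-substituted h0 on support
    Q = np.full((max_atoms, M), -1, dtype=np.intp)
    used = np.zeros((k, M), dtype=bool)
    n = np.zeros(M, dtype=np.intp)
    frozen = np.zeros(M, dtype=bool)  # numerically dependent supports

    arange_m = np.arange(M)
    # All columns march in lockstep; columns that have met the tolerance ride
    # along with zeroed commits (cheaper than index gathers at every step).
    for j in range(max_atoms):
        live = (res2 > delta) & ~frozen
        if not live.any():
            break
        habs = np.abs(h)
        habs[used] = -1.0
        sel = np.argmax(habs, axis=0)

        if j > 0:
            g = G[Q[:j], sel]  # (j, M) correlations of the new atom with the support
            v = np.zeros((j, M), dtype=complex)
            for r in range(j):
                acc = g[r]
                if r:
                    acc = acc - np.sum(L[:, r, :r].T * v[:r], axis=0)
                v[r] = acc / L[:, r, r]
            d2 = Gdiag[sel] - np.sum(np.abs(v) ** 2, axis=0)
        else:
            v = np.zeros((0, M), dtype=complex)
            d2 = Gdiag[sel].copy()

        ok = d2 > 1e-12 * np.maximum(Gdiag[sel], 1.0)
        frozen |= live & ~ok  # dependent atom: freeze the patch as it is
        commit = live & ok
        if not commit.any():
            continue
        d = np.sqrt(np.maximum(d2, 1e-300))

        if j > 0:
            cj = (h0[sel, arange_m] - np.sum(v.conj() * c[:j], axis=0)) / d
        else:
            cj = h0[sel, arange_m] / d
        wj = gram_update(W[:j], v, sel, G, d)
        cj = np.where(commit, cj, 0.0)
        wj = np.where(commit, wj, 0.0)  # keep retired columns free of garbage
        L[commit, j, :j] = v.conj().T[commit]
        L[:, j, j] = np.where(commit, d, 1.0)
        c[j] = cj
        W[j] = wj
        h -= wj * cj
        res2 -= np.abs(cj) ** 2
        Q[j] = np.where(commit, sel, -1)
        used[sel, arange_m] |= commit
        n += commit

    # final least-squares coefficients; pad unused diagonal so the
    # triangular solve is well defined for patches with fewer atoms
    for r in range(max_atoms):
        pad = n <= r
        if pad.any():
            L[pad, r, r] = 1.0
    coefs = _back_substitute(L, c)
    return Q, coefs, n, np.maximum(res2, 0.0)


def reconstruct(D: np.ndarray, supports: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Patch reconstructions ``D @ alpha`` from batched supports/coefficients."""
    w2 = D.shape[0]
    N = supports.shape[1]
    if HAVE_NUMBA:
        return reconstruct_jit(
            np.ascontiguousarray(D, dtype=np.complex128),
            supports.astype(np.int64),
            np.ascontiguousarray(coefs, dtype=np.complex128),
        )
    out = np.zeros((w2, N), dtype=complex)
    for m in range(supports.shape[0]):
        valid = supports[m] >= 0
        if not valid.any():
            break
        out[:, valid] += D[:, supports[m, valid]] * coefs[m, valid]
    return out


def omp(patch: np.ndarray, D: np.ndarray, delta: float, max_atoms: int = 30) -> SparseCode:
    """Sparse-code a single patch; see :func:`batch_omp` for the rules."""
    patch = np.asarray(patch, dtype=complex).reshape(-1, 1)
    supports, coefs, n, _ = batch_omp(patch, D, delta, max_atoms)
    m = int(n[0])
    return SparseCode(
        support=tuple(int(j) for j in supports[:m, 0]),
        coefficients=coefs[:m, 0].copy(),
        k=D.shape[1],
    )


def code_patches(
    patches: np.ndarray,
    D: np.ndarray,
    delta: float,
    max_atoms: int = 30,
) -> tuple[list[SparseCode], np.ndarray]:
    """OMP-code every patch column; returns the codes and ``D @ alpha_i``."""
    supports, coefs, n, _ = batch_omp(patches, D, delta, max_atoms)
    codes = [
        SparseCode(
            support=tuple(int(j) for j in supports[: n[i], i]),
            coefficients=coefs[: n[i], i].copy(),
            k=D.shape[1],
        )
        for i in range(patches.shape[1])
    ]
    return codes, reconstruct(D, supports, coefs)
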