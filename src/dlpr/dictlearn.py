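"""Complex-domain online dictionary learning.

Alternates two steps over random mini-batches of patches:

1. sparse coding — each batch patch ``x`` is coded by minimizing
   ``||x - D a||_2^2 + lambda ||a||_1`` over complex ``a``, solved by variable
   splitting with an augmented Lagrangian (ADMM with the complex
   soft-threshold as the l1 proximal map);
2. atom update — sufficient statistics ``A += sum a a^H`` and
   ``B += sum x a^H`` are accumulated, and the dictionary columns are updated
   by one sweep of projected block-coordinate descent,
   ``d_j <- Proj_{||.||<=1}( d_j + (b_j - D a_j) / A_jj )``,
   which minimizes the accumulated quadratic surrogate under the unit-ball
   constraint on every atom.

The accumulators make the procedure online: statistics from earlier batches
keep contributing, so a state can be carried across outer iterations of the
retrieval solver (warm start).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import soft_threshold

__all__ = [
    "Dictionary",
    "CODLState",
    "soft_threshold",
    "l1_code",
    "l1_code_batch",
    "update_atoms",
    "surrogate_value",
    "init_dictionary",
    "codl",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class Dictionary:
    """Complex ``w^2 x k`` dictionary with unit-ball-normalized atoms."""

    atoms: np.ndarray

    def __post_init__(self) -> None:
        atoms = np.asarray(self.atoms, dtype=complex)
        if atoms.ndim != 2:
            raise ValueError("dictionary atoms must form a 2-D matrix")
        if not np.all(np.isfinite(atoms)):
            raise ValueError("dictionary contains non-finite entries")
        norms = np.linalg.norm(atoms, axis=0)
        if np.any(norms > 1.0 + _NORM_TOL):
            raise ValueError("atom norms must not exceed 1")
        object.__setattr__(self, "atoms", atoms)

    @property
    def k(self) -> int:
        return self.atoms.shape[1]

    @property
    def patch_dim(self) -> int:
        return self.atoms.shape[0]


def project_unit_ball(atoms: np.ndarray) -> np.ndarray:
    """Scale any column with norm > 1 back onto the unit sphere."""
    norms = np.linalg.norm(atoms, axis=0)
    scale = np.where(norms > 1.0, norms, 1.0)
    return atoms / scale




def l1_code_batch(
    X: np.ndarray,
    D: np.ndarray,
    lam: float,
    inner_iters: int = 100,
    tol: float = 1e-5,
    rho: float | None = None,
) -> tuple[np.ndarray, bool]:
    """l1-regularized coding of every column of ``X`` against ``D``.

    Minimizes ``||x - D a||^2 + lam*||a||_1`` per column by ADMM on the split
    ``a = b``: the quadratic step solves ``(D^H D + rho I) a = D^H x +
    rho (b - d)`` through one cached dense inverse, the l1 step is the complex
    soft-threshold with level ``lam/(2 rho)``.  Iterations stop when the
    relative change of the sparse iterate falls below ``tol``.  Returns the
    sparse iterate and a convergence flag.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X = np.atleast_2d(np.asarray(X, dtype=complex))
    D = np.asarray(D, dtype=complex)
    k = D.shape[1]
    if rho is None:
        rho = max(1.0, 10.0 * lam)
    G = D.conj().T @ D
    # the quadratic step reuses one dense inverse for every iteration/patch
    Winv = np.linalg.inv(G + rho * np.eye(k))
    DtX = D.conj().T @ X

    beta = np.zeros((k, X.shape[1]), dtype=complex)
    dual = np.zeros_like(beta)
    kappa = lam / (2.0 * rho)
    converged = False
    for it in range(inner_iters):
        alpha = Winv @ (DtX + rho * (beta - dual))
        beta_new = soft_threshold(alpha + dual, kappa)
        dual += alpha - beta_new
        if it % 4 == 3 or it == inner_iters - 1:  # convergence check cadence
            num = np.linalg.norm(beta_new - beta)
            den = np.linalg.norm(beta_new) + 1e-30
            if num <= tol * den:
                beta = beta_new
                converged = True
                break
        beta = beta_new
    return beta, converged


def l1_code(
    patch: np.ndarray,
    D: np.ndarray,
    lam: float,
    inner_iters: int = 100,
    tol: float = 1e-5,
) -> np.ndarray:
    """l1 sparse code of a single patch (see :func:`l1_code_batch`)."""
    beta, converged = l1_code_batch(np.asarray(patch).reshape(-1, 1), D, lam, inner_iters, tol)
    if not converged:
        warnings.warn("l1 coding did not reach tolerance; returning best iterate", RuntimeWarning)
    return beta[:, 0]


def update_atoms(D: np.ndarray, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """One projected block-coordinate sweep over the dictionary columns.

    Columns whose accumulated code energy ``A_jj`` is zero are passed through
    unchanged.  Returns a new array; sweeps use the already-updated columns,
    as block-coordinate descent requires.
    """
    D = np.array(D, dtype=complex, copy=True)
    Adiag = A.diagonal().real
    for j in range(D.shape[1]):
        if Adiag[j] <= 1e-15:
            continue
        u = D[:, j] + (B[:, j] - D @ A[:, j]) / Adiag[j]
        nrm = np.linalg.norm(u)
        if nrm > 1.0:
            u = u / nrm
        D[:, j] = u
    return D


def surrogate_value(D: np.ndarray, A: np.ndarray, B: np.ndarray) -> float:
    """Quadratic surrogate ``tr(D^H D A) - 2 Re tr(D^H B)`` (atom-update objective)."""
    return float(np.real(np.einsum("ij,ji->", D.conj().T @ D, A))
                 - 2.0 * np.real(np.einsum("ij,ij->", D.conj(), B)))


def init_dictionary(
    patches: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Initial atoms: random training patches (unit-normalized), padded with
    random unit-norm complex vectors when ``k`` exceeds the patch count."""
    w2, N = patches.shape
    m = min(k, N)
    cols = rng.choice(N, size=m, replace=False)
    D = np.array(patches[:, cols], dtype=complex)
    norms = np.linalg.norm(D, axis=0)
    dead = norms < 1e-12
    if dead.any():
        D[:, dead] = _random_atoms(w2, int(dead.sum()), rng)
        norms = np.linalg.norm(D, axis=0)
    D /= norms
    if k > m:
        D = np.concatenate([D, _random_atoms(w2, k - m, rng)], axis=1)
    return D


def _random_atoms(w2: int, count: int, rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((w2, count)) + 1j * rng.standard_normal((w2, count))
    return a / np.linalg.norm(a, axis=0)


@dataclass
class CODLState:
    """Carrier of the online learning state (dictionary + accumulators)."""

    D: np.ndarray
    lam: float = 0.11
    eta: int = 64
    seed: int = 0
    inner_iters: int = 100
    tol: float = 1e-5
    A: np.ndarray = field(init=False)
    B: np.ndarray = field(init=False)
    t: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=complex)
        k = self.D.shape[1]
        self.A = np.zeros((k, k), dtype=complex)
        self.B = np.zeros((self.D.shape[0], k), dtype=complex)
        self._rng = np.random.default_rng(self.seed)
        self._order: np.ndarray | None = None
        self._pos = 0

    def _next_batch(self, n_patches: int) -> np.ndarray:
        """Mini-batch indices, sampled without replacement within an epoch."""
        eta = min(self.eta, n_patches)
        if self._order is None or len(self._order) != n_patches or self._pos + eta > n_patches:
            self._order = self._rng.permutation(n_patches)
            self._pos = 0
        batch = self._order[self._pos : self._pos + eta]
        self._pos += eta
        return batch

    def step(self, patches: np.ndarray, lam: float | None = None) -> None:
        """One online iteration: code a mini-batch, accumulate, update atoms."""
        lam_eff = self.lam if lam is None else lam
        batch = patches[:, self._next_batch(patches.shape[1])]
        codes, _ = l1_code_batch(batch, self.D, lam_eff, self.inner_iters, self.tol)
        self.A += codes @ codes.conj().T
        self.B += batch @ codes.conj().T
        self.D = update_atoms(self.D, self.A, self.B)
        self._replace_degenerate_atoms(batch, codes)
        self.t += 1

    def _replace_degenerate_atoms(self, batch: np.ndarray, codes: np.ndarray) -> None:
        """Swap near-duplicate or dead atoms for the worst-coded batch patches.

        Mutual coherence close to 1 means two atoms compete for the same
        patch cluster and the factorization has stalled; the less-used twin
        is re-seeded with the current batch patch carrying the largest coding
        residual (its accumulator row/column is cleared so the old statistics
        do not drag it back).  This is the usual maintenance step of online
        dictionary learning; it never increases the surrogate support.
        """
        D = self.D
        norms = np.linalg.norm(D, axis=0)
        gram = np.abs(D.conj().T @ D) / np.outer(np.maximum(norms, 1e-12),
                                                 np.maximum(norms, 1e-12))
        np.fill_diagonal(gram, 0.0)
        usage = self.A.diagonal().real
        residual = batch - D @ codes
        res_norm = np.linalg.norm(residual, axis=0)
        order = np.argsort(res_norm)[::-1]
        cursor = 0
        replace = set(np.nonzero(norms < 1e-12)[0].tolist())
        for j, l in zip(*np.nonzero(gram > 0.98)):
            if j < l and j not in replace and l not in replace:
                replace.add(j if usage[j] <= usage[l] else l)
        for j in sorted(replace):
            if cursor >= batch.shape[1] or res_norm[order[cursor]] < 1e-12:
                break
            patch = batch[:, order[cursor]]
            cursor += 1
            self.D[:, j] = patch / np.linalg.norm(patch)
            self.A[j, :] = 0.0
            self.A[:, j] = 0.0
            self.B[:, j] = 0.0

    def run(self, patches: np.ndarray, T: int, lam: float | None = None) -> np.ndarray:
        for _ in range(T):
            self.step(patches, lam=lam)
        return self.D


def codl(
    patches: np.ndarray,
    k: int = 128,
    T: int = 30,
    eta: int = 64,
    lam: float = 0.11,
    seed: int = 0,
    D_init: Dictionary | np.ndarray | None = None,
) -> Dictionary:
    """Learn a complex dictionary from patches by T online iterations."""
    patches = np.asarray(patches, dtype=complex)
    if k < 1:
        raise ValueError("dictionary must have at least one atom")
    if patches.ndim != 2 or patches.shape[1] < 1:
        raise ValueError("at least one training patch is required")
    rng = np.random.default_rng(seed)
    if D_init is None:
        D0 = init_dictionary(patches, k, rng)
    else:
        D0 = D_init.atoms if isinstance(D_init, Dictionary) else np.asarray(D_init, dtype=complex)
    state = CODLState(D=D0, lam=lam, eta=eta, seed=seed)
    state.run(patches, T)
    return Dictionary(atoms=project_unit_ball(state.D))
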