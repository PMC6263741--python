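"""Alternating-minimization phase retrieval with a learned patch dictionary.

The estimate is refined by cycling through the planes of the optical system:

1. forward propagation ``v_s = A_s x``;
2. a sensor-plane filter replacing each magnitude ``|v_s|`` by the proximity
   operator of the noise negative log-likelihood (Poisson, Gaussian, or exact
   magnitude substitution in the noiseless case) while keeping the phase of
   ``v_s``;
3. backpropagation ``x_half = (1/S) sum_s A_s^H u_s``;
4. object-plane sparse modeling: patches of ``x_half`` are coded on a complex
   dictionary (learned online from those same patches, or supplied as a
   class prior) with the pursuit tolerance calibrated from the estimated
   noise level of ``x_half``;
5. the object update fuses backprojection and coded patches through the
   closed-form diagonal solution of the quadratic subproblem.

Variants: ``dlpr`` (full algorithm, per-iteration dictionary learning),
``prior_plugged`` (fixed pre-trained dictionary, learning skipped) and
``gsf`` (ablation: steps 4-5 skipped entirely, i.e. the Gerchberg-Saxton
loop with sensor-plane filtering only).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .dictlearn import CODLState, Dictionary, init_dictionary, project_unit_ball
from .forward import MaskSet, ObservationSet, backpropagate, propagate
from .patches import PatchGrid, extract_patches, multiplicity_map, scatter_patches
from .sparse import batch_omp, estimate_noise_std, omp_tolerance, reconstruct

__all__ = [
    "DLPRConfig",
    "SolverHistory",
    "SolverDiverged",
    "sensor_update_poisson",
    "sensor_update_noiseless",
    "sensor_update_gaussian",
    "object_update",
    "dlpr",
]

MODES = ("poisson", "gaussian", "noiseless")
VARIANTS = ("dlpr", "prior_plugged", "gsf")


class SolverDiverged(RuntimeError):
    """Raised when an iterate turns non-finite; names the offending step."""


@dataclass(frozen=True)
class DLPRConfig:
    """Solver hyperparameters.

    ``gamma`` (sensor-plane penalty) and ``beta`` (patch-model weight)
    default to the noise-adaptive rules ``gamma = 1/chi, beta = chi/1000``
    for Poisson observations and ``gamma = sigma^2/10, beta = 0.01/sigma^2``
    for Gaussian ones (the product ``beta*gamma = 1e-3`` in both cases, which
    makes the object update patch-dominated); in the noiseless mode only the
    product matters and it defaults to 1e3, i.e. data-dominated, since exact
    intensities need no patch-model smoothing.
    """

    mode: str = "poisson"
    variant: str = "dlpr"
    chi: float | None = None
    sigma: float | None = None
    gamma: float | None = None
    beta: float | None = None
    S: int = 12
    w: int = 10
    stride: int = 1
    iterations: int = 20
    lam: float = 0.11
    T: int = 30
    eta: int = 64
    k: int = 128
    mu: float = 0.96
    max_atoms: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.mode == "poisson" and (self.chi is None or self.chi <= 0):
            raise ValueError("poisson mode requires chi > 0")
        if self.mode == "gaussian" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("gaussian mode requires sigma > 0")
        g, b = self.resolved_gamma_beta()
        if g <= 0 or b <= 0:
            raise ValueError("gamma and beta must be positive")

    def resolved_gamma_beta(self) -> tuple[float, float]:
        if self.mode == "poisson":
            gamma = 1.0 / self.chi if self.gamma is None else self.gamma
            beta = self.chi / 1000.0 if self.beta is None else self.beta
        elif self.mode == "gaussian":
            gamma = self.sigma**2 / 10.0 if self.gamma is None else self.gamma
            beta = 0.01 / self.sigma**2 if self.beta is None else self.beta
        else:
            # exact intensities: trust the backprojection, keep the sparse
            # model as a mild regularizer (beta*gamma large = data-dominated)
            gamma = 1.0 if self.gamma is None else self.gamma
            beta = 1e3 if self.beta is None else self.beta
        return gamma, beta

    def resolved_max_atoms(self) -> int:
        return min(self.w * self.w, 30) if self.max_atoms is None else self.max_atoms


@dataclass
class SolverHistory:
    """Per-iteration diagnostics of one solver run."""

    objective: list[float] = dc_field(default_factory=list)
    rmse: list[float] = dc_field(default_factory=list)
    sensor_residual: list[float] = dc_field(default_factory=list)
    sigma_x: list[float] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.objective)


def sensor_update_poisson(
    v: np.ndarray, z: np.ndarray, gamma: float, chi: float
) -> np.ndarray:
    """Proximity operator of the Poisson data term, applied per pixel.

    The updated magnitude is the positive root of the quadratic stationarity
    condition of ``b^2 chi - z log(b^2 chi) + (1/gamma)(b - |v|)^2``; the
    phase of ``v`` is retained.
    """
    if gamma <= 0 or chi <= 0:
        raise ValueError("gamma and chi must be positive")
    z = np.asarray(z)
    if np.any(z < 0):
        raise ValueError("poisson counts must be nonnegative")
    absv = np.abs(v)
    c = 1.0 + gamma * chi
    b = (absv + np.sqrt(absv**2 + 4.0 * z * gamma * c)) / (2.0 * c)
    return b * _unit_phase(v)


def sensor_update_noiseless(v: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact magnitude substitution ``|u| = sqrt(y)`` keeping the phase of v."""
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("noiseless intensities must be nonnegative")
    return np.sqrt(y) * _unit_phase(v)


def sensor_update_gaussian(
    v: np.ndarray, z: np.ndarray, gamma: float, sigma: float
) -> np.ndarray:
    """Proximity operator of the Gaussian intensity data term.

    The updated magnitude is the nonnegative root of the depressed cubic
    ``b^3 + C b + D = 0`` with ``C = sigma^2/(2 gamma) - z`` and
    ``D = -(sigma^2/(2 gamma)) |v|`` that minimizes
    ``(b^2 - z)^2 / sigma^2 + (b - |v|)^2 / gamma``; negative observations
    are valid inputs.
    """
    if gamma <= 0 or sigma <= 0:
        raise ValueError("gamma and sigma must be positive")
    absv = np.abs(v)
    s2g = sigma**2 / (2.0 * gamma)
    b = _cubic_nonneg_root(s2g - np.asarray(z, dtype=float), -s2g * absv, np.asarray(z, float),
                           absv, sigma, gamma)
    return b * _unit_phase(v)


def _unit_phase(v: np.ndarray) -> np.ndarray:
    """``exp(j angle(v))`` with the zero-phase convention at v = 0."""
    absv = np.abs(v)
    safe = np.where(absv > 0, absv, 1.0)
    return np.where(absv > 0, v / safe, 1.0 + 0.0j)


def _cubic_nonneg_root(
    C: np.ndarray,
    Dc: np.ndarray,
    z: np.ndarray,
    absv: np.ndarray,
    sigma: float,
    gamma: float,
) -> np.ndarray:
    """Nonnegative real root of ``b^3 + C b + Dc`` minimizing the prox objective.

    All three Cardano roots are formed in complex arithmetic, the (near-)real
    nonnegative candidates plus b = 0 are compared on the scalar objective,
    and the winner is polished by a few guarded Newton steps on the cubic.
    """
    C = np.asarray(C, dtype=float)
    Dc = np.asarray(Dc, dtype=float)
    disc = np.asarray(Dc**2 / 4.0 + C**3 / 27.0, dtype=complex)
    s = np.sqrt(disc)
    cube = -Dc / 2.0 + s
    # avoid the degenerate branch where the principal cube root cancels
    alt = -Dc / 2.0 - s
    cube = np.where(np.abs(cube) >= np.abs(alt), cube, alt)
    u = np.where(np.abs(cube) > 0, cube, 1.0) ** (1.0 / 3.0)
    u = np.where(np.abs(cube) > 0, u, 0.0)
    omega = np.exp(2j * np.pi / 3.0)

    def objective(b: np.ndarray) -> np.ndarray:
        return (b**2 - z) ** 2 / sigma**2 + (b - absv) ** 2 / gamma

    best = np.zeros_like(C)
    best_f = objective(best)
    for kk in range(3):
        uk = u * omega**kk
        with np.errstate(divide="ignore", invalid="ignore"):
            root = uk - np.where(np.abs(uk) > 0, C / (3.0 * uk), 0.0)
        cand = np.where(
            (np.abs(root.imag) <= 1e-8 * (1.0 + np.abs(root.real))) & (root.real > 0),
            root.real,
            0.0,
        )
        f = objective(cand)
        take = f < best_f
        best = np.where(take, cand, best)
        best_f = np.where(take, f, best_f)

    # guarded Newton polish on the cubic around the selected root
    b = best
    for _ in range(3):
        fval = b**3 + C * b + Dc
        fprime = 3.0 * b**2 + C
        step = np.where(np.abs(fprime) > 1e-30, fval / np.where(fprime != 0, fprime, 1.0), 0.0)
        b_new = np.clip(b - step, 0.0, None)
        improved = objective(b_new) <= objective(b)
        b = np.where(improved, b_new, b)
    return b


def object_update(
    us: np.ndarray,
    masks: MaskSet,
    patch_numerator: np.ndarray,
    multiplicity: np.ndarray,
    gamma: float,
    beta: float,
) -> np.ndarray:
    """Closed-form object-plane least squares update.

    Solves the normal equations of the quadratic subproblem exactly: the
    system matrix ``beta*gamma * sum_s A_s^H A_s + sum_i R_i^H R_i`` is
    diagonal (``S*beta*gamma + mu_j``), so the update is an elementwise
    division of ``beta*gamma * sum_s A_s^H u_s + patch_numerator``, where
    ``patch_numerator = sum_i R_i^H D alpha_i`` is the un-normalized sum of
    reconstructed patches.  With the default parameter rules ``beta*gamma``
    is 1e-3 for every noise level, so the coded patches dominate the update
    and the backprojection enters as a small data-consistency correction; the
    noise level is accounted for in the sensor filter and in the pursuit
    tolerance rather than here.
    """
    if gamma * beta <= 0:
        raise ValueError("gamma*beta must be positive")
    S = masks.S
    bp = np.zeros(masks.image_shape, dtype=complex)
    for s in range(S):
        bp += backpropagate(us[s], masks.phases[s])
    num = (beta * gamma) * bp + patch_numerator
    den = S * (beta * gamma) + multiplicity
    return num / den


def _initial_estimate(
    obs: ObservationSet,
    masks: MaskSet,
    config: DLPRConfig,
    perturbation: float = 0.25,
    power_iters: int = 50,
) -> np.ndarray:
    """Seeded, mode-dependent initialization.

    Exact intensities: the spectral start — power iterations on the
    intensity-weighted backprojection operator ``x -> sum_s A_s^H diag(z_s)
    A_s x`` from a seeded random field — which is accurate whenever the data
    are informative.  Noisy intensities: a flat field at the global RMS
    amplitude implied by the observed energy (``sum z = S*chi*||x||^2`` in
    expectation for Poisson counts) with a small seeded circular complex
    perturbation; in the photon-starved regime the spectral eigenvector is
    pure noise, whereas the flat field's coherent phase lets the first
    backprojection already carry the scene structure.  The perturbation is
    essential in either case: an exactly real-valued start lies on the
    symmetric saddle between the object and its conjugate twin, where the
    alternating projections stagnate.
    """
    z = np.maximum(obs.z, 0.0)
    energy = z.sum() / masks.S  # estimate of ||x||^2 (in counts for Poisson)
    if config.mode == "poisson":
        energy /= config.chi
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    noise = rng.standard_normal(masks.image_shape) + 1j * rng.standard_normal(masks.image_shape)
    if config.mode == "noiseless":
        x = noise
        for _ in range(power_iters):
            acc = np.zeros_like(x)
            for s in range(masks.S):
                acc += backpropagate(z[s] * propagate(x, masks.phases[s]), masks.phases[s])
            nrm = np.linalg.norm(acc)
            if nrm == 0:
                break
            x = acc / nrm
        return x * np.sqrt(energy)
    amp = np.sqrt(energy / z[0].size)
    return amp * (1.0 + perturbation * noise / np.sqrt(2.0))


def _sensor_filter(v: np.ndarray, obs: ObservationSet, config: DLPRConfig, gamma: float) -> np.ndarray:
    if config.mode == "poisson":
        return sensor_update_poisson(v, obs.z, gamma, config.chi)
    if config.mode == "gaussian":
        return sensor_update_gaussian(v, obs.z, gamma, config.sigma)
    return sensor_update_noiseless(v, obs.z)


def _objective(
    u: np.ndarray,
    v: np.ndarray,
    obs: ObservationSet,
    config: DLPRConfig,
    gamma: float,
    beta: float,
    patch_residual_sq: float,
) -> float:
    """Monitoring value of the variational objective (l0 code term dropped)."""
    data = 0.0
    if config.mode == "poisson":
        theta = np.maximum(np.abs(u) ** 2 * config.chi, 1e-300)
        data = float(np.sum(theta - np.where(obs.z > 0, obs.z * np.log(theta), 0.0)))
    elif config.mode == "gaussian":
        data = float(np.sum((np.abs(u) ** 2 - obs.z) ** 2) / config.sigma**2)
    quad = float(np.sum(np.abs(u - v) ** 2) / gamma)
    return data + quad + beta * patch_residual_sq


def dlpr(
    obs: ObservationSet,
    masks: MaskSet,
    config: DLPRConfig,
    prior: Dictionary | None = None,
    truth: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, Dictionary | None, SolverHistory]:
    """Run the alternating phase retrieval loop.

    Parameters
    ----------
    obs, masks
        The observation stack and the phase masks that produced it.
    config
        Solver settings; ``config.mode`` must match ``obs.noise_model``.
    prior
        Pre-trained dictionary; required by (and only by) the
        ``prior_plugged`` variant.
    truth
        Optional ground-truth complex field; enables the per-iteration
        wrapped-phase RMSE in the returned history.
    x0
        Optional initial estimate overriding the default amplitude
        backprojection (useful for reproducibility studies).

    Returns
    -------
    (estimate, dictionary, history); the dictionary is None for ``gsf``.
    """
    if obs.noise_model != config.mode:
        raise ValueError(
            f"config mode {config.mode!r} does not match observations {obs.noise_model!r}"
        )
    if obs.z.shape[0] != masks.S or obs.z.shape[1:] != masks.image_shape:
        raise ValueError("observations and masks have inconsistent shapes")
    if config.variant == "prior_plugged" and prior is None:
        raise ValueError("the prior_plugged variant requires a pre-trained dictionary")

    from .evaluate import align_global_phase, rmse_phase

    gamma, beta = config.resolved_gamma_beta()
    S = masks.S
    x = _initial_estimate(obs, masks, config) if x0 is None else np.asarray(x0, dtype=complex)
    history = SolverHistory()

    use_patches = config.variant != "gsf"
    grid = mu = codl_state = D = None
    if use_patches:
        grid = PatchGrid(w=config.w, image_shape=masks.image_shape, stride=config.stride)
        mu = multiplicity_map(grid).counts
        if config.variant == "prior_plugged":
            D = prior.atoms
    max_atoms = config.resolved_max_atoms()
    rng_seed = np.random.SeedSequence(config.seed)

    for it in range(config.iterations):
        v = np.stack([propagate(x, masks.phases[s]) for s in range(S)])
        u = _sensor_filter(v, obs, config, gamma)
        x_half = np.zeros(masks.image_shape, dtype=complex)
        for s in range(S):
            x_half += backpropagate(u[s], masks.phases[s])
        x_half /= S
        if not np.all(np.isfinite(x_half)):
            raise SolverDiverged(f"non-finite iterate after backprojection at iteration {it}")

        patch_res_sq = 0.0
        if not use_patches:
            x = x_half
        else:
            P = extract_patches(x_half, grid)
            sig_x = estimate_noise_std(x_half)
            delta = omp_tolerance(sig_x, config.w, config.mu)
            history.sigma_x.append(sig_x)
            if config.variant == "dlpr":
                # the l1 level is calibrated for unit-amplitude objects; scale
                # it with the working amplitude so learning is gain-invariant
                scale = float(np.median(np.abs(x_half)))
                lam_eff = config.lam * max(scale, 1e-12)
                if codl_state is None:
                    init_rng = np.random.default_rng(rng_seed.spawn(1)[0])
                    D0 = init_dictionary(P, config.k, init_rng)
                    # in-loop coding runs at a relaxed tolerance: the batch
                    # statistics are averaged, so near-converged codes suffice
                    codl_state = CODLState(D=D0, lam=config.lam, eta=config.eta,
                                           seed=int(rng_seed.generate_state(1)[0] % (2**31)),
                                           inner_iters=40, tol=1e-4)
                codl_state.run(P, config.T, lam=lam_eff)
                D = project_unit_ball(codl_state.D)
            supports, coefs, _, res2 = batch_omp(P, D, delta, max_atoms)
            recon = reconstruct(D, supports, coefs)
            patch_res_sq = float(res2.sum())
            numerator = scatter_patches(recon, grid)
            x = object_update(u, masks, numerator, mu, gamma, beta)
            if not np.all(np.isfinite(x)):
                raise SolverDiverged(f"non-finite iterate after object update at iteration {it}")

        history.objective.append(
            _objective(u, np.stack([propagate(x, masks.phases[s]) for s in range(S)]),
                       obs, config, gamma, beta, patch_res_sq)
        )
        history.sensor_residual.append(float(np.sqrt(np.sum(np.abs(u - v) ** 2))))
        if truth is not None:
            aligned = align_global_phase(x, truth)
            history.rmse.append(rmse_phase(np.angle(aligned), np.angle(truth)))

    final_dict = Dictionary(atoms=project_unit_ball(D)) if (use_patches and D is not None) else None
    return x, final_dict, history
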