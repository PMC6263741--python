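"""Coded-diffraction-pattern acquisition model.

The object wavefront ``x`` is modulated by a random quaternary phase mask
``M_s`` and propagated to the sensor by a unitary 2-D DFT, ``A_s = F M_s``.
The sensor records the intensity ``y_s = |A_s x|^2`` corrupted either by
photon noise (``z_s ~ Poisson(y_s * chi)``, with ``chi`` photons per unit
intensity) or by additive Gaussian noise (``z_s = y_s + sigma * eps``).

The DFT is unitary in both directions so that the propagation operators
satisfy ``A_s^H A_s = I``; energy is conserved between the object and sensor
planes and back-propagation is the exact adjoint (and inverse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MASK_ALPHABET",
    "MaskSet",
    "ObservationSet",
    "generate_masks",
    "propagate",
    "backpropagate",
    "clean_intensities",
    "observe",
    "snr_global",
]

#: The quaternary phase alphabet of the random masks.
MASK_ALPHABET = (0.0, np.pi / 2.0, -np.pi / 2.0, np.pi)


@dataclass(frozen=True)
class MaskSet:
    """S random phase masks, stored as phases in {0, pi/2, -pi/2, pi}."""

    phases: np.ndarray  # (S, rows, cols)
    seed: int | None = None

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases, dtype=float)
        if phases.ndim != 3 or phases.shape[0] < 1:
            raise ValueError("mask phases must be a (S, rows, cols) array with S >= 1")
        object.__setattr__(self, "phases", phases)

    @property
    def S(self) -> int:
        return self.phases.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.phases.shape[1:]

    @property
    def values(self) -> np.ndarray:
        """Unit-modulus complex mask entries ``exp(1j*phi)``."""
        return np.exp(1j * self.phases)


@dataclass(frozen=True)
class ObservationSet:
    """S sensor intensity images plus the noise model that produced them."""

    z: np.ndarray  # (S, rows, cols)
    noise_model: str  # poisson | gaussian | noiseless
    chi: float | None = None
    sigma: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 3:
            raise ValueError("observations must be a (S, rows, cols) array")
        if self.noise_model not in ("poisson", "gaussian", "noiseless"):
            raise ValueError(f"unknown noise model: {self.noise_model!r}")
        object.__setattr__(self, "z", z)

    @property
    def S(self) -> int:
        return self.z.shape[0]


def generate_masks(S: int, shape: tuple[int, int], seed: int = 0) -> MaskSet:
    """Draw S i.i.d. quaternary phase masks, each value equiprobable."""
    if S < 1:
        raise ValueError("at least one mask is required")
    rng = np.random.default_rng(seed)
    phases = rng.choice(MASK_ALPHABET, size=(S, *shape))
    return MaskSet(phases=phases, seed=seed)


def _check_shape(x: np.ndarray, mask_phase: np.ndarray) -> None:
    if x.shape != mask_phase.shape:
        raise ValueError(f"shape mismatch: field {x.shape} vs mask {mask_phase.shape}")


def propagate(x: np.ndarray, mask_phase: np.ndarray) -> np.ndarray:
    """Object to sensor plane: unitary 2-D DFT of the mask-modulated field."""
    x = np.asarray(x)
    mask_phase = np.asarray(mask_phase)
    _check_shape(x, mask_phase)
    return np.fft.fft2(np.exp(1j * mask_phase) * x, norm="ortho")


def backpropagate(u: np.ndarray, mask_phase: np.ndarray) -> np.ndarray:
    """Sensor to object plane: the exact adjoint (= inverse) of propagate."""
    u = np.asarray(u)
    mask_phase = np.asarray(mask_phase)
    _check_shape(u, mask_phase)
    return np.exp(-1j * mask_phase) * np.fft.ifft2(u, norm="ortho")


def clean_intensities(x: np.ndarray, masks: MaskSet) -> np.ndarray:
    """Noise-free sensor intensities ``y_s = |A_s x|^2`` for every mask."""
    _check_shape(np.asarray(x), masks.phases[0])
    u = np.fft.fft2(masks.values * x[None, :, :], axes=(-2, -1), norm="ortho")
    return np.abs(u) ** 2


def observe(
    x: np.ndarray,
    masks: MaskSet,
    noise_model: str = "poisson",
    chi_or_sigma: float | None = None,
    seed: int = 0,
) -> ObservationSet:
    """Simulate the sensor measurements for every mask.

    Poisson observations are photon counts with mean ``y*chi``; Gaussian
    observations are ``y + sigma*N(0,1)`` and may be negative (they are not
    clipped, which would bias low-SNR pixels); noiseless observations are
    ``y`` exactly.
    """
    y = clean_intensities(x, masks)
    rng = np.random.default_rng(seed)
    if noise_model == "poisson":
        if chi_or_sigma is None or chi_or_sigma <= 0:
            raise ValueError("poisson observations require chi > 0")
        z = rng.poisson(y * chi_or_sigma).astype(float)
        return ObservationSet(z=z, noise_model="poisson", chi=float(chi_or_sigma), seed=seed)
    if noise_model == "gaussian":
        if chi_or_sigma is None or chi_or_sigma < 0:
            raise ValueError("gaussian observations require sigma >= 0")
        z = y + chi_or_sigma * rng.standard_normal(y.shape)
        return ObservationSet(z=z, noise_model="gaussian", sigma=float(chi_or_sigma), seed=seed)
    if noise_model == "noiseless":
        return ObservationSet(z=y, noise_model="noiseless", seed=seed)
    raise ValueError(f"unknown noise model: {noise_model!r}")


def snr_global(x: np.ndarray, masks: MaskSet, chi: float) -> float:
    """Global sensor-plane SNR in dB for Poisson observations.

    ``10 log10( chi * sum(y^2) / sum(y) )`` over all masks and pixels, where
    ``y`` are the clean intensities; per-pixel SNR of a Poisson count with
    mean ``y*chi`` is ``y*chi``, and this is the energy-weighted aggregate.
    """
    if chi <= 0:
        raise ValueError("chi must be positive")
    y = clean_intensities(x, masks)
    total = y.sum()
    if total == 0:
        raise ValueError("all-zero intensities: SNR undefined")
    return float(10.0 * np.log10(chi * (y**2).sum() / total))
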