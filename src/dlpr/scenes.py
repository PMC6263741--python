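"""Synthetic complex-valued test scenes.

A scene is an object wavefront ``x = a * exp(1j * psi)`` with strictly
positive amplitude ``a`` and absolute (unwrapped) phase ``psi`` in radians.
Five canonical phase surfaces are provided (Gaussian bump, octant-truncated
Gaussian, random smooth mountain, centered paraboloid, shear plane) together
with four amplitude-coupling groups that relate the amplitude to the phase:

* group 1 — invariant amplitude, ``a = 1``;
* group 2 — amplitude independent of the phase (a separate surface);
* group 3 — amplitude highly similar to the phase,
  ``a = k0 + k1 * |psi| / max|psi|``;
* group 4 — amplitude weakly similar to the phase,
  ``a = k0 + k1 * |cos(15 psi)|``.

The standard nine-scene test suite pairs these groups with the truncated
Gaussian and shear-plane phases; it is the input of the simulated phase
retrieval studies in :mod:`dlpr.evaluate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SURFACE_KINDS",
    "DEFAULT_PEAK",
    "PhaseSurface",
    "AmplitudeMap",
    "ComplexScene",
    "make_phase_surface",
    "couple_amplitude",
    "make_test_suite",
    "make_prior_surfaces",
]

SURFACE_KINDS = ("gaussian", "truncated_gaussian", "mountain", "quadratic", "shear_plane")

#: Default peak height (radians) of the generated phase surfaces; gives the
#: interferometric phase roughly two full fringes, as in typical wrapped-phase
#: imagery of smooth surfaces.
DEFAULT_PEAK = 12.0

#: Normalized width of the Gaussian bump (fraction of the image half-size).
_GAUSS_WIDTH = 0.35


@dataclass(frozen=True)
class PhaseSurface:
    """Absolute phase ``psi`` in radians on a 2-D pixel grid."""

    values: np.ndarray
    kind: str = "custom"
    peak: float = float("nan")
    seed: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"phase surface must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("phase surface contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class AmplitudeMap:
    """Strictly positive, dimensionless amplitude ``a``."""

    values: np.ndarray
    group: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"amplitude map must be 2-D, got shape {values.shape}")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("amplitude map must be finite and strictly positive")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ComplexScene:
    """Object wavefront ``x = a * exp(1j*psi)`` with its ground truth."""

    field: np.ndarray
    amplitude: AmplitudeMap
    phase: PhaseSurface
    group: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if self.field.shape != self.phase.shape:
            raise ValueError("field shape does not match amplitude/phase")

    @classmethod
    def from_parts(
        cls, amplitude: AmplitudeMap, phase: PhaseSurface, group: int, name: str = ""
    ) -> "ComplexScene":
        field_ = amplitude.values * np.exp(1j * phase.values)
        return cls(field=field_, amplitude=amplitude, phase=phase, group=group, name=name)

    @property
    def shape(self) -> tuple[int, int]:
        return self.field.shape

    @property
    def wrapped_phase(self) -> np.ndarray:
        """Interferometric phase ``angle(x)`` in [-pi, pi)."""
        return np.angle(self.field)


def _grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Normalized coordinates centered on pixel (rows//2, cols//2).

    The center pixel maps exactly to (0, 0) so constructed surfaces attain
    their nominal peak at a pixel.
    """
    rows, cols = shape
    r = (np.arange(rows) - rows // 2) / max(rows // 2, 1)
    c = (np.arange(cols) - cols // 2) / max(cols // 2, 1)
    v, u = np.meshgrid(r, c, indexing="ij")
    return u, v  # u: horizontal (+x right), v: vertical (+ down in row index)


def _gaussian(shape: tuple[int, int], peak: float) -> np.ndarray:
    u, v = _grid(shape)
    return peak * np.exp(-(u**2 + v**2) / (2.0 * _GAUSS_WIDTH**2))


def _octant_mask(shape: tuple[int, int]) -> np.ndarray:
    """True on the *kept* (odd-indexed) angular octants about the center.

    Octants are indexed 0..7 counterclockwise from the +x axis; even-indexed
    octants are removed.  The vertical axis points up (negative row index).
    """
    u, v = _grid(shape)
    theta = np.mod(np.arctan2(-v, u), 2.0 * np.pi)
    octant = np.floor(theta / (np.pi / 4.0)).astype(int) % 8
    return octant % 2 == 1


def _mountain(shape: tuple[int, int], peak: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    u, v = _grid(shape)
    surf = np.zeros(shape, dtype=float)
    for p in range(4):
        for q in range(4):
            if p == 0 and q == 0:
                continue
            amp = rng.normal() / (1.0 + p * p + q * q)
            phase0 = rng.uniform(0.0, 2.0 * np.pi)
            surf += amp * np.cos(np.pi * (p * u + q * v) + phase0)
    surf -= surf.min()
    top = surf.max()
    if top > 0:
        surf *= peak / top
    return surf


def _quadratic(shape: tuple[int, int], peak: float) -> np.ndarray:
    u, v = _grid(shape)
    return peak * np.clip(1.0 - (u**2 + v**2) / 2.0, 0.0, None)


def _shear_plane(shape: tuple[int, int], peak: float) -> np.ndarray:
    u, v = _grid(shape)
    return peak * (u + v + 2.0) / 4.0


def make_phase_surface(
    kind: str,
    size: tuple[int, int],
    peak: float = DEFAULT_PEAK,
    seed: int = 0,
) -> PhaseSurface:
    """Generate one of the canonical absolute-phase surfaces.

    Parameters
    ----------
    kind
        One of ``gaussian``, ``truncated_gaussian``, ``mountain``,
        ``quadratic``, ``shear_plane``.  The truncated Gaussian is the
        Gaussian bump with the four alternate angular octants (about the grid
        center) set to zero; the shear plane is an affine ramp whose total
        rise equals ``peak``; the mountain is a seeded sum of low-frequency
        harmonics.
    size
        (rows, cols) of the surface.
    peak
        Maximum phase value in radians (must be positive).
    seed
        Random seed; only the ``mountain`` family uses it.
    """
    rows, cols = size
    if rows < 2 or cols < 2:
        raise ValueError("surface size must be at least 2x2")
    if peak <= 0:
        raise ValueError("peak must be positive")
    if kind == "gaussian":
        values = _gaussian(size, peak)
    elif kind == "truncated_gaussian":
        values = _gaussian(size, peak)
        values[~_octant_mask(size)] = 0.0
    elif kind == "mountain":
        values = _mountain(size, peak, seed)
    elif kind == "quadratic":
        values = _quadratic(size, peak)
    elif kind == "shear_plane":
        values = _shear_plane(size, peak)
    else:
        raise ValueError(f"unknown phase surface kind: {kind!r} (choose from {SURFACE_KINDS})")
    return PhaseSurface(values=values, kind=kind, peak=peak, seed=seed)


def couple_amplitude(
    psi: PhaseSurface,
    group: int,
    k0: float = 1.0,
    k1: float = 1.0,
    independent_amplitude: AmplitudeMap | np.ndarray | None = None,
) -> AmplitudeMap:
    """Build an amplitude image coupled to the phase per the group rules.

    ``a = k0 + k1 * f(psi)`` with ``f`` depending on the group; group 1 is the
    constant amplitude ``a = 1`` and group 2 uses a supplied independent image
    (shifted to be strictly positive if needed).
    """
    p = psi.values
    if group == 1:
        values = np.ones_like(p)
    elif group == 2:
        if independent_amplitude is None:
            raise ValueError("group 2 requires an independent amplitude image")
        if isinstance(independent_amplitude, AmplitudeMap):
            independent_amplitude = independent_amplitude.values
        values = np.asarray(independent_amplitude, dtype=float)
        lo = values.min()
        if lo <= 0:
            values = values - lo + 1.0
    elif group == 3:
        top = np.max(np.abs(p))
        if top == 0:
            raise ValueError("group 3 amplitude is degenerate for an all-zero phase")
        values = k0 + k1 * np.abs(p) / top
    elif group == 4:
        values = k0 + k1 * np.abs(np.cos(15.0 * p))
    else:
        raise ValueError(f"amplitude group must be 1-4, got {group}")
    return AmplitudeMap(values=values, group=group)


def _rescaled_amplitude(kind: str, size: tuple[int, int], peak: float, seed: int) -> AmplitudeMap:
    """A named surface rescaled to [1, 2], used as an independent amplitude."""
    surf = make_phase_surface(kind, size, peak=peak, seed=seed).values
    return AmplitudeMap(values=1.0 + surf / peak, group=2)


#: (amplitude spec, phase kind, group) for the nine standard scenes.
_SUITE_ROWS = (
    ("constant", "truncated_gaussian", 1),
    ("constant", "shear_plane", 1),
    ("mountain", "shear_plane", 2),
    ("quadratic", "truncated_gaussian", 2),
    ("gaussian", "shear_plane", 2),
    ("highly_similar", "truncated_gaussian", 3),
    ("highly_similar", "shear_plane", 3),
    ("less_similar", "truncated_gaussian", 4),
    ("less_similar", "shear_plane", 4),
)


def make_test_suite(
    size: tuple[int, int] = (100, 100),
    seed: int = 0,
    peak: float = DEFAULT_PEAK,
) -> list[ComplexScene]:
    """The nine standard amplitude/phase pairings, in suite order.

    Rows 1-2 have constant amplitude (group 1); rows 3-5 couple the shear
    plane / truncated Gaussian phases with independent mountain, quadratic and
    Gaussian amplitudes (group 2); rows 6-7 use the highly similar coupling
    (group 3) and rows 8-9 the weakly similar one (group 4).
    """
    scenes: list[ComplexScene] = []
    for idx, (amp_spec, phase_kind, group) in enumerate(_SUITE_ROWS, start=1):
        phase = make_phase_surface(phase_kind, size, peak=peak, seed=seed)
        if group == 2:
            independent = _rescaled_amplitude(amp_spec, size, peak, seed)
            amp = couple_amplitude(phase, 2, independent_amplitude=independent)
        else:
            amp = couple_amplitude(phase, group)
        name = f"{idx}-{amp_spec}-{phase_kind}"
        scenes.append(ComplexScene.from_parts(amp, phase, group, name=name))
    return scenes


def make_prior_surfaces(
    size: tuple[int, int] = (100, 100),
    peak: float = DEFAULT_PEAK,
) -> list[ComplexScene]:
    """Clean class-prior scenes: a Gaussian surface and its four quarters.

    Each quarter keeps the Gaussian bump on one quadrant (about the grid
    center) and is zero elsewhere, producing the sharp fringe discontinuities
    characteristic of truncated surfaces.  All five scenes have unit
    amplitude; they are the training set for the class-specific (prior
    dictionary) retrieval workflow.
    """
    full = _gaussian(size, peak)
    rows, cols = size
    cr, cc = rows // 2, cols // 2
    surfaces = [full]
    for rsel, csel in ((slice(None, cr), slice(None, cc)),
                       (slice(None, cr), slice(cc, None)),
                       (slice(cr, None), slice(None, cc)),
                       (slice(cr, None), slice(cc, None))):
        quarter = np.zeros_like(full)
        quarter[rsel, csel] = full[rsel, csel]
        surfaces.append(quarter)
    scenes = []
    for i, surf in enumerate(surfaces):
        phase = PhaseSurface(values=surf, kind="gaussian_quarter" if i else "gaussian", peak=peak)
        amp = couple_amplitude(phase, 1)
        scenes.append(ComplexScene.from_parts(amp, phase, 1, name=f"prior-{i}"))
    return scenes
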