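"""Overlapping patch extraction and aggregation.

A :class:`PatchGrid` enumerates the top-left positions of all ``w x w``
patches that fit inside an image at a given stride (trailing positions are
included so every pixel is covered).  ``extract_patches`` returns one
column per patch, vectorized column-major within the ``w x w`` block;
``aggregate_patches`` is the exact left inverse: each pixel is the sum of the
contributions of the patches covering it, divided by its multiplicity (the
number of covering patches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchGrid",
    "PixelMultiplicity",
    "extract_patches",
    "scatter_patches",
    "aggregate_patches",
    "multiplicity_map",
]


@dataclass(frozen=True)
class PixelMultiplicity:
    """Per-pixel count of covering patches (diagonal of sum R_i^H R_i)."""

    counts: np.ndarray


@dataclass(frozen=True)
class PatchGrid:
    """Geometry of the overlapping patch decomposition of an image."""

    w: int
    image_shape: tuple[int, int]
    stride: int = 1

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if self.w < 1 or self.stride < 1:
            raise ValueError("patch width and stride must be >= 1")
        if rows < self.w or cols < self.w:
            raise ValueError(
                f"image {self.image_shape} is smaller than the patch width {self.w}"
            )

    @staticmethod
    def _positions(n: int, w: int, stride: int) -> np.ndarray:
        pos = list(range(0, n - w + 1, stride))
        if pos[-1] != n - w:  # keep the trailing patch so the grid covers the image
            pos.append(n - w)
        return np.asarray(pos, dtype=np.intp)

    @property
    def row_positions(self) -> np.ndarray:
        return self._positions(self.image_shape[0], self.w, self.stride)

    @property
    def col_positions(self) -> np.ndarray:
        return self._positions(self.image_shape[1], self.w, self.stride)

    @property
    def index_set(self) -> np.ndarray:
        """(n_patches, 2) top-left (row, col) positions, row-major order."""
        rp, cp = self.row_positions, self.col_positions
        rr, cc = np.meshgrid(rp, cp, indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1)

    @property
    def n_patches(self) -> int:
        return len(self.row_positions) * len(self.col_positions)

    def linear_indices(self) -> np.ndarray:
        """(n_patches, w^2) flat pixel indices of each patch's entries.

        Entries within a patch are ordered column-major (rows fastest), the
        fixed vectorization convention of the package.
        """
        rows, cols = self.image_shape
        w = self.w
        # entry m = i + j*w maps to pixel offset (i, j): rows vary fastest
        jj, ii = np.divmod(np.arange(w * w), w)
        off = ii * cols + jj
        tl = self.index_set
        base = tl[:, 0] * cols + tl[:, 1]
        return base[:, None] + off[None, :]


def extract_patches(x: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Extract all patches of ``x`` as a ``(w^2, n_patches)`` matrix."""
    x = np.asarray(x)
    if x.shape != grid.image_shape:
        raise ValueError(f"image shape {x.shape} does not match grid {grid.image_shape}")
    idx = grid.linear_indices()
    return x.reshape(-1)[idx].T


def scatter_patches(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Sum patches back into image positions (``sum_i R_i^H p_i``, no normalization)."""
    patches = np.asarray(patches)
    if patches.shape != (grid.w**2, grid.n_patches):
        raise ValueError(
            f"patch matrix shape {patches.shape} does not match grid "
            f"({grid.w**2}, {grid.n_patches})"
        )
    idx = grid.linear_indices().ravel()
    n = grid.image_shape[0] * grid.image_shape[1]
    vals = patches.T.ravel()
    if np.iscomplexobj(vals):
        out = np.bincount(idx, weights=vals.real, minlength=n) + 1j * np.bincount(
            idx, weights=vals.imag, minlength=n
        )
    else:
        out = np.bincount(idx, weights=vals, minlength=n)
    return out.reshape(grid.image_shape)


def multiplicity_map(grid: PatchGrid) -> PixelMultiplicity:
    """Number of patches covering each pixel."""
    idx = grid.linear_indices().ravel()
    n = grid.image_shape[0] * grid.image_shape[1]
    counts = np.bincount(idx, minlength=n).reshape(grid.image_shape)
    return PixelMultiplicity(counts=counts)


def aggregate_patches(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Multiplicity-normalized patch aggregation (left inverse of extraction)."""
    counts = multiplicity_map(grid).counts
    if np.any(counts == 0):
        raise ValueError("patch grid does not cover the image: some pixels have no patch")
    return scatter_patches(patches, grid) / counts
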