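"""Binary mathematical morphology.

Implements the operators the segmentation pipeline is built from, directly
from their set definitions on a discrete grid Z^2:

* dilation          A ⊕ B = {c | c = a + b, a ∈ A, b ∈ B}
* erosion           A ⊖ B = {c | c + b ∈ A for every b ∈ B}
* reflection        B̌   = {-b | b ∈ B}
* duality           (A ⊖ B)^c = A^c ⊕ B̌
* decomposition     A ⊖ (B ⊕ C) = (A ⊖ B) ⊖ C
* reconstruction from a marker: the union of the connected components of
  the mask that contain at least one marker pixel.

Structuring elements carry an explicit anchor; offsets are taken relative
to it.  Cells outside the grid are background: erosion treats them as
absent and dilation results are cropped to the grid.  Reconstruction is
computed by component labeling (identical, by definition, to iterated
conditional dilation, which is kept as an independent oracle in the test
suite) and works on 2D slices and slice-stacked 3D volumes alike.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructuringElement:
    """A small binary probe shape with an explicit anchor cell."""

    grid: np.ndarray
    anchor: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", g)
        if g.ndim != 2:
            raise ValueError("structuring element must be 2D")
        if not g.any():
            raise ValueError("structuring element must have at least one true cell")
        ar, ac = self.anchor
        if not (0 <= ar < g.shape[0] and 0 <= ac < g.shape[1]):
            raise ValueError(f"anchor {self.anchor} outside grid of shape {g.shape}")

    @property
    def offsets(self) -> np.ndarray:
        """(n, 2) array of true-cell coordinates relative to the anchor."""
        rr, cc = np.nonzero(self.grid)
        return np.stack([rr - self.anchor[0], cc - self.anchor[1]], axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructuringElement):
            return NotImplemented
        a = {tuple(o) for o in self.offsets}
        b = {tuple(o) for o in other.offsets}
        return a == b


def disk_2x2() -> StructuringElement:
    """The 2x2 disk: geometrically a full 2x2 square, anchored at (0, 0)."""
    return StructuringElement(np.ones((2, 2), dtype=bool), anchor=(0, 0))


def se_from_offsets(offsets) -> StructuringElement:
    """Build a structuring element from a set of (row, col) offsets."""
    off = np.asarray(list(offsets), dtype=int).reshape(-1, 2)
    if off.size == 0:
        raise ValueError("structuring element must have at least one cell")
    # frame must contain the anchor (origin) even if no cell sits on it
    lo = np.minimum(off.min(axis=0), 0)
    hi = np.maximum(off.max(axis=0), 0)
    grid = np.zeros(hi - lo + 1, dtype=bool)
    grid[off[:, 0] - lo[0], off[:, 1] - lo[1]] = True
    return StructuringElement(grid, anchor=(int(-lo[0]), int(-lo[1])))


def _shifted(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate a boolean grid by (dr, dc), zero-filling exposed cells."""
    out = np.zeros_like(a)
    src_r = slice(max(0, -dr), a.shape[0] - max(0, dr))
    src_c = slice(max(0, -dc), a.shape[1] - max(0, dc))
    dst_r = slice(max(0, dr), a.shape[0] - max(0, -dr))
    dst_c = slice(max(0, dc), a.shape[1] - max(0, -dc))
    out[dst_r, dst_c] = a[src_r, src_c]
    return out


def _as_grid(a) -> np.ndarray:
    grid = a.grid if hasattr(a, "grid") else np.asarray(a, dtype=bool)
    if grid.ndim != 2:
        raise ValueError("expected a 2D binary mask")
    return np.asarray(grid, dtype=bool)


def dilate(a, b: StructuringElement) -> np.ndarray:
    """Dilation A ⊕ B, cropped to the grid bounds of ``a``."""
    grid = _as_grid(a)
    out = np.zeros_like(grid)
    for dr, dc in b.offsets:
        out |= _shifted(grid, int(dr), int(dc))
    return out


def erode(a, b: StructuringElement) -> np.ndarray:
    """Erosion A ⊖ B; cells outside the grid count as background."""
    grid = _as_grid(a)
    out = np.ones_like(grid)
    for dr, dc in b.offsets:
        out &= _shifted(grid, -int(dr), -int(dc))
    return out


def reflect(b: StructuringElement) -> StructuringElement:
    """Reflection B̌: every offset negated about the anchor."""
    return se_from_offsets(-b.offsets)


def dilate_se(b: StructuringElement, c: StructuringElement) -> StructuringElement:
    """B ⊕ C as a structuring element (Minkowski sum of offsets)."""
    sums = (b.offsets[:, None, :] + c.offsets[None, :, :]).reshape(-1, 2)
    return se_from_offsets({tuple(s) for s in sums})


def erode_decomposed(a, b: StructuringElement, c: StructuringElement) -> np.ndarray:
    """A ⊖ (B ⊕ C) computed as the chain (A ⊖ B) ⊖ C.

    The grid is padded with background before the first erosion: the
    intermediate image A ⊖ B can be true just outside the original frame
    (where B points back into it), and those cells feed the second
    erosion.  With the padding the chain equals the direct erosion on
    the whole grid, not just away from the borders.
    """
    grid = _as_grid(a)
    pad = int(np.abs(b.offsets).max() + np.abs(c.offsets).max()) + 1
    padded = np.pad(grid, pad, constant_values=False)
    out = erode(erode(padded, b), c)
    return out[pad:-pad, pad:-pad]


# ---------------------------------------------------------------------------
# Reconstruction and hole filling
# ---------------------------------------------------------------------------

_CONNECTIVITY_ALIASES = {
    "face": 1,
    "face+corner": None,  # full connectivity for the dimensionality
    4: 1,
    8: None,
    6: 1,
    26: None,
}


def _structure(ndim: int, connectivity) -> np.ndarray:
    rank = _CONNECTIVITY_ALIASES.get(connectivity, connectivity)
    if rank is None:
        rank = ndim
    return ndimage.generate_binary_structure(ndim, int(rank))


def reconstruct(marker, mask, connectivity="face+corner") -> np.ndarray:
    """Binary reconstruction of ``mask`` from ``marker``.

    Returns the union of the connected components of ``mask`` that contain
    at least one pixel of ``marker``.  Marker cells outside the mask are
    dropped with a warning.  Works for 2D and 3D grids; ``connectivity``
    is ``"face"`` (4/6-neighbour) or ``"face+corner"`` (8/26-neighbour,
    the default).
    """
    marker = np.asarray(marker.grid if hasattr(marker, "grid") else marker, dtype=bool)
    mask = np.asarray(mask.grid if hasattr(mask, "grid") else mask, dtype=bool)
    if marker.shape != mask.shape:
        raise ValueError(f"marker shape {marker.shape} != mask shape {mask.shape}")
    stray = marker & ~mask
    if stray.any():
        warnings.warn(
            f"{int(stray.sum())} marker cell(s) outside the mask were dropped",
            stacklevel=2,
        )
        marker = marker & mask
    if not marker.any():
        return np.zeros_like(mask)
    labels, _ = ndimage.label(mask, structure=_structure(mask.ndim, connectivity))
    hit = np.unique(labels[marker])
    hit = hit[hit > 0]
    return np.isin(labels, hit)


def fill_holes(a, connectivity="face+corner") -> np.ndarray:
    """Fill background regions not connected to the grid border.

    Computed as complement -> reconstruction from a border marker ->
    complement, so a "hole" reachable from the border (even through a
    one-pixel channel) is preserved.
    """
    grid = _as_grid(a)
    background = ~grid
    border = np.zeros_like(background)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    marker = border & background
    if not marker.any():
        return np.ones_like(grid)
    outside = reconstruct(marker, background, connectivity=connectivity)
    return ~outside
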