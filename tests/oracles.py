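"""Independent brute-force oracles for the morphology operators.

These evaluate the set definitions literally (double loops, BFS flood
fill, iterated conditional dilation) and are deliberately slow and
simple; the production code must agree with them exactly.
"""

from collections import deque

import numpy as np
from scipy import ndimage


def brute_dilate(a: np.ndarray, offsets) -> np.ndarray:
    """{c = x + y : x in A, y in B}, cropped to the grid."""
    out = np.zeros_like(a, dtype=bool)
    for r, c in zip(*np.nonzero(a)):
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < a.shape[0] and 0 <= cc < a.shape[1]:
                out[rr, cc] = True
    return out


def brute_erode(a: np.ndarray, offsets) -> np.ndarray:
    """{c : c + y in A for every y in B}; outside the grid is background."""
    out = np.zeros_like(a, dtype=bool)
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            ok = True
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < a.shape[0] and 0 <= cc < a.shape[1] and a[rr, cc]):
                    ok = False
                    break
            out[r, c] = ok
    return out


def _neighbours(shape, pos, full: bool):
    ndim = len(shape)
    for delta in np.ndindex(*([3] * ndim)):
        d = tuple(x - 1 for x in delta)
        if all(x == 0 for x in d):
            continue
        if not full and sum(abs(x) for x in d) != 1:
            continue
        q = tuple(p + x for p, x in zip(pos, d))
        if all(0 <= x < s for x, s in zip(q, shape)):
            yield q


def bfs_components(mask: np.ndarray, full_connectivity: bool = True) -> np.ndarray:
    """Flood-fill component labeling (BFS), 2D or 3D."""
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for pos in zip(*np.nonzero(mask)):
        if labels[pos]:
            continue
        nxt += 1
        labels[pos] = nxt
        q = deque([pos])
        while q:
            p = q.popleft()
            for n in _neighbours(mask.shape, p, full_connectivity):
                if mask[n] and not labels[n]:
                    labels[n] = nxt
                    q.append(n)
    return labels


def component_union_reconstruct(marker, mask, full_connectivity=True) -> np.ndarray:
    """Union of the components of ``mask`` containing a marker pixel."""
    labels = bfs_components(np.asarray(mask, bool), full_connectivity)
    hit = sorted(set(labels[np.asarray(marker, bool) & np.asarray(mask, bool)].tolist()) - {0})
    return np.isin(labels, hit)


def iterative_reconstruct(marker, mask, full_connectivity=True) -> np.ndarray:
    """Iterated conditional dilation of the marker inside the mask."""
    marker = np.asarray(marker, bool) & np.asarray(mask, bool)
    mask = np.asarray(mask, bool)
    structure = ndimage.generate_binary_structure(
        mask.ndim, mask.ndim if full_connectivity else 1
    )
    return ndimage.binary_dilation(marker, structure=structure, iterations=0, mask=mask)


def flood_fill_holes(a: np.ndarray, full_connectivity=True) -> np.ndarray:
    """Fill holes by BFS flood fill of the background from the border."""
    a = np.asarray(a, bool)
    bg = ~a
    seeds = np.zeros_like(bg)
    seeds[0, :] = seeds[-1, :] = True
    seeds[:, 0] = seeds[:, -1] = True
    seeds &= bg
    labels = bfs_components(bg, full_connectivity)
    outside = sorted(set(labels[seeds].tolist()) - {0})
    return a | (bg & ~np.isin(labels, outside))
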