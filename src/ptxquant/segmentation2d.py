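"""Per-slice 2D processing: smoothing, body mask, adaptive HU thresholds.

The stage runs slice by slice:

1. Gaussian smoothing (discretised 5x5 kernel, sigma = 0.5 px) to damp
   noise and texture before thresholding.
2. A fixed threshold Th_M = -500 HU yields a body mask separating the
   patient from surrounding scanner air; morphological hole filling
   restores lung parenchyma and intrathoracic air that the threshold
   removed.
3. The HU histogram of body-masked voxels (whole volume) is analysed to
   place two adaptive cutoffs: Th_A separating air from parenchyma and
   Th_L separating parenchyma from soft tissue.  If the histogram does
   not show the required modes the fixed defaults (-870, -200 HU) are
   used instead.
4. Voxels inside the body mask are labeled AIR (< Th_A) or LUNG
   ([Th_A, Th_L)); the boundary value is assigned upward (LUNG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .morphology import fill_holes

logger = logging.getLogger(__name__)

AIR_LABEL = 1
LUNG_LABEL = 2

#: Histogram design: 10-HU bins over [-1100, 300], modes are local maxima
#: with prominence >= 1% of total mass, cutoffs at the valley minimum
#: between adjacent modes (middle bin on ties).
HIST_RANGE = (-1100.0, 300.0)
HIST_BIN_WIDTH = 10.0
PEAK_PROMINENCE_FRACTION = 0.001
AIR_MODE_MAX_HU = -900.0   # a mode at or below this is "air"
TISSUE_MODE_MIN_HU = -300.0  # a mode at or above this is "soft tissue"


@dataclass(frozen=True)
class ThresholdSet:
    """The three HU cutoffs governing segmentation.

    ``th_m`` bounds the body mask, ``th_a`` separates air from lung
    parenchyma and ``th_l`` separates parenchyma from soft tissue; a
    coherent labeling requires th_a < th_l (air is darkest).  ``th_m``
    is an independent cutoff and normally lies between the two.
    """

    th_m: float = -500.0
    th_a: float = -870.0
    th_l: float = -200.0
    source: str = "fixed_default"

    def __post_init__(self) -> None:
        if not (self.th_a < self.th_l):
            raise ValueError(
                f"incoherent thresholds: need th_a < th_l, got "
                f"({self.th_a}, {self.th_l})"
            )


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian pre-filter: sigma in pixels, odd kernel size."""

    sigma: float = 0.5
    kernel_size: tuple[int, int] = (5, 5)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if any(k < 1 for k in self.kernel_size):
            raise ValueError(f"kernel size must be >= 1, got {self.kernel_size}")


def gaussian_kernel(p: SmoothingParams) -> np.ndarray:
    """Discretised, renormalised Gaussian g(x, y) sampled on the kernel grid."""
    kr, kc = p.kernel_size
    ys = np.arange(kr) - (kr - 1) / 2.0
    xs = np.arange(kc) - (kc - 1) / 2.0
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    k = np.exp(-(xx**2 + yy**2) / (2.0 * p.sigma**2)) / (2.0 * np.pi * p.sigma**2)
    return k / k.sum()


def gaussian_smooth(slice_hu: np.ndarray, p: SmoothingParams | None = None) -> np.ndarray:
    """Convolve one slice with the truncated normalised Gaussian kernel."""
    p = p or SmoothingParams()
    slice_hu = np.asarray(slice_hu, dtype=np.float64)
    if slice_hu.ndim != 2:
        raise ValueError("gaussian_smooth operates on a single 2D slice")
    return ndimage.convolve(slice_hu, gaussian_kernel(p), mode="reflect")


def smooth_volume(voxels: np.ndarray, p: SmoothingParams | None = None) -> np.ndarray:
    """Apply :func:`gaussian_smooth` slice by slice along axis 0."""
    return np.stack([gaussian_smooth(s, p) for s in voxels], axis=0)


def body_mask(slice_hu: np.ndarray, t: ThresholdSet | None = None) -> np.ndarray:
    """Extract the body region of one (smoothed) slice.

    Threshold at Th_M, keep the largest connected region, then fill holes
    so lung parenchyma and intrathoracic air stay inside the mask.
    Returns an all-false mask (with a warning) if the slice contains no
    body voxels.
    """
    t = t or ThresholdSet()
    raw = np.asarray(slice_hu) >= t.th_m
    if not raw.any():
        logger.warning("slice contains no voxels >= Th_M=%g HU; empty body mask", t.th_m)
        return raw
    labels, n = ndimage.label(raw, structure=ndimage.generate_binary_structure(2, 2))
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (int(np.argmax(sizes)) + 1)
    return fill_holes(raw)


def body_mask_volume(voxels: np.ndarray, t: ThresholdSet | None = None) -> np.ndarray:
    """Per-slice body masks stacked into a 3D mask."""
    return np.stack([body_mask(s, t) for s in voxels], axis=0)


def _valley_cut(counts: np.ndarray, centers: np.ndarray, i: int, j: int) -> float:
    """HU value of the minimum-count valley strictly between peaks i < j.

    On ties (a flat near-empty gap between well-separated modes) the
    middle tied bin is used, keeping the cut centred in the gap.
    """
    seg = counts[i + 1 : j]
    ties = np.flatnonzero(seg == seg.min())
    mid = ties[len(ties) // 2]
    return float(centers[i + 1 + mid])


def estimate_thresholds(
    voxels_hu: np.ndarray,
    mask: np.ndarray,
    defaults: ThresholdSet | None = None,
) -> ThresholdSet:
    """Adaptive Th_A/Th_L from the body-masked HU histogram.

    Locates the air mode (near -1000 HU), the parenchyma mode between air
    and tissue, and the soft-tissue mode (near 0-60 HU); Th_A and Th_L are
    the valley minima between adjacent modes.  Falls back to ``defaults``
    (source tagged ``fixed_default``) when fewer than three modes are
    found. Only the histogram of masked voxels is used, so the estimate is
    invariant to voxel order.
    """
    from scipy.signal import find_peaks

    defaults = defaults or ThresholdSet()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot estimate thresholds from an empty mask")
    values = np.asarray(voxels_hu, dtype=np.float64)[mask]
    nbins = int(round((HIST_RANGE[1] - HIST_RANGE[0]) / HIST_BIN_WIDTH))
    counts, edges = np.histogram(values, bins=nbins, range=HIST_RANGE)
    centers = (edges[:-1] + edges[1:]) / 2.0

    peaks, _ = find_peaks(counts, prominence=PEAK_PROMINENCE_FRACTION * counts.sum())
    air = [p for p in peaks if centers[p] <= AIR_MODE_MAX_HU]
    tissue = [p for p in peaks if centers[p] >= TISSUE_MODE_MIN_HU]
    mid = [p for p in peaks if AIR_MODE_MAX_HU < centers[p] < TISSUE_MODE_MIN_HU]
    if not (air and tissue and mid):
        logger.info(
            "histogram not trimodal (%d air / %d parenchyma / %d tissue modes); "
            "falling back to fixed thresholds (%g, %g)",
            len(air), len(mid), len(tissue), defaults.th_a, defaults.th_l,
        )
        return replace(defaults, source="fixed_default")

    air_pk = max(air, key=lambda p: counts[p])
    tis_pk = max(tissue, key=lambda p: counts[p])
    par_pk = max(mid, key=lambda p: counts[p])
    th_a = _valley_cut(counts, centers, air_pk, par_pk)
    th_l = _valley_cut(counts, centers, par_pk, tis_pk)
    if not (th_a < th_l):
        logger.warning("estimated cutoffs incoherent (%g, %g); using defaults", th_a, th_l)
        return replace(defaults, source="fixed_default")
    return ThresholdSet(th_m=defaults.th_m, th_a=th_a, th_l=th_l, source="histogram_estimated")


def classify_air_lung(
    voxels_hu: np.ndarray,
    body: np.ndarray,
    t: ThresholdSet,
) -> np.ndarray:
    """Two-class labeling inside the body mask.

    voxel < Th_A -> AIR (1); Th_A <= voxel < Th_L -> LUNG (2); otherwise
    (and everywhere outside the body mask) 0.  Comparisons are half-open,
    so a voxel exactly at Th_A is LUNG.
    """
    voxels_hu = np.asarray(voxels_hu)
    body = np.asarray(body, dtype=bool)
    if voxels_hu.shape != body.shape:
        raise ValueError(f"volume shape {voxels_hu.shape} != body mask shape {body.shape}")
    out = np.zeros(voxels_hu.shape, dtype=np.int32)
    out[body & (voxels_hu < t.th_a)] = AIR_LABEL
    out[body & (voxels_hu >= t.th_a) & (voxels_hu < t.th_l)] = LUNG_LABEL
    return out
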