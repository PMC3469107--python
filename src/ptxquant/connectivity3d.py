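"""3D connectivity analysis: prune air that is not pneumothorax.

The 2D stage labels every sub-Th_A voxel inside the body as AIR, which
sweeps in the tracheal/bronchial lumen, bowel gas entering the scanned
range, and any air reaching the exterior.  True pneumothorax must have
finite boundaries inside the pleural cavity, so a whole air component is
excluded (reconstruction semantics: components are kept or removed in
full) when it

* touches a non-body voxel or an axial volume face (continuity with the
  exterior, or with airway/bowel air entering the scanned range),
* is the tracheal lumen found by the automatic airway seed (the air
  component whose topmost-slice centroid is closest to the body centroid
  in the most cranial air-containing slice; a centrality gate keeps a
  peripheral pleural pocket from being mistaken for the trachea), or
* is smaller than ``min_component_voxels`` (noise speckle guard).

Everything that survives constitutes the pneumothorax mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .segmentation2d import AIR_LABEL

logger = logging.getLogger(__name__)

#: Maximum distance of an airway-seed candidate from the body centroid,
#: as a fraction of the body's equivalent in-plane radius.  The tracheal
#: lumen sits mid-mediastinum; pleural air hugs the chest wall.
AIRWAY_SEED_CENTRALITY = 0.35


@dataclass(frozen=True)
class ConnectivityConfig:
    """Parameters of the 3D pruning stage."""

    connectivity_3d: int = 26  # 6 = face, 26 = face+edge+corner
    min_component_voxels: int = 8
    airway_seed: str = "auto"  # or "none"

    def __post_init__(self) -> None:
        if self.connectivity_3d not in (6, 26):
            raise ValueError("connectivity_3d must be 6 or 26")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if self.airway_seed not in ("auto", "none"):
            raise ValueError("airway_seed must be 'auto' or 'none'")


@dataclass
class AirComponent:
    """One labeled connected air region and its exclusion status."""

    label: int
    voxel_count: int
    centroid: tuple[float, float, float]
    slice_range: tuple[int, int]
    touches_exterior: bool = False
    touches_body_boundary: bool = False
    excluded: bool = False
    exclusion_reason: str = "none"

    def exclude(self, reason: str) -> None:
        self.excluded = True
        self.exclusion_reason = reason


def _structure3d(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def label_air_components(
    labels: np.ndarray,
    cfg: ConnectivityConfig | None = None,
) -> tuple[list[AirComponent], np.ndarray]:
    """3D-connected components of the AIR class.

    Returns the component descriptors and the 3D component label map
    (0 = non-air).  An input without AIR voxels yields an empty list.
    """
    cfg = cfg or ConnectivityConfig()
    grid = np.asarray(labels.grid if hasattr(labels, "grid") else labels)
    if grid.ndim != 3:
        raise ValueError("expected a 3D label stack")
    air = grid == AIR_LABEL
    comp_map, n = ndimage.label(air, structure=_structure3d(cfg.connectivity_3d))
    components: list[AirComponent] = []
    if n == 0:
        return components, comp_map
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(air, comp_map, index=idx).astype(int)
    centroids = ndimage.center_of_mass(air, comp_map, index=idx)
    slices = ndimage.find_objects(comp_map)
    for lab, count, cen, slc in zip(idx, counts, centroids, slices):
        components.append(
            AirComponent(
                label=int(lab),
                voxel_count=int(count),
                centroid=tuple(float(c) for c in cen),
                slice_range=(slc[0].start, slc[0].stop - 1),
            )
        )
    return components, comp_map


def _find_airway_seed(
    components: list[AirComponent],
    comp_map: np.ndarray,
    body: np.ndarray,
) -> int | None:
    """Label of the tracheal-lumen component, or None.

    In the most cranial slice containing air, the candidate is the
    component whose centroid in its own topmost slice lies nearest the
    body-mask centroid of that slice; it is accepted only if that
    distance is within AIRWAY_SEED_CENTRALITY of the body's equivalent
    in-plane radius (the trachea is a central structure).
    """
    if not components:
        return None
    top = min(c.slice_range[0] for c in components)
    body_slice = body[top]
    if not body_slice.any():
        return None
    body_centroid = np.array(ndimage.center_of_mass(body_slice))
    body_radius = float(np.sqrt(body_slice.sum() / np.pi))

    best: tuple[float, int] | None = None
    for comp in components:
        if comp.slice_range[0] != top:
            continue
        in_top = comp_map[top] == comp.label
        if not in_top.any():
            continue
        cen = np.array(ndimage.center_of_mass(in_top))
        dist = float(np.linalg.norm(cen - body_centroid))
        if best is None or dist < best[0]:
            best = (dist, comp.label)
    if best is None or best[0] > AIRWAY_SEED_CENTRALITY * body_radius:
        return None
    return best[1]


def exclude_external_air(
    components: list[AirComponent],
    labels: np.ndarray,
    body: np.ndarray,
    cfg: ConnectivityConfig | None = None,
    comp_map: np.ndarray | None = None,
) -> np.ndarray:
    """Prune air components continuous with extra-pleural spaces.

    Mutates the ``components`` descriptors in place (exclusion status and
    reason) and returns the pruned label map: the input map with AIR
    voxels of excluded components set to 0.
    """
    cfg = cfg or ConnectivityConfig()
    grid = np.asarray(labels.grid if hasattr(labels, "grid") else labels)
    body = np.asarray(body.grid if hasattr(body, "grid") else body, dtype=bool)
    if grid.shape != body.shape:
        raise ValueError("label map and body mask shapes differ")
    if comp_map is None:
        _, comp_map = label_air_components(grid, cfg)

    # exterior continuity: 26-adjacency to any non-body voxel, regardless
    # of the labeling connectivity, or presence on the top/bottom face
    non_body_halo = ndimage.binary_dilation(
        ~body, structure=ndimage.generate_binary_structure(3, 3)
    )
    face_labels = set(np.unique(comp_map[[0, -1]])) - {0}
    halo_labels = set(np.unique(comp_map[non_body_halo])) - {0}
    for comp in components:
        comp.touches_body_boundary = comp.label in halo_labels
        comp.touches_exterior = comp.touches_body_boundary or comp.label in face_labels
        if comp.touches_exterior:
            comp.exclude("exterior_connected")

    if cfg.airway_seed == "auto":
        kept = [c for c in components if not c.excluded]
        seed = _find_airway_seed(kept, comp_map, body)
        if seed is not None:
            for comp in components:
                if comp.label == seed:
                    comp.exclude("airway_seed")
                    logger.info("airway seed: component %d excluded", seed)

    for comp in components:
        if not comp.excluded and comp.voxel_count < cfg.min_component_voxels:
            comp.exclude("below_min_size")

    pruned = grid.copy()
    excluded_labels = [c.label for c in components if c.excluded]
    if excluded_labels:
        pruned[np.isin(comp_map, excluded_labels)] = 0
    return pruned
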