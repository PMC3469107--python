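"""Volumetric measurement: physical volumes and relative pneumothorax size.

The relative pneumothorax volume is

    V_ptx = V_air / (V_air + V_lung)

where V_air counts voxels of the pruned AIR class (surviving pneumothorax
components) and V_lung counts parenchyma-labeled voxels, each scaled by
the physical voxel volume.  Vessels and small airways excluded by the
intensity thresholding are not part of V_lung, so the denominator is the
aerated lung plus pleural air rather than the full anatomic pleural
region; the ratio is slightly biased versus manual pleural contours.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .segmentation2d import AIR_LABEL, LUNG_LABEL, ThresholdSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumeReport:
    """Volumes in mm^3 and the relative pneumothorax fraction."""

    v_air: float
    v_lung: float
    v_ptx: float
    thresholds_used: ThresholdSet
    n_components_kept: int = 0
    n_components_excluded: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["v_ptx_pct"] = round(100.0 * self.v_ptx, 2)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def voxel_volume(spacing) -> float:
    """Physical volume of one voxel (mm^3) from the (slice, row, col) spacing."""
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive mm values, got {spacing}")
    return spacing[0] * spacing[1] * spacing[2]


def measure(
    labels,
    spacing,
    thresholds: ThresholdSet | None = None,
    n_components_kept: int = 0,
    n_components_excluded: int = 0,
) -> VolumeReport:
    """Convert a pruned AIR/LUNG label map into a volume report."""
    if spacing is None:
        raise ValueError("spacing is required to compute physical volumes")
    grid = np.asarray(labels.grid if hasattr(labels, "grid") else labels)
    vv = voxel_volume(spacing)
    v_air = float(np.count_nonzero(grid == AIR_LABEL)) * vv
    v_lung = float(np.count_nonzero(grid == LUNG_LABEL)) * vv
    denom = v_air + v_lung
    if denom > 0:
        v_ptx = v_air / denom
    else:
        logger.warning("no air or lung voxels; reporting V_ptx = 0")
        v_ptx = 0.0
    return VolumeReport(
        v_air=v_air,
        v_lung=v_lung,
        v_ptx=v_ptx,
        thresholds_used=thresholds or ThresholdSet(),
        n_components_kept=n_components_kept,
        n_components_excluded=n_components_excluded,
    )
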