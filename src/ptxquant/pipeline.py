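"""End-to-end pneumothorax quantification.

Wires the stages in order: per-slice Gaussian smoothing -> body mask ->
adaptive threshold estimation from the masked volume histogram -> air/lung
classification -> 3D connected-component labeling -> exclusion of air
continuous with extra-pleural spaces -> volumetric measurement.  The run
is a pure function of the input volume and the configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .connectivity3d import (
    AirComponent,
    ConnectivityConfig,
    exclude_external_air,
    label_air_components,
)
from .core_io import CTVolume, LabelMap, read_volume, write_labelmap
from .quantify import VolumeReport, measure
from .segmentation2d import (
    SmoothingParams,
    ThresholdSet,
    body_mask_volume,
    classify_air_lung,
    estimate_thresholds,
    smooth_volume,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    smoothing: SmoothingParams = field(default_factory=SmoothingParams)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    adaptive_thresholds: bool = True
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Everything a run produces, for reporting and inspection."""

    report: VolumeReport
    pneumothorax_labels: LabelMap
    body_mask: object  # 3D boolean array
    components: list[AirComponent]
    thresholds: ThresholdSet


def run_pipeline(volume: CTVolume, cfg: RunConfig | None = None) -> PipelineResult:
    """Quantify pneumothorax in one CT volume."""
    cfg = cfg or RunConfig()

    logger.info("smoothing %d slices", volume.n_slices)
    smoothed = smooth_volume(volume.voxels, cfg.smoothing)

    logger.info("extracting body mask at Th_M=%g HU", cfg.thresholds.th_m)
    body = body_mask_volume(smoothed, cfg.thresholds)

    if cfg.adaptive_thresholds and body.any():
        thresholds = estimate_thresholds(smoothed, body, cfg.thresholds)
    else:
        thresholds = cfg.thresholds
    logger.info(
        "thresholds (%s): Th_A=%g, Th_L=%g, Th_M=%g HU",
        thresholds.source, thresholds.th_a, thresholds.th_l, thresholds.th_m,
    )

    labels = classify_air_lung(smoothed, body, thresholds)
    components, comp_map = label_air_components(labels, cfg.connectivity)
    pruned = exclude_external_air(components, labels, body, cfg.connectivity, comp_map)

    kept = sum(1 for c in components if not c.excluded)
    excluded = len(components) - kept
    report = measure(
        pruned,
        volume.spacing,
        thresholds=thresholds,
        n_components_kept=kept,
        n_components_excluded=excluded,
    )
    logger.info(
        "V_air=%.1f mm3, V_lung=%.1f mm3, V_ptx=%.2f%% (%d kept / %d excluded)",
        report.v_air, report.v_lung, 100 * report.v_ptx, kept, excluded,
    )
    return PipelineResult(
        report=report,
        pneumothorax_labels=LabelMap(pruned),
        body_mask=body,
        components=components,
        thresholds=thresholds,
    )


def run_on_file(input_path, output_dir, cfg: RunConfig | None = None) -> VolumeReport:
    """Run the pipeline on a volume file and write report + artifacts."""
    cfg = cfg or RunConfig()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    volume = read_volume(input_path)
    result = run_pipeline(volume, cfg)
    (output_dir / "report.json").write_text(result.report.to_json(sort_keys=True) + "\n")
    (output_dir / "config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    write_labelmap(
        result.pneumothorax_labels, output_dir / "pneumothorax_mask.nii.gz",
        spacing=volume.spacing,
    )
    return result.report
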