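"""CT volume and label-map I/O.

Establishes the geometry conventions every other module relies on:

* axis 0 is the through-plane (slice, z) axis; axes 1-2 are in-plane
  (row, col),
* grids are 0-based and indexed ``[slice][row][col]``,
* voxel values are Hounsfield Units (HU) stored as floating point,
* physical spacing is carried separately as an (slice, row, col) triple
  in millimetres.

DICOM series are read with :mod:`pydicom` (rescale slope/intercept applied,
slices sorted by physical position along the slice normal, never by file
name); NIfTI-1 volumes and integer label maps are read and written with
:mod:`nibabel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

logger = logging.getLogger(__name__)

#: Plausible HU range after rescale; values outside are clipped with a warning.
HU_MIN = -1100.0
HU_MAX = 3100.0


class VolumeIOError(RuntimeError):
    """Raised when a volume or label map cannot be read or written."""


@dataclass
class CTVolume:
    """A chest CT volume in Hounsfield Units.

    Parameters
    ----------
    voxels
        3D float array indexed ``[slice, row, col]``, in HU.
    spacing
        Physical voxel spacing in mm for the (slice, row, col) axes.
    origin
        Physical position (mm) of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_axis: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        ns, nr, nc = self.voxels.shape
        if ns < 1 or nr < 16 or nc < 16:
            raise ValueError(
                f"volume must have >=1 slice and >=16x16 in-plane, got {self.voxels.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            logger.warning(
                "HU values [%g, %g] outside plausible range [%g, %g]; clipping",
                lo, hi, HU_MIN, HU_MAX,
            )
            np.clip(self.voxels, HU_MIN, HU_MAX, out=self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class BinaryMask:
    """A 2D or 3D boolean grid aligned to a CT volume region."""

    grid: np.ndarray
    spacing: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim not in (2, 3):
            raise ValueError(f"mask must be 2D or 3D, got {self.grid.ndim}D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape


@dataclass
class LabelMap:
    """An integer component/class map; 0 is background."""

    grid: np.ndarray
    labels: frozenset[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label map grid must be integer-valued")
        if self.grid.ndim not in (2, 3):
            raise ValueError(f"label map must be 2D or 3D, got {self.grid.ndim}D")
        present = frozenset(int(v) for v in np.unique(self.grid) if v != 0)
        if self.labels is None:
            self.labels = present
        else:
            self.labels = frozenset(int(v) for v in self.labels)
            if not present <= self.labels:
                raise ValueError(
                    f"grid contains labels {sorted(present - self.labels)} not in label set"
                )


# ---------------------------------------------------------------------------
# DICOM reading
# ---------------------------------------------------------------------------

def _dicom_slice_position(ds: pydicom.Dataset) -> float:
    """Position of a slice along the slice normal (mm)."""
    try:
        ipp = np.asarray([float(v) for v in ds.ImagePositionPatient])
        iop = np.asarray([float(v) for v in ds.ImageOrientationPatient])
        normal = np.cross(iop[:3], iop[3:])
        return float(np.dot(ipp, normal))
    except AttributeError:
        # fall back to slice location if orientation tags are absent
        return float(ds.SliceLocation)


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets: list[tuple[float, Path, pydicom.Dataset]] = []
    series_uid: str | None = None
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue  # non-DICOM clutter in the directory
        uid = str(getattr(ds, "SeriesInstanceUID", ""))
        if series_uid is None:
            series_uid = uid
        elif uid != series_uid:
            raise VolumeIOError(
                f"mixed DICOM series: {f.name} belongs to series {uid!r}, "
                f"expected {series_uid!r}"
            )
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise VolumeIOError(
                f"{f.name}: missing RescaleSlope/RescaleIntercept; cannot convert to HU"
            )
        datasets.append((_dicom_slice_position(ds), f, ds))
    if not datasets:
        raise VolumeIOError(f"no DICOM files found in {path}")
    datasets.sort(key=lambda t: t[0])

    positions = np.array([t[0] for t in datasets])
    slices = []
    for _, _, ds in datasets:
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) + float(
            ds.RescaleIntercept
        )
        slices.append(hu)
    voxels = np.stack(slices, axis=0)

    ds0 = datasets[0][2]
    row_sp, col_sp = (float(v) for v in ds0.PixelSpacing)
    if len(datasets) > 1:
        slice_sp = float(np.median(np.diff(positions)))
    else:
        slice_sp = float(getattr(ds0, "SliceThickness", 1.0))
    origin = tuple(float(v) for v in getattr(ds0, "ImagePositionPatient", (0, 0, 0)))
    return CTVolume(voxels, spacing=(slice_sp, row_sp, col_sp), origin=origin)


# ---------------------------------------------------------------------------
# NIfTI reading / writing
# ---------------------------------------------------------------------------
# Convention: on disk the array is stored (col, row, slice) with spacing in
# the NIfTI zooms, so generic viewers see the usual (i, j, k) order; in memory
# we transpose to [slice, row, col].

def _nifti_to_volume(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, tuple]:
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"expected a 3D NIfTI, got {data.ndim}D")
    grid = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return grid, spacing, origin


def _volume_to_nifti(grid: np.ndarray, spacing, origin) -> nib.Nifti1Image:
    data = np.transpose(grid, (2, 1, 0))
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    affine[:3, 3] = origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    return img


def read_volume(path, format_hint: str = "auto") -> CTVolume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    Voxels are returned in HU (DICOM rescale slope/intercept applied);
    slices are ordered by physical position along the slice normal.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such path: {path}")
    if format_hint == "auto":
        format_hint = "dicom_dir" if path.is_dir() else "nifti"
    if format_hint == "dicom_dir":
        return _read_dicom_series(path)
    if format_hint == "nifti":
        img = nib.load(str(path))
        grid, spacing, origin = _nifti_to_volume(img)
        return CTVolume(grid.astype(np.float32), spacing=spacing, origin=origin)
    raise ValueError(f"unknown format hint {format_hint!r}")


def write_volume(vol: CTVolume, path, format: str = "nifti") -> None:
    """Write a CT volume as NIfTI-1 with lossless geometry."""
    if format != "nifti":
        raise ValueError(f"unsupported output format {format!r}")
    path = Path(path)
    if not path.parent.is_dir():
        raise VolumeIOError(f"parent directory does not exist: {path.parent}")
    img = _volume_to_nifti(vol.voxels.astype(np.float32), vol.spacing, vol.origin)
    nib.save(img, str(path))


def write_labelmap(lm: LabelMap, path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write an integer label map as NIfTI-1 (int32, lossless)."""
    path = Path(path)
    if not path.parent.is_dir():
        raise VolumeIOError(f"parent directory does not exist: {path.parent}")
    grid = lm.grid
    if grid.ndim == 2:
        grid = grid[np.newaxis, :, :]
    img = _volume_to_nifti(grid.astype(np.int32), spacing, (0.0, 0.0, 0.0))
    nib.save(img, str(path))


def read_labelmap(path) -> LabelMap:
    """Read an integer label map written by :func:`write_labelmap`."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such path: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(data == np.round(data)):
            raise VolumeIOError(f"{path}: float-valued data cannot be read as a label map")
        data = data.astype(np.int64)
    grid = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    return LabelMap(grid.astype(np.int32))
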