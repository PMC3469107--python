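import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

import ptxquant as pq


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_ct_dataset(
    pixels: np.ndarray,
    z: float,
    series_uid: str,
    slope: float = 1.0,
    intercept: float = -1024.0,
    pixel_spacing=(0.7, 0.7),
) -> Dataset:
    """Minimal CT DICOM dataset around a stored-value pixel array."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelSpacing = list(pixel_spacing)
    ds.ImagePositionPatient = [0.0, 0.0, z]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SliceThickness = 2.5
    ds.PixelData = pixels.astype(np.int16).tobytes()
    return ds


@pytest.fixture
def dicom_series_factory(tmp_path):
    """Write a synthetic DICOM series; returns (dir, write) helpers."""

    def write(slices, zs, filenames=None, series_uid=None, **kwargs):
        series_uid = series_uid or generate_uid()
        d = tmp_path / "series"
        d.mkdir(exist_ok=True)
        if filenames is None:
            filenames = [f"slice{i:03d}.dcm" for i in range(len(slices))]
        for arr, z, name in zip(slices, zs, filenames):
            ds = make_ct_dataset(np.asarray(arr), z, series_uid, **kwargs)
            ds.save_as(d / name, enforce_file_format=True)
        return d

    return write


@pytest.fixture(scope="session")
def small_phantom():
    """A moderate-pneumothorax phantom at reduced size, shared per session."""
    return pq.generate(pq.PhantomSpec(shape=(32, 192, 192), ptx_fraction=0.2, seed=42))


@pytest.fixture(scope="session")
def small_phantom_result(small_phantom):
    return pq.run_pipeline(small_phantom.volume)
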