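import numpy as np
import pytest

from lbmct.ct_io import ImageVolume


@pytest.fixture
def cube_ct():
    """All-air CT with a 20^3 soft-tissue cube (a minimal 'body')."""
    vox = np.full((40, 40, 40), -1000.0)
    vox[10:30, 10:30, 10:30] = 40.0
    return ImageVolume(vox, (1.0, 1.0, 1.0), modality="CT")


@pytest.fixture
def dicom_slice_factory(tmp_path):
    """Writes a minimal one-series CT DICOM slice; returns (dir, write_fn)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    series_uid = generate_uid()
    sdir = tmp_path / "series"
    sdir.mkdir()

    def write(filename, z, stored_value, slope=1.0, intercept=-1024.0,
              series=series_uid, shape=(4, 4)):
        ds = Dataset()
        ds.SeriesInstanceUID = series
        ds.SOPInstanceUID = generate_uid()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.Modality = "CT"
        ds.ImagePositionPatient = [0.0, 0.0, float(z)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [0.5, 0.7]
        ds.SliceThickness = 2.0
        ds.Rows, ds.Columns = shape
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        ds.PixelData = (np.ones(shape, dtype=np.uint16) * stored_value).tobytes()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = ds.SOPClassUID
        ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        ds.save_as(sdir / filename, enforce_file_format=True)

    return sdir, write


TABLE_PE_LC = np.array([[41, 6, 0], [12, 65, 5], [0, 4, 108]])
"""Published 3x3 cross-classification (rows PE-based, cols LC-based,
order PMD/SMD/PMR) used as a worked input throughout the tests."""
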