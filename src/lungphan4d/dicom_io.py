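"""Minimal DICOM CT series writer.

One file per axial slice (fixed SI position), int16 pixels with rescale
slope/intercept carrying HU.  The series is geometrically faithful
(spacing, positions, orientation) but carries synthetic equipment
metadata — it identifies itself as a digital phantom, not a scanner.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np


def write_ct_series(volume, directory, series_description: str | None = None) -> list[Path]:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # deterministic UIDs derived from volume identity so re-runs re-create
    # the same series
    entropy = f"{volume.name}|{volume.values.shape}|{volume.spacing}|{volume.origin}"
    root = "1.2.826.0.1.3680043.10.1082."  # generic org root + package arc
    series_uid = generate_uid(prefix=root, entropy_srcs=[entropy, "series"])
    study_uid = generate_uid(prefix=root, entropy_srcs=[entropy, "study"])
    frame_uid = generate_uid(prefix=root, entropy_srcs=[entropy, "frame"])

    nx, ny, nz = volume.values.shape
    paths = []
    for k in range(nz):
        sl = np.asarray(volume.values[:, :, k], dtype=np.float64)
        pixels = np.rint(sl + 1024.0).astype(np.int16)  # intercept -1024

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(
            prefix=root, entropy_srcs=[entropy, f"slice{k}"]
        )
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.SeriesDescription = series_description or (volume.name or "digital phantom")
        ds.Manufacturer = "lungphan4d (synthetic)"
        ds.PatientName = "PHANTOM^DIGITAL"
        ds.PatientID = "LUNGPHAN4D"
        ds.StudyDate = ds.SeriesDate = datetime.date(2000, 1, 1).strftime("%Y%m%d")
        ds.StudyTime = ds.SeriesTime = "000000"

        # pixel grid: rows advance along AP (axis 1), columns along lateral
        # (axis 0); slices along SI (axis 2)
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [f"{volume.spacing[1]:.6g}", f"{volume.spacing[0]:.6g}"]
        ds.SliceThickness = f"{volume.spacing[2]:.6g}"
        ds.ImagePositionPatient = [
            f"{volume.origin[0]:.6g}",
            f"{volume.origin[1]:.6g}",
            f"{volume.origin[2] + k * volume.spacing[2]:.6g}",
        ]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.InstanceNumber = k + 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleIntercept = "-1024"
        ds.RescaleSlope = "1"
        ds.PixelData = np.ascontiguousarray(pixels.T).tobytes()

        path = directory / f"{(volume.name or 'ct').replace(' ', '_')}_{k:04d}.dcm"
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths
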