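"""Volume I/O: NIfTI-1 files and DICOM CT series.

Conventions
-----------
* In memory, arrays are indexed ``(x, y, z)`` (see :mod:`focusedview.core`).
* NIfTI round trips are lossless (float32 image, uint8 labels).
* DICOM stores one file per axial slice as unsigned 16-bit values with
  ``RescaleSlope = 1`` and ``RescaleIntercept = -1024``, so the focused-view
  mask value of -1000 HU maps to the exact stored integer 24 and round
  trips bit-exactly; arbitrary HU round-trip error is bounded by the
  0.5 HU rounding quantum.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .core import LabelMap, ValidationError, Volume

#: fixed rescale so that -1000 HU is exactly representable (stored 24)
RESCALE_INTERCEPT = -1024.0
RESCALE_SLOPE = 1.0


@dataclass
class SeriesMeta:
    """Metadata describing one DICOM CT series."""

    modality: str = "CT"
    slice_spacing_mm: float = 1.0
    slice_thickness_mm: float = 1.0
    rescale_slope: float = RESCALE_SLOPE
    rescale_intercept: float = RESCALE_INTERCEPT
    orientation: tuple = (1, 0, 0, 0, 1, 0)
    series_uid: str = field(default_factory=generate_uid)
    frame_of_reference_uid: str = field(default_factory=generate_uid)

    def __post_init__(self):
        if self.rescale_slope == 0:
            raise ValidationError("rescale_slope must be non-zero")


def _affine(volume: Union[Volume, LabelMap]) -> np.ndarray:
    aff = np.diag(list(volume.spacing_mm) + [1.0])
    aff[:3, 3] = volume.origin_mm
    return aff


def save_nifti(obj: Union[Volume, LabelMap], path: Union[str, Path]) -> Path:
    """Write a Volume (float32) or LabelMap (uint8) as NIfTI-1."""
    path = Path(path)
    if isinstance(obj, LabelMap):
        data = obj.labels.astype(np.uint8)
    else:
        data = obj.intensities.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(obj))
    img.header.set_zooms(obj.spacing_mm)
    nib.save(img, str(path))
    return path


def _read_nifti(path: Path) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3-D NIfTI image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data, tuple(float(z) for z in zooms), origin)


def read_labelmap(path: Union[str, Path]) -> LabelMap:
    """Read a label NIfTI written by :func:`save_nifti`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return LabelMap(
        np.rint(data).astype(np.uint8), tuple(float(z) for z in zooms), origin
    )


def _read_dicom_dir(path: Path, spacing_rtol: float = 1e-3) -> Volume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValidationError(f"no DICOM image files found in {path}")
    uids = {getattr(ds, "SeriesInstanceUID", "") for ds in slices}
    if len(uids) > 1:
        raise ValidationError(
            f"directory {path} mixes {len(uids)} DICOM series; "
            "expected exactly one"
        )
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zpos) > 1:
        dz = np.diff(zpos)
        if np.any(dz <= 0):
            raise ValidationError("duplicate or non-monotone slice positions")
        if np.ptp(dz) > spacing_rtol * np.median(dz) + 1e-6:
            raise ValidationError(
                f"non-uniform slice spacing (range {dz.min():.4f}-"
                f"{dz.max():.4f} mm); a slice may be missing"
            )
        dz0 = float(np.median(dz))
    else:
        dz0 = float(getattr(slices[0], "SliceThickness", 1.0))
    ref = slices[0]
    dy, dx = (float(v) for v in ref.PixelSpacing)
    slope = float(getattr(ref, "RescaleSlope", 1.0))
    intercept = float(getattr(ref, "RescaleIntercept", 0.0))
    # pixel_array is (rows, cols) = (y, x); transpose into (x, y)
    stack = np.stack(
        [ds.pixel_array.T.astype(np.float32) for ds in slices], axis=-1
    )
    hu = stack * slope + intercept
    origin = tuple(float(v) for v in ref.ImagePositionPatient)
    return Volume(hu, (dx, dy, dz0), origin)


def read_volume(path: Union[str, Path]) -> Volume:
    """Read a NIfTI file or a single-series DICOM directory as HU."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        return _read_nifti(path)
    raise ValidationError(f"unsupported input {path}: expected NIfTI or DICOM dir")


def write_focused_dicom(
    volume: Volume,
    template: Optional[SeriesMeta],
    path: Union[str, Path],
    description: str = "Focused view CTA",
) -> List[Path]:
    """Export a volume as a DICOM CT series, one file per axial slice.

    A fresh SeriesInstanceUID is always generated, so the output is a new
    series distinct from any template it derives metadata from.
    """
    if volume.shape[2] == 0 or volume.intensities.size == 0:
        raise ValidationError("cannot export an empty volume (0 slices)")
    meta = template or SeriesMeta(
        slice_spacing_mm=volume.spacing_mm[2],
        slice_thickness_mm=volume.spacing_mm[2],
    )
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()  # always new, never the template's
    study_uid = generate_uid()
    stored = np.rint(
        (volume.intensities - RESCALE_INTERCEPT) / RESCALE_SLOPE
    ).astype(np.uint16)
    nx, ny, nz = volume.shape
    written: List[Path] = []
    for k in range(nz):
        fm = FileMetaDataset()
        fm.MediaStorageSOPClassUID = CTImageStorage
        fm.MediaStorageSOPInstanceUID = generate_uid()
        fm.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=fm, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = fm.MediaStorageSOPInstanceUID
        ds.Modality = meta.modality
        ds.SeriesDescription = description
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = meta.frame_of_reference_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            volume.origin_mm[0],
            volume.origin_mm[1],
            volume.origin_mm[2] + k * volume.spacing_mm[2],
        ]
        ds.ImageOrientationPatient = list(meta.orientation)
        ds.PixelSpacing = [volume.spacing_mm[1], volume.spacing_mm[0]]  # row, col
        ds.SliceThickness = meta.slice_thickness_mm
        ds.RescaleSlope = RESCALE_SLOPE
        ds.RescaleIntercept = RESCALE_INTERCEPT
        ds.RescaleType = "HU"
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.ascontiguousarray(stored[:, :, k].T).tobytes()
        fname = out / f"slice_{k + 1:04d}.dcm"
        ds.save_as(str(fname), enforce_file_format=True)
        written.append(fname)
    return written
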