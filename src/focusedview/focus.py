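"""Focused-view CTA construction: blank everything outside the predicted
segmentation to air and export.

The focused view keeps the original HU values wherever the label map
marks brain/cranial cavity (class 1) or extracranial arteries (class 2)
and sets every other voxel to exactly -1000 HU.  Masking is idempotent
and never introduces any value other than -1000.
"""

from __future__ import annotations

import time
from pathlib import Path
from typing import Dict, Union

import numpy as np

from .core import AIR_HU, LabelMap, ValidationError, Volume


class StageError(RuntimeError):
    """An end-to-end conversion failure, tagged with the failing stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


def apply_focus_mask(volume: Volume, labels: LabelMap) -> Volume:
    """Return the focused-view volume for ``volume`` under ``labels``."""
    labels.check_aligned(volume)
    out = np.where(
        labels.labels > 0, volume.intensities, np.float32(AIR_HU)
    ).astype(np.float32)
    return volume.with_intensities(out)


def convert_case(
    model,
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    overlap_fraction: float = 0.5,
) -> Dict:
    """End-to-end conversion: read -> preprocess -> predict -> mask -> export.

    Writes the focused-view DICOM series under ``out_path/focused_dicom``
    and the predicted labels as NIfTI; returns wall time, per-class voxel
    counts and output locations.  Failures carry the name of the stage
    they occurred in.
    """
    from . import volio
    from .infer import segment_volume

    t0 = time.perf_counter()
    try:
        volume = volio.read_volume(in_path)
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise StageError("volio.read_volume", e) from e
    try:
        labels, _ = segment_volume(model, volume, overlap_fraction)
    except Exception as e:
        raise StageError("infer.segment_volume", e) from e
    try:
        focused = apply_focus_mask(volume, labels)
    except Exception as e:
        raise StageError("focus.apply_focus_mask", e) from e
    out_path = Path(out_path)
    try:
        dicom_dir = out_path / "focused_dicom"
        files = volio.write_focused_dicom(focused, None, dicom_dir)
        label_path = volio.save_nifti(labels, out_path / "labels.nii.gz")
    except Exception as e:
        raise StageError("volio.write_focused_dicom", e) from e
    counts = {int(c): int((labels.labels == c).sum()) for c in (0, 1, 2)}
    return {
        "wall_time_s": time.perf_counter() - t0,
        "voxel_counts": counts,
        "dicom_dir": str(dicom_dir),
        "dicom_files": [str(f) for f in files],
        "labels_nifti": str(label_path),
    }
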