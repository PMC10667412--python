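"""Full-volume segmentation: sliding-window inference with overlap
averaging, argmax label extraction, and native-grid mapping.

Windows are placed at a stride of ``window * (1 - overlap_fraction)``
along each axis, with the final window snapped to the far edge; each
voxel's probability is the unweighted mean over every window covering it.
Volumes smaller than the window are padded with the normalized image of
air (-1000 HU) and the padding is cropped from the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import AIR_HU, LabelMap, ValidationError, Volume
from .preprocess import apply_recorded_normalization, normalize, normalized_air_value, resample_inplane


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel class probabilities (3, X, Y, Z) with volume geometry."""

    probabilities: np.ndarray
    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float32)
        if p.ndim != 4:
            raise ValidationError(f"probabilities must be 4-D, got {p.ndim}-D")
        if p.size and (p.min() < -1e-5 or p.max() > 1 + 1e-5):
            raise ValidationError("probabilities outside [0, 1]")
        sums = p.sum(axis=0)
        if p.size and np.abs(sums - 1.0).max() > 1e-4:
            raise ValidationError("per-voxel class probabilities must sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def shape(self):
        return self.probabilities.shape[1:]


def _window_starts(size: int, win: int, stride: int) -> List[int]:
    starts = list(range(0, size - win + 1, stride))
    if starts[-1] != size - win:
        starts.append(size - win)  # snap the final window to the far edge
    return starts


def sliding_window_predict_array(
    model,
    image: np.ndarray,
    window_shape: Optional[Tuple[int, int, int]] = None,
    overlap_fraction: float = 0.5,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Sliding-window prediction over a (normalized) image array.

    Returns ``(n_classes, X, Y, Z)`` mean probabilities.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValidationError(
            f"overlap_fraction must be in [0, 1), got {overlap_fraction}"
        )
    win = tuple(int(w) for w in (window_shape or model.window_shape))
    img = np.asarray(image, dtype=np.float32)
    pad = [(0, max(0, w - s)) for w, s in zip(win, img.shape)]
    padded = np.pad(img, pad, constant_values=pad_value) if any(
        p[1] for p in pad
    ) else img
    if any(w > s for w, s in zip(win, padded.shape)):
        raise ValidationError(f"window {win} larger than padded volume")
    strides = [max(1, int(round(w * (1 - overlap_fraction)))) for w in win]
    n_classes = None
    acc = cnt = None
    for x0 in _window_starts(padded.shape[0], win[0], strides[0]):
        for y0 in _window_starts(padded.shape[1], win[1], strides[1]):
            for z0 in _window_starts(padded.shape[2], win[2], strides[2]):
                sl = (
                    slice(x0, x0 + win[0]),
                    slice(y0, y0 + win[1]),
                    slice(z0, z0 + win[2]),
                )
                p = model.predict_probs(padded[sl])
                if acc is None:
                    n_classes = p.shape[0]
                    acc = np.zeros((n_classes,) + padded.shape, dtype=np.float64)
                    cnt = np.zeros(padded.shape, dtype=np.int32)
                acc[(slice(None),) + sl] += p
                cnt[sl] += 1
    probs = (acc / cnt).astype(np.float32)
    crop = tuple(slice(0, s) for s in img.shape)
    return probs[(slice(None),) + crop]


def sliding_window_predict(
    model,
    volume: Volume,
    window_shape: Optional[Tuple[int, int, int]] = None,
    overlap_fraction: float = 0.5,
    pad_value: float = AIR_HU,
) -> ProbabilityMap:
    """Sliding-window prediction over a :class:`Volume` (already in the
    intensity units the model was trained on)."""
    probs = sliding_window_predict_array(
        model, volume.intensities, window_shape, overlap_fraction, pad_value
    )
    return ProbabilityMap(probs, volume.spacing_mm, volume.origin_mm)


def labels_from_probabilities_array(probs: np.ndarray) -> np.ndarray:
    """Per-voxel argmax; ties break toward the lowest class index."""
    return np.argmax(probs, axis=0).astype(np.uint8)


def labels_from_probabilities(pmap: ProbabilityMap) -> LabelMap:
    return LabelMap(
        labels_from_probabilities_array(pmap.probabilities),
        pmap.spacing_mm,
        pmap.origin_mm,
    )


def _map_labels_to_grid(
    labels: np.ndarray,
    src_spacing: Tuple[float, float, float],
    dst_shape: Tuple[int, int, int],
    dst_spacing: Tuple[float, float, float],
) -> np.ndarray:
    """Nearest-neighbour resample of a label grid onto a target grid."""
    idx = []
    for ax in range(3):
        centers = (np.arange(dst_shape[ax]) + 0.5) * dst_spacing[ax]
        j = np.clip(
            np.floor(centers / src_spacing[ax]).astype(int),
            0,
            labels.shape[ax] - 1,
        )
        idx.append(j)
    return labels[np.ix_(idx[0], idx[1], idx[2])]


def segment_volume(
    model,
    volume: Volume,
    overlap_fraction: float = 0.5,
) -> Tuple[LabelMap, ProbabilityMap]:
    """Segment a raw-HU volume with a trained bundle or ensemble.

    The volume is resampled in-plane to the bundle's training spacing,
    normalized with the recorded strategy, segmented by sliding window,
    and the predicted labels are mapped back (nearest neighbour) onto the
    volume's native grid — the focused-view mask is always applied to the
    original CTA, never the resampled one.
    """
    preproc = model.preproc
    res_vol, _ = resample_inplane(volume, preproc.inplane_spacing_mm)
    norm_vol, stats = normalize(res_vol, preproc.normalization)
    probs = sliding_window_predict_array(
        model,
        norm_vol.intensities,
        model.window_shape,
        overlap_fraction,
        pad_value=normalized_air_value(stats),
    )
    pmap = ProbabilityMap(probs, res_vol.spacing_mm, res_vol.origin_mm)
    res_labels = labels_from_probabilities_array(probs)
    native = _map_labels_to_grid(
        res_labels, res_vol.spacing_mm, volume.shape, volume.spacing_mm
    )
    return (
        LabelMap(native, volume.spacing_mm, volume.origin_mm,
                 volume.axis_orientation),
        pmap,
    )
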