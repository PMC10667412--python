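"""Resampling, intensity normalization, patch sampling and augmentation.

These are the operations the patch-based training pipeline applies between
raw HU volumes and network input: in-plane resampling to a target voxel
spacing (the through-plane axis is never resampled), per-volume intensity
normalization (z-norm or divide-by-1000, with the statistics recorded so
inference applies the identical transform), uniform random patch
extraction, and stochastic augmentation (in-plane rotation, small
out-of-plane tilt, additive Gaussian noise in normalized units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import AIR_HU, LabelMap, ValidationError, Volume

INPLANE_SPACING_CHOICES = (0.5, 0.7, 1.0)
NORMALIZATION_CHOICES = ("z_norm", "divide_by_1000")


@dataclass(frozen=True)
class PreprocConfig:
    inplane_spacing_mm: float = 0.7
    normalization: str = "z_norm"

    def __post_init__(self):
        if not any(
            abs(self.inplane_spacing_mm - c) < 1e-9 for c in INPLANE_SPACING_CHOICES
        ):
            raise ValidationError(
                f"inplane_spacing_mm: must be one of {INPLANE_SPACING_CHOICES}, "
                f"got {self.inplane_spacing_mm}"
            )
        if self.normalization not in NORMALIZATION_CHOICES:
            raise ValidationError(
                f"normalization: must be one of {NORMALIZATION_CHOICES}, "
                f"got {self.normalization!r}"
            )


@dataclass(frozen=True)
class AugmentConfig:
    rotation_freq: float = 0.25
    tilt_freq: float = 0.04
    noise_freq: float = 0.60
    noise_factor: float = 0.003
    rotation_max_deg: float = 15.0
    tilt_max_deg: float = 5.0

    def __post_init__(self):
        for name in ("rotation_freq", "tilt_freq", "noise_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}: must be in [0, 1], got {v}")
        if self.noise_factor < 0:
            raise ValidationError(f"noise_factor: must be >= 0, got {self.noise_factor}")
        if self.rotation_max_deg < 0 or self.tilt_max_deg < 0:
            raise ValidationError("rotation/tilt angles must be >= 0")


@dataclass
class PatchPair:
    """An image patch and its aligned label patch (network window shape)."""

    image: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValidationError(
                f"patch shapes differ: image {self.image.shape} vs "
                f"labels {self.labels.shape}"
            )


def resample_inplane(
    volume: Volume, target_mm: float, labels: Optional[LabelMap] = None
) -> Tuple[Volume, Optional[LabelMap]]:
    """Resample the in-plane (x, y) axes to ``target_mm`` voxel spacing.

    The image is interpolated linearly, labels by nearest neighbour; the
    through-plane axis is untouched.
    """
    if target_mm <= 0:
        raise ValidationError(f"target_mm must be > 0, got {target_mm}")
    sx, sy, sz = volume.spacing_mm
    zoom = (sx / target_mm, sy / target_mm, 1.0)
    if abs(zoom[0] - 1) < 1e-9 and abs(zoom[1] - 1) < 1e-9:
        return volume, labels
    img = ndimage.zoom(volume.intensities, zoom, order=1, mode="nearest")
    new_vol = Volume(
        np.clip(img, -1024.0, 3071.0),
        (target_mm, target_mm, sz),
        volume.origin_mm,
        volume.axis_orientation,
    )
    new_lab = None
    if labels is not None:
        labels.check_aligned(volume)
        lab = ndimage.zoom(labels.labels, zoom, order=0, mode="nearest")
        if lab.shape != img.shape:  # rare off-by-one from rounding
            lab = lab[: img.shape[0], : img.shape[1], : img.shape[2]]
        new_lab = LabelMap(
            lab, (target_mm, target_mm, sz), labels.origin_mm, labels.axis_orientation
        )
    return new_vol, new_lab


def normalize(volume: Volume, strategy: str) -> Tuple[Volume, Dict[str, float]]:
    """Normalize intensities; return the volume and the recorded statistics.

    ``z_norm`` standardizes over all voxels of the volume; the returned
    statistics let inference apply exactly the same affine transform.
    """
    if strategy not in NORMALIZATION_CHOICES:
        raise ValidationError(
            f"strategy must be one of {NORMALIZATION_CHOICES}, got {strategy!r}"
        )
    x = volume.intensities
    if strategy == "z_norm":
        mean = float(x.mean())
        sd = float(x.std())
        if sd == 0:
            raise ValidationError("z_norm undefined: volume has zero variance")
        out = (x - mean) / sd
        stats = {"strategy": "z_norm", "mean": mean, "sd": sd}
    else:
        out = x / 1000.0
        stats = {"strategy": "divide_by_1000"}
    return volume.with_intensities(out.astype(np.float32)), stats


def apply_recorded_normalization(x: np.ndarray, stats: Dict) -> np.ndarray:
    """Apply stored normalization statistics to a raw-HU array."""
    if stats["strategy"] == "z_norm":
        return ((x - stats["mean"]) / stats["sd"]).astype(np.float32)
    return (x / 1000.0).astype(np.float32)


def normalized_air_value(stats: Dict) -> float:
    """The image of -1000 HU (air / padding) under recorded normalization."""
    return float(apply_recorded_normalization(np.float32(AIR_HU), stats))


def sample_patch(
    image: np.ndarray,
    labels: np.ndarray,
    window_shape: Tuple[int, int, int],
    rng: np.random.Generator,
    reject_background: bool = True,
    max_rejects: int = 10,
    pad_value: float = AIR_HU,
) -> PatchPair:
    """Extract one uniformly random crop of ``window_shape``.

    Volumes smaller than the window are padded with ``pad_value`` (labels
    with background).  With ``reject_background`` on, all-background label
    crops are re-drawn up to ``max_rejects`` times; the final draw is kept
    regardless so sampling always terminates.
    """
    window_shape = tuple(int(w) for w in window_shape)
    if image.shape != labels.shape:
        raise ValidationError("image/label shapes differ")
    pad = [(0, max(0, w - s)) for w, s in zip(window_shape, image.shape)]
    if any(p[1] for p in pad):
        image = np.pad(image, pad, constant_values=pad_value)
        labels = np.pad(labels, pad, constant_values=0)
    if any(w > s for w, s in zip(window_shape, image.shape)):
        raise ValidationError(
            f"window {window_shape} larger than padded volume {image.shape}"
        )
    tries = max_rejects + 1 if reject_background else 1
    for _ in range(tries):
        corner = [
            int(rng.integers(0, s - w + 1))
            for s, w in zip(image.shape, window_shape)
        ]
        sl = tuple(slice(c, c + w) for c, w in zip(corner, window_shape))
        lab = labels[sl]
        if not reject_background or lab.any():
            break
    return PatchPair(np.ascontiguousarray(image[sl]), np.ascontiguousarray(lab))


def augment(
    pair: PatchPair, cfg: AugmentConfig, rng: np.random.Generator
) -> PatchPair:
    """Stochastic augmentation of one patch pair.

    Each transform fires independently with its configured frequency:
    in-plane rotation (image linear, labels nearest), small out-of-plane
    tilt, additive Gaussian noise of sd ``noise_factor`` in normalized
    intensity units (image only).  Label values stay within {0, 1, 2} and
    the patch shape never changes.
    """
    img, lab = pair.image, pair.labels
    if rng.uniform() < cfg.rotation_freq:
        ang = rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg)
        img = ndimage.rotate(img, ang, axes=(0, 1), reshape=False, order=1,
                             mode="nearest")
        lab = ndimage.rotate(lab, ang, axes=(0, 1), reshape=False, order=0,
                             mode="nearest")
    if rng.uniform() < cfg.tilt_freq:
        ang = rng.uniform(-cfg.tilt_max_deg, cfg.tilt_max_deg)
        img = ndimage.rotate(img, ang, axes=(0, 2), reshape=False, order=1,
                             mode="nearest")
        lab = ndimage.rotate(lab, ang, axes=(0, 2), reshape=False, order=0,
                             mode="nearest")
    if rng.uniform() < cfg.noise_freq and cfg.noise_factor > 0:
        img = img + rng.normal(0.0, cfg.noise_factor, img.shape).astype(img.dtype)
    return PatchPair(np.ascontiguousarray(img, dtype=np.float32),
                     np.ascontiguousarray(lab))
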