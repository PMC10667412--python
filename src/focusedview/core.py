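"""Core volumetric containers shared by every pipeline stage.

A :class:`Volume` is a 3-D scalar field in Hounsfield units (HU) together
with its voxel geometry; a :class:`LabelMap` is an aligned integer field
over the three segmentation classes:

* 0 — background (everything to be blanked out),
* 1 — brain / cranial cavity including intracranial vessels,
* 2 — extracranial stroke-related arteries (arch-to-skull-base lumina).

All modules use one in-memory convention: arrays are indexed ``(x, y, z)``
with 0-based voxel indices, ``z`` the through-plane (slice stacking) axis,
and ``spacing_mm`` ordered the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0
#: HU value assigned to masked-out / padded voxels (air).
AIR_HU = -1000.0

VALID_LABELS = (0, 1, 2)


class ValidationError(ValueError):
    """Raised when a container or config violates its invariants."""


def _as_tuple3(v, name: str) -> Tuple[float, float, float]:
    t = tuple(float(x) for x in np.atleast_1d(np.asarray(v, dtype=float)).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValidationError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class Volume:
    """A 3-D CT volume in HU with voxel geometry metadata."""

    intensities: np.ndarray
    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: Tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float32)
        if arr.ndim != 3:
            raise ValidationError(f"intensities must be 3-D, got ndim={arr.ndim}")
        if arr.size and (arr.min() < HU_MIN or arr.max() > HU_MAX):
            raise ValidationError(
                f"intensities outside valid HU range [{HU_MIN}, {HU_MAX}]: "
                f"[{arr.min():.1f}, {arr.max():.1f}]"
            )
        sp = _as_tuple3(self.spacing_mm, "spacing_mm")
        if any(s <= 0 for s in sp):
            raise ValidationError(f"spacing_mm must be strictly positive, got {sp}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing_mm", sp)
        object.__setattr__(self, "origin_mm", _as_tuple3(self.origin_mm, "origin_mm"))
        object.__setattr__(self, "axis_orientation", tuple(self.axis_orientation))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def with_intensities(self, arr: np.ndarray) -> "Volume":
        """Same geometry, new voxel values."""
        return replace(self, intensities=arr)


@dataclass(frozen=True)
class LabelMap:
    """Integer segmentation aligned voxel-for-voxel with a :class:`Volume`."""

    labels: np.ndarray
    spacing_mm: Tuple[float, float, float]
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: Tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValidationError(f"labels must be 3-D, got ndim={arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr, 1) == 0):
                raise ValidationError("labels must be integral")
            arr = arr.astype(np.uint8)
        if arr.size and not np.isin(np.unique(arr), VALID_LABELS).all():
            raise ValidationError(
                f"labels contain values outside {VALID_LABELS}: {np.unique(arr)}"
            )
        sp = _as_tuple3(self.spacing_mm, "spacing_mm")
        if any(s <= 0 for s in sp):
            raise ValidationError(f"spacing_mm must be strictly positive, got {sp}")
        object.__setattr__(self, "labels", arr.astype(np.uint8))
        object.__setattr__(self, "spacing_mm", sp)
        object.__setattr__(self, "origin_mm", _as_tuple3(self.origin_mm, "origin_mm"))
        object.__setattr__(self, "axis_orientation", tuple(self.axis_orientation))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def check_aligned(self, volume: Volume, tol: float = 1e-6) -> None:
        """Raise unless this map shares grid and geometry with ``volume``."""
        if self.shape != volume.shape:
            raise ValidationError(
                f"label shape {self.shape} != volume shape {volume.shape}"
            )
        if any(abs(a - b) > tol for a, b in zip(self.spacing_mm, volume.spacing_mm)):
            raise ValidationError(
                f"label spacing {self.spacing_mm} != volume spacing {volume.spacing_mm}"
            )


def one_hot(labels: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """One-hot encode a label array to shape ``(n_classes, *labels.shape)``."""
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out
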