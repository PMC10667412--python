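"""Synthetic head-and-neck CTA phantoms with ground-truth labels.

The generator emulates the anatomy a stroke CTA covers — aortic-arch
region to cranial vertex — at the level of detail the two-class annotation
protocol needs: an air background at -1000 HU, a soft-tissue neck column
with a vertebra-like bone core, a skull shell enclosing a brain ellipsoid
(the cranial cavity, class 1), and a configurable number of
contrast-opacified tortuous vessels (~400 HU) climbing from the inferior
"arch" region to the skull base (extracranial lumina, class 2).  Vessels
are deliberately routed close to the vertebral column and skull base,
because vessel-near-bone configurations are the hard case for the
segmentation task.

No claim of anatomical realism is made; the phantoms exist so that every
downstream stage (training, inference, masking, export) is exercisable
and testable without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.interpolate import CubicSpline

from .core import AIR_HU, HU_MAX, HU_MIN, LabelMap, ValidationError, Volume

#: default mean/sd HU per material (sd 0 = flat regions; texture comes
#: from ``noise_sd_hu``).  Plausible CTA values, freely configurable.
DEFAULT_HU = {
    "air": (-1000.0, 0.0),
    "soft_tissue": (40.0, 0.0),
    "brain": (30.0, 0.0),
    "bone": (1000.0, 0.0),
    "vessel": (400.0, 0.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic CTA phantom."""

    grid_shape: Tuple[int, int, int] = (64, 64, 96)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    hu_materials: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HU)
    )
    vessel_count: int = 4
    tortuosity: float = 3.0  # mm amplitude of centerline undulation
    vessel_radius_mm: Tuple[float, float] = (1.5, 3.0)
    stenosis_prob: float = 0.15
    noise_sd_hu: float = 10.0
    seed: int = 0

    def __post_init__(self):
        gs = tuple(int(v) for v in self.grid_shape)
        if len(gs) != 3 or any(v < 16 for v in gs):
            raise ValidationError(f"grid_shape: all axes must be >= 16, got {gs}")
        sp = tuple(float(v) for v in self.spacing_mm)
        if len(sp) != 3 or any(v <= 0 for v in sp):
            raise ValidationError(f"spacing_mm: must be strictly positive, got {sp}")
        mats = dict(DEFAULT_HU)
        mats.update(self.hu_materials)
        if abs(mats["air"][0] - AIR_HU) > 1e-9:
            raise ValidationError(
                f"hu_materials: air mean is fixed at {AIR_HU}, got {mats['air'][0]}"
            )
        if mats["vessel"][0] <= mats["soft_tissue"][0]:
            raise ValidationError(
                "hu_materials: vessel mean must exceed soft-tissue mean"
            )
        if self.vessel_count < 0:
            raise ValidationError(f"vessel_count: must be >= 0, got {self.vessel_count}")
        if not 0.0 <= self.stenosis_prob <= 1.0:
            raise ValidationError(
                f"stenosis_prob: must be in [0, 1], got {self.stenosis_prob}"
            )
        if self.noise_sd_hu < 0:
            raise ValidationError(f"noise_sd_hu: must be >= 0, got {self.noise_sd_hu}")
        r_lo, r_hi = (float(self.vessel_radius_mm[0]), float(self.vessel_radius_mm[1]))
        if r_lo <= 0 or r_hi < r_lo:
            raise ValidationError(
                f"vessel_radius_mm: need 0 < lo <= hi, got {(r_lo, r_hi)}"
            )
        if self.tortuosity < 0:
            raise ValidationError(f"tortuosity: must be >= 0, got {self.tortuosity}")
        object.__setattr__(self, "grid_shape", gs)
        object.__setattr__(self, "spacing_mm", sp)
        object.__setattr__(self, "hu_materials", mats)
        object.__setattr__(self, "vessel_radius_mm", (r_lo, r_hi))


def _geometry(spec: PhantomSpec):
    """Anatomy landmarks in mm, derived from the grid extent."""
    ext = np.array(spec.grid_shape) * np.array(spec.spacing_mm)  # mm extent
    cx, cy = ext[0] / 2.0, ext[1] / 2.0
    head_r = 0.38 * min(ext[0], ext[1])  # outer scalp radius
    skull_outer = head_r - 0.05 * head_r
    skull_thick = max(1.5, 0.08 * skull_outer)
    cavity_r = skull_outer - skull_thick
    head_cz = ext[2] - head_r - 1.0  # head centre near the vertex
    skull_base_z = head_cz - 0.55 * skull_outer  # vessels stop climbing here
    neck_r = 0.30 * min(ext[0], ext[1])
    return dict(
        ext=ext,
        cx=cx,
        cy=cy,
        head_r=head_r,
        skull_outer=skull_outer,
        cavity_r=cavity_r,
        head_cz=head_cz,
        skull_base_z=skull_base_z,
        neck_r=neck_r,
        vert_r=max(2.0, 0.10 * min(ext[0], ext[1])),
        vert_y=cy + 0.12 * ext[1],
    )


def vessel_centerlines(
    spec: PhantomSpec,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Deterministic tortuous vessel centerlines for ``spec``.

    Returns one ``(points, radii)`` pair per vessel: ``points`` is an
    ``(n, 3)`` array of finely sampled positions in mm running from the
    inferior arch region to the skull base, ``radii`` the local lumen
    radius in mm at each sample (reduced over a short window when a focal
    stenosis is drawn).  Exposed separately so the analytic tube volume
    ``sum(pi * r_i^2 * dl_i)`` can serve as an independent oracle for the
    rasterized class-2 voxel count.
    """
    rng = np.random.default_rng(spec.seed)
    geo = _geometry(spec)
    out = []
    r_lo, r_hi = spec.vessel_radius_mm
    for i in range(spec.vessel_count):
        # coarse waypoints along z, jittered in-plane by the tortuosity
        z0, z1 = 1.0, geo["skull_base_z"]
        n_way = 6
        zs = np.linspace(z0, z1, n_way)
        frac = (i + 0.5) / spec.vessel_count
        x_base = geo["cx"] + (frac - 0.5) * 1.5 * geo["neck_r"]
        y_base = geo["cy"] + rng.uniform(-0.3, 0.3) * geo["neck_r"]
        xs = x_base + rng.uniform(-1, 1, n_way) * spec.tortuosity
        ys = y_base + rng.uniform(-1, 1, n_way) * spec.tortuosity
        # drift toward the vertebral column near the skull base (hard case)
        pull = np.linspace(0.0, 1.0, n_way) ** 2
        ys = ys + pull * (geo["vert_y"] - ys) * 0.35
        sx, sy = CubicSpline(zs, xs), CubicSpline(zs, ys)
        n_fine = max(16, int((z1 - z0) / 0.5))
        zf = np.linspace(z0, z1, n_fine)
        xf, yf = sx(zf), sy(zf)
        # helical perturbation in the upper third, mimicking tortuous course
        upper = (zf - z0) / (z1 - z0) > 2.0 / 3.0
        phase = rng.uniform(0, 2 * np.pi)
        amp = 0.4 * spec.tortuosity * upper
        xf = xf + amp * np.cos(2 * np.pi * 2.5 * (zf - z0) / (z1 - z0) + phase)
        yf = yf + amp * np.sin(2 * np.pi * 2.5 * (zf - z0) / (z1 - z0) + phase)
        pts = np.column_stack([xf, yf, zf])
        radius = rng.uniform(r_lo, r_hi)
        radii = np.full(n_fine, radius)
        if rng.uniform() < spec.stenosis_prob:
            c = rng.integers(n_fine // 4, 3 * n_fine // 4)
            w = max(2, n_fine // 10)
            lo, hi = max(0, c - w), min(n_fine, c + w)
            radii[lo:hi] *= 0.4
        out.append((pts, radii))
    return out


def _stamp_tube(mask: np.ndarray, pts: np.ndarray, radii: np.ndarray, spacing):
    """Rasterize a polyline tube into a boolean voxel mask."""
    sp = np.asarray(spacing, dtype=float)
    shape = mask.shape
    for p, r in zip(pts, radii):
        vox = p / sp
        lo = np.maximum(np.floor(vox - r / sp).astype(int), 0)
        hi = np.minimum(np.ceil(vox + r / sp).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        gx = (np.arange(lo[0], hi[0]) + 0.5) * sp[0] - p[0]
        gy = (np.arange(lo[1], hi[1]) + 0.5) * sp[1] - p[1]
        gz = (np.arange(lo[2], hi[2]) + 0.5) * sp[2] - p[2]
        d2 = (
            gx[:, None, None] ** 2 + gy[None, :, None] ** 2 + gz[None, None, :] ** 2
        )
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= r * r


def generate_phantom(spec: PhantomSpec) -> Tuple[Volume, LabelMap]:
    """Generate one phantom volume plus its two-class ground truth.

    Deterministic given ``spec.seed``: the same spec always produces
    bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    geo = _geometry(spec)
    sp = np.asarray(spec.spacing_mm)
    shape = spec.grid_shape
    # voxel-centre coordinate grids in mm
    xs = (np.arange(shape[0]) + 0.5) * sp[0]
    ys = (np.arange(shape[1]) + 0.5) * sp[1]
    zs = (np.arange(shape[2]) + 0.5) * sp[2]
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    r_head2 = (X - geo["cx"]) ** 2 + (Y - geo["cy"]) ** 2 + (Z - geo["head_cz"]) ** 2
    head = r_head2 <= geo["head_r"] ** 2
    skull = (r_head2 <= geo["skull_outer"] ** 2) & (r_head2 > geo["cavity_r"] ** 2)
    cavity = r_head2 <= geo["cavity_r"] ** 2

    rho2 = (X - geo["cx"]) ** 2 + (Y - geo["cy"]) ** 2
    neck = (rho2 <= geo["neck_r"] ** 2) & (Z <= geo["head_cz"]) & ~head
    vert = (
        ((X - geo["cx"]) ** 2 + (Y - geo["vert_y"]) ** 2 <= geo["vert_r"] ** 2)
        & (Z <= geo["skull_base_z"])
    )

    vessel = np.zeros(shape, dtype=bool)
    for pts, radii in vessel_centerlines(spec):
        _stamp_tube(vessel, pts, radii, sp)

    mats = spec.hu_materials
    hu = np.full(shape, mats["air"][0], dtype=np.float32)
    hu[neck] = mats["soft_tissue"][0]
    hu[head & ~skull & ~cavity] = mats["soft_tissue"][0]  # scalp
    hu[vert] = mats["bone"][0]
    hu[skull] = mats["bone"][0]
    hu[cavity] = mats["brain"][0]
    # lumen displaces everything outside the cranial cavity, including bone
    # (the vessel-near/through-bone configuration is the hard case)
    hu[vessel & ~cavity] = mats["vessel"][0]

    # per-material texture, then detector noise
    for region, role in [
        (neck | (head & ~skull & ~cavity), "soft_tissue"),
        (skull | vert, "bone"),
        (cavity, "brain"),
        (vessel & ~cavity, "vessel"),
        (~(neck | head | vert | vessel), "air"),
    ]:
        sd = mats[role][1]
        if sd > 0:
            hu[region] += rng.normal(0.0, sd, int(region.sum())).astype(np.float32)
    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, shape).astype(np.float32)
    np.clip(hu, HU_MIN, HU_MAX, out=hu)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[cavity] = 1
    labels[vessel & ~cavity] = 2  # extracranial lumina only

    vol = Volume(hu, spec.spacing_mm)
    lab = LabelMap(labels, spec.spacing_mm)
    return vol, lab


def apply_noise(volume: Volume, sd_hu: float, seed: int) -> Volume:
    """Additive zero-mean Gaussian HU noise, clipped to the valid range."""
    if sd_hu < 0:
        raise ValidationError(f"sd_hu: must be >= 0, got {sd_hu}")
    if sd_hu == 0:
        return volume
    rng = np.random.default_rng(seed)
    noisy = volume.intensities + rng.normal(0.0, sd_hu, volume.shape).astype(
        np.float32
    )
    return volume.with_intensities(np.clip(noisy, HU_MIN, HU_MAX))


def generate_dataset(
    n: int, base_spec: PhantomSpec, seed: int = 0
) -> List[Tuple[Volume, LabelMap]]:
    """Generate ``n`` phantoms with per-case seeds derived from ``seed``."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n)
    return [generate_phantom(replace(base_spec, seed=int(s))) for s in case_seeds]
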