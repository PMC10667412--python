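"""Hyperparameter search over the tuned pipeline parameters.

The search space covers preprocessing (in-plane spacing, normalization),
network (architecture, window shape, batch size, learning rate, L2,
optimizer, instance norm) and augmentation (rotation/tilt/noise
frequencies, noise factor).  Trials are cheap by construction: each one
trains a single cross-validation fold with a capped epoch budget and is
scored by the best mean validation dice it reaches.  Configurations are
drawn by seeded uniform random sampling (log-uniform on rates and
regularization strengths), which the planted-optimum sanity check in the
test suite validates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ValidationError
from .model import ArchConfig
from .preprocess import AugmentConfig, PreprocConfig
from .train import TrainConfig


@dataclass(frozen=True)
class HyperConfig:
    """One sampled point in the search space."""

    inplane_spacing_mm: float = 0.7
    normalization: str = "z_norm"
    window_xy: int = 160
    window_z: int = 48
    architecture: str = "dual_attention_unet"
    batch_size: int = 13
    learning_rate: float = 4e-4
    l2_strength: float = 2e-4
    optimizer: str = "rmsprop"
    instance_norm: bool = True
    rotation_freq: float = 0.25
    tilt_freq: float = 0.04
    noise_freq: float = 0.60
    noise_factor: float = 0.003

    def to_configs(
        self,
        base_filters: int = 16,
        depth: int = 4,
        window_shape: Optional[Tuple[int, int, int]] = None,
        **train_overrides,
    ) -> Tuple[PreprocConfig, ArchConfig, TrainConfig, AugmentConfig]:
        """Materialize the component configs; a reduced-scale window or
        network size may be injected for desk-scale runs."""
        preproc = PreprocConfig(self.inplane_spacing_mm, self.normalization)
        arch = ArchConfig(
            architecture=self.architecture,
            window_shape=window_shape
            or (self.window_xy, self.window_xy, self.window_z),
            base_filters=base_filters,
            depth=depth,
            instance_norm=self.instance_norm,
            l2_strength=self.l2_strength,
        )
        tkw = dict(
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            optimizer=self.optimizer,
        )
        tkw.update(train_overrides)
        return preproc, arch, TrainConfig(**tkw), AugmentConfig(
            rotation_freq=self.rotation_freq,
            tilt_freq=self.tilt_freq,
            noise_freq=self.noise_freq,
            noise_factor=self.noise_factor,
        )


#: the tuned full-scale configuration shipped as the package default
OPTIMAL_CONFIG = HyperConfig()


@dataclass(frozen=True)
class SearchSpace:
    inplane_spacing_mm: Tuple[float, ...] = (0.5, 0.7, 1.0)
    normalization: Tuple[str, ...] = ("z_norm", "divide_by_1000")
    window_xy: Tuple[int, ...] = (160, 192, 224, 256)  # 160-256 step 32
    window_z: Tuple[int, ...] = (16, 32, 48, 64)  # 16-64 step 16
    architecture: Tuple[str, ...] = ("basic_unet", "dual_attention_unet")
    batch_size: Tuple[int, int] = (1, 15)  # inclusive, step 1
    learning_rate: Tuple[float, float] = (1e-4, 1e-3)  # log-uniform
    l2_strength: Tuple[float, float] = (1e-4, 1e-3)  # log-uniform
    optimizer: Tuple[str, ...] = ("adam", "rmsprop")
    instance_norm: Tuple[bool, ...] = (True, False)
    rotation_freq: Tuple[float, float] = (0.0, 0.5)
    tilt_freq: Tuple[float, float] = (0.0, 0.5)
    noise_freq: Tuple[float, float] = (0.0, 0.7)
    noise_factor: Tuple[float, float] = (1e-4, 1e-2)  # log-uniform


def _log_uniform(rng, lo, hi):
    if lo == hi:
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_config(space: SearchSpace, rng: np.random.Generator) -> HyperConfig:
    """Draw one configuration uniformly from the space (log-uniform on
    learning rate, L2 strength and noise factor)."""
    return HyperConfig(
        inplane_spacing_mm=float(rng.choice(space.inplane_spacing_mm)),
        normalization=str(rng.choice(space.normalization)),
        window_xy=int(rng.choice(space.window_xy)),
        window_z=int(rng.choice(space.window_z)),
        architecture=str(rng.choice(space.architecture)),
        batch_size=int(rng.integers(space.batch_size[0], space.batch_size[1] + 1)),
        learning_rate=_log_uniform(rng, *space.learning_rate),
        l2_strength=_log_uniform(rng, *space.l2_strength),
        optimizer=str(rng.choice(space.optimizer)),
        instance_norm=bool(rng.choice(space.instance_norm)),
        rotation_freq=float(rng.uniform(*space.rotation_freq)),
        tilt_freq=float(rng.uniform(*space.tilt_freq)),
        noise_freq=float(rng.uniform(*space.noise_freq)),
        noise_factor=_log_uniform(rng, *space.noise_factor),
    )


def fold_training_objective(
    data,
    fold,
    max_epochs: int = 50,
    **reduced_scale,
) -> Callable[[HyperConfig], float]:
    """The default trial objective: train one fold under an epoch cap and
    return the best mean validation dice."""
    from .train import train_fold

    def objective(cfg: HyperConfig) -> float:
        preproc, arch, tcfg, aug = cfg.to_configs(
            max_epochs=max_epochs, **reduced_scale
        )
        bundle, _ = train_fold(fold, arch, tcfg, preproc, aug, data)
        return bundle.best_val_dice

    return objective


def run_search(
    space: SearchSpace,
    n_trials: int,
    objective: Callable[[HyperConfig], float],
    seed: int = 0,
) -> Tuple[pd.DataFrame, HyperConfig]:
    """Run ``n_trials`` random-sampling trials; failures are recorded and
    the search continues.  Returns the trial table (one row per attempted
    trial, ranked best-first) and the best configuration."""
    if n_trials < 1:
        raise ValidationError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    rows = []
    configs = []
    for t in range(n_trials):
        cfg = sample_config(space, rng)
        configs.append(cfg)
        row = {"trial": t, **asdict(cfg)}
        try:
            row["score"] = float(objective(cfg))
            row["error"] = ""
        except Exception as e:  # noqa: BLE001 - per-trial isolation
            row["score"] = float("nan")
            row["error"] = str(e)
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["score"].isna().all():
        raise RuntimeError("no successful trials")
    best_idx = int(table["score"].idxmax(skipna=True))
    table = table.sort_values("score", ascending=False, ignore_index=True)
    return table, configs[best_idx]
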