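"""Per-fold training with categorical dice loss, early stopping, and the
averaging ensemble over cross-validation folds.

One "epoch" is a fixed number of sampled patch batches (patch sampling
has no natural epoch boundary); after each epoch the model is scored by
the mean foreground Dice over full validation scans segmented with
sliding-window inference, the best-scoring weights are retained, and
training stops once a configured number of epochs pass without
improvement.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import AIR_HU, LabelMap, ValidationError, Volume, one_hot
from .model import ArchConfig, UNet3D, build_network
from .preprocess import (
    AugmentConfig,
    PatchPair,
    PreprocConfig,
    augment,
    normalize,
    normalized_air_value,
    resample_inplane,
    sample_patch,
)
from . import nn

FOREGROUND_CLASSES = (1, 2)
DICE_EPS = 1e-6


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------
def dice_loss(
    probabilities: np.ndarray,
    truth: np.ndarray,
    eps: float = DICE_EPS,
) -> float:
    """Mean categorical dice loss over the two foreground classes.

    ``probabilities`` is ``(C, X, Y, Z)`` (or batched ``(N, C, X, Y, Z)``,
    pooled over the batch); ``truth`` is the aligned integer label array.
    Returns ``1 - mean_c dice_c`` with smoothing ``eps``, in [0, 1].
    """
    p, g = _check_loss_shapes(probabilities, truth)
    loss = 1.0
    for c in FOREGROUND_CLASSES:
        num = 2.0 * float((p[:, c] * g[:, c]).sum()) + eps
        den = float(p[:, c].sum() + g[:, c].sum()) + eps
        loss -= 0.5 * num / den
    return float(loss)


def dice_loss_grad(
    probabilities: np.ndarray,
    truth: np.ndarray,
    eps: float = DICE_EPS,
) -> Tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the probabilities."""
    p, g = _check_loss_shapes(probabilities, truth)
    grad = np.zeros_like(p)
    loss = 1.0
    for c in FOREGROUND_CLASSES:
        num = 2.0 * float((p[:, c] * g[:, c]).sum()) + eps
        den = float(p[:, c].sum() + g[:, c].sum()) + eps
        loss -= 0.5 * num / den
        # d/dp of -(1/2) * num/den
        grad[:, c] = -0.5 * (2.0 * g[:, c] * den - num) / den**2
    if probabilities.ndim == 4:
        grad = grad[0]
    return float(loss), grad.astype(probabilities.dtype)


def _check_loss_shapes(probabilities: np.ndarray, truth: np.ndarray):
    p = np.asarray(probabilities)
    if p.ndim == 4:
        p = p[None]
    if p.ndim != 5:
        raise ValidationError(f"probabilities must be 4-D or 5-D, got {p.ndim}-D")
    t = np.asarray(truth)
    if t.ndim == 3:
        t = t[None]
    if t.shape != (p.shape[0],) + p.shape[2:]:
        raise ValidationError(
            f"truth shape {t.shape} does not match probabilities {p.shape}"
        )
    g = np.stack([one_hot(t[i], p.shape[1]) for i in range(t.shape[0])])
    return p, g


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class FoldPlan:
    """Cross-validation plan: disjoint validation sets, shared train pool."""

    fold_count: int
    folds: Tuple[Tuple[Tuple[str, ...], Tuple[str, ...]], ...]  # (train, val)

    @property
    def assignments(self) -> Dict[str, int]:
        out = {}
        for i, (_, val) in enumerate(self.folds):
            for sid in val:
                out[sid] = i
        return out


def make_folds(
    scan_ids: Sequence[str],
    fold_count: int = 5,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> FoldPlan:
    """Assign each of ``fold_count`` folds a disjoint validation set of
    ``val_fraction`` of the scans; the rest of the scans train that fold."""
    ids = [str(s) for s in scan_ids]
    if len(set(ids)) != len(ids):
        raise ValidationError("scan_ids contains duplicates")
    n = len(ids)
    if n < fold_count:
        raise ValidationError(f"need >= {fold_count} scans, got {n}")
    val_n = max(1, int(round(val_fraction * n)))
    if val_n * fold_count > n:
        raise ValidationError(
            f"cannot draw {fold_count} disjoint validation sets of {val_n} "
            f"from {n} scans"
        )
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    folds = []
    for i in range(fold_count):
        val = tuple(sorted(perm[i * val_n : (i + 1) * val_n]))
        train = tuple(sorted(s for s in ids if s not in val))
        folds.append((train, val))
    return FoldPlan(fold_count, tuple(folds))


# --------------------------------------------------------------------------
# configuration / bundles
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 13
    learning_rate: float = 4e-4
    optimizer: str = "rmsprop"
    patience_epochs: int = 50
    max_epochs: int = 1000
    batches_per_epoch: int = 50
    val_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValidationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.patience_epochs <= 0:
            raise ValidationError("patience_epochs must be > 0")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class ModelBundle:
    """A trained model plus everything inference needs to reproduce its
    preprocessing: architecture config, normalization strategy, fold id."""

    network: UNet3D
    arch: ArchConfig
    preproc: PreprocConfig
    fold_index: int = 0
    seed: int = 0
    best_epoch: int = -1
    best_val_dice: float = float("nan")

    @property
    def window_shape(self):
        return self.arch.window_shape

    def predict_probs(self, patch: np.ndarray) -> np.ndarray:
        return self.network.predict_probs(patch)

    def save(self, path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "arch": self.arch.to_dict(),
            "preproc": {
                "inplane_spacing_mm": self.preproc.inplane_spacing_mm,
                "normalization": self.preproc.normalization,
            },
            "fold_index": self.fold_index,
            "seed": self.seed,
            "best_epoch": self.best_epoch,
            "best_val_dice": self.best_val_dice,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        np.savez(path / "weights.npz", **self.network.state_dict())
        return path

    @staticmethod
    def load(path) -> "ModelBundle":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        arch = ArchConfig.from_dict(manifest["arch"])
        net = build_network(arch)
        with np.load(path / "weights.npz") as npz:
            net.load_state_dict(dict(npz))
        return ModelBundle(
            network=net,
            arch=arch,
            preproc=PreprocConfig(**manifest["preproc"]),
            fold_index=int(manifest["fold_index"]),
            seed=int(manifest["seed"]),
            best_epoch=int(manifest["best_epoch"]),
            best_val_dice=float(manifest["best_val_dice"]),
        )


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------
def _preprocess_case(
    vol: Volume, lab: Optional[LabelMap], preproc: PreprocConfig
):
    vol, lab = resample_inplane(vol, preproc.inplane_spacing_mm, lab)
    nvol, stats = normalize(vol, preproc.normalization)
    return nvol.intensities, (lab.labels if lab is not None else None), stats


def validation_dice(
    model, cases, overlap: float = 0.0
) -> float:
    """Mean foreground dice over preprocessed (image, labels, stats) cases."""
    from .evalstats import dice_coefficient
    from .infer import labels_from_probabilities_array, sliding_window_predict_array

    scores = []
    for img, lab, stats in cases:
        probs = sliding_window_predict_array(
            model, img, model.window_shape, overlap,
            pad_value=normalized_air_value(stats),
        )
        pred = labels_from_probabilities_array(probs)
        for c in FOREGROUND_CLASSES:
            scores.append(dice_coefficient(pred, lab, c))
    return float(np.mean(scores))


def train_fold(
    fold: Tuple[Sequence[str], Sequence[str]],
    arch: ArchConfig,
    tcfg: TrainConfig,
    preproc: PreprocConfig,
    aug: Optional[AugmentConfig],
    data: Mapping[str, Tuple[Volume, LabelMap]],
    fold_index: int = 0,
) -> Tuple[ModelBundle, pd.DataFrame]:
    """Train one fold's model; return the best-checkpoint bundle and log.

    The checkpoint retained is the one with the highest validation mean
    foreground dice seen so far; training stops after
    ``tcfg.patience_epochs`` epochs without improvement, or at
    ``tcfg.max_epochs``.
    """
    train_ids, val_ids = fold
    if not train_ids or not val_ids:
        raise ValidationError("fold must have non-empty train and validation sets")
    rng = np.random.default_rng(tcfg.seed)
    train_cases = [_preprocess_case(*data[s], preproc) for s in train_ids]
    val_cases = [_preprocess_case(*data[s], preproc) for s in val_ids]

    net = build_network(arch, seed=tcfg.seed)
    opt = nn.make_optimizer(
        tcfg.optimizer, net.parameters(), tcfg.learning_rate, arch.l2_strength
    )

    best_state = net.state_dict()
    best_dice = -np.inf
    best_epoch = -1
    rows = []
    for epoch in range(tcfg.max_epochs):
        losses = []
        for _ in range(tcfg.batches_per_epoch):
            imgs, labs = [], []
            for _ in range(tcfg.batch_size):
                ci = int(rng.integers(len(train_cases)))
                img, lab, stats = train_cases[ci]
                pair = sample_patch(
                    img, lab, arch.window_shape, rng,
                    pad_value=normalized_air_value(stats),
                )
                if aug is not None:
                    pair = augment(pair, aug, rng)
                imgs.append(pair.image)
                labs.append(pair.labels)
            x = np.stack(imgs)[:, None].astype(np.float32)
            y = np.stack(labs)
            probs = net.forward(x, train=True)
            loss, dprobs = dice_loss_grad(probs, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            losses.append(loss)
            net.backward(dprobs)
            opt.step(net.gradients())
        vdice = validation_dice(net, val_cases, overlap=tcfg.val_overlap)
        rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_dice": vdice}
        )
        if vdice > best_dice:
            best_dice = vdice
            best_epoch = epoch
            best_state = net.state_dict()
        elif epoch - best_epoch >= tcfg.patience_epochs:
            break
    net.load_state_dict(best_state)
    bundle = ModelBundle(
        network=net,
        arch=arch,
        preproc=preproc,
        fold_index=fold_index,
        seed=tcfg.seed,
        best_epoch=best_epoch,
        best_val_dice=float(best_dice),
    )
    return bundle, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ensembling
# --------------------------------------------------------------------------
class Ensemble:
    """Averaging ensemble: the mean of member per-voxel probabilities.

    The mean of normalized probability maps is itself normalized, so no
    renormalization is applied.
    """

    def __init__(self, members: Sequence[ModelBundle]):
        if not members:
            raise ValidationError("ensemble needs at least one member")
        ref = members[0]
        for m in members[1:]:
            if m.arch != ref.arch or m.preproc != ref.preproc:
                raise ValidationError(
                    "ensemble members must share architecture and "
                    "preprocessing configuration"
                )
        self.members = list(members)
        self.arch = ref.arch
        self.preproc = ref.preproc

    @property
    def window_shape(self):
        return self.arch.window_shape

    def predict_probs(self, patch: np.ndarray) -> np.ndarray:
        acc = self.members[0].predict_probs(patch)
        for m in self.members[1:]:
            acc = acc + m.predict_probs(patch)
        return acc / len(self.members)


def build_ensemble(bundles: Sequence[ModelBundle]) -> Ensemble:
    return Ensemble(bundles)
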