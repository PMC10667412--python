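"""Shared fixtures.

The expensive fixture is ``reduced_training``: one seed-fixed training run
of the reduced dual-attention U-Net on 20 synthetic phantoms, shared
(session-scoped) by the training unit tests and the end-to-end learning
check so the suite trains only once.
"""

from __future__ import annotations

import numpy as np
import pytest

from focusedview.evalstats import dice_coefficient
from focusedview.infer import segment_volume
from focusedview.model import ArchConfig
from focusedview.phantom import PhantomSpec, generate_dataset, generate_phantom
from focusedview.preprocess import PreprocConfig
from focusedview.train import TrainConfig, train_fold

#: the reduced-scale study conditions (also used by scripts/acceptance.py)
REDUCED_ARCH = dict(
    architecture="dual_attention_unet",
    window_shape=(32, 32, 16),
    base_filters=8,
    depth=2,
    l2_strength=2e-4,
)
REDUCED_TRAIN = dict(
    batch_size=3,
    learning_rate=2e-3,
    optimizer="rmsprop",
    patience_epochs=30,
    max_epochs=26,
    batches_per_epoch=15,
)
PHANTOM_GRID = (48, 48, 64)


@pytest.fixture(scope="session")
def small_phantom():
    """A small noiseless-by-default phantom pair for fast I/O tests."""
    return generate_phantom(PhantomSpec(grid_shape=(32, 32, 24), seed=4))


@pytest.fixture(scope="session")
def phantom_pair():
    """A mid-sized phantom with default noise."""
    return generate_phantom(PhantomSpec(grid_shape=PHANTOM_GRID, seed=3))


@pytest.fixture(scope="session")
def reduced_training():
    """Train the reduced network once on 20 phantoms; 16 train / 2 val /
    2 held-out test cases, fixed seeds throughout."""
    spec = PhantomSpec(grid_shape=PHANTOM_GRID)
    data = {
        f"case{i:02d}": vl
        for i, vl in enumerate(generate_dataset(20, spec, seed=11))
    }
    ids = sorted(data)
    train_ids, val_ids, test_ids = ids[:16], ids[16:18], ids[18:]
    arch = ArchConfig(**REDUCED_ARCH)
    tcfg = TrainConfig(seed=0, **REDUCED_TRAIN)
    preproc = PreprocConfig(inplane_spacing_mm=1.0, normalization="z_norm")
    bundle, log = train_fold((train_ids, val_ids), arch, tcfg, preproc, None, data)
    dice = {1: [], 2: []}
    for tid in test_ids:
        vol, lab = data[tid]
        pred, _ = segment_volume(bundle, vol, overlap_fraction=0.5)
        for c in (1, 2):
            dice[c].append(dice_coefficient(pred, lab, c))
    return {
        "bundle": bundle,
        "log": log,
        "data": data,
        "train_ids": train_ids,
        "val_ids": val_ids,
        "test_ids": test_ids,
        "heldout_dice": {c: float(np.mean(v)) for c, v in dice.items()},
    }
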