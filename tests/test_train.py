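"""Dice loss contracts, fold construction, early stopping, ensembling."""

import numpy as np
import pytest

import focusedview.train as train_mod
from focusedview.core import ValidationError, one_hot
from focusedview.model import ArchConfig
from focusedview.preprocess import PreprocConfig
from focusedview.train import (
    ModelBundle,
    TrainConfig,
    build_ensemble,
    dice_loss,
    dice_loss_grad,
    make_folds,
    train_fold,
)

EPS = 1e-6


class TestDiceLoss:
    def test_perfect_one_hot_is_zero(self):
        y = np.random.default_rng(0).integers(0, 3, (6, 6, 4))
        # ensure both foreground classes present
        y[0, 0, 0], y[0, 0, 1] = 1, 2
        p = one_hot(y)
        assert dice_loss(p, y) <= 1e-6

    def test_all_background_prediction_approaches_one(self):
        y = np.ones((4, 4, 4), dtype=np.uint8)
        y[2:] = 2  # both foreground classes present in the truth
        p = np.zeros((3, 4, 4, 4), dtype=np.float64)
        p[0] = 1.0  # predicts background everywhere: zero overlap
        loss = dice_loss(p, y, eps=1e-12)
        assert loss > 1.0 - 1e-6

    def test_uniform_probability_closed_form(self):
        """Uniform 1/3 probabilities against the closed form
        1 - (1/2) sum_c (2 n_c/3 + eps) / (N/3 + n_c + eps)."""
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, (5, 7, 3))
        n_tot = y.size
        p = np.full((3,) + y.shape, 1.0 / 3.0, dtype=np.float64)
        expected = 1.0
        for c in (1, 2):
            n_c = int((y == c).sum())
            expected -= 0.5 * (2 * n_c / 3 + EPS) / (n_tot / 3 + n_c + EPS)
        assert abs(dice_loss(p, y) - expected) < 1e-10

    def test_bounded_and_permutation_invariant(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, (4, 4, 2))
        logits = rng.normal(size=(3, 4, 4, 2))
        p = np.exp(logits) / np.exp(logits).sum(0)
        l0 = dice_loss(p, y)
        assert 0.0 <= l0 <= 1.0
        perm = rng.permutation(y.size)
        yp = y.ravel()[perm].reshape(y.shape)
        pp = p.reshape(3, -1)[:, perm].reshape(p.shape)
        assert abs(dice_loss(pp, yp) - l0) < 1e-12

    def test_monotone_improvement_toward_truth(self):
        """Flipping one-hot predictions voxel-by-voxel toward the truth
        never increases the loss."""
        rng = np.random.default_rng(3)
        y = rng.integers(0, 3, (4, 4, 2))
        pred = rng.integers(0, 3, y.shape)
        wrong = list(zip(*np.nonzero(pred != y)))
        last = dice_loss(one_hot(pred), y)
        for idx in wrong:
            pred[idx] = y[idx]
            cur = dice_loss(one_hot(pred), y)
            assert cur <= last + 1e-12
            last = cur

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, (3, 3, 2))
        p = rng.uniform(0.1, 1.0, (3, 3, 3, 2))
        p /= p.sum(0)
        _, g = dice_loss_grad(p, y)
        eps = 1e-7
        for _ in range(5):
            i = tuple(rng.integers(0, s) for s in p.shape)
            old = p[i]
            p[i] = old + eps
            fp = dice_loss(p, y)
            p[i] = old - eps
            fm = dice_loss(p, y)
            p[i] = old
            assert abs((fp - fm) / (2 * eps) - g[i]) < 1e-6

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            dice_loss(np.zeros((3, 4, 4, 4)), np.zeros((5, 5, 5), dtype=int))


class TestFolds:
    def test_hundred_scans_give_disjoint_tens(self):
        ids = [f"s{i}" for i in range(100)]
        plan = make_folds(ids, fold_count=5, seed=1)
        vals = [set(v) for _, v in plan.folds]
        assert all(len(v) == 10 for v in vals)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not (vals[i] & vals[j])
        for tr, va in plan.folds:
            assert set(tr) | set(va) == set(ids)
            assert not (set(tr) & set(va))

    def test_small_cohort_with_explicit_fraction(self):
        plan = make_folds([f"s{i}" for i in range(10)], fold_count=5, seed=0,
                          val_fraction=0.2)
        vals = [set(v) for _, v in plan.folds]
        assert all(len(v) == 2 for v in vals)
        assert len(set.union(*vals)) == 10

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(30)]
        assert make_folds(ids, seed=5) == make_folds(ids, seed=5)
        assert make_folds(ids, seed=5) != make_folds(ids, seed=6)

    def test_too_few_scans_rejected(self):
        with pytest.raises(ValidationError):
            make_folds(["a", "b"], fold_count=5)


class TestEarlyStopping:
    def test_stops_after_patience_and_keeps_best(self, monkeypatch):
        """With patience 1 and a strictly worsening metric, training runs
        two epochs and retains the first checkpoint."""
        scores = iter([0.9, 0.8, 0.7, 0.6])
        monkeypatch.setattr(
            train_mod, "validation_dice", lambda *a, **k: next(scores)
        )
        from focusedview.phantom import PhantomSpec, generate_dataset

        data = {
            f"c{i}": vl
            for i, vl in enumerate(
                generate_dataset(3, PhantomSpec(grid_shape=(16, 16, 16)), 0)
            )
        }
        arch = ArchConfig(architecture="basic_unet", window_shape=(16, 16, 8),
                          base_filters=2, depth=1)
        tcfg = TrainConfig(batch_size=1, patience_epochs=1, max_epochs=10,
                           batches_per_epoch=1, learning_rate=1e-3,
                           optimizer="adam", seed=0)
        preproc = PreprocConfig(1.0, "z_norm")
        bundle, log = train_fold((["c0", "c1"], ["c2"]), arch, tcfg, preproc,
                                 None, data)
        assert len(log) == 2  # epoch 0 best, epoch 1 worse, stop
        assert bundle.best_epoch == 0
        assert bundle.best_val_dice == 0.9

    def test_best_checkpoint_never_worse_than_any_epoch(self, reduced_training):
        log = reduced_training["log"]
        assert reduced_training["bundle"].best_val_dice == log["val_dice"].max()
        assert len(log) == log["epoch"].nunique()


class TestLearning:
    def test_reduced_network_learns_segmentation(self, reduced_training):
        """The reduced dual-attention U-Net reaches a useful validation
        dice on phantoms — the learning signal is real, not noise."""
        assert reduced_training["bundle"].best_val_dice >= 0.6
        log = reduced_training["log"]
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]

    def test_bundle_save_load_round_trip(self, reduced_training, tmp_path):
        bundle = reduced_training["bundle"]
        bundle.save(tmp_path / "fold_0")
        loaded = ModelBundle.load(tmp_path / "fold_0")
        x = np.random.default_rng(0).normal(size=bundle.window_shape).astype(
            np.float32
        )
        assert np.array_equal(bundle.predict_probs(x), loaded.predict_probs(x))
        assert loaded.preproc == bundle.preproc


class _ConstantModel:
    def __init__(self, probs, window):
        self._p = probs
        self.window_shape = window
        self.arch = None
        self.preproc = None

    def predict_probs(self, patch):
        return np.broadcast_to(
            self._p.reshape(3, 1, 1, 1), (3,) + patch.shape
        ).astype(np.float32)


class TestEnsemble:
    def test_singleton_ensemble_identity(self, reduced_training):
        bundle = reduced_training["bundle"]
        ens = build_ensemble([bundle])
        x = np.random.default_rng(1).normal(size=bundle.window_shape).astype(
            np.float32
        )
        assert np.array_equal(ens.predict_probs(x), bundle.predict_probs(x))

    def test_two_constant_members_average(self):
        from focusedview.train import Ensemble

        p = np.array([0.5, 0.3, 0.2])
        q = np.array([0.1, 0.1, 0.8])
        ens = Ensemble.__new__(Ensemble)
        ens.members = [_ConstantModel(p, (4, 4, 4)), _ConstantModel(q, (4, 4, 4))]
        out = ens.predict_probs(np.zeros((4, 4, 4)))
        assert np.allclose(out[:, 0, 0, 0], (p + q) / 2)

    def test_five_members_match_explicit_mean(self):
        cfg = ArchConfig(architecture="basic_unet", window_shape=(16, 16, 8),
                         base_filters=2, depth=1)
        from focusedview.model import build_network
        from focusedview.train import Ensemble

        nets = [build_network(cfg, seed=s) for s in range(5)]
        ens = Ensemble.__new__(Ensemble)
        ens.members = nets
        x = np.random.default_rng(2).normal(size=(16, 16, 8)).astype(np.float32)
        explicit = np.mean([n.predict_probs(x) for n in nets], axis=0)
        assert np.abs(ens.predict_probs(x) - explicit).max() < 1e-6
        assert np.abs(ens.predict_probs(x).sum(0) - 1).max() < 1e-5

    def test_mismatched_members_rejected(self, reduced_training):
        bundle = reduced_training["bundle"]
        other = ModelBundle(
            network=bundle.network,
            arch=bundle.arch,
            preproc=PreprocConfig(0.5, "z_norm"),
        )
        with pytest.raises(ValidationError):
            build_ensemble([bundle, other])
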