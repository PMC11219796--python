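"""Losses, augmentation, the optimization schedule and evaluation metrics."""

import numpy as np
import pytest

import cryoflex as cf
from cryoflex.boxing import SampleBox
from cryoflex.nn import Tensor
from cryoflex.train import OCC_THRESHOLDS


class TestMaskedMSE:
    def test_exact_cases(self, rng):
        pred = rng.normal(size=(10, 10, 10)).astype(np.float32)
        assert cf.masked_mse(pred, pred, np.ones_like(pred, bool)) == 0.0
        target = pred.copy()
        mask = np.zeros_like(pred, bool)
        mask.ravel()[[3, 77, 400, 512, 999]] = True
        target[mask] -= 1.0
        target[~mask] += rng.normal(0, 5, size=(~mask).sum())  # ignored
        assert cf.masked_mse(pred, target, mask) == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            pred = rng.normal(size=(6, 6, 6))
            target = rng.normal(size=(6, 6, 6))
            mask = rng.random((6, 6, 6)) > 0.6
            if not mask.any():
                continue
            brute = np.sum((pred[mask] - target[mask]) ** 2) / mask.sum()
            assert cf.masked_mse(pred.astype(np.float32), target, mask) == \
                pytest.approx(brute, abs=1e-5)

    def test_equals_plain_mse_when_all_true(self, rng):
        pred = rng.normal(size=(5, 5, 5))
        target = rng.normal(size=(5, 5, 5))
        assert cf.masked_mse(pred, target, np.ones_like(pred, bool)) == \
            pytest.approx(float(np.mean((pred - target) ** 2)), rel=1e-5)

    def test_empty_mask_raises(self):
        z = np.zeros((4, 4, 4), np.float32)
        with pytest.raises(ValueError):
            cf.masked_mse(z, z, np.zeros_like(z, bool))


class TestWeightedCrossEntropy:
    def test_near_perfect_probabilities(self):
        truth = np.zeros((4, 4, 4), np.float32)
        truth[0, 0, 0] = 1.0
        probs = np.empty((2, 4, 4, 4), np.float32)
        probs[1] = np.where(truth > 0, 1 - 1e-7, 1e-7)
        probs[0] = 1 - probs[1]
        assert cf.weighted_cross_entropy(probs, truth) < 1e-5

    def test_uniform_half_hand_formula(self):
        truth = np.zeros((4, 4, 4), np.float32)
        truth.ravel()[:10] = 1.0  # 10 occupied, 54 background
        probs = np.full((2, 4, 4, 4), 0.5, np.float32)
        w0, w1 = 0.05, 0.95
        hand = (10 * w1 * np.log(2) + 54 * w0 * np.log(2)) / (10 * w1 + 54 * w0)
        assert cf.weighted_cross_entropy(probs, truth) == \
            pytest.approx(hand, abs=1e-6)

    def test_weight_swap_symmetry(self, rng):
        logits = rng.normal(0, 1, (2, 4, 4, 4)).astype(np.float32)
        e = np.exp(logits)
        probs = (e / e.sum(axis=0)).astype(np.float32)
        imbalanced = np.zeros((4, 4, 4), np.float32)
        imbalanced.ravel()[:5] = 1.0
        a = cf.weighted_cross_entropy(probs, imbalanced, (0.05, 0.95))
        b = cf.weighted_cross_entropy(probs, imbalanced, (0.95, 0.05))
        assert a != pytest.approx(b, rel=1e-3)
        balanced = np.zeros((4, 4, 4), np.float32)
        balanced.ravel()[:32] = 1.0
        # same per-voxel probability for both classes -> swap has no effect
        probs_sym = np.full((2, 4, 4, 4), 0.5, np.float32)
        a = cf.weighted_cross_entropy(probs_sym, balanced, (0.05, 0.95))
        b = cf.weighted_cross_entropy(probs_sym, balanced, (0.95, 0.05))
        assert a == pytest.approx(b, abs=1e-7)

    def test_invalid_probabilities(self):
        bad = np.full((2, 4, 4, 4), 1.5, np.float32)
        with pytest.raises(ValueError):
            cf.weighted_cross_entropy(bad, np.zeros((4, 4, 4)))


def _sample(rng):
    return SampleBox(rng.random((2, 8, 8, 8)).astype(np.float32), (0, 0, 0),
                     rng.random((4, 4, 4)).astype(np.float32),
                     rng.random((4, 4, 4)) > 0.5,
                     (rng.random((8, 8, 8)) > 0.8).astype(np.float32))


class TestAugment:
    def test_exactly_eight_involutions(self, rng):
        sample = _sample(rng)
        out = cf.augment_box(sample)
        assert len(out) == 8
        # identity present; every transform applied twice is the original
        assert any(np.array_equal(o.channels, sample.channels) for o in out)
        for o in out:
            twice = None
            for oo in cf.augment_box(o):
                if np.array_equal(oo.channels, sample.channels):
                    twice = oo
            assert twice is not None
            assert np.array_equal(twice.label, sample.label)
            assert np.array_equal(twice.mask, sample.mask)
            assert np.array_equal(twice.occupancy, sample.occupancy)

    def test_constant_box_gives_copies(self):
        sample = SampleBox(np.full((1, 8, 8, 8), 0.3, np.float32), (0, 0, 0),
                           np.full((4, 4, 4), 1.0, np.float32),
                           np.ones((4, 4, 4), bool))
        for o in cf.augment_box(sample):
            assert np.array_equal(o.channels, sample.channels)
            assert np.array_equal(o.label, sample.label)

    def test_flip_equivariant_stub_loss_invariance(self, rng):
        """A mean-pooling predictor is flip-equivariant, so the loss of every
        augmented copy equals the unaugmented loss."""
        sample = _sample(rng)

        def stub_loss(s):
            pred = s.channels[0, 2:6, 2:6, 2:6]  # crop commutes with flips
            return cf.masked_mse(pred, s.label, s.mask)

        base = stub_loss(sample)
        for o in cf.augment_box(sample):
            assert stub_loss(o) == pytest.approx(base, rel=1e-6)


class _ConstantLossStub:
    """Objective whose loss never improves: exercises the lr/stop schedule."""

    def __init__(self, value=1.0):
        self.p = Tensor(np.zeros(1, np.float32), requires_grad=True)
        self.value = value
        self.saved = 0

    def parameters(self):
        return [self.p]

    def batch_loss(self, samples):
        out = self.p * 0.0
        out.data = out.data + self.value
        return out

    def state(self):
        self.saved += 1
        return {"p": self.p.data.copy(), "tag": self.saved}

    def load(self, state):
        self.loaded = state


class TestSchedule:
    def test_constant_loss_walkthrough(self):
        stub = _ConstantLossStub()
        cfg = cf.TrainConfig(epochs=200, batch_size=2, learning_rate=0.004,
                             augment=False, seed=0)
        result = cf.train(stub, [1, 2], [3], cfg)
        h = result.history
        # improvement only on the very first epoch, then 30 stagnant epochs
        assert len(h) == 31
        assert result.best_epoch == 1
        assert result.lr_halvings == [10, 20]  # stagnant counts at halving
        lrs = h["lr"].to_numpy()
        assert lrs[9] == pytest.approx(0.004)        # before first halving
        assert lrs[10] == pytest.approx(0.002)       # stagnant == 10
        assert lrs[20] == pytest.approx(0.001)       # stagnant == 20
        assert h["stagnant"].iloc[-1] == 30
        # min-validation checkpoint (epoch 1 snapshot) is restored
        assert stub.loaded["tag"] == 1

    def test_overfit_smoke_and_determinism(self, small_entry):
        from cryoflex.model import entry_sample_boxes
        from cryoflex.nn import NetworkConfig, build_rmsf_network
        from cryoflex.train import RMSFObjective

        boxes = entry_sample_boxes(small_entry, "dual")[:6]
        cfg = cf.TrainConfig(epochs=12, batch_size=6, augment=False, seed=4,
                             micro_batch=3)

        losses = []
        for _ in range(2):
            net = build_rmsf_network(NetworkConfig(variant="dual",
                                                   base_channels=4, seed=4))
            res = cf.train(RMSFObjective(net), boxes, boxes, cfg)
            losses.append(res)
        h0 = losses[0].history
        assert h0["train_loss"].iloc[-1] < 0.5 * h0["train_loss"].iloc[0]
        # identical seed -> bit-identical history
        assert np.array_equal(h0["val_loss"].to_numpy(),
                              losses[1].history["val_loss"].to_numpy())

    def test_empty_sets_raise(self):
        with pytest.raises(ValueError):
            cf.train(_ConstantLossStub(), [], [1], cf.TrainConfig())


class TestMetrics:
    def test_pearson_cases(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 3.0])
        hand = (np.sum((a - a.mean()) * (b - b.mean()))
                / np.sqrt(np.sum((a - a.mean()) ** 2)
                          * np.sum((b - b.mean()) ** 2)))
        assert cf.pearson_cc(a, b) == pytest.approx(hand)
        assert cf.pearson_cc(a, a) == pytest.approx(1.0)
        assert cf.pearson_cc(a, -a) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            cf.pearson_cc(a, np.ones(4))

    def test_evaluate_entry(self, rng):
        shape = (8, 8, 8)
        mask = rng.random(shape) > 0.5
        vals = rng.normal(1.5, 0.5, shape).astype(np.float32)
        truth = cf.RMSFMap(cf.VoxelGrid(vals, 1.5), mask)
        pred = cf.RMSFMap(cf.VoxelGrid(vals.copy(), 1.5), mask)
        out = cf.evaluate_entry(pred, truth, [1.0, 2.0], [1.0, 2.0])
        assert out["voxel_cc"] == pytest.approx(1.0)
        assert out["residue_cc"] == pytest.approx(1.0)
        # affine rescaling leaves the correlation unchanged
        scaled = cf.RMSFMap(cf.VoxelGrid(2.0 * vals + 1.0, 1.5), mask)
        noise = cf.RMSFMap(
            cf.VoxelGrid((vals + rng.normal(0, 0.2, shape)).astype(np.float32),
                         1.5), mask)
        assert cf.evaluate_entry(scaled, noise)["voxel_cc"] == \
            pytest.approx(cf.evaluate_entry(pred, noise)["voxel_cc"], abs=1e-6)
        # voxels outside the mask are irrelevant
        outside = cf.RMSFMap(cf.VoxelGrid(
            np.where(mask, vals, rng.normal(size=shape)).astype(np.float32),
            1.5), mask)
        assert cf.evaluate_entry(outside, truth)["voxel_cc"] == \
            pytest.approx(1.0)
        with pytest.raises(ValueError):
            cf.evaluate_entry(
                cf.RMSFMap(cf.VoxelGrid(vals, 1.5), np.zeros(shape, bool)),
                truth)

    def test_two_residue_toy(self):
        pred = np.array([1.0, 3.0])
        truth = np.array([2.0, 5.0])
        assert cf.pearson_cc(pred, truth) == pytest.approx(1.0)

    def test_kfold_arithmetic(self):
        entries = list(range(20))
        folds = cf.kfold_split(entries, k=5, seed=3)
        assert len(folds) == 5
        all_test = [e for f in folds for e in f["test"]]
        assert sorted(all_test) == entries  # each entry tested exactly once
        for f in folds:
            assert len(f["test"]) == 4
            assert len(f["val"]) == 4
            assert len(f["train"]) == 12
            assert not set(f["test"]) & (set(f["train"]) | set(f["val"]))
        with pytest.raises(ValueError):
            cf.kfold_split([1, 2, 3], k=5)

    def test_occ_metrics(self):
        truth = np.zeros((1, 4, 4, 4), np.float32)
        truth.ravel()[:3] = 1.0
        perfect = np.empty((1, 2, 4, 4, 4), np.float32)
        perfect[:, 1] = truth
        perfect[:, 0] = 1 - truth
        table = cf.occ_metrics(perfect, truth)
        assert len(table) == len(OCC_THRESHOLDS) == 6
        assert (table[["precision", "recall", "f1"]] == 1.0).all().all()
        # TP=2 FP=1 FN=1 at threshold 0.5
        probs = np.zeros((1, 2, 4, 4, 4), np.float32)
        probs[:, 1].ravel()[[0, 1, 3]] = 0.9  # predicts voxels 0,1,3
        probs[:, 0] = 1 - probs[:, 1]
        row = cf.occ_metrics(probs, truth).set_index("threshold").loc[0.5]
        assert row["precision"] == pytest.approx(2 / 3)
        assert row["recall"] == pytest.approx(2 / 3)
        assert row["f1"] == pytest.approx(2 / 3)


class TestPredictPipeline:
    def test_prediction_plumbing(self, small_entry):
        from cryoflex.nn import NetworkConfig, build_rmsf_network
        net = build_rmsf_network(NetworkConfig(variant="dual",
                                               base_channels=2, seed=0))
        pred = cf.predict_rmsf_map(net, small_entry.cryo_map,
                                   small_entry.model, "dual")
        occ = cf.occupancy_annotation(small_entry.model, small_entry.cryo_map)
        assert np.array_equal(pred.rmsf_map.mask, occ.values > 0)
        assert len(pred.per_atom) == small_entry.model.n_atoms
        assert len(pred.per_residue) == len(small_entry.model.residue_keys())
        # a single-atom residue's value equals the map value at its voxel
        idx = cf.world_to_voxel(small_entry.cryo_map,
                                small_entry.model.coords[0])
        assert pred.per_residue[0] == pytest.approx(
            pred.rmsf_map.values.values[idx])
        with pytest.raises(ValueError):
            cf.predict_rmsf_map(net, small_entry.cryo_map, small_entry.model,
                                "cryo")
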