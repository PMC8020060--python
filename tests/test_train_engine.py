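"""Losses (closed-form identities and numeric gradients), the training
loop, fine-tuning on degraded volumes, and checkpoint round-trips."""

import numpy as np
import pytest

from comproseg.phantom_gen import PhantomParams, generate_cohort
from comproseg.train_engine import (
    Cohort,
    TrainConfig,
    TrainingDivergedError,
    finetune,
    load_checkpoint,
    loss_l2d,
    loss_l2d_grad,
    loss_l3d,
    loss_l3d_grad,
    save_checkpoint,
    train,
)
from comproseg.unet_models import UNetConfig, build_unet


def random_probs(rng, shape):
    """A valid probability map over 3 classes with the given spatial shape."""
    z = rng.normal(size=(3, *shape))
    e = np.exp(z - z.max(axis=0))
    return e / e.sum(axis=0)


def one_hot_from_labels(labels):
    t = np.zeros((3, *labels.shape))
    for c in range(3):
        t[c] = labels == c
    return t


@pytest.fixture(scope="module")
def tiny_cohort():
    params = PhantomParams(grid_shape=(32, 32, 24), spacing=(7.2, 7.2, 10.0), seed=3)
    patients, split = generate_cohort(params, n_ct=2, n_cbct=0)
    return Cohort(patients, split)


class TestLossL3D:
    def test_perfect_prediction_is_minus_four(self):
        rng = np.random.default_rng(0)
        t = one_hot_from_labels(rng.integers(0, 3, size=(6, 6, 6)))
        assert loss_l3d(t, t) == pytest.approx(-4.0)

    def test_bounded_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = one_hot_from_labels(rng.integers(0, 3, size=(5, 5, 4)))
            p = random_probs(rng, (5, 5, 4))
            assert -4.0 <= loss_l3d(p, t) <= 0.0

    def test_rectum_weighted_three_to_one(self):
        # flipping the prediction of one rectum voxel moves the loss ~3x more
        # than flipping one bladder voxel of the same geometry
        t = np.zeros((3, 4, 4, 4))
        t[0, 1, 1, 1] = 1
        t[1, 2, 2, 2] = 1
        t[2] = 1 - t[0] - t[1]
        base = loss_l3d(t, t)
        miss_b = t.copy()
        miss_b[0, 1, 1, 1], miss_b[2, 1, 1, 1] = 0, 1
        miss_r = t.copy()
        miss_r[1, 2, 2, 2], miss_r[2, 2, 2, 2] = 0, 1
        db = loss_l3d(miss_b, t) - base
        dr = loss_l3d(miss_r, t) - base
        assert dr == pytest.approx(3 * db)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        t = one_hot_from_labels(rng.integers(0, 3, size=(3, 3, 3)))
        p = random_probs(rng, (3, 3, 3))
        _, g = loss_l3d_grad(p, t)
        h = 1e-6
        for idx in [(0, 0, 0, 0), (1, 1, 2, 0), (0, 2, 2, 2), (2, 1, 1, 1)]:
            pp, pm = p.copy(), p.copy()
            pp[idx] += h
            pm[idx] -= h
            num = (loss_l3d(pp, t) - loss_l3d(pm, t)) / (2 * h)
            assert g[idx] == pytest.approx(num, abs=1e-5)

    def test_background_gradient_is_zero(self):
        rng = np.random.default_rng(3)
        t = one_hot_from_labels(rng.integers(0, 3, size=(4, 4, 4)))
        _, g = loss_l3d_grad(random_probs(rng, (4, 4, 4)), t)
        assert (g[2] == 0).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss_l3d(np.zeros((3, 4, 4, 4)), np.zeros((3, 4, 4, 2)))


class TestLossL2D:
    def test_uniform_prediction_closed_form(self):
        n = 7 * 5
        t = one_hot_from_labels(np.random.default_rng(0).integers(0, 3, size=(7, 5)))
        p = np.full((3, 7, 5), 1 / 3)
        assert loss_l2d(p, t) == pytest.approx(n * np.log(3))

    def test_perfect_prediction_is_zero(self):
        t = one_hot_from_labels(np.random.default_rng(1).integers(0, 3, size=(6, 6)))
        assert loss_l2d(t, t) == pytest.approx(0.0)

    def test_clamp_keeps_loss_finite_at_zero_probability(self):
        t = np.zeros((3, 1, 1))
        t[0] = 1
        p = np.zeros((3, 1, 1))
        p[1] = 1
        assert np.isfinite(loss_l2d(p, t))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        t = one_hot_from_labels(rng.integers(0, 3, size=(4, 4)))
        p = random_probs(rng, (4, 4))
        _, g = loss_l2d_grad(p, t)
        h = 1e-7
        for idx in [(0, 0, 0), (1, 2, 3), (2, 1, 1)]:
            pp, pm = p.copy(), p.copy()
            pp[idx] += h
            pm[idx] -= h
            num = (loss_l2d(pp, t) - loss_l2d(pm, t)) / (2 * h)
            assert g[idx] == pytest.approx(num, rel=1e-3)

    def test_batched_input_accepted(self):
        rng = np.random.default_rng(5)
        t = np.stack([one_hot_from_labels(rng.integers(0, 3, size=(4, 4)))
                      for _ in range(2)])
        p = np.stack([random_probs(rng, (4, 4)) for _ in range(2)])
        assert loss_l2d(p, t) == pytest.approx(
            loss_l2d(p[0], t[0]) + loss_l2d(p[1], t[1]))


class TestTrainConfig:
    def test_bad_phase_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(phase="warmup")

    def test_finetune_requires_ratio(self):
        with pytest.raises(ValueError):
            TrainConfig(phase="finetune")


class TestTraining:
    def test_3d_loss_decreases(self, tiny_cohort):
        model = build_unet(UNetConfig(dims=3, depth=2, base_features=4), seed=0)
        hist = train(model, tiny_cohort,
                     TrainConfig(epochs=15, learning_rate=3e-2, seed=0))
        assert len(hist) == 15
        assert hist[-1] < hist[0]

    def test_2d_loss_decreases_and_is_per_pixel(self, tiny_cohort):
        model = build_unet(UNetConfig(dims=2, depth=1, base_features=8), seed=0)
        hist = train(model, tiny_cohort,
                     TrainConfig(epochs=8, batch_size=4, learning_rate=1e-3, seed=0))
        assert hist[-1] < hist[0]
        # per-pixel cross-entropy can never exceed the clamp bound
        assert all(0 <= h <= -np.log(1e-7) for h in hist)

    def test_training_is_seeded(self, tiny_cohort):
        outs = []
        for _ in range(2):
            model = build_unet(UNetConfig(dims=3, depth=2, base_features=2), seed=1)
            hist = train(model, tiny_cohort, TrainConfig(epochs=2, seed=5))
            outs.append((hist, model.get_weights()))
        assert outs[0][0] == outs[1][0]
        assert all((a == b).all() for a, b in zip(outs[0][1], outs[1][1]))

    def test_ce_weight_adds_positive_term(self, tiny_cohort):
        # the auxiliary CE term is >= 0, so with it the reported 3D loss
        # must sit above the pure soft-Dice loss of an identical run
        hists = []
        for cw in (0.0, 1.0):
            model = build_unet(UNetConfig(dims=3, depth=2, base_features=2), seed=0)
            hists.append(train(model, tiny_cohort,
                               TrainConfig(epochs=1, seed=0, ce_weight=cw)))
        assert hists[1][0] > hists[0][0]

    def test_divergence_raises(self, tiny_cohort):
        model = build_unet(UNetConfig(dims=3, depth=2, base_features=2), seed=0)
        model.set_weights([np.full_like(w, np.nan) for w in model.get_weights()])
        with pytest.raises(TrainingDivergedError):
            train(model, tiny_cohort, TrainConfig(epochs=1, seed=0))


class TestFinetune:
    def test_base_model_untouched_and_copy_returned(self, tiny_cohort):
        model = build_unet(UNetConfig(dims=3, depth=2, base_features=2), seed=0)
        before = model.get_weights()
        ft, hist = finetune(model, tiny_cohort, ratio=32,
                            cfg=TrainConfig(epochs=2, seed=0))
        assert ft is not model
        assert all((a == b).all() for a, b in zip(model.get_weights(), before))
        assert len(hist) == 2

    def test_ratio_one_equals_base_phase_retraining(self, tiny_cohort):
        # at ratio 1 the degraded set is the identity, so fine-tuning must
        # reproduce a base-phase run from the same weights and seed
        cfg = TrainConfig(epochs=2, seed=3)
        model = build_unet(UNetConfig(dims=3, depth=2, base_features=2), seed=2)
        ft, _ = finetune(model, tiny_cohort, ratio=1, cfg=cfg)
        ref = build_unet(UNetConfig(dims=3, depth=2, base_features=2), seed=2)
        train(ref, tiny_cohort, cfg)
        assert all(np.allclose(a, b) for a, b in zip(ft.get_weights(), ref.get_weights()))

    def test_invalid_ratio_rejected(self, tiny_cohort):
        model = build_unet(UNetConfig(dims=3, depth=2, base_features=2), seed=0)
        with pytest.raises(ValueError):
            finetune(model, tiny_cohort, ratio=0.5, cfg=TrainConfig(epochs=1))


class TestCheckpoints:
    def test_round_trip_reproduces_outputs(self, tmp_path):
        model = build_unet(UNetConfig(dims=2, depth=1, base_features=4), seed=7)
        cfg = TrainConfig(epochs=3, seed=7)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, cfg, [0.5, 0.4, 0.3])
        loaded, manifest = load_checkpoint(path)
        x = np.random.default_rng(0).normal(size=(1, 1, 16, 16)).astype(np.float32)
        assert np.allclose(model.forward(x), loaded.forward(x))
        assert manifest["loss_history"] == [0.5, 0.4, 0.3]
        assert manifest["phase"] == "base" and manifest["seed"] == 7

    def test_train_writes_checkpoint(self, tiny_cohort, tmp_path):
        model = build_unet(UNetConfig(dims=3, depth=2, base_features=2), seed=0)
        path = tmp_path / "m.npz"
        hist = train(model, tiny_cohort, TrainConfig(epochs=1, seed=0),
                     checkpoint=path)
        loaded, manifest = load_checkpoint(path)
        assert manifest["loss_history"] == [float(h) for h in hist]
        assert all((a == b).all() for a, b in
                   zip(loaded.get_weights(), model.get_weights()))
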