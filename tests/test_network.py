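import numpy as np
import pytest

from cryotrace.grid import DensityMap, normalize_map, partition_grids
from cryotrace.labels import LabelMasks, make_label_masks
from cryotrace.nn import (
    ModelConfig,
    MultiModalNet,
    TrainConfig,
    augment_batch,
    lambda_schedule,
    predict_map,
    total_loss,
    train,
    weighted_cross_entropy,
)
from cryotrace.nn.augment import _apply_spatial, sample_spatial_ops
from cryotrace.nn.autodiff import Tensor
from cryotrace.nn.loss import LossWeights
from cryotrace.nn.train import Checkpoint, clip_gradients
from cryotrace.structure import encode_structure
from cryotrace.synthetic import SyntheticSpec, gen_toy_structure, simulate_density


@pytest.fixture(scope="module")
def tiny_model():
    return MultiModalNet(ModelConfig.tiny(window=12, seed=0))


class TestForward:
    def test_logit_channel_counts_and_shape(self, tiny_model):
        rng = np.random.default_rng(0)
        d = rng.random((12, 12, 12), dtype=np.float32)
        enc = (rng.random((24, 12, 12, 12)) < 0.02).astype(np.float32)
        lb, lc, la = tiny_model.forward(d, enc)
        assert lb.shape == (4, 12, 12, 12)
        assert lc.shape == (4, 12, 12, 12)
        assert la.shape == (21, 12, 12, 12)

    def test_zeroed_encoding_fallback(self, tiny_model):
        d = np.random.default_rng(1).random((12, 12, 12), dtype=np.float32)
        lb, _, _ = tiny_model.forward(d, None)
        assert np.all(np.isfinite(lb.data))

    def test_eval_forward_is_deterministic(self, tiny_model):
        d = np.random.default_rng(2).random((12, 12, 12), dtype=np.float32)
        tiny_model.eval_mode()
        out1 = tiny_model.forward(d, None)[0].data
        out2 = tiny_model.forward(d, None)[0].data
        np.testing.assert_array_equal(out1, out2)

    def test_parameter_count_deterministic_for_config(self):
        n1 = MultiModalNet(ModelConfig.tiny(seed=0)).n_parameters()
        n2 = MultiModalNet(ModelConfig.tiny(seed=99)).n_parameters()
        assert n1 == n2

    def test_shape_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(
                np.zeros((12, 12, 12)), np.zeros((24, 10, 10, 10))
            )

    def test_downsampled_encoders_still_emit_full_resolution(self):
        cfg = ModelConfig.tiny(window=8, seed=0)
        cfg.downsample_encoders = True
        model = MultiModalNet(cfg)
        lb, _, la = model.forward(np.zeros((8, 8, 8), dtype=np.float32), None)
        assert lb.shape == (4, 8, 8, 8)
        assert la.shape == (21, 8, 8, 8)


class TestLoss:
    def test_uniform_logits_single_voxel_gives_log_k(self):
        logits = Tensor(np.zeros((4, 1, 1, 1)))
        labels = np.full((1, 1, 1), 3)
        loss = weighted_cross_entropy(logits, labels)
        assert loss.item() == pytest.approx(np.log(4), abs=1e-6)

    def test_confident_logits_drive_loss_to_zero(self):
        logits = np.zeros((4, 1, 1, 1))
        logits[2] = 50.0
        loss = weighted_cross_entropy(Tensor(logits), np.full((1, 1, 1), 2))
        assert loss.item() < 1e-6

    def test_loss_linear_in_class_weight(self):
        logits = Tensor(np.random.default_rng(0).normal(size=(4, 2, 2, 2)))
        labels = np.full((2, 2, 2), 1)
        w1 = np.ones(4)
        w2 = w1.copy()
        w2[1] = 2.0
        l1 = weighted_cross_entropy(logits, labels, w1).item()
        l2 = weighted_cross_entropy(logits, labels, w2).item()
        assert l2 == pytest.approx(2 * l1, rel=1e-9)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(Tensor(np.zeros((4, 1, 1, 1))), np.full((1, 1, 1), 4))

    def test_total_loss_weighted_sums(self):
        one = Tensor(np.float64(1.0))
        two = Tensor(np.float64(2.0))
        zero = Tensor(np.float64(0.0))
        assert total_loss(one, one, one, LossWeights(0.6, 0.3, 0.1)).item() == pytest.approx(1.0)
        assert total_loss(two, zero, zero, LossWeights(0.25, 0.4, 0.35)).item() == pytest.approx(0.5)
        assert total_loss(two, one, one, LossWeights(1.0, 0.0, 0.0)).item() == pytest.approx(2.0)

    def test_lambda_must_sum_to_one(self):
        with pytest.raises(ValueError):
            LossWeights(0.5, 0.3, 0.1)

    def test_total_loss_invariant_under_task_permutation(self):
        vals = [Tensor(np.float64(v)) for v in (1.5, 0.7, 2.2)]
        lams = (0.6, 0.3, 0.1)
        base = total_loss(*vals, LossWeights(*lams)).item()
        perm = [2, 0, 1]
        permuted = total_loss(
            vals[perm[0]], vals[perm[1]], vals[perm[2]],
            LossWeights(lams[perm[0]], lams[perm[1]], lams[perm[2]]),
        ).item()
        assert permuted == pytest.approx(base, abs=1e-12)


class TestLambdaSchedule:
    def test_printed_endpoints(self):
        assert lambda_schedule(0).as_tuple() == pytest.approx((0.6, 0.3, 0.1))
        assert lambda_schedule(25).as_tuple() == pytest.approx((0.25, 0.4, 0.35))
        assert lambda_schedule(40).as_tuple() == pytest.approx((0.25, 0.4, 0.35))

    def test_ramp_midpoint_is_mean_of_endpoints(self):
        mid = lambda_schedule(22.5).as_tuple()
        expected = tuple((a + b) / 2 for a, b in zip((0.6, 0.3, 0.1), (0.25, 0.4, 0.35)))
        assert mid == pytest.approx(expected)

    def test_always_sums_to_one(self):
        for e in np.linspace(0, 40, 81):
            assert sum(lambda_schedule(float(e)).as_tuple()) == pytest.approx(1.0, abs=1e-9)


class TestAugment:
    def _window(self):
        rng = np.random.default_rng(3)
        density = rng.random((10, 10, 10)).astype(np.float32)
        enc = (rng.random((24, 10, 10, 10)) < 0.05).astype(np.float32)
        masks = LabelMasks(
            backbone=rng.integers(0, 4, (10, 10, 10)).astype(np.int8),
            calpha=rng.integers(0, 4, (10, 10, 10)).astype(np.int8),
            amino=rng.integers(0, 21, (10, 10, 10)).astype(np.int8),
        )
        return density, enc, masks

    def test_four_quarter_turns_are_identity(self):
        arr = np.random.default_rng(0).random((6, 6, 6))
        ops = {"rotations": [((0, 1), 1)], "flips": [], "shifts": (0, 0, 0)}
        out = arr
        for _ in range(4):
            out = _apply_spatial(out, ops)
        np.testing.assert_array_equal(out, arr)

    def test_same_seed_reproduces_augmentation(self):
        density, enc, masks = self._window()
        a1 = augment_batch(density, enc, masks, rng_seed=42)
        a2 = augment_batch(density, enc, masks, rng_seed=42)
        np.testing.assert_array_equal(a1[0], a2[0])
        np.testing.assert_array_equal(a1[1], a2[1])
        np.testing.assert_array_equal(a1[2].calpha, a2[2].calpha)

    def test_spatial_transform_moves_labels_with_density(self):
        # a marker volume transported by the same ops as the mask must agree
        density, enc, masks = self._window()
        rng = np.random.default_rng(9)
        ops = sample_spatial_ops(rng)
        marker = (masks.calpha == 3).astype(np.float32)
        moved_marker = _apply_spatial(marker, ops)
        moved_mask = _apply_spatial(masks.calpha, ops)
        np.testing.assert_array_equal(
            np.argwhere(moved_marker > 0.5), np.argwhere(moved_mask == 3)
        )

    def test_masks_stay_integer_and_density_in_range(self):
        density, enc, masks = self._window()
        d, e, m = augment_batch(density, enc, masks, rng_seed=5)
        assert m.calpha.dtype == masks.calpha.dtype
        assert d.min() >= 0.0 and d.max() <= 1.0
        assert set(np.unique(e)).issubset({0.0, 1.0})


def _tiny_dataset(n_windows=3, window=12, seed=4):
    spec = SyntheticSpec(n_residues=30, seed=seed, noise_sd=0.02)
    truth = gen_toy_structure(spec)
    dmap = normalize_map(simulate_density(truth, spec))
    masks = make_label_masks(truth, dmap)
    enc = encode_structure(truth, dmap)
    pad = max(1, window // 8)
    core = window - 2 * pad
    b = partition_grids(dmap.data, core, pad)
    mb = {
        k: partition_grids(getattr(masks, k), core, pad)
        for k in ("backbone", "calpha", "amino")
    }
    eb = [partition_grids(enc[c], core, pad) for c in range(24)]
    order = np.argsort([w.sum() for w in b.windows])[::-1][:n_windows]
    ds = []
    for n in order:
        m = LabelMasks(
            mb["backbone"].windows[n], mb["calpha"].windows[n], mb["amino"].windows[n]
        )
        e = np.stack([eb[c].windows[n] for c in range(24)])
        ds.append((b.windows[n], e, m))
    return ds, dmap, enc


class TestTraining:
    def test_loss_decreases_and_checkpoint_tracks_best(self):
        ds, _, _ = _tiny_dataset()
        model = MultiModalNet(ModelConfig.tiny(window=12, seed=0))
        ckpt = train(
            model, ds, TrainConfig(epochs=4, seed=0, lr=3e-3, augment=False,
                                   class_weighting="none")
        )
        totals = [e["train_total"] for e in ckpt.log]
        assert totals[-1] < totals[0]
        assert ckpt.best_epoch >= 0
        assert ckpt.best_val_loss == min(e["val_total"] for e in ckpt.log)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(MultiModalNet(ModelConfig.tiny(window=12)), [])

    def test_gradient_clipping_bounds_global_norm(self):
        ds, _, _ = _tiny_dataset(n_windows=1)
        model = MultiModalNet(ModelConfig.tiny(window=12, seed=1))
        from cryotrace.nn.train import _window_losses

        model.zero_grad()
        d, e, m = ds[0]
        lb, lc, la = _window_losses(model, d, e, m, {})
        total_loss(lb, lc, la, lambda_schedule(0)).backward()
        clip_gradients(model.parameters(), max_norm=0.01)
        post = np.sqrt(
            sum((p.grad.astype(float) ** 2).sum() for p in model.parameters() if p.grad is not None)
        )
        assert post <= 0.01 + 1e-9

    def test_fixed_seed_training_reproduces_log(self):
        ds, _, _ = _tiny_dataset(n_windows=2)
        cfg = TrainConfig(epochs=2, seed=7, lr=1e-3)
        log1 = train(MultiModalNet(ModelConfig.tiny(window=12, seed=3)), ds, cfg).log
        log2 = train(MultiModalNet(ModelConfig.tiny(window=12, seed=3)), ds, cfg).log
        assert [e["train_total"] for e in log1] == [e["train_total"] for e in log2]

    def test_checkpoint_save_load_round_trip(self, tmp_path, tiny_model):
        ckpt = Checkpoint(
            state=tiny_model.state_dict(),
            model_config=tiny_model.config.to_dict(),
            class_weights={"backbone": np.ones(4)},
        )
        path = tmp_path / "ckpt.npz"
        ckpt.save(path)
        back = Checkpoint.load(path)
        model2 = back.build_model()
        for a, b in zip(tiny_model.state_dict(), model2.state_dict()):
            np.testing.assert_array_equal(a, b)


class _OracleLogitModel:
    """Stub emitting high-margin logits reproducing the density as Cα class."""

    def __init__(self, window):
        self.config = ModelConfig.tiny(window=window)

    def eval_mode(self):
        pass

    def forward(self, density, enc):
        hot = np.asarray(density) > 0.5
        lb = np.zeros((4,) + hot.shape, dtype=np.float32)
        lc = np.zeros((4,) + hot.shape, dtype=np.float32)
        la = np.zeros((21,) + hot.shape, dtype=np.float32)
        lc[3, hot] = 40.0
        lc[0, ~hot] = 40.0
        lb[3, hot] = 40.0
        lb[0, ~hot] = 40.0
        la[1, hot] = 40.0
        la[0, ~hot] = 40.0
        return Tensor(lb), Tensor(lc), Tensor(la)


class TestPredictMap:
    def test_oracle_logits_recover_mask_probabilities(self):
        rng = np.random.default_rng(0)
        mask = (rng.random((20, 18, 15)) < 0.01).astype(np.float32)
        dmap = DensityMap(data=mask)
        pred = predict_map(_OracleLogitModel(16), dmap)
        assert pred.calpha_p.shape == dmap.shape
        assert np.all(pred.calpha_p[mask > 0.5] > 0.99)
        assert np.all(pred.calpha_p[mask < 0.5] < 0.01)

    def test_amino_probabilities_renormalized_per_voxel(self):
        dmap = DensityMap(data=np.random.default_rng(1).random((20, 18, 15)).astype(np.float32))
        model = MultiModalNet(ModelConfig.tiny(window=16, seed=0))
        pred = predict_map(model, dmap)
        np.testing.assert_allclose(pred.amino_p.sum(axis=0), 1.0, atol=1e-5)
        assert pred.backbone_p.min() >= 0 and pred.backbone_p.max() <= 1

    def test_absent_encoding_equals_zero_encoding(self):
        dmap = DensityMap(data=np.random.default_rng(2).random((18, 18, 18)).astype(np.float32))
        model = MultiModalNet(ModelConfig.tiny(window=16, seed=0))
        p_none = predict_map(model, dmap)
        p_zero = predict_map(model, dmap, np.zeros((24,) + dmap.shape, dtype=np.float32))
        np.testing.assert_array_equal(p_none.calpha_p, p_zero.calpha_p)

    def test_encoding_shape_mismatch_rejected(self):
        dmap = DensityMap(data=np.zeros((18, 18, 18)))
        model = MultiModalNet(ModelConfig.tiny(window=16, seed=0))
        with pytest.raises(ValueError):
            predict_map(model, dmap, np.zeros((24, 10, 10, 10)))
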