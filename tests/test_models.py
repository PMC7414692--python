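import numpy as np
import pytest

from rpecount import (
    AnnotatedImage,
    CountModel,
    DensityMap,
    MLPSpec,
    TrainConfig,
    count,
    load_model,
    predict_density,
    save_model,
    train_lrr,
    train_mlp,
)
from rpecount.features import DESCRIPTOR_DIM, FeatureMap
from rpecount.models import forward_raw, mse_loss, training_loss


def _random_pair(rng, h=16, w=16, target_weights=None, noise=0.0):
    """A synthetic (FeatureMap, DensityMap) pair; targets linear in the
    descriptors when target_weights is given."""
    X = rng.random((h, w, DESCRIPTOR_DIM)).astype(np.float32)
    fm = FeatureMap(descriptors=X, patch_size=16)
    if target_weights is None:
        vals = rng.random((h, w)) * 0.01
    else:
        vals = X.reshape(-1, DESCRIPTOR_DIM).astype(np.float64) @ target_weights
        vals = vals.reshape(h, w)
        if noise:
            vals = np.maximum(vals + rng.normal(0, noise, vals.shape), 0.0)
    return fm, DensityMap(values=vals)


@pytest.fixture
def realizable_pair():
    rng = np.random.default_rng(7)
    w_true = rng.random(DESCRIPTOR_DIM) * 0.001  # raw densities O(1e-2)
    return _random_pair(rng, target_weights=w_true), w_true


class TestTrainMLP:
    def test_zero_targets_learn_near_zero(self):
        rng = np.random.default_rng(0)
        fm, _ = _random_pair(rng)
        dm = DensityMap(values=np.zeros((16, 16)))
        cfg = TrainConfig(epochs=30, pixels_per_image=256, batch_size=64, seed=0)
        model = train_mlp([(fm, dm)], MLPSpec(hidden_sizes=(32,)), cfg)
        pred = predict_density(model, fm)
        assert np.abs(pred.values).mean() < 1e-3

    def test_linearly_realizable_targets_fit_far_below_variance(self, realizable_pair):
        (fm, dm), _ = realizable_pair
        cfg = TrainConfig(epochs=500, pixels_per_image=256, batch_size=32,
                          learning_rate=1e-2, seed=1)
        model = train_mlp([(fm, dm)], MLPSpec(hidden_sizes=(64,)), cfg)
        scaled_var = np.var(dm.values.ravel() * cfg.density_scale)
        assert model.meta["final_loss"] < scaled_var / 100.0

    def test_same_seed_gives_identical_parameters(self):
        rng = np.random.default_rng(2)
        pair = _random_pair(rng)
        cfg = TrainConfig(epochs=3, pixels_per_image=128, batch_size=32, seed=5)
        m1 = train_mlp([pair], MLPSpec(hidden_sizes=(16,)), cfg)
        m2 = train_mlp([pair], MLPSpec(hidden_sizes=(16,)), cfg)
        for a, b in zip(m1.params["weights"], m2.params["weights"]):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(m1.params["biases"], m2.params["biases"]):
            np.testing.assert_array_equal(a, b)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_mlp([], MLPSpec(hidden_sizes=(8,)), TrainConfig())

    def test_divergence_aborts_naming_epoch(self):
        rng = np.random.default_rng(3)
        pair = _random_pair(rng)
        cfg = TrainConfig(epochs=5, pixels_per_image=128, batch_size=32,
                          learning_rate=1e9, seed=0)
        with np.errstate(all="ignore"), pytest.raises(RuntimeError, match="epoch"):
            train_mlp([pair], MLPSpec(hidden_sizes=(16,)), cfg)


class TestTrainLRR:
    def test_matches_normal_equations_oracle(self):
        # brute-force (Xc'Xc + lam I)^-1 Xc' yc with unpenalized intercept
        rng = np.random.default_rng(4)
        fm, dm = _random_pair(rng, h=20, w=10)  # 200 descriptor/target pairs
        lam = 1.0
        cfg = TrainConfig(pixels_per_image=200, foreground_fraction=1.0,
                          ridge_lambda=lam, seed=0)
        model = train_lrr([(fm, dm)], cfg)

        X = fm.descriptors.reshape(-1, DESCRIPTOR_DIM).astype(np.float64)
        y = dm.values.ravel() * cfg.density_scale
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = np.linalg.solve(Xc.T @ Xc + lam * np.eye(DESCRIPTOR_DIM), Xc.T @ yc)
        b = y.mean() - X.mean(axis=0) @ w
        np.testing.assert_allclose(model.params["w"], w, atol=1e-8)
        assert model.params["b"] == pytest.approx(b, abs=1e-8)

    def test_infinite_penalty_shrinks_to_mean(self):
        rng = np.random.default_rng(5)
        fm, dm = _random_pair(rng)
        cfg = TrainConfig(pixels_per_image=256, ridge_lambda=1e12, seed=0)
        model = train_lrr([(fm, dm)], cfg)
        assert np.abs(model.params["w"]).max() < 1e-6
        assert model.params["b"] == pytest.approx(
            dm.values.mean() * cfg.density_scale, rel=1e-3
        )

    def test_realizable_targets_fit_exactly_with_tiny_penalty(self, realizable_pair):
        (fm, dm), _ = realizable_pair
        cfg = TrainConfig(pixels_per_image=256, ridge_lambda=1e-10, seed=0)
        model = train_lrr([(fm, dm)], cfg)
        pred = forward_raw(model, fm.descriptors.reshape(-1, DESCRIPTOR_DIM))
        resid = mse_loss(pred, dm.values.ravel() * cfg.density_scale)
        assert resid < 1e-6

    def test_singular_design_with_zero_penalty_rejected(self):
        fm = FeatureMap(
            descriptors=np.zeros((8, 8, DESCRIPTOR_DIM), dtype=np.float32), patch_size=16
        )
        dm = DensityMap(values=np.full((8, 8), 0.01))
        cfg = TrainConfig(pixels_per_image=64, ridge_lambda=0.0, seed=0)
        with pytest.raises(ValueError, match="ridge_lambda"):
            train_lrr([(fm, dm)], cfg)

    def test_mlp_matches_lrr_on_realizable_targets(self):
        # the MLP's hypothesis class contains every linear map, so with
        # enough samples its held-out error should not exceed the ridge
        # baseline's by more than a sliver of the target variance
        rng = np.random.default_rng(7)
        w_true = rng.random(DESCRIPTOR_DIM) * 0.001
        train = [_random_pair(rng, target_weights=w_true) for _ in range(8)]
        rng2 = np.random.default_rng(8)
        Xt = rng2.random((2048, DESCRIPTOR_DIM))
        cfg = TrainConfig(epochs=300, pixels_per_image=256, batch_size=64,
                          learning_rate=1e-2, seed=1)
        mlp = train_mlp(train, MLPSpec(hidden_sizes=(64,)), cfg)
        lrr = train_lrr(train, cfg)
        yt = (Xt @ w_true) * cfg.density_scale
        err_mlp = mse_loss(forward_raw(mlp, Xt), yt)
        err_lrr = mse_loss(forward_raw(lrr, Xt), yt)
        assert err_mlp <= err_lrr + 0.05 * np.var(yt)


class TestPredict:
    def test_zero_model_predicts_zero(self):
        spec = MLPSpec(hidden_sizes=(8,))
        params = {
            "weights": [np.zeros((DESCRIPTOR_DIM, 8)), np.zeros((8, 1))],
            "biases": [np.zeros(8), np.zeros(1)],
        }
        model = CountModel(kind="mlp", params=params, density_scale=100.0, spec=spec)
        fm = FeatureMap(
            descriptors=np.random.default_rng(0).random((8, 8, DESCRIPTOR_DIM)).astype(np.float32),
            patch_size=16,
        )
        assert predict_density(model, fm).total == 0.0

    def test_negative_outputs_clipped(self):
        model = CountModel(
            kind="lrr",
            params={"w": np.zeros(DESCRIPTOR_DIM), "b": -5.0},
            density_scale=100.0,
            ridge_lambda=1.0,
        )
        fm = FeatureMap(
            descriptors=np.zeros((4, 4, DESCRIPTOR_DIM), dtype=np.float32), patch_size=16
        )
        dm = predict_density(model, fm)
        assert dm.values.min() >= 0.0 and dm.total == 0.0

    def test_hand_set_single_relu_unit_forward_pass(self):
        # network computing max(0, f_0): W0 = e_0 -> ReLU -> W1 = 1
        W0 = np.zeros((DESCRIPTOR_DIM, 1))
        W0[0, 0] = 1.0
        params = {"weights": [W0, np.ones((1, 1))], "biases": [np.zeros(1), np.zeros(1)]}
        model = CountModel(
            kind="mlp", params=params, density_scale=100.0, spec=MLPSpec(hidden_sizes=(1,))
        )
        rng = np.random.default_rng(1)
        desc = rng.normal(size=(5, 6, DESCRIPTOR_DIM)).astype(np.float32)
        fm = FeatureMap(descriptors=desc, patch_size=16)
        expected = np.maximum(desc[:, :, 0].astype(np.float64), 0.0) / 100.0
        np.testing.assert_allclose(predict_density(model, fm).values, expected, atol=1e-7)

    def test_dimension_mismatch_rejected(self):
        model = CountModel(
            kind="lrr", params={"w": np.zeros(64), "b": 0.0}, density_scale=100.0
        )
        with pytest.raises(ValueError, match="dim"):
            forward_raw(model, np.zeros((3, DESCRIPTOR_DIM)))


class TestLossDefinition:
    def test_objective_matches_two_loop_reimplementation(self):
        # naive reimplementation of the training objective on a 4x4 image
        rng = np.random.default_rng(9)
        fm, dm = _random_pair(rng, h=4, w=4)
        cfg = TrainConfig(epochs=2, pixels_per_image=16, batch_size=8, seed=0)
        model = train_mlp([(fm, dm)], MLPSpec(hidden_sizes=(8,)), cfg)
        fast = training_loss(model, fm, dm)
        naive = 0.0
        for y in range(4):
            for x in range(4):
                f = fm.descriptors[y, x].astype(np.float64)[None, :]
                pred = float(forward_raw(model, f)[0])
                naive += (pred - dm.values[y, x] * model.density_scale) ** 2
        naive /= 16.0
        assert fast == pytest.approx(naive, abs=1e-10)


class TestCountAndSerialization:
    def test_zero_model_counts_zero(self, small_mosaic):
        model = CountModel(
            kind="lrr",
            params={"w": np.zeros(DESCRIPTOR_DIM), "b": 0.0},
            density_scale=100.0,
            meta={"patch_size": 16},
        )
        assert count(model, small_mosaic) == 0.0

    def test_save_load_round_trip_mlp(self, tmp_path):
        rng = np.random.default_rng(10)
        pair = _random_pair(rng)
        cfg = TrainConfig(epochs=2, pixels_per_image=64, batch_size=32, seed=0)
        model = train_mlp([pair], MLPSpec(hidden_sizes=(8,)), cfg)
        model.meta["patch_size"] = 16
        p = tmp_path / "m.npz"
        save_model(model, p)
        back = load_model(p)
        assert back.kind == "mlp" and back.spec == model.spec
        X = rng.random((10, DESCRIPTOR_DIM))
        np.testing.assert_array_equal(forward_raw(back, X), forward_raw(model, X))

    def test_save_load_round_trip_lrr(self, tmp_path):
        rng = np.random.default_rng(11)
        pair = _random_pair(rng)
        model = train_lrr([pair], TrainConfig(pixels_per_image=64, seed=0))
        p = tmp_path / "l.npz"
        save_model(model, p)
        back = load_model(p)
        assert back.ridge_lambda == model.ridge_lambda
        np.testing.assert_array_equal(back.params["w"], model.params["w"])
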