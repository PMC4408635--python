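import numpy as np
import pytest

from endoshape import (
    GradientField,
    RBFGradientModel,
    RBFTrainingConfig,
    correct_gradients,
    load_model,
    save_model,
    train_rbf,
)


@pytest.fixture(scope="module")
def identity_pairs():
    rng = np.random.default_rng(0)
    X = rng.uniform(-2.0, 2.0, (400, 2))
    return X, X.copy()


@pytest.fixture(scope="module")
def affine_pairs():
    rng = np.random.default_rng(1)
    X = rng.uniform(-2.0, 2.0, (500, 2))
    Y = np.column_stack([2.0 * X[:, 0] + 0.1, 2.0 * X[:, 1] - 0.1])
    return X, Y


class TestTraining:
    def test_identity_map_learned_quickly(self, identity_pairs):
        X, Y = identity_pairs
        res = RBFGradientModel(X[:300], Y[:300], RBFTrainingConfig()).fit()
        assert res.converged and res.epochs < 50
        held = res.predict(X[300:])
        mse = np.mean(np.sum((held - Y[300:]) ** 2, axis=1))
        assert mse < 0.1

    def test_affine_map_recovered_on_held_out(self, affine_pairs):
        X, Y = affine_pairs
        res = RBFGradientModel(X[:400], Y[:400], RBFTrainingConfig()).fit()
        held = res.predict(X[400:])
        mse = np.mean(np.sum((held - Y[400:]) ** 2, axis=1))
        # training stops right at the in-sample goal; held-out error is
        # allowed the usual small generalization gap
        assert mse < 1.5 * res.error_goal

    def test_training_error_non_increasing(self, affine_pairs):
        X, Y = affine_pairs
        res = RBFGradientModel(X, Y, RBFTrainingConfig(error_goal=1e-9, max_epochs=40)).fit()
        hist = res.error_history
        assert np.all(np.diff(hist) <= 1e-9 * np.maximum(hist[:-1], 1.0))

    def test_epoch_cap_respected_with_flag(self, affine_pairs):
        X, Y = affine_pairs
        res = RBFGradientModel(X, Y, RBFTrainingConfig(error_goal=1e-12, max_epochs=15)).fit()
        assert res.epochs == 15 and not res.converged

    def test_deterministic_given_seed(self, affine_pairs):
        X, Y = affine_pairs
        cfg = RBFTrainingConfig(error_goal=1e-6, max_epochs=30, seed=3)
        r1 = RBFGradientModel(X, Y, cfg).fit()
        r2 = RBFGradientModel(X, Y, cfg).fit()
        assert np.array_equal(r1.centers, r2.centers)
        assert np.allclose(r1.weights, r2.weights)

    def test_degenerate_inputs_rejected(self):
        X = np.ones((50, 2))
        with pytest.raises(ValueError):
            RBFGradientModel(X, X)

    def test_too_few_pairs_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(ValueError):
            RBFGradientModel(X, X)

    def test_functional_wrapper(self, identity_pairs):
        res = train_rbf(identity_pairs)
        assert res.final_error <= 0.1


class TestCorrection:
    def test_identity_model_passes_field_through(self, identity_pairs, camera_96):
        res = train_rbf(identity_pairs)
        rng = np.random.default_rng(2)
        p = rng.uniform(-1.5, 1.5, (96, 96))
        q = rng.uniform(-1.5, 1.5, (96, 96))
        g = GradientField(p, q, np.ones_like(p, bool), "vbw")
        gc = correct_gradients(res, g)
        assert gc.provenance == "nn-corrected"
        assert np.allclose(gc.p, p, atol=0.5)
        # error_goal = 0.1 (MSE over two components) ~ per-component RMS 0.22
        assert np.mean(np.abs(gc.p - p)) < 0.25

    def test_pure_function(self, identity_pairs):
        res = train_rbf(identity_pairs)
        g = GradientField(
            np.full((8, 8), 0.3), np.full((8, 8), -0.2), np.ones((8, 8), bool), "vbw"
        )
        a = correct_gradients(res, g)
        b = correct_gradients(res, g)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.q, b.q)

    def test_mask_preserved(self, identity_pairs):
        res = train_rbf(identity_pairs)
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        g = GradientField(np.full((8, 8), 0.1), np.full((8, 8), 0.1), mask, "vbw")
        gc = correct_gradients(res, g)
        assert np.array_equal(gc.mask, mask)
        assert np.all(np.isnan(gc.p[~mask]))

    def test_wrong_provenance_rejected(self, identity_pairs):
        res = train_rbf(identity_pairs)
        g = GradientField(np.ones((4, 4)), np.ones((4, 4)), np.ones((4, 4), bool), "true")
        with pytest.raises(ValueError):
            correct_gradients(res, g)

    def test_far_inputs_flagged_extrapolated(self, identity_pairs):
        res = train_rbf(identity_pairs)
        p = np.full((4, 4), 100.0)  # far outside the [-2, 2] training hull
        g = GradientField(p, p, np.ones((4, 4), bool), "vbw")
        gc = correct_gradients(res, g)
        assert gc.extrapolated.all()


class TestSerialization:
    def test_round_trip_predictions_identical(self, affine_pairs, tmp_path):
        X, Y = affine_pairs
        res = RBFGradientModel(X, Y).fit()
        path = tmp_path / "model.json"
        save_model(res, path)
        loaded = load_model(path)
        pts = np.random.default_rng(5).uniform(-2, 2, (100, 2))
        assert np.allclose(res.predict(pts), loaded.predict(pts), atol=0, rtol=0)

    def test_retrain_same_seed_same_centers(self, affine_pairs, tmp_path):
        X, Y = affine_pairs
        cfg = RBFTrainingConfig(max_epochs=25, error_goal=1e-9, seed=9)
        res = RBFGradientModel(X, Y, cfg).fit()
        save_model(res, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        res2 = RBFGradientModel(X, Y, cfg).fit()
        assert loaded.centers.shape[0] == res2.centers.shape[0]

    def test_truncated_file_clean_error(self, affine_pairs, tmp_path):
        res = RBFGradientModel(*affine_pairs).fit()
        path = tmp_path / "model.json"
        save_model(res, path)
        path.write_text(path.read_text()[:40])
        with pytest.raises(ValueError):
            load_model(path)

    def test_version_mismatch_rejected(self, affine_pairs, tmp_path):
        import json

        res = RBFGradientModel(*affine_pairs).fit()
        path = tmp_path / "model.json"
        save_model(res, path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError):
            load_model(path)
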