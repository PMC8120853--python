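import numpy as np
import pytest

from lpicaps.capsnet import (
    CapsuleNet,
    EnsembleModel,
    TrainConfig,
    classify,
    count_capsule_params,
    default_hidden_widths,
    squash,
    train_ensemble,
    train_one,
)

DIMS = {"SF": 320, "Mtf": 29, "PC": 100, "SS": 20}


def tiny_dims():
    return {"A": 6, "B": 4}


def random_features(rng, dims, n):
    return {c: rng.normal(size=(n, d)) for c, d in dims.items()}


def separable_dataset(seed=0, n=240, dims=None):
    """Two Gaussian blobs per channel, linearly separable."""
    dims = dims or tiny_dims()
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    X = {}
    for c, d in dims.items():
        centers = np.where(y[:, None] == 1, 1.5, -1.5)
        X[c] = rng.normal(size=(n, d)) * 0.5 + centers
    return X, y


class TestSquash:
    def test_zero_maps_to_zero(self):
        assert not squash(np.zeros(3)).any()

    def test_unit_norm_halves(self):
        v = squash(np.array([1.0, 0.0, 0.0]))
        assert np.linalg.norm(v) == pytest.approx(0.5)
        assert v[0] > 0

    def test_norm_three_gives_point_nine(self):
        v = squash(np.array([0.0, 3.0, 0.0]))
        assert np.linalg.norm(v) == pytest.approx(0.9)

    def test_monotone_bounded_direction_preserving(self):
        rng = np.random.default_rng(1)
        S = rng.normal(size=(10_000, 3)) * rng.lognormal(size=(10_000, 1))
        V = squash(S)
        norms_in = np.linalg.norm(S, axis=1)
        norms_out = np.linalg.norm(V, axis=1)
        assert (norms_out < 1).all()
        order = np.argsort(norms_in)
        assert (np.diff(norms_out[order]) >= -1e-12).all()
        cos = np.sum(S * V, axis=1) / np.maximum(norms_in * norms_out, 1e-300)
        assert np.allclose(cos, 1.0)


class TestArchitecture:
    def test_capsule_stage_has_36_params_in_canonical_config(self):
        assert count_capsule_params(4, 3) == 36
        model = CapsuleNet(DIMS, seed=0)
        assert model.capsule_stage_parameter_count == 36

    @pytest.mark.parametrize("n,d,expect", [(1, 1, 1), (5, 2, 20), (4, 3, 36)])
    def test_param_count_formula(self, n, d, expect):
        assert count_capsule_params(n, d) == expect

    def test_subnets_have_five_layers_ending_in_dim_three(self):
        model = CapsuleNet(DIMS, seed=0)
        for c in DIMS:
            assert len(model.layers[c]) == 5
            assert model.layers[c][-1]["W"].shape[1] == 3

    def test_hidden_width_taper_is_capped(self):
        assert default_hidden_widths(320)[0] <= 32
        assert default_hidden_widths(4) == sorted(default_hidden_widths(4), reverse=True)

    def test_score_bounded_below_one(self):
        rng = np.random.default_rng(0)
        model = CapsuleNet(tiny_dims(), seed=0)
        scores = model.predict_scores(random_features(rng, tiny_dims(), 50))
        assert ((scores >= 0) & (scores < 1)).all()

    def test_zeroed_transformation_matrices_give_zero_scores(self):
        rng = np.random.default_rng(0)
        model = CapsuleNet(tiny_dims(), seed=0)
        for c in model.capsule_W:
            model.capsule_W[c][...] = 0.0
        scores = model.predict_scores(random_features(rng, tiny_dims(), 10))
        assert not scores.any()

    def test_eval_mode_deterministic(self):
        rng = np.random.default_rng(0)
        X = random_features(rng, tiny_dims(), 8)
        model = CapsuleNet(tiny_dims(), seed=3)
        assert np.array_equal(model.predict_scores(X), model.predict_scores(X))

    def test_dimension_mismatch_names_channel(self):
        model = CapsuleNet(tiny_dims(), seed=0)
        bad = {"A": np.zeros((2, 6)), "B": np.zeros((2, 5))}
        with pytest.raises(ValueError, match="'B'"):
            model.predict_scores(bad)


class TestClassify:
    @pytest.mark.parametrize(
        "score,threshold,expect",
        [(0.6, 0.5, "interact"), (0.5, 0.5, "no_interact"), (0.9, 0.87, "interact"),
         (0.86, 0.87, "no_interact")],
    )
    def test_strict_threshold_rule(self, score, threshold, expect):
        assert classify(score, threshold) == expect


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        X, y = separable_dataset()
        model = CapsuleNet(tiny_dims(), dropout=0.0, seed=0)
        before = {k: v.copy() for k, v in model.parameters()}
        train_one(model, X, y, TrainConfig(learning_rate=0.0, weight_decay=0.0, epochs=2), seed=0)
        for k, v in model.parameters():
            assert np.array_equal(before[k], v)

    def test_same_seed_reproduces_parameters_exactly(self):
        X, y = separable_dataset()
        runs = []
        for _ in range(2):
            model = CapsuleNet(tiny_dims(), seed=7)
            train_one(model, X, y, TrainConfig(epochs=3), seed=5)
            runs.append({k: v.copy() for k, v in model.parameters()})
        for k in runs[0]:
            assert np.array_equal(runs[0][k], runs[1][k])

    def test_loss_decreases_on_separable_data(self):
        X, y = separable_dataset()
        model = CapsuleNet(tiny_dims(), seed=0)
        trace = train_one(model, X, y, TrainConfig(epochs=15), seed=0)
        assert trace[-1] < trace[0]
        scores = model.predict_scores(X)
        from lpicaps.metrics import auc_auprc

        auc, _ = auc_auprc(scores, y)
        assert auc > 0.95

    def test_gradients_match_finite_differences(self):
        # spot-check the hand-written backprop on a tiny deterministic net
        dims = {"A": 3}
        model = CapsuleNet(dims, hidden_widths={"A": [3, 3, 3, 3]}, dropout=0.0, seed=1)
        rng = np.random.default_rng(0)
        X = {"A": rng.normal(size=(4, 3))}
        y = np.array([1.0, 0.0, 1.0, 0.0])
        cfg = TrainConfig()
        _, grads, _ = model.loss_and_grads(X, y, cfg, rng)
        eps = 1e-6
        for key, arr in model.parameters()[:6] + [model.parameters()[-1]]:
            flat = arr.reshape(-1)
            idx = 0 if flat.size == 1 else flat.size // 2
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _, _ = model.loss_and_grads(X, y, cfg, rng)
            flat[idx] = orig - eps
            lm, _, _ = model.loss_and_grads(X, y, cfg, rng)
            flat[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[key].reshape(-1)[idx] == pytest.approx(numeric, abs=1e-5)

    def test_nonfinite_loss_aborts_with_diagnostics(self):
        X, y = separable_dataset(n=40)
        model = CapsuleNet(tiny_dims(), seed=0)
        model.layers["A"][0]["W"][...] = np.inf
        with pytest.raises(RuntimeError, match="non-finite"):
            train_one(model, X, y, TrainConfig(epochs=1), seed=0)


class TestEnsemble:
    def test_one_member_equals_member_scores(self):
        X, y = separable_dataset(n=80)
        pos = {c: X[c][y == 1] for c in X}
        neg = {c: X[c][y == 0] for c in X}
        ens = train_ensemble(pos, [neg], TrainConfig(epochs=3), seed=0)
        assert len(ens.members) == 1
        single = ens.members[0].predict_scores(X)
        assert np.allclose(ens.predict_scores(X), single)

    def test_member_count_matches_subsets(self):
        X, y = separable_dataset(n=120)
        pos = {c: X[c][y == 1][:20] for c in X}
        subs = [
            {c: X[c][y == 0][i * 20 : (i + 1) * 20] for c in X} for i in range(3)
        ]
        ens = train_ensemble(pos, subs, TrainConfig(epochs=2), seed=0)
        assert len(ens.members) == 3

    def test_serialization_roundtrip_preserves_scores(self, tmp_path):
        X, y = separable_dataset(n=80)
        pos = {c: X[c][y == 1] for c in X}
        neg = {c: X[c][y == 0] for c in X}
        ens = train_ensemble(
            pos, [neg], TrainConfig(epochs=3), seed=0, fingerprint="abc123"
        )
        path = tmp_path / "model.npz"
        ens.save(path)
        loaded = EnsembleModel.load(path, expected_fingerprint="abc123")
        assert np.array_equal(loaded.predict_scores(X), ens.predict_scores(X))

    def test_fingerprint_mismatch_refused(self, tmp_path):
        X, y = separable_dataset(n=40)
        pos = {c: X[c][y == 1] for c in X}
        neg = {c: X[c][y == 0] for c in X}
        ens = train_ensemble(pos, [neg], TrainConfig(epochs=1), seed=0, fingerprint="aaa")
        path = tmp_path / "model.npz"
        ens.save(path)
        with pytest.raises(ValueError, match="fingerprint"):
            EnsembleModel.load(path, expected_fingerprint="bbb")
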