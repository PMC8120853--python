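import numpy as np
import pytest

from lpicaps.metrics import (
    ConfusionCounts,
    auc_auprc,
    confusion,
    cross_validate,
    evaluate,
    metrics_from_confusion,
)


def pairwise_auc_oracle(scores, labels):
    """O(n^2) concordance count with half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_simple_split(self):
        c = confusion([0.9, 0.1], [1, 0], 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_all_zero_scores_predict_nothing(self):
        c = confusion([0.0] * 5, [1, 1, 0, 0, 0], 0.5)
        assert c.tp == 0 and c.fp == 0 and c.fn == 2 and c.tn == 3

    def test_boundary_score_counts_negative(self):
        c = confusion([0.5], [1], 0.5)
        assert c.fn == 1 and c.tp == 0

    def test_matches_hand_count_on_random_case(self):
        rng = np.random.default_rng(0)
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        c = confusion(scores, labels, 0.4)
        tp = sum(1 for s, l in zip(scores, labels) if s > 0.4 and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s > 0.4 and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s <= 0.4 and l == 1)
        tn = sum(1 for s, l in zip(scores, labels) if s <= 0.4 and l == 0)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert c.total == 20

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0.5, 0.5], [1], 0.5)


class TestMetricFormulas:
    def test_hand_computed_example(self):
        rep = metrics_from_confusion(ConfusionCounts(tp=9, fp=1, tn=8, fn=2))
        assert rep.precision == pytest.approx(0.9)
        assert rep.recall == pytest.approx(9 / 11)
        assert rep.f_value == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))
        assert rep.accuracy == pytest.approx(0.85)

    def test_perfect_classifier(self):
        rep = metrics_from_confusion(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f_value) == (1, 1, 1, 1)

    def test_zero_denominator_flagged_not_raised(self):
        rep = metrics_from_confusion(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert rep.precision == 0.0
        assert "precision" in rep.undefined

    def test_f_bounded_by_max_of_precision_recall(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 30, 4)
            if tp + fp + tn + fn == 0:
                continue
            rep = metrics_from_confusion(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            for v in (rep.accuracy, rep.precision, rep.recall, rep.f_value):
                assert 0.0 <= v <= 1.0
            assert rep.f_value <= max(rep.precision, rep.recall) + 1e-12


class TestAuc:
    def test_perfect_separation(self):
        auc, auprc = auc_auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert auprc == 1.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        scores = np.round(rng.random(50), 2)  # rounding forces ties
        labels = rng.integers(0, 2, 50)
        if labels.sum() in (0, 50):
            labels[0] = 1 - labels[0]
        auc, _ = auc_auprc(scores, labels)
        assert auc == pytest.approx(pairwise_auc_oracle(scores, labels))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        auc, _ = auc_auprc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        a1, _ = auc_auprc(scores, labels)
        a2, _ = auc_auprc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_auprc([0.1, 0.9], [1, 1])


class _MeanTrainer:
    """Degenerate trainer: scores by mean feature value (deterministic)."""

    def __init__(self, X, y, seed):
        pass

    def predict_scores(self, X):
        return 1 / (1 + np.exp(-np.concatenate(list(X.values()), axis=1).mean(axis=1)))


class TestCrossValidate:
    def _data(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = {"A": rng.normal(size=(n, 4)) + y[:, None]}
        return X, y

    def test_fold_sizes(self):
        X, y = self._data()
        out = cross_validate(X, y, 5, lambda Xt, yt, s: _MeanTrainer(Xt, yt, s), seed=0)
        assert len(out["folds"]) == 5

    def test_same_seed_same_folds(self):
        X, y = self._data()
        r1 = cross_validate(X, y, 4, lambda Xt, yt, s: _MeanTrainer(Xt, yt, s), seed=9)
        r2 = cross_validate(X, y, 4, lambda Xt, yt, s: _MeanTrainer(Xt, yt, s), seed=9)
        assert [f.as_dict() for f in r1["folds"]] == [f.as_dict() for f in r2["folds"]]

    def test_stratification_within_one_item(self):
        from sklearn.model_selection import StratifiedKFold

        X, y = self._data(n=103, seed=2)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=1)
        global_rate = y.mean()
        for _, test_idx in skf.split(np.zeros(len(y)), y):
            n_pos = y[test_idx].sum()
            expect = global_rate * len(test_idx)
            assert abs(n_pos - expect) <= 1.0

    def test_too_few_positives_rejected(self):
        X = {"A": np.zeros((10, 2))}
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            cross_validate(X, y, 3, lambda Xt, yt, s: _MeanTrainer(Xt, yt, s))

    def test_summary_mean_sd_present(self):
        X, y = self._data()
        out = cross_validate(X, y, 5, lambda Xt, yt, s: _MeanTrainer(Xt, yt, s), seed=0)
        assert set(out["summary"]) >= {"accuracy", "auc", "f_value"}
        assert "mean" in out["summary"]["auc"] and "sd" in out["summary"]["auc"]
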