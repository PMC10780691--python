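"""Classifier and evaluation harness: attention score oracle, gradient
correctness, split discipline, metric formulas, paired ablation."""

import numpy as np
import pytest

from gaitshield.evaluate import (
    CVPlan,
    compute_metrics,
    interpatient_split,
    prepare_sequences,
    protect_sequences,
    run_ablation,
)
from gaitshield.nn import LSTMAttentionClassifier, ModelConfig, attention_score
from gaitshield.projection import ProjectionMatrix, generate_matrix
from gaitshield.synthetic import generate_cohort


class TestAttentionScore:
    def test_identity_matrix_reduces_to_dot_product(self):
        rng = np.random.default_rng(0)
        h_t, h_s = rng.normal(size=4), rng.normal(size=4)
        assert attention_score(h_t, h_s, np.eye(4)) == pytest.approx(h_t @ h_s)

    def test_zero_query_scores_zero(self):
        rng = np.random.default_rng(1)
        assert attention_score(np.zeros(4), rng.normal(size=4), rng.normal(size=(4, 4))) == 0.0

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        h_t, h_s = rng.normal(size=4), rng.normal(size=4)
        W = rng.normal(size=(4, 4))
        oracle = sum(
            h_t[i] * W[i, j] * h_s[j] for i in range(4) for j in range(4)
        )
        assert attention_score(h_t, h_s, W) == pytest.approx(oracle, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_score(np.zeros(3), np.zeros(4), np.eye(3))


class TestModel:
    def test_softmax_output_sums_to_one(self):
        rng = np.random.default_rng(3)
        m = LSTMAttentionClassifier(ModelConfig(train_seed=0), n_features=5)
        X = [rng.normal(size=(8, 5)) for _ in range(4)]
        prob = m.predict_proba(X)
        assert np.allclose(prob.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_matches_layer_arithmetic(self):
        H, D, d = 5, 4, 7
        cfg = ModelConfig(lstm_units=H, dense_units=D)
        m = LSTMAttentionClassifier(cfg, n_features=d)
        expected = (d * 4 * H + H * 4 * H + 4 * H) + H * H + (H * D + D) + (D * 2 + 2)
        assert m.n_parameters == expected

    def test_inference_is_deterministic(self):
        rng = np.random.default_rng(4)
        m = LSTMAttentionClassifier(ModelConfig(dropout_rate=0.3, train_seed=1), n_features=3)
        X = [rng.normal(size=(6, 3))]
        assert np.array_equal(m.predict_proba(X), m.predict_proba(X))

    def test_gradients_match_finite_differences(self):
        cfg = ModelConfig(lstm_units=4, dense_units=3, dropout_rate=0.0,
                          l1_penalty=0.002, train_seed=0)
        m = LSTMAttentionClassifier(cfg, n_features=3)
        rng = np.random.default_rng(5)
        X = [rng.normal(size=(5, 3)), rng.normal(size=(4, 3))]
        onehot = np.eye(2)[[0, 1]]
        x, mask = m._pad(X)
        m._forward(x, mask, train=False)
        grads = m._backward(onehot)
        eps = 1e-6
        for name, g in grads.items():
            flat = m.params[name].ravel()
            gn = np.zeros_like(flat)
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp = m._loss(m._forward(x, mask, train=False), onehot)
                flat[i] = orig - eps
                lm = m._loss(m._forward(x, mask, train=False), onehot)
                flat[i] = orig
                gn[i] = (lp - lm) / (2 * eps)
            rel = np.abs(g.ravel() - gn).max() / (np.abs(gn).max() + 1e-12)
            assert rel < 1e-5, f"gradient mismatch in {name}"

    def test_padding_is_inert(self):
        """A sequence's prediction is unchanged by batching it with longer ones."""
        rng = np.random.default_rng(6)
        m = LSTMAttentionClassifier(ModelConfig(train_seed=2), n_features=3)
        short = rng.normal(size=(4, 3))
        long = rng.normal(size=(9, 3))
        alone = m.predict_proba([short])[0]
        padded = m.predict_proba([short, long])[0]
        assert np.allclose(alone, padded, atol=1e-10)

    def test_learns_a_separable_sequence_problem(self):
        rng = np.random.default_rng(7)
        X = [rng.normal(loc=(1.0 if y else -1.0), size=(10, 2)) for y in range(2) for _ in range(8)]
        y = np.array([yy for yy in range(2) for _ in range(8)])
        cfg = ModelConfig(lstm_units=8, dense_units=4, epochs=60, train_seed=3)
        m = LSTMAttentionClassifier(cfg, n_features=2).fit(X, y)
        assert (m.predict(X) == y).mean() >= 0.9


class TestInterpatientSplit:
    def test_paper_scale_cohort_counts(self):
        labels = {f"H{i}": "healthy" for i in range(23)}
        labels |= {f"P{i}": "dementia" for i in range(20)}
        folds = interpatient_split(labels, CVPlan(n_folds=20, seed=1))
        for train, test in folds:
            assert len(train) == 28 and len(test) == 15

    def test_train_and_test_always_disjoint(self):
        labels = {f"S{i}": ("healthy" if i % 2 else "dementia") for i in range(12)}
        for train, test in interpatient_split(labels, CVPlan(n_folds=8, seed=2)):
            assert not train & test
            assert train | test == set(labels)

    def test_same_seed_reproduces_folds(self):
        labels = {f"S{i}": ("healthy" if i % 2 else "dementia") for i in range(16)}
        a = interpatient_split(labels, CVPlan(n_folds=4, seed=3))
        b = interpatient_split(labels, CVPlan(n_folds=4, seed=3))
        assert a == b

    def test_too_few_subjects_without_fallback(self):
        labels = {f"S{i}": ("healthy" if i % 2 else "dementia") for i in range(6)}
        with pytest.raises(ValueError):
            interpatient_split(labels, CVPlan(n_folds=2, seed=4, allow_fallback=False))


class TestMetrics:
    def test_perfect_separation_scores_100(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(y, p)
        assert all(m[k] == 100.0 for k in m)

    def test_confusion_matrix_example(self):
        # TP=3, FP=1, FN=1, TN=5
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        p = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.2, 0.3, 0.4])
        m = compute_metrics(y, p)
        assert m["precision"] == pytest.approx(75.0)
        assert m["sensitivity"] == pytest.approx(75.0)
        assert m["specificity"] == pytest.approx(83.33, abs=0.01)
        assert m["accuracy"] == pytest.approx(80.0)

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 4000)
        p = rng.random(4000)
        assert compute_metrics(y, p)["auc_roc"] == pytest.approx(50.0, abs=3.0)

    def test_single_class_auc_is_missing_with_warning(self):
        with pytest.warns(UserWarning):
            m = compute_metrics(np.zeros(5, dtype=int), np.full(5, 0.2))
        assert m["auc_roc"] is None


def _tiny_cohort():
    return generate_cohort(4, 4, recordings_per_subject=2, n_frames=40, seed=21)


def _tiny_cfg(epochs=25):
    return ModelConfig(lstm_units=8, dense_units=4, epochs=epochs, train_seed=0)


class TestAblation:
    def test_square_identity_projection_changes_nothing(self):
        """q = j with an identity matrix is the information-preserving limit."""
        cohort = _tiny_cohort()

        def identity_factory(j, q, seed):
            return ProjectionMatrix(entries=np.eye(j), j=j, q=j, seed=seed)

        plan = CVPlan(n_folds=2, seed=5)
        recs = prepare_sequences(cohort)
        j = recs[0].channels.shape[1]
        protected = protect_sequences(
            recs, identity_factory(j, j, 0), feat_scale=6, mat_scale=0, encrypted=False
        )
        for r, p in zip(recs, protected):
            assert np.abs(r.channels - p.channels).max() <= 1e-6

    def test_paired_arms_share_folds_and_seeds(self):
        cohort = _tiny_cohort()
        plan = CVPlan(n_folds=2, seed=6)
        res = run_ablation(cohort, _tiny_cfg(epochs=5), plan, encrypted=False)
        res2 = run_ablation(cohort, _tiny_cfg(epochs=5), plan, encrypted=False)
        assert res.fold_fingerprint == res2.fold_fingerprint
        assert res.unprotected.per_fold == res2.unprotected.per_fold
        assert res.protected.per_fold == res2.protected.per_fold

    def test_encrypted_and_plain_protection_routes_agree(self):
        cohort = generate_cohort(2, 2, recordings_per_subject=2, n_frames=20, seed=22)
        recs = prepare_sequences(cohort)
        j = recs[0].channels.shape[1]
        M = generate_matrix(j, j - 1, seed=9)
        enc = protect_sequences(recs[:2], M, crypto_seed=1, encrypted=True)
        plain = protect_sequences(recs[:2], M, encrypted=False)
        for a, b in zip(enc, plain):
            assert np.abs(a.channels - b.channels).max() <= 1e-9
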