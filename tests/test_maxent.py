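"""MaxEnt/IRLS core: oracle agreement, invariants, persistence."""

import io

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from meshent.maxent import (
    MaxEntClassifier,
    TrainingError,
    classify,
    load_model,
    predict_proba,
    ranked_features,
    save_model,
    train_maxent,
)

# 8 instances, one feature; feature mostly but not perfectly predictive
ONE_FEATURE = [
    (frozenset({"f"}), 1),
    (frozenset({"f"}), 1),
    (frozenset({"f"}), 1),
    (frozenset({"f"}), 0),
    (frozenset(), 1),
    (frozenset(), 0),
    (frozenset(), 0),
    (frozenset(), 0),
]

SEPARABLE = [(frozenset({"f"}), 1)] * 4 + [(frozenset(), 0)] * 4


def _penalized_objective(w, b, instances, prior_variance):
    """Independent evaluation of the reduced penalized log-likelihood."""
    total = 0.0
    for fs, y in instances:
        eta = (w if "f" in fs else 0.0) + b
        total += y * eta - np.logaddexp(0.0, eta)
    return total - w * w / (4.0 * prior_variance)


def _grid_search_optimum(instances, prior_variance):
    """Coarse-to-fine exhaustive maximization over (w, b)."""
    center, span = np.zeros(2), 8.0
    for _ in range(6):
        ws = np.linspace(center[0] - span, center[0] + span, 41)
        bs = np.linspace(center[1] - span, center[1] + span, 41)
        values = [
            (_penalized_objective(w, b, instances, prior_variance), w, b)
            for w in ws
            for b in bs
        ]
        _, w_best, b_best = max(values)
        center, span = np.array([w_best, b_best]), span / 8.0
    return center


class TestTraining:
    def test_separable_feature_gets_positive_weight_difference(self):
        model = train_maxent(SEPARABLE)
        idx = model.vocabulary_.index("f")
        assert model.weights_pos_[idx] - model.weights_neg_[idx] > 0
        for fs, y in SEPARABLE:
            assert classify(model, fs, delta=0.0) == y

    def test_irls_matches_grid_search_oracle(self):
        model = train_maxent(ONE_FEATURE, prior_variance=1.0)
        w_oracle, b_oracle = _grid_search_optimum(ONE_FEATURE, prior_variance=1.0)
        diff = model.weights_pos_ - model.weights_neg_
        assert diff[0] == pytest.approx(w_oracle, abs=1e-3)
        assert diff[1] == pytest.approx(b_oracle, abs=1e-3)

    def test_duplicated_data_with_halved_prior_variance_is_invariant(self):
        # duplicating every instance doubles the log-likelihood term, so the
        # Gaussian penalty must double too (variance halves) to keep the
        # penalized optimum — and hence all probabilities — unchanged
        base = train_maxent(ONE_FEATURE, prior_variance=1.0)
        doubled = train_maxent(ONE_FEATURE * 2, prior_variance=0.5)
        probes = [frozenset(), frozenset({"f"})]
        for fs in probes:
            assert predict_proba(doubled, fs) == pytest.approx(
                predict_proba(base, fs), abs=1e-6
            )
        plain_double = train_maxent(ONE_FEATURE * 2, prior_variance=1.0)
        for fs in probes:
            assert classify(plain_double, fs, 0.0) == classify(base, fs, 0.0)

    def test_single_class_input_is_a_training_error(self):
        with pytest.raises(TrainingError):
            train_maxent([(frozenset({"f"}), 1)] * 4)

    def test_objective_is_nondecreasing_over_iterations(self):
        model = train_maxent(ONE_FEATURE)
        path = model.objective_path_
        assert np.all(np.diff(path) >= -1e-12)
        assert model.converged_

    def test_instance_order_does_not_change_weights(self):
        model_a = train_maxent(ONE_FEATURE)
        model_b = train_maxent(list(reversed(ONE_FEATURE)))
        np.testing.assert_allclose(
            model_a.weights_pos_, model_b.weights_pos_, atol=1e-8
        )

    def test_agrees_with_independent_penalized_logistic_fit(self, small_synthetic):
        # two-class MaxEnt with shared binary features == ridge logistic on
        # the weight differences; sklearn is the independent route
        _, tree, corpus = small_synthetic
        rng = np.random.default_rng(3)
        docs = corpus.documents[:120]
        from meshent.features import build_feature_set

        target = sorted(tree.terms)[-1]
        feature_sets = [build_feature_set(d) for d in docs]
        y = np.array([int(target in d.annotations) for d in docs])
        if y.sum() < 2:  # ensure both classes
            y[:2] = 1
        model = MaxEntClassifier(prior_variance=1.0, tol=1e-12, max_iter=200)
        model.fit(feature_sets, y)
        vocab = {f: i for i, f in enumerate(model.vocabulary_)}
        X = np.zeros((len(docs), len(vocab)))
        for i, fs in enumerate(feature_sets):
            for f in fs:
                X[i, vocab[f]] = 1.0
        ref = LogisticRegression(
            C=2.0, tol=1e-12, max_iter=5000, solver="lbfgs"
        ).fit(X, y)
        ours = model.predict_proba(feature_sets)[:, 1]
        theirs = ref.predict_proba(X)[:, 1]
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestPrediction:
    def test_probabilities_sum_to_one(self):
        model = train_maxent(ONE_FEATURE)
        proba = model.predict_proba([frozenset({"f"}), frozenset(), frozenset({"zz"})])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_unseen_features_are_ignored(self):
        model = train_maxent(ONE_FEATURE)
        assert predict_proba(model, frozenset({"never-seen"})) == pytest.approx(
            predict_proba(model, frozenset())
        )

    def test_zero_weight_model_gives_half(self):
        model = train_maxent(ONE_FEATURE)
        model.weights_pos_ = np.zeros_like(model.weights_pos_)
        model.weights_neg_ = np.zeros_like(model.weights_neg_)
        assert predict_proba(model, frozenset({"f"})) == 0.5

    def test_delta_threshold_is_strict(self):
        model = train_maxent(ONE_FEATURE)
        model.weights_pos_ = np.zeros_like(model.weights_pos_)
        model.weights_neg_ = np.zeros_like(model.weights_neg_)
        # proba exactly 0.5: not above 0.5 + 0.0
        assert classify(model, frozenset(), delta=0.0) == 0

    def test_delta_out_of_range_rejected(self):
        model = train_maxent(ONE_FEATURE)
        with pytest.raises(ValueError):
            classify(model, frozenset(), delta=0.6)
        with pytest.raises(ValueError):
            classify(model, frozenset(), delta=-0.1)


class TestRankedFeatures:
    def test_separable_feature_heads_positive_list(self):
        model = train_maxent(SEPARABLE)
        positive, negative = ranked_features(model, 1)
        assert positive == ["f"]

    def test_k_larger_than_vocabulary_returns_full_lists(self):
        model = train_maxent(ONE_FEATURE)
        positive, negative = ranked_features(model, 100)
        assert len(positive) == len(model.vocabulary_)
        assert sorted(positive) == sorted(negative)


class TestPersistence:
    def test_text_round_trip_preserves_predictions(self):
        model = train_maxent(ONE_FEATURE, term_id="T1")
        buffer = io.StringIO()
        save_model(model, buffer)
        restored = load_model(io.StringIO(buffer.getvalue()))
        assert restored.term_id == "T1"
        for fs in [frozenset(), frozenset({"f"})]:
            assert predict_proba(restored, fs) == pytest.approx(
                predict_proba(model, fs), abs=1e-12
            )
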