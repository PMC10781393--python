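import warnings

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from stridesense import (FAMILIES, CvSpec, FatigueClassifier, PredictionRecord,
                         SyntheticConfig, benchmark_classifiers,
                         evaluate_metrics, generate_cohort, null_config,
                         per_class_report, predict_and_threshold,
                         train_sequence_model)
from stridesense.fatigue import sequence_backend_available
from stridesense.features import extract_features, feature_matrix
from stridesense.exceptions import (CapabilityError, ParameterError,
                                    TrainingError)


def _metrics_oracle(y_pred, y_true):
    """Literal confusion-count computation, positive class = 1."""
    tp = sum(1 for p, t in zip(y_pred, y_true) if p == 1 and t == 1)
    fp = sum(1 for p, t in zip(y_pred, y_true) if p == 1 and t == 0)
    fn = sum(1 for p, t in zip(y_pred, y_true) if p == 0 and t == 1)
    tn = sum(1 for p, t in zip(y_pred, y_true) if p == 0 and t == 0)
    acc = (tp + tn) / len(y_pred)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, prec, rec, f1


def _records(y_pred, y_true):
    return [PredictionRecord(float(p), int(p), int(t))
            for p, t in zip(y_pred, y_true)]


def _xy(cohort):
    return feature_matrix(extract_features(cohort))


class TestTraining:
    def test_effect_cohort_is_learnable(self, effect_cohort):
        X, y, _ = _xy(effect_cohort)
        Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.25,
                                              random_state=0, stratify=y)
        m = FatigueClassifier("extra_trees", random_state=0).fit(Xtr, ytr)
        acc = np.mean(m.predict(Xte) == yte)
        assert acc > 0.8

    def test_null_cohort_at_chance(self, null_cohort):
        X, y, _ = _xy(null_cohort)
        accs = []
        for seed in range(5):
            Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.25,
                                                  random_state=seed,
                                                  stratify=y)
            m = FatigueClassifier("extra_trees", random_state=seed).fit(Xtr, ytr)
            accs.append(np.mean(m.predict(Xte) == yte))
        n_test = len(y) // 4
        band = 3 * np.sqrt(0.25 / n_test)
        assert abs(np.median(accs) - 0.5) < band

    def test_deterministic_given_random_state(self, effect_cohort):
        X, y, _ = _xy(effect_cohort)
        s1 = FatigueClassifier("random_forest", random_state=5).fit(X, y)\
            .decision_scores(X)
        s2 = FatigueClassifier("random_forest", random_state=5).fit(X, y)\
            .decision_scores(X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(TrainingError):
            FatigueClassifier("extra_trees").fit(X, np.ones(10, dtype=int))

    def test_nonfinite_features_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X[0, 0] = np.nan
        with pytest.raises(TrainingError):
            FatigueClassifier("extra_trees").fit(X, [0, 1] * 5)

    def test_dummy_predicts_all_positive(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        m = FatigueClassifier("dummy_all_positive").fit(X, y)
        assert (m.predict(rng.normal(size=(50, 3))) == 1).all()

    @pytest.mark.parametrize("family", [f for f in FAMILIES if f != "lstm"])
    def test_every_family_emits_unit_interval_scores(self, family,
                                                     effect_cohort):
        X, y, _ = _xy(effect_cohort)
        m = FatigueClassifier(family, random_state=0).fit(X[:100], y[:100])
        s = m.decision_scores(X[100:])
        assert ((s >= 0) & (s <= 1)).all()


class TestThresholding:
    def test_boundary_inclusive(self):
        m = FatigueClassifier(threshold=0.5)
        m.estimator_ = None  # bypass fit; use records directly
        scores = np.array([0.4, 0.5, 0.6])
        states = (scores >= m.threshold).astype(int)
        assert list(states) == [0, 1, 1]

    def test_tau_extremes(self, effect_cohort):
        X, y, _ = _xy(effect_cohort)
        m0 = FatigueClassifier("extra_trees", threshold=0.0,
                               random_state=0).fit(X, y)
        assert (m0.predict(X) == 1).all()
        m1 = FatigueClassifier("logistic", threshold=1.0,
                               random_state=0).fit(X, y)
        s = m1.decision_scores(X)
        np.testing.assert_array_equal(m1.predict(X), (s >= 1.0).astype(int))

    def test_record_count_matches_input(self, effect_cohort):
        X, y, g = _xy(effect_cohort)
        m = FatigueClassifier("naive_bayes").fit(X, y)
        recs = predict_and_threshold(m, X, y, g)
        assert len(recs) == len(y)
        assert all(r.predicted_state == (r.score >= 0.5) for r in recs)


class TestMetrics:
    def test_all_positive_closed_form(self):
        recs = _records([1] * 20, [1] * 10 + [0] * 10)
        m = evaluate_metrics(recs)
        assert m.recall == 1.0
        assert m.precision == 0.5
        assert m.accuracy == 0.5
        assert m.f1 == pytest.approx(2 / 3)

    def test_perfect_predictor(self):
        y = [0, 1, 1, 0, 1]
        m = evaluate_metrics(_records(y, y))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(5, 500))
            y_pred = rng.integers(0, 2, n)
            y_true = rng.integers(0, 2, n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = evaluate_metrics(_records(y_pred, y_true))
            oracle = _metrics_oracle(y_pred, y_true)
            assert (m.accuracy, m.precision, m.recall, m.f1) == oracle

    def test_zero_denominator_convention(self):
        with pytest.warns(UserWarning, match="precision"):
            m = evaluate_metrics(_records([0, 0], [0, 0]))
        assert m.precision == 0.0

    def test_all_positive_identities(self):
        # precision = accuracy = prevalence; F1 = 2p/(p+1)
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            y_true = rng.integers(0, 2, n)
            if y_true.sum() == 0:
                continue
            m = evaluate_metrics(_records([1] * n, y_true))
            p = y_true.mean()
            assert m.recall == 1.0
            assert m.precision == pytest.approx(p, abs=1e-12)
            assert m.accuracy == pytest.approx(p, abs=1e-12)
            assert m.f1 == pytest.approx(2 * p / (p + 1), abs=1e-12)


class TestBenchmark:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        return generate_cohort(SyntheticConfig(
            n_participants=5, strides_per_condition=10,
            amplitude_attenuation=0.3, seed=21))

    def test_table_shape_and_ranges(self, small_cohort):
        table = benchmark_classifiers(small_cohort)
        assert len(table) == 14
        for col in ("accuracy", "precision", "recall", "f1"):
            assert table[col].between(0, 1).all()

    def test_dummy_row_has_unit_recall(self, small_cohort):
        table = benchmark_classifiers(
            small_cohort, families=("dummy_all_positive",))
        assert table.iloc[0]["recall"] == 1.0

    def test_same_seed_identical_table(self, small_cohort):
        fams = ("extra_trees", "logistic", "dummy_all_positive")
        t1 = benchmark_classifiers(small_cohort, fams, random_state=3)
        t2 = benchmark_classifiers(small_cohort, fams, random_state=3)
        assert t1.equals(t2)

    def test_stratified_scheme_also_runs(self, small_cohort):
        t = benchmark_classifiers(small_cohort, ("decision_tree",),
                                  CvSpec(scheme="stratified", n_splits=4))
        assert len(t) == 1

    def test_unknown_scheme_rejected(self, small_cohort):
        with pytest.raises(ParameterError):
            benchmark_classifiers(small_cohort, ("lda",),
                                  CvSpec(scheme="loo"))


def test_per_class_report_layout():
    recs = _records([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
    rep = per_class_report(recs)
    assert list(rep.index) == ["0", "1", "accuracy", "macro avg",
                               "weighted avg"]
    assert rep.loc["accuracy", "f1-score"] == pytest.approx(3 / 5)


def test_sequence_model_contract(effect_cohort):
    """Softmax probabilities sum to 1 when a backend exists; otherwise the
    documented capability error is raised."""
    if not sequence_backend_available():
        with pytest.raises(CapabilityError, match="backend unavailable"):
            train_sequence_model(effect_cohort, epochs=1)
    else:  # exercised only where a deep-learning backend is installed
        model, history = train_sequence_model(effect_cohort, epochs=2)
        import torch
        with torch.no_grad():
            p = model(torch.tensor(effect_cohort.tensor(),
                                   dtype=torch.float32).permute(0, 2, 1))
        np.testing.assert_allclose(p.sum(-1).numpy(), 1.0, atol=1e-6)
        assert len(history["val_loss"]) == 2
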