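"""Fatigue classification: model families, thresholding, metrics, benchmark.

A per-stride feature vector is mapped to a fatigue score in [0, 1] by one of
the classical model families below (mirroring the usual benchmark lineup for
this task), then thresholded at tau (default 0.5, boundary inclusive) to a
binary fatigued/non-fatigued call.  The positive class is *fatigued* (1)
throughout, so recall measures the fraction of fatigued strides detected.

The all-positive baseline (``dummy_all_positive``) calls every stride
fatigued; on any dataset its recall is exactly 1 and its precision and
accuracy both equal the positive prevalence — a useful floor for reading
benchmark tables.

An LSTM sequence model over raw stride channels is available behind an
optional deep-learning backend (PyTorch); when no backend is importable,
:func:`train_sequence_model` raises :class:`~stridesense.exceptions.CapabilityError`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.decomposition import PCA
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.pipeline import make_pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .exceptions import CapabilityError, ParameterError, TrainingError
from .features import StrideFeaturizer, extract_features, feature_matrix
from .io import StrideDataset

#: benchmark lineup; order matches the usual reporting order
FAMILIES = (
    "extra_trees", "random_forest", "qda", "knn", "decision_tree",
    "gradient_boosting", "logistic", "adaboost", "lda", "ridge",
    "lightgbm_like", "svm_linear", "naive_bayes", "dummy_all_positive",
)


def _base_estimator(family: str, hyperparameters: dict, random_state: int):
    hp = dict(hyperparameters or {})
    if family == "extra_trees":
        return ExtraTreesClassifier(random_state=random_state,
                                    **{"n_estimators": 100, **hp})
    if family == "random_forest":
        return RandomForestClassifier(random_state=random_state,
                                      **{"n_estimators": 100, **hp})
    if family == "qda":
        # some features are exactly collinear (band powers sum to total
        # power), so drop the null directions with PCA before the class
        # covariances, and regularize the rest
        return make_pipeline(
            StandardScaler(),
            PCA(n_components=0.9999, svd_solver="full"),
            QuadraticDiscriminantAnalysis(**{"reg_param": 0.1, **hp}))
    if family == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**hp))
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=random_state, **hp)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=random_state, **hp)
    if family == "logistic":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000, **hp))
    if family == "adaboost":
        return AdaBoostClassifier(random_state=random_state, **hp)
    if family == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if family == "ridge":
        return make_pipeline(StandardScaler(), RidgeClassifier(**hp))
    if family == "lightgbm_like":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(random_state=random_state, verbose=-1,
                              **{"n_estimators": 100, **hp})
    if family == "svm_linear":
        return make_pipeline(StandardScaler(),
                             SVC(kernel="linear", random_state=random_state, **hp))
    if family == "naive_bayes":
        return GaussianNB(**hp)
    if family == "dummy_all_positive":
        return DummyClassifier(strategy="constant", constant=1)
    raise ParameterError(f"unknown model family {family!r}; "
                         f"choose from {FAMILIES}")


class FatigueClassifier(BaseEstimator, ClassifierMixin):
    """Thresholded binary fatigue classifier over stride feature vectors.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    threshold : float
        Score threshold tau in [0, 1]; a stride is called fatigued when its
        score is >= tau (boundary inclusive).
    hyperparameters : dict, optional
        Passed through to the underlying estimator.
    random_state : int
        Seeds every stochastic family; fitting is deterministic given it.
    """

    def __init__(self, family: str = "extra_trees", threshold: float = 0.5,
                 hyperparameters: dict | None = None, random_state: int = 0):
        self.family = family
        self.threshold = threshold
        self.hyperparameters = hyperparameters
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if not 0 <= self.threshold <= 1:
            raise ParameterError("threshold must lie in [0, 1]")
        if not np.isfinite(X).all():
            raise TrainingError("non-finite values in the feature matrix")
        classes = np.unique(y)
        if self.family != "dummy_all_positive" and len(classes) < 2:
            raise TrainingError("training data contains a single class")
        self.estimator_ = _base_estimator(self.family, self.hyperparameters,
                                          self.random_state)
        self.estimator_.fit(X, y)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Fatigue score in [0, 1] per stride (probability of class 1 where
        available, otherwise a sigmoid-squashed decision function)."""
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        est = self.estimator_
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(X)
            cls = list(getattr(est, "classes_", [0, 1]))
            return proba[:, cls.index(1)] if 1 in cls else np.zeros(len(X))
        return expit(est.decision_function(X))

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.decision_scores(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)


@dataclass
class PredictionRecord:
    """One scored stride: score in [0,1], thresholded call, and the truth."""

    score: float
    predicted_state: int
    true_state: int
    participant_id: str = ""


def predict_and_threshold(model: FatigueClassifier, X, y_true,
                          participant_ids=None) -> list[PredictionRecord]:
    """Score every stride and apply the model's threshold tau."""
    scores = model.decision_scores(X)
    y_true = np.asarray(y_true, dtype=int)
    if participant_ids is None:
        participant_ids = [""] * len(scores)
    return [
        PredictionRecord(float(s), int(s >= model.threshold), int(t), str(p))
        for s, t, p in zip(scores, y_true, participant_ids)
    ]


@dataclass
class ClassifierMetrics:
    """Accuracy / precision / recall / F1 with per-class support."""

    classifier: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    support_negative: int
    support_positive: int


def evaluate_metrics(records: list[PredictionRecord],
                     classifier: str = "") -> ClassifierMetrics:
    """Confusion-matrix metrics with fatigued (1) as the positive class.

    Zero-denominator precision or recall is reported as 0 with a warning so
    benchmark tables stay total; F1 is 0 when precision + recall is 0.
    """
    if not records:
        raise ParameterError("no prediction records to evaluate")
    y_pred = np.array([r.predicted_state for r in records])
    y_true = np.array([r.true_state for r in records])
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    accuracy = (tp + tn) / len(records)
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision set to 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no positive truths; recall set to 0", stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return ClassifierMetrics(classifier, accuracy, precision, recall, f1,
                             tn + fp, tp + fn)


def per_class_report(records: list[PredictionRecord]) -> pd.DataFrame:
    """Per-class precision/recall/F1 table with accuracy, macro and weighted
    averages (the standard classification-report layout)."""
    y_pred = np.array([r.predicted_state for r in records])
    y_true = np.array([r.true_state for r in records])
    rows = {}
    per_class = []
    supports = []
    for cls in (0, 1):
        tp = int(np.sum((y_pred == cls) & (y_true == cls)))
        predp = int(np.sum(y_pred == cls))
        actp = int(np.sum(y_true == cls))
        p = tp / predp if predp else 0.0
        r = tp / actp if actp else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        rows[str(cls)] = {"precision": p, "recall": r, "f1-score": f,
                          "support": actp}
        per_class.append((p, r, f))
        supports.append(actp)
    acc = float(np.mean(y_pred == y_true))
    n = len(records)
    rows["accuracy"] = {"precision": np.nan, "recall": np.nan,
                        "f1-score": acc, "support": n}
    w = np.array(supports) / n
    arr = np.array(per_class)
    rows["macro avg"] = dict(zip(("precision", "recall", "f1-score"),
                                 arr.mean(axis=0))) | {"support": n}
    rows["weighted avg"] = dict(zip(("precision", "recall", "f1-score"),
                                    (arr * w[:, None]).sum(axis=0))) | {"support": n}
    return pd.DataFrame(rows).T


@dataclass
class CvSpec:
    """Cross-validation protocol: subject-wise grouping (default) prevents
    participant identity leakage; 'stratified' mixes strides of one runner
    across folds."""

    scheme: str = "subject"   # 'subject' or 'stratified'
    n_splits: int = 5
    seed: int = 0


def _folds(cv: CvSpec, X, y, groups):
    if cv.scheme == "subject":
        n = min(cv.n_splits, len(np.unique(groups)))
        if n < 2:
            raise ParameterError("subject-wise CV needs >= 2 participants")
        return GroupKFold(n_splits=n).split(X, y, groups)
    if cv.scheme == "stratified":
        return StratifiedKFold(n_splits=cv.n_splits, shuffle=True,
                               random_state=cv.seed).split(X, y)
    raise ParameterError(f"unknown cv scheme {cv.scheme!r}")


def benchmark_classifiers(ds: StrideDataset,
                          families: tuple[str, ...] = FAMILIES,
                          cv: CvSpec | None = None,
                          featurizer: StrideFeaturizer | None = None,
                          random_state: int = 0) -> pd.DataFrame:
    """Cross-validated Accuracy/Precision/Recall/F1 per model family.

    Metrics are averaged over folds; deterministic given the seed.
    """
    cv = cv or CvSpec()
    featurizer = featurizer or StrideFeaturizer()
    df = extract_features(ds, featurizer._config())
    X, y, groups = feature_matrix(df)
    rows = []
    for family in families:
        fold_metrics = []
        for tr, te in _folds(cv, X, y, groups):
            model = FatigueClassifier(family=family, random_state=random_state)
            model.fit(X[tr], y[tr])
            recs = predict_and_threshold(model, X[te], y[te])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = evaluate_metrics(recs, family)
            fold_metrics.append((m.accuracy, m.precision, m.recall, m.f1))
        acc, prec, rec, f1 = np.mean(fold_metrics, axis=0)
        rows.append({"classifier": family, "accuracy": acc, "precision": prec,
                     "recall": rec, "f1": f1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional LSTM sequence model


def sequence_backend_available() -> bool:
    """True when a deep-learning backend (PyTorch) is importable."""
    try:
        import torch  # noqa: F401
        return True
    except ImportError:
        return False


def train_sequence_model(ds: StrideDataset, epochs: int = 5000,
                         batch_size: int = 32, validation_split: float = 0.1,
                         hidden_units: int = 32, random_state: int = 0):
    """Train an LSTM over raw stride channels with a 2-unit softmax head.

    The reference configuration is epochs=5000, batch_size=32 and a 10%
    validation split; desk-scale tests run reduced epochs.  Returns the
    fitted torch module together with per-epoch loss/accuracy curves.
    Raises CapabilityError when no deep-learning backend is installed.
    """
    if not sequence_backend_available():
        raise CapabilityError(
            "sequence-model backend unavailable: install torch to train the "
            "LSTM fatigue model")
    if epochs < 1:
        raise ParameterError("epochs must be >= 1")
    import torch
    from torch import nn

    torch.manual_seed(random_state)
    X = torch.tensor(ds.tensor(), dtype=torch.float32).permute(0, 2, 1)  # N,L,C
    y = torch.tensor(ds.labels, dtype=torch.long)
    n_val = max(1, int(round(validation_split * len(X))))
    gen = torch.Generator().manual_seed(random_state)
    perm = torch.randperm(len(X), generator=gen)
    va, tr = perm[:n_val], perm[n_val:]

    class _LstmHead(nn.Module):
        def __init__(self, n_channels: int):
            super().__init__()
            self.lstm = nn.LSTM(n_channels, hidden_units, batch_first=True)
            self.dense = nn.Linear(hidden_units, 2)

        def forward(self, x):
            out, _ = self.lstm(x)
            return torch.softmax(self.dense(out[:, -1]), dim=-1)

    model = _LstmHead(X.shape[-1])
    opt = torch.optim.Adam(model.parameters())
    lossfn = nn.NLLLoss()
    history = {"loss": [], "val_loss": [], "accuracy": [], "val_accuracy": []}
    for _ in range(epochs):
        model.train()
        ep_loss, correct = 0.0, 0
        for i in range(0, len(tr), batch_size):
            idx = tr[i:i + batch_size]
            opt.zero_grad()
            prob = model(X[idx])
            loss = lossfn(torch.log(prob.clamp_min(1e-12)), y[idx])
            loss.backward()
            opt.step()
            ep_loss += float(loss) * len(idx)
            correct += int((prob.argmax(-1) == y[idx]).sum())
        model.eval()
        with torch.no_grad():
            pv = model(X[va])
            vl = float(lossfn(torch.log(pv.clamp_min(1e-12)), y[va]))
            vacc = float((pv.argmax(-1) == y[va]).float().mean())
        history["loss"].append(ep_loss / len(tr))
        history["accuracy"].append(correct / len(tr))
        history["val_loss"].append(vl)
        history["val_accuracy"].append(vacc)
    return model, history
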