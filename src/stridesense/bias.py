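"""Systematic-bias estimation, correction, localization and minimization.

Bias B is the mean signed deviation of predictions from truth over a
validation set.  Correction subtracts B; by construction the corrected
series has zero mean bias against the same truths (exact to round-off).
Localization ranks features by the absolute Pearson correlation between the
feature column and the per-sample residual, pointing at inputs whose
variation the model systematically mis-handles.  The minimization loop
alternates bias estimation, localization, and a linear residual correction
on the top-k localized features (with intercept, so a pure constant offset
is absorbed in one iteration) until |B| falls below a threshold epsilon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression

from .exceptions import ParameterError

logger = logging.getLogger(__name__)


def estimate_bias(predicted, true) -> float:
    """Mean signed deviation: mean(predicted - true)."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ParameterError("predicted and true must be equal-length, non-empty")
    return float(np.mean(predicted - true))


def correct_predictions(predicted, bias: float) -> np.ndarray:
    """Subtract the estimated bias from every prediction."""
    return np.asarray(predicted, dtype=float) - float(bias)


def localize_bias(features: np.ndarray, residuals,
                  feature_names: list[str] | None = None) -> list[tuple[str, float]]:
    """Rank features by |Pearson correlation| with the residuals.

    Constant feature columns get score 0 with a warning.  Ties are broken
    by feature name so the ranking is deterministic.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    r = np.asarray(residuals, dtype=float)
    if X.shape[0] != len(r) or len(r) < 3:
        raise ParameterError("need >= 3 rows with matching residuals")
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ParameterError("feature_names length mismatch")
    scores = []
    r_sd = np.std(r)
    for j, name in enumerate(names):
        col = X[:, j]
        if np.std(col) == 0 or r_sd == 0:
            if np.std(col) == 0:
                warnings.warn(f"constant feature {name!r}; score set to 0",
                              stacklevel=2)
            scores.append((name, 0.0))
        else:
            scores.append((name, float(abs(np.corrcoef(col, r)[0, 1]))))
    return sorted(scores, key=lambda t: (-t[1], t[0]))


@dataclass
class BiasReport:
    """Outcome of the iterative bias-minimization loop for the stamina and
    fatigue prediction channels."""

    B_stamina: float
    B_fatigue: float
    B_stamina_post: float
    B_fatigue_post: float
    localized_stamina: list[tuple[str, float]]
    localized_fatigue: list[tuple[str, float]]
    epsilon: float
    iterations: int
    converged: bool
    trajectory: list[dict[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "B_stamina": self.B_stamina,
            "B_fatigue": self.B_fatigue,
            "B_stamina_post": self.B_stamina_post,
            "B_fatigue_post": self.B_fatigue_post,
            "localized_stamina": [list(t) for t in self.localized_stamina],
            "localized_fatigue": [list(t) for t in self.localized_fatigue],
            "epsilon": self.epsilon,
            "iterations": self.iterations,
            "converged": self.converged,
            "trajectory": self.trajectory,
        }


@dataclass
class _LoopResult:
    corrected: np.ndarray
    bias_pre: float
    bias_post: float
    localized: list[tuple[str, float]]
    iterations: int
    converged: bool
    trajectory: list[float]


def _minimize_one(predicted, true, features, feature_names, epsilon, max_iter,
                  top_k) -> _LoopResult:
    pred = np.asarray(predicted, dtype=float).copy()
    true = np.asarray(true, dtype=float)
    X = np.atleast_2d(np.asarray(features, dtype=float))
    bias_pre = estimate_bias(pred, true)
    localized: list[tuple[str, float]] = []
    traj = [abs(bias_pre)]
    iterations = 0
    b = bias_pre
    while abs(b) > epsilon and iterations < max_iter:
        residual = pred - true
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = localize_bias(X, residual, feature_names)
        if iterations == 0:
            localized = ranked
        top = [feature_names.index(name) for name, _ in ranked[:top_k]]
        reg = LinearRegression().fit(X[:, top], residual)
        pred = pred - reg.predict(X[:, top])
        b = estimate_bias(pred, true)
        traj.append(abs(b))
        iterations += 1
    return _LoopResult(pred, bias_pre, b, localized, iterations,
                       abs(b) <= epsilon, traj)


def minimize_bias_loop(predicted, true, features,
                       feature_names: list[str] | None = None,
                       epsilon: float = 1e-3, max_iter: int = 10,
                       top_k: int = 3) -> tuple[np.ndarray, dict]:
    """Iteratively drive |mean bias| below epsilon for one prediction channel.

    Each iteration estimates the bias, ranks features by association with
    the residual, fits a linear residual model (with intercept) on the top-k
    features, and subtracts the fitted residual — the concrete control
    function C.  If epsilon already exceeds the initial |B|, zero iterations
    run and the loop reports convergence.  Reaching ``max_iter`` without
    convergence is reported (converged=False), never raised.

    Returns (corrected predictions, summary dict with the trajectory).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    res = _minimize_one(predicted, true, X, names, epsilon, max_iter, top_k)
    if not res.converged:
        logger.warning("bias loop hit max_iter=%d with |B|=%.3g > epsilon=%.3g",
                       max_iter, abs(res.bias_post), epsilon)
    return res.corrected, {
        "bias_pre": res.bias_pre, "bias_post": res.bias_post,
        "localized": res.localized, "iterations": res.iterations,
        "converged": res.converged, "trajectory": res.trajectory,
    }


def build_bias_report(stamina_pred, stamina_true, fatigue_pred, fatigue_true,
                      features, feature_names: list[str] | None = None,
                      epsilon: float = 1e-3, max_iter: int = 10,
                      top_k: int = 3) -> tuple[np.ndarray, np.ndarray, BiasReport]:
    """Run the minimization loop on both prediction channels and assemble a
    joint report; overall convergence requires both |B'| <= epsilon."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    rs = _minimize_one(stamina_pred, stamina_true, X, names, epsilon, max_iter, top_k)
    rf = _minimize_one(fatigue_pred, fatigue_true, X, names, epsilon, max_iter, top_k)
    report = BiasReport(
        B_stamina=rs.bias_pre, B_fatigue=rf.bias_pre,
        B_stamina_post=rs.bias_post, B_fatigue_post=rf.bias_post,
        localized_stamina=rs.localized, localized_fatigue=rf.localized,
        epsilon=epsilon, iterations=max(rs.iterations, rf.iterations),
        converged=rs.converged and rf.converged,
        trajectory=[{"stamina_absB": s, "fatigue_absB": f}
                    for s, f in zip(
                        rs.trajectory + [rs.trajectory[-1]] * (len(rf.trajectory) - len(rs.trajectory)),
                        rf.trajectory + [rf.trajectory[-1]] * (len(rs.trajectory) - len(rf.trajectory)))],
    )
    return rs.corrected, rf.corrected, report


class BiasCorrector:
    """fit/transform wrapper around constant-offset bias correction.

    ``fit(predicted, true)`` estimates B on a calibration pair;
    ``transform(predicted)`` subtracts it.  Useful inside rolling-window
    correction in the training-control loop.
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "BiasCorrector":
        if params:
            raise ParameterError(f"unknown parameters {sorted(params)}")
        return self

    def fit(self, predicted, true) -> "BiasCorrector":
        self.bias_ = estimate_bias(predicted, true)
        return self

    def transform(self, predicted) -> np.ndarray:
        return correct_predictions(predicted, self.bias_)
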