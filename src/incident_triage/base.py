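"""Binary base classifiers: L2 logistic regression, linear SVM, RBF SVM.

Each fitted model exposes a real-valued decision score plus a calibrated
probability for the task's positive class. Logistic regression probabilities
are native sigmoid outputs; SVM scores are passed through a Platt-style
logistic map fitted on held-out (or, failing that, training) scores. The
calibrated probability is always monotone nondecreasing in the score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "PairTask",
    "OneVsRestTask",
    "PlattCalibrator",
    "BaseClassifierModel",
    "train_base",
    "decision_and_prob",
    "tune_hyperparameters",
]

ALGORITHMS = ("logreg", "svm_linear", "svm_rbf")

# Standard log2 grids; C in 2^-5..2^15 (step 2^2), gamma in 2^-15..2^3.
DEFAULT_C_GRID = [2.0**p for p in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0**p for p in range(-15, 4, 2)]

_SOLVER_TOL = 1e-4
_MAX_ITER = 1000

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class PairTask:
    """Discriminate label ``a`` (positive) from label ``b``."""

    a: str
    b: str


@dataclass(frozen=True)
class OneVsRestTask:
    """Discriminate ``label`` (positive) from all other classes."""

    label: str


Task = Union[PairTask, OneVsRestTask]


@dataclass(frozen=True)
class PlattCalibrator:
    """p = sigmoid(slope * score + intercept), slope >= 0."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("calibration slope must be nonnegative (monotone map)")

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        z = np.clip(self.slope * np.asarray(scores, dtype=float) + self.intercept, -500, 500)
        return 1.0 / (1.0 + np.exp(-z))


def _fit_platt(scores: np.ndarray, y: np.ndarray) -> PlattCalibrator:
    scores = np.asarray(scores, dtype=float).reshape(-1, 1)
    if len(np.unique(y)) < 2:
        return PlattCalibrator(slope=1.0, intercept=0.0)
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=_MAX_ITER, tol=_SOLVER_TOL)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        lr.fit(scores, y)
    slope = float(lr.coef_[0, 0])
    intercept = float(lr.intercept_[0])
    if slope < 0:  # degenerate anti-correlated fit; fall back to identity map
        logger.warning("Platt fit produced a negative slope; using identity calibration")
        slope, intercept = 1.0, 0.0
    return PlattCalibrator(slope=slope, intercept=intercept)


@dataclass(frozen=True)
class BaseClassifierModel:
    task: Task
    algorithm: str
    hyperparams: Mapping[str, float]
    positive_label: str
    negative_label: str
    estimator: object = field(repr=False)
    calibrator: Optional[PlattCalibrator] = None

    def decision_score(self, X) -> np.ndarray:
        """Signed distance-style score; positive favors the positive label."""
        return np.asarray(self.estimator.decision_function(X), dtype=float)

    def predict_prob(self, X) -> np.ndarray:
        """Calibrated probability of the positive label."""
        if self.algorithm == "logreg":
            pos_col = int(np.where(self.estimator.classes_ == 1)[0][0])
            return self.estimator.predict_proba(X)[:, pos_col]
        cal = self.calibrator or PlattCalibrator(1.0, 0.0)
        return cal(self.decision_score(X))


def _make_estimator(algorithm: str, hyperparams: Mapping[str, float]):
    C = float(hyperparams.get("C", 1.0))
    if C <= 0:
        raise ValueError("C must be positive")
    if algorithm == "logreg":
        # default penalty is L2
        return LogisticRegression(C=C, solver="lbfgs", tol=_SOLVER_TOL, max_iter=_MAX_ITER)
    if algorithm == "svm_linear":
        return SVC(kernel="linear", C=C, random_state=0)
    if algorithm == "svm_rbf":
        gamma = hyperparams.get("gamma", "scale")
        if not isinstance(gamma, str) and float(gamma) <= 0:
            raise ValueError("gamma must be positive")
        return SVC(kernel="rbf", C=C, gamma=gamma, random_state=0)
    raise ValueError(f"unknown algorithm {algorithm!r}; valid: {', '.join(ALGORITHMS)}")


def train_base(
    X,
    y: Sequence,
    algorithm: str,
    hyperparams: Optional[Mapping[str, float]] = None,
    task: Optional[Task] = None,
    positive_label: Optional[str] = None,
    calibration_data: Optional[tuple] = None,
) -> BaseClassifierModel:
    """Fit one binary discriminator.

    ``y`` holds exactly two distinct labels. The positive label defaults to
    the task's ``a`` / target label, else the first label encountered in
    ``y``. ``calibration_data`` is an optional ``(X_val, y_val)`` pair of
    held-out examples for Platt calibration of SVM scores; without it,
    calibration falls back to the training scores.
    """
    hyperparams = dict(hyperparams or {"C": 1.0})
    y = np.asarray(y)
    classes = list(dict.fromkeys(y.tolist()))
    if len(classes) < 2:
        raise ValueError("training labels contain a single class; need both")
    if len(classes) > 2:
        raise ValueError(f"expected binary labels, got {len(classes)} classes")
    if positive_label is None:
        if isinstance(task, PairTask):
            positive_label = task.a
        elif isinstance(task, OneVsRestTask):
            positive_label = task.label
        else:
            positive_label = classes[0]
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} absent from training labels")
    negative_label = next(c for c in classes if c != positive_label)

    y_bin = (y == positive_label).astype(int)
    est = _make_estimator(algorithm, hyperparams)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y_bin)
        if getattr(est, "n_iter_", None) is not None and np.max(est.n_iter_) >= _MAX_ITER:
            logger.warning("solver hit the iteration cap (%d) for %s", _MAX_ITER, algorithm)

    calibrator = None
    if algorithm != "logreg":
        if calibration_data is not None:
            X_cal, y_cal = calibration_data
            y_cal_bin = (np.asarray(y_cal) == positive_label).astype(int)
        else:
            X_cal, y_cal_bin = X, y_bin
        calibrator = _fit_platt(est.decision_function(X_cal), y_cal_bin)

    return BaseClassifierModel(
        task=task if task is not None else PairTask(str(positive_label), str(negative_label)),
        algorithm=algorithm,
        hyperparams=hyperparams,
        positive_label=str(positive_label),
        negative_label=str(negative_label),
        estimator=est,
        calibrator=calibrator,
    )


def decision_and_prob(model: BaseClassifierModel, x) -> tuple[float, float]:
    """Score and calibrated positive-class probability for one feature vector."""
    if not hasattr(model.estimator, "classes_"):
        raise ValueError("model is not fitted")
    if sp.issparse(x):
        X = x
    else:
        X = np.atleast_2d(np.asarray(x))
    return float(model.decision_score(X)[0]), float(model.predict_prob(X)[0])


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def mean_validation_f(folds: Sequence[tuple], algorithm: str, hyperparams: Mapping) -> float:
    """Mean positive-class validation F over the repetitions for one grid point."""
    fs = []
    for X_tr, y_tr, X_val, y_val in folds:
        est = _make_estimator(algorithm, hyperparams)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X_tr, np.asarray(y_tr))
        fs.append(_binary_f1(np.asarray(y_val), est.predict(X_val)))
    return float(np.mean(fs))


def tune_hyperparameters(
    folds: Sequence[tuple],
    algorithm: str,
    grid: Optional[Sequence[Mapping[str, float]]] = None,
) -> dict:
    """Pick the grid point with the best mean validation F-score.

    ``folds`` is a sequence of ``(X_train, y_train, X_val, y_val)`` tuples
    (one per repetition); ``y`` values are binary task labels with positive
    class 1. F is the positive-class F. Ties break toward smaller C, then
    smaller gamma.
    """
    if not folds:
        raise ValueError("need at least one (train, validation) repetition")
    if grid is None:
        if algorithm == "svm_rbf":
            grid = [{"C": c, "gamma": g} for c in DEFAULT_C_GRID for g in DEFAULT_GAMMA_GRID]
        else:
            grid = [{"C": c} for c in DEFAULT_C_GRID]
    if not grid:
        raise ValueError("hyperparameter grid is empty")

    best: Optional[tuple] = None
    any_ok = False
    for hp in grid:
        try:
            mean_f = mean_validation_f(folds, algorithm, hp)
        except Exception as exc:  # noqa: BLE001 - skip unfittable grid points
            logger.warning("grid point %s failed (%s); skipped", hp, exc)
            continue
        any_ok = True
        key = (-mean_f, float(hp.get("C", 1.0)), float(hp.get("gamma", 0.0)))
        if best is None or key < best[0]:
            best = (key, dict(hp))
    if not any_ok or best is None:
        raise ValueError("every hyperparameter grid point failed to train")
    return best[1]


def save_model(model: BaseClassifierModel, path) -> None:
    joblib.dump({"format_version": _MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path) -> BaseClassifierModel:
    bundle = joblib.load(path)
    if bundle.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {bundle.get('format_version')}")
    return bundle["model"]
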