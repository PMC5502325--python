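"""Uniform adapter over the seven classifier families, plus AUC scoring.

Families: linear / polynomial / RBF support vector machines, random forest,
lasso-penalised logistic regression, plain logistic regression, and logistic
regression with classic forward-backward (stepwise) feature selection on AIC.
Every family exposes the same contract: fit on a training set, return a
continuous decision score per test subject (higher = more case-like), never
touching test labels.  With 11 cases in 163 subjects, the margin and GLM
families use inverse-prevalence class weighting by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

FAMILIES = (
    "svm_linear",
    "svm_poly",
    "svm_rbf",
    "random_forest",
    "lasso",
    "logistic",
    "stepwise_logistic",
)

_LEGAL_PARAMS = {
    "svm_linear": {"C", "class_weight"},
    "svm_poly": {"C", "degree", "class_weight"},
    "svm_rbf": {"C", "gamma", "class_weight"},
    "random_forest": {"n_estimators", "max_features"},
    "lasso": {"C", "class_weight"},
    "logistic": {"class_weight"},
    "stepwise_logistic": {"criterion", "class_weight"},
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family with fixed hyperparameters.

    ``feature_subset``, when set, restricts fitting and scoring to the named
    variables.
    """

    family: str
    hyperparameters: tuple = ()
    feature_subset: tuple | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        illegal = {k for k, _ in self.hyperparameters} - _LEGAL_PARAMS[self.family]
        if illegal:
            raise ValueError(f"illegal hyperparameters for {self.family}: {illegal}")

    @classmethod
    def make(cls, family: str, feature_subset: Sequence[str] | None = None, **hp):
        return cls(
            family=family,
            hyperparameters=tuple(sorted(hp.items())),
            feature_subset=None if feature_subset is None else tuple(feature_subset),
        )

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "hyperparameters": dict(self.hyperparameters),
                "feature_subset": None
                if self.feature_subset is None
                else list(self.feature_subset),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls.make(
            d["family"], feature_subset=d["feature_subset"], **d["hyperparameters"]
        )


def default_grid(family: str) -> list[ModelSpec]:
    """Inner-loop hyperparameter grid for a family."""
    cs = (0.01, 0.1, 1.0, 10.0, 100.0)
    if family == "svm_linear":
        return [ModelSpec.make(family, C=c) for c in cs]
    if family == "svm_rbf":
        return [
            ModelSpec.make(family, C=c, gamma=g)
            for c in cs
            for g in (0.01, 0.1, 1.0, 10.0)
        ]
    if family == "svm_poly":
        return [ModelSpec.make(family, C=c, degree=d) for c in cs for d in (2, 3)]
    if family == "random_forest":
        return [
            ModelSpec.make(family, n_estimators=500, max_features=mf)
            for mf in ("sqrt", 0.33)
        ]
    if family == "lasso":
        return [
            ModelSpec.make(family, C=float(c))
            for c in np.logspace(-2, 2, 20)
        ]
    if family in ("logistic", "stepwise_logistic"):
        return [ModelSpec.make(family)]
    raise ValueError(f"unknown family {family!r}")


def small_grid(family: str) -> list[ModelSpec]:
    """Reduced grid for simulation studies and permutation reruns."""
    if family == "svm_linear":
        return [ModelSpec.make(family, C=c) for c in (0.1, 1.0)]
    if family == "svm_rbf":
        return [ModelSpec.make(family, C=c, gamma=0.1) for c in (1.0, 10.0)]
    if family == "svm_poly":
        return [ModelSpec.make(family, C=1.0, degree=d) for d in (2, 3)]
    if family == "random_forest":
        return [ModelSpec.make(family, n_estimators=100, max_features="sqrt")]
    if family == "lasso":
        return [ModelSpec.make(family, C=c) for c in (0.1, 1.0)]
    return [ModelSpec.make(family)]


def _build_estimator(spec: ModelSpec, seed: int | None):
    hp = spec.params
    cw = hp.pop("class_weight", "balanced")
    if spec.family == "svm_linear":
        return SVC(kernel="linear", C=hp.get("C", 1.0), class_weight=cw)
    if spec.family == "svm_poly":
        return SVC(
            kernel="poly",
            C=hp.get("C", 1.0),
            degree=hp.get("degree", 2),
            coef0=1.0,
            gamma="scale",
            class_weight=cw,
        )
    if spec.family == "svm_rbf":
        return SVC(
            kernel="rbf",
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            class_weight=cw,
        )
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500),
            max_features=hp.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "lasso":
        return LogisticRegression(
            penalty="l1",
            C=hp.get("C", 1.0),
            solver="liblinear",
            class_weight=cw,
            max_iter=2000,
        )
    if spec.family == "logistic":
        return LogisticRegression(
            penalty=None, solver="lbfgs", class_weight=cw, max_iter=2000
        )
    raise ValueError(spec.family)


def _loglik(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _irls_logit(X1: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Newton-Raphson (IRLS) logistic fit; X1 already carries the intercept
    column.  A small ridge stabilises the Hessian when requested."""
    beta = np.zeros(X1.shape[1])
    eye = np.eye(X1.shape[1])
    eye[0, 0] = 0.0  # never penalise the intercept
    for _ in range(60):
        eta = np.clip(X1 @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        grad = X1.T @ (y - p) - ridge * (eye @ beta)
        hess = (X1 * w[:, None]).T @ X1 + ridge * eye + 1e-10 * np.eye(X1.shape[1])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _fit_logit_aic(X: np.ndarray, y: np.ndarray) -> float:
    """AIC of a maximum-likelihood logistic fit on X (intercept included).

    Perfect or quasi-perfect separation is detected by exploding
    coefficients; the fit then falls back to a ridge-stabilised one with a
    warning, keeping the criterion finite and comparisons well defined.
    """
    k = X.shape[1] + 1  # parameters incl. intercept
    if X.shape[1] == 0:
        p = np.full(y.shape, y.mean())
        return 2 * 1 - 2 * _loglik(p, y)
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = _irls_logit(X1, y)
    if np.max(np.abs(beta[1:])) > 30.0:
        warnings.warn(
            "separation detected in stepwise fit; using ridge-stabilised "
            "logistic regression",
            stacklevel=2,
        )
        beta = _irls_logit(X1, y, ridge=0.01)
    p = 1.0 / (1.0 + np.exp(-np.clip(X1 @ beta, -30, 30)))
    return 2 * k - 2 * _loglik(p, y)


def _screen_candidates(
    X: np.ndarray,
    y: np.ndarray,
    current: list[int],
    candidates: list[int],
    top: int,
) -> list[int]:
    """Rank forward candidates by the Rao score statistic of adding each one
    to the current logistic model; returns the ``top`` indices."""
    X1 = np.column_stack([np.ones(len(y))] + [X[:, j] for j in current])
    beta = _irls_logit(X1, y)
    eta = np.clip(X1 @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-10)
    Xc = X[:, candidates]
    U = Xc.T @ (y - p)
    xWx = np.einsum("ij,ij->j", Xc, Xc * w[:, None])
    C = Xc.T @ (X1 * w[:, None])
    A = X1.T @ (X1 * w[:, None]) + 1e-10 * np.eye(X1.shape[1])
    V = xWx - np.einsum("ij,ij->i", C, np.linalg.solve(A, C.T).T)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(V > 1e-12, U**2 / V, 0.0)
    order = np.argsort(-score, kind="stable")[:top]
    return [candidates[i] for i in order]


def stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    criterion: str = "aic",
) -> list[str]:
    """Forward-backward hill-climb on the logistic-regression AIC.

    Repeatedly adds the variable giving the largest criterion improvement,
    then tests single removals, until no move strictly improves.  Returns a
    possibly empty subset.
    """
    if criterion != "aic":
        raise ValueError("only the AIC criterion is implemented")
    if len(names) < 1:
        raise ValueError("at least one candidate variable required")
    names = list(names)
    current: list[int] = []
    best = _fit_logit_aic(X[:, current], y)
    improved = True
    while improved:
        improved = False
        # forward step; with a large candidate pool, a vectorised Rao score
        # test pre-screens candidates and exact AIC is evaluated on the top
        # handful only (the score and likelihood-ratio orderings agree to
        # first order)
        candidates = [j for j in range(len(names)) if j not in current]
        if len(candidates) > 16:
            candidates = _screen_candidates(X, y, current, candidates, top=10)
        scores = [
            (_fit_logit_aic(X[:, current + [j]], y), j) for j in candidates
        ]
        if scores:
            s, j = min(scores)
            if s < best - 1e-9:
                current.append(j)
                best = s
                improved = True
        # backward step
        if len(current) > 1:
            scores = [
                (_fit_logit_aic(X[:, [c for c in current if c != j]], y), j)
                for j in current
            ]
            s, j = min(scores)
            if s < best - 1e-9:
                current.remove(j)
                best = s
                improved = True
    return [names[j] for j in sorted(current)]


def fit_score(
    spec: ModelSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    feature_names: Sequence[str] | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Fit the specified model and return continuous test scores.

    Scores are the decision margin (SVMs), predicted case probability
    (forest, GLMs) or linear predictor; higher means more case-like.  Test
    labels are never an input.
    """
    train_y = np.asarray(train_y)
    if np.unique(train_y).size < 2:
        raise ValueError("training data contains a single class")

    if spec.feature_subset is not None:
        if feature_names is None:
            raise ValueError("feature_names required to apply a feature_subset")
        idx = [list(feature_names).index(n) for n in spec.feature_subset]
        train_X = train_X[:, idx]
        test_X = test_X[:, idx]
        feature_names = list(spec.feature_subset)

    if train_X.shape[1] == 0:
        # no features: uninformative constant score
        return np.zeros(test_X.shape[0])

    if spec.family == "stepwise_logistic":
        local_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(train_X.shape[1])]
        )
        subset = stepwise_select(train_X, train_y, local_names)
        if not subset:
            return np.zeros(test_X.shape[0])
        idx = [local_names.index(n) for n in subset]
        est = _build_estimator(ModelSpec.make("logistic"), seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(train_X[:, idx], train_y)
            scores = est.predict_proba(test_X[:, idx])[:, 1]
    else:
        est = _build_estimator(spec, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(train_X, train_y)
            if hasattr(est, "decision_function"):
                scores = est.decision_function(test_X)
            else:
                scores = est.predict_proba(test_X)[:, 1]

    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError(f"non-finite scores from {spec.family}")
    return scores


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney identity.

    The probability that a randomly chosen case outscores a randomly chosen
    control, ties counted one half; 0.5 is chance level.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, scores))
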