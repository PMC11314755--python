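"""The seven-classifier bank used on the selected features.

All classifiers expose one contract: fit on (X, y) with y ∈ {0, 1}, then
produce a continuous class-1 score for new samples (probability where the
estimator provides one, decision value otherwise — downstream thresholding
only requires a monotone score scale).  Features are standardised with
training statistics inside the model for the scale-sensitive estimators.
"""

from __future__ import annotations

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CLASSIFIER_KINDS = ("KNN", "PLS", "RF", "LDA", "SVMR", "SVML", "SVMP")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "KNN": {"n_neighbors": 5},
    "PLS": {"n_components": 2},
    "RF": {"n_estimators": 500},
    "LDA": {},
    "SVMR": {"C": 1.0, "gamma": "auto"},  # gamma = 1/p
    "SVML": {"C": 1.0},
    "SVMP": {"C": 1.0, "degree": 3, "gamma": "auto"},
}


class ScoreModel:
    """Uniform fit/score wrapper around one of the seven classifier kinds."""

    def __init__(self, kind: str, estimator, standardise: bool, is_pls: bool = False):
        self.kind = kind
        self._pipe = (
            Pipeline([("scale", StandardScaler()), ("clf", estimator)]) if standardise else estimator
        )
        self._is_pls = is_pls
        self._constant_score: float | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ScoreModel":
        X, y = np.asarray(X, dtype=float), np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2 or counts.min() < 2:
            raise ValueError("need >= 2 samples in each of two classes")
        if np.allclose(X.var(axis=0), 0.0):
            # degenerate design: constant features carry no signal; score by class-1 rate
            self._constant_score = float(np.mean(y))
            return self
        self._pipe.fit(X, y.astype(float) if self._is_pls else y)
        return self

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._constant_score is not None:
            return np.full(len(X), self._constant_score)
        if self._is_pls:
            return np.asarray(self._pipe.predict(X)).ravel()
        est = self._pipe[-1] if isinstance(self._pipe, Pipeline) else self._pipe
        if hasattr(est, "predict_proba"):
            return self._pipe.predict_proba(X)[:, 1]
        return np.asarray(self._pipe.decision_function(X)).ravel()

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.scores(X) >= threshold).astype(int)


def fit_classifier(
    kind: str, X: np.ndarray, y: np.ndarray, hyperparams: dict | None = None, seed: int = 0
) -> ScoreModel:
    """Build and fit one of {KNN, PLS, RF, LDA, SVMR, SVML, SVMP}."""
    if kind not in CLASSIFIER_KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    hp = dict(DEFAULT_HYPERPARAMS[kind])
    hp.update(hyperparams or {})
    if kind == "KNN":
        hp["n_neighbors"] = min(hp["n_neighbors"], max(1, np.asarray(X).shape[0] - 1))
        model = ScoreModel(kind, KNeighborsClassifier(**hp), standardise=True)
    elif kind == "PLS":
        n_comp = min(hp["n_components"], np.asarray(X).shape[1])
        model = ScoreModel(kind, PLSRegression(n_components=n_comp, scale=True), standardise=False, is_pls=True)
    elif kind == "RF":
        model = ScoreModel(kind, RandomForestClassifier(random_state=seed, n_jobs=1, **hp), standardise=False)
    elif kind == "LDA":
        model = ScoreModel(kind, LinearDiscriminantAnalysis(**hp), standardise=False)
    else:
        kernel = {"SVMR": "rbf", "SVML": "linear", "SVMP": "poly"}[kind]
        model = ScoreModel(kind, SVC(kernel=kernel, random_state=seed, **hp), standardise=True)
    return model.fit(X, y)
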