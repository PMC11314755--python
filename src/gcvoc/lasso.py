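"""Pipeline 2: two-step LASSO feature selection and logistic refit.

Step one fits L1-penalised logistic regression along a penalty path,
choosing the penalty by cross-validated deviance (CV-minimum by default,
one-standard-error rule as an option) and keeping the features with
nonzero coefficients.  Step two refits an unpenalised logistic model on
the selected features and uses its predicted probabilities for
classification.  Standardisation always uses training statistics only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from gcvoc.selection import SelectionResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LassoConfig:
    path_len: int = 40
    c_min: float = 1e-3
    c_max: float = 1e2
    rule: str = "cv-min"  # or "1-se"
    cv_folds: int = 10
    seed: int = 0
    max_features: int | None = None

    def __post_init__(self) -> None:
        if self.cv_folds < 3:
            raise ValueError("cv_folds must be >= 3")
        if self.path_len < 20:
            raise ValueError("path_len must be >= 20")
        if self.rule not in ("cv-min", "1-se"):
            raise ValueError(f"unknown penalty-selection rule {self.rule!r}")


def _standardise(X: np.ndarray, mean=None, sd=None):
    if mean is None:
        mean, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _l1_fit(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    m = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=0)
    m.fit(X, y)
    return m


def lasso_select(X: pd.DataFrame, y: np.ndarray, cfg: LassoConfig = LassoConfig()) -> SelectionResult:
    """Features with nonzero L1-logistic coefficients at the CV-chosen penalty.

    Constant features are dropped with a warning before fitting.  If the
    chosen penalty zeroes every coefficient, the fallback is the smallest
    penalty strength on the path that yields at least one nonzero
    coefficient.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two label classes")
    const = X.columns[X.std(axis=0).values == 0.0]
    if len(const):
        logger.warning("dropping %d constant features before LASSO", len(const))
        X = X.drop(columns=list(const))
    cols = list(X.columns)
    Xs, mean, sd = _standardise(X.values)

    Cs = np.logspace(np.log10(cfg.c_min), np.log10(cfg.c_max), cfg.path_len)
    skf = StratifiedKFold(n_splits=min(cfg.cv_folds, int(np.bincount(y).min())), shuffle=True, random_state=cfg.seed)
    dev = np.zeros((cfg.path_len, skf.get_n_splits()))
    for j, (tr, te) in enumerate(skf.split(Xs, y)):
        Xtr, m_, s_ = _standardise(X.values[tr])
        Xte, _, _ = _standardise(X.values[te], m_, s_)
        for i, C in enumerate(Cs):
            m = _l1_fit(Xtr, y[tr], C)
            p = np.clip(m.predict_proba(Xte)[:, 1], 1e-12, 1 - 1e-12)
            dev[i, j] = log_loss(y[te], p, labels=[0, 1])
    mean_dev = dev.mean(axis=1)
    i_min = int(np.argmin(mean_dev))
    if cfg.rule == "1-se":
        se = dev.std(axis=1, ddof=1) / np.sqrt(dev.shape[1])
        # strongest penalty (smallest C) whose deviance is within 1 SE of the minimum
        ok = np.nonzero(mean_dev <= mean_dev[i_min] + se[i_min])[0]
        i_chosen = int(ok[0])
    else:
        i_chosen = i_min

    model = _l1_fit(Xs, y, Cs[i_chosen])
    coef = model.coef_.ravel()
    if not np.any(coef != 0):
        # walk toward weaker penalties (on the path, then beyond) until something enters
        candidates = list(Cs[i_chosen + 1:]) + list(Cs[-1] * 10.0 ** np.arange(1, 8))
        for C in candidates:
            model = _l1_fit(Xs, y, C)
            coef = model.coef_.ravel()
            if np.any(coef != 0):
                logger.warning("empty LASSO selection; fell back to C=%.4g", C)
                break
        else:
            raise ValueError("no penalty yields a nonzero coefficient")
    nz = np.nonzero(coef != 0)[0]
    order = nz[np.lexsort((nz, -np.abs(coef[nz])))]
    if cfg.max_features is not None:
        order = order[: cfg.max_features]
    ids = [cols[i] for i in order]
    return SelectionResult(ids, {cols[i]: float(coef[i]) for i in order}, "lasso")


def refit_and_score(
    selected: SelectionResult | list[str],
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_new: pd.DataFrame,
) -> np.ndarray:
    """Unpenalised logistic refit on the selected features; class-1 probabilities.

    With an empty selection the model is intercept-only and every
    probability equals the training class-1 rate.  Perfect separation is
    handled by refitting with a tiny ridge penalty (logged).
    """
    feats = selected.feature_ids if isinstance(selected, SelectionResult) else list(selected)
    y_train = np.asarray(y_train).astype(int)
    if not feats:
        return np.full(len(X_new), float(np.mean(y_train)))
    Xt, mean, sd = _standardise(X_train[feats].values)
    Xn, _, _ = _standardise(X_new[feats].values, mean, sd)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            m = LogisticRegression(C=np.inf, max_iter=1000)
            m.fit(Xt, y_train)
            if np.abs(m.coef_).max() > 1e3:  # separation: coefficients diverging
                raise ConvergenceWarning("separation")
        except Warning:
            logger.warning("perfect separation in logistic refit; using tiny ridge penalty")
            m = LogisticRegression(C=1e4, max_iter=2000)
            m.fit(Xt, y_train)
    p = m.predict_proba(Xn)[:, 1]
    return np.clip(p, 1e-12, 1 - 1e-12)
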