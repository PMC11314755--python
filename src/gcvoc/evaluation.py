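"""Diagnostic-performance reporting.

Scores become predictions at the ROC-optimal (Youden) threshold — the
cutoff maximising sensitivity + specificity — and are summarised as
accuracy/sensitivity/specificity with 95% Wilson confidence intervals
plus the rank-statistic AUC.  Faecal calprotectin is evaluated the same
way at fixed clinical cutoffs (100 and 250 µg/g).  PCA coordinates and
per-feature boxplot summaries back the study's visualisations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiagnosticEvaluation:
    comparison: str
    model: str
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    auc: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_row(self) -> dict:
        return {
            "comparison": self.comparison,
            "model": self.model,
            "n": self.n,
            "threshold": self.threshold,
            "accuracy": self.accuracy,
            "accuracy_lo": self.accuracy_ci[0],
            "accuracy_hi": self.accuracy_ci[1],
            "sensitivity": self.sensitivity,
            "sensitivity_lo": self.sensitivity_ci[0],
            "sensitivity_hi": self.sensitivity_ci[1],
            "specificity": self.specificity,
            "specificity_lo": self.specificity_ci[0],
            "specificity_hi": self.specificity_ci[1],
            "auc": self.auc,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


def binomial_ci(successes: int, n: int, method: str = "wilson") -> tuple[float, float]:
    """95% CI for a proportion; Wilson score by default, Clopper–Pearson option."""
    if n == 0:
        raise ValueError("n must be positive")
    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    lo, hi = proportion_confint(successes, n, alpha=0.05, method=sm_method)
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Youden-optimal cutoff: maximises sensitivity + specificity.

    Candidate thresholds are midpoints between adjacent distinct scores
    (plus one below the minimum and one above the maximum); a sample is
    called positive when its score is >= the threshold.  Ties are broken
    toward higher specificity, i.e. the highest optimal threshold.
    """
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels).astype(int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    best_t, best_j = cands[0], -np.inf
    for t in cands:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and t > best_t):
            best_j, best_t = j, t
    return float(best_t)


def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
    comparison: str = "",
    model: str = "",
    ci_method: str = "wilson",
) -> DiagnosticEvaluation:
    """Confusion counts, rates with 95% CIs, and the rank-statistic AUC."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels).astype(int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be present")
    if threshold is None:
        threshold = optimal_threshold(scores, labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = len(labels)
    auc = float(roc_auc_score(labels, scores))
    return DiagnosticEvaluation(
        comparison=comparison,
        model=model,
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / n,
        accuracy_ci=binomial_ci(tp + tn, n, ci_method),
        sensitivity=tp / (tp + fn),
        sensitivity_ci=binomial_ci(tp, tp + fn, ci_method),
        specificity=tn / (tn + fp),
        specificity_ci=binomial_ci(tn, tn + fp, ci_method),
        auc=auc,
    )


def fcp_evaluate(
    records: pd.DataFrame, cutoff: float, comparison: str = "IBD_vs_control"
) -> DiagnosticEvaluation:
    """Faecal-calprotectin rule: IBD-positive iff FCP >= cutoff (µg/g)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    df = records.copy()
    missing = df["fcp_ug_per_g"].isna()
    if missing.any():
        logger.warning("excluding %d records with missing FCP", int(missing.sum()))
        df = df[~missing]
    labels = (df["group"] != "control").astype(int).values
    return evaluate(
        df["fcp_ug_per_g"].values, labels, threshold=cutoff,
        comparison=comparison, model=f"FCP>={cutoff:g}",
    )


def pca_report(
    X: pd.DataFrame, labels: np.ndarray | pd.Series, n_components: int = 2, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centred 2-D PCA projection with a deterministic sign convention.

    Each component is flipped, if needed, so its largest-magnitude
    loading is positive.  Returns (coordinates, variance-explained).
    """
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA report needs >= 3 samples and >= 2 features")
    if n_components > X.shape[1]:
        raise ValueError(f"fewer features ({X.shape[1]}) than components requested ({n_components})")
    V = X.values - X.values.mean(axis=0)
    if scale:
        sd = V.std(axis=0)
        V = V / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(V)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1
    out = pd.DataFrame(
        coords, index=X.index, columns=[f"PC{j + 1}" for j in range(n_components)]
    )
    out["label"] = np.asarray(labels)
    return out, pca.explained_variance_ratio_


def boxplot_report(
    fm_values: pd.DataFrame,
    labels: pd.Series,
    selected: list[str],
    partition: pd.Series | None = None,
) -> pd.DataFrame:
    """Five-number summaries per selected feature and group.

    When a partition is given, each feature also gets a
    ``direction_consistent`` flag: True when the sign of
    median(positive) − median(negative) agrees between the training and
    validation partitions.
    """
    missing = [f for f in selected if f not in fm_values.columns]
    if missing:
        raise KeyError(f"selected features not in matrix: {missing}")
    rows = []
    labels = pd.Series(np.asarray(labels), index=fm_values.index)
    parts = (
        {"all": fm_values.index}
        if partition is None
        else {p: partition[partition == p].index.intersection(fm_values.index) for p in ("training", "validation")}
    )
    direction: dict[str, dict[str, float]] = {f: {} for f in selected}
    for pname, idx in parts.items():
        sub, lab = fm_values.loc[idx], labels.loc[idx]
        for f in selected:
            for grp in sorted(lab.unique()):
                v = sub.loc[lab == grp, f].values
                if v.size == 0:
                    continue
                q1, med, q3 = np.percentile(v, [25, 50, 75])
                iqr = q3 - q1
                lo_w = v[v >= q1 - 1.5 * iqr].min()
                hi_w = v[v <= q3 + 1.5 * iqr].max()
                rows.append(
                    dict(partition=pname, feature_id=f, group=grp, median=med,
                         q1=q1, q3=q3, whisker_lo=lo_w, whisker_hi=hi_w, n=v.size)
                )
            groups = sorted(lab.unique())
            if len(groups) == 2:
                d = float(
                    np.median(sub.loc[lab == groups[1], f]) - np.median(sub.loc[lab == groups[0], f])
                )
                direction[f][pname] = d
    out = pd.DataFrame(rows)
    if partition is not None:
        flag = {
            f: (np.sign(d.get("training", 0.0)) == np.sign(d.get("validation", 0.0)))
            for f, d in direction.items()
        }
        out["direction_consistent"] = out["feature_id"].map(flag)
    return out
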