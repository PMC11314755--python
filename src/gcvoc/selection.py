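"""Feature selection for pipeline 1: univariate screen, boruta, RFE, union.

The screen ranks all 3601 wavelet coefficients by a two-sided
Mann–Whitney U test and keeps the 100 smallest p-values.  Boruta then
compares real-feature random-forest importances against shuffled "shadow"
copies with binomial confirm/reject tests; RFE recursively eliminates
low-importance features and picks the subset size with the best
cross-validated accuracy.  The final selection is the rank-ordered union
of the boruta and RFE selections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score


@dataclass
class SelectionResult:
    """Ordered selected features with per-feature scores and provenance."""

    feature_ids: list[str]
    scores: dict[str, float]
    method: str  # univariate | boruta | rfe | union | lasso

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids in selection")
        for f in self.feature_ids:
            if not np.isfinite(self.scores[f]):
                raise ValueError(f"non-finite score for {f}")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "score": [self.scores[f] for f in self.feature_ids],
                "method": self.method,
            }
        )


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) != 2:
        raise ValueError(f"need exactly two label classes, got {np.unique(y)}")


def univariate_screen(X: pd.DataFrame, y: np.ndarray, k: int = 100, test: str = "mannwhitney") -> SelectionResult:
    """Keep the min(k, p) features with the smallest two-sided test p-values.

    Default test is the Mann–Whitney U (rank) test; Welch's t is available
    as an alternative.  Ties are broken by feature (column) order.
    """
    y = np.asarray(y)
    _check_two_classes(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    a = X.values[y == np.unique(y)[0]]
    b = X.values[y == np.unique(y)[1]]
    if test == "mannwhitney":
        # constant columns make exact MWU degenerate; method="asymptotic" handles them (p=1)
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method="asymptotic")
        pvals = np.nan_to_num(np.asarray(res.pvalue), nan=1.0)
    elif test == "welch":
        res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        pvals = np.nan_to_num(np.asarray(res.pvalue), nan=1.0)
    else:
        raise ValueError(f"unknown univariate test {test!r}")
    order = np.lexsort((np.arange(X.shape[1]), pvals))  # stable: p-value, then column order
    keep = order[: min(k, X.shape[1])]
    ids = [X.columns[i] for i in keep]
    return SelectionResult(ids, {X.columns[i]: float(pvals[i]) for i in keep}, "univariate")


def _default_rf(seed: int, n_estimators: int = 200) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)


def boruta_select(
    X: pd.DataFrame,
    y: np.ndarray,
    rf: RandomForestClassifier | None = None,
    max_iter: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> SelectionResult:
    """All-relevant feature selection by the boruta shadow-feature procedure.

    Each iteration appends a column-shuffled "shadow" copy of every
    still-undecided feature, fits a random forest on the extended matrix,
    and scores a *hit* for every real feature whose importance exceeds the
    best shadow importance.  Features are confirmed or rejected by
    two-sided binomial tests on their hit counts at level ``alpha`` with
    Bonferroni correction across features; features still tentative at
    ``max_iter`` are resolved by comparing their median importance against
    the median of the per-iteration best-shadow importances.
    """
    y = np.asarray(y)
    _check_two_classes(y)
    if max_iter < 5:
        raise ValueError("max_iter must be >= 5")
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    cols = list(X.columns)
    TENTATIVE, CONFIRMED, REJECTED = 0, 1, -1
    decision = np.full(p, TENTATIVE)
    hits = np.zeros(p, dtype=int)
    imp_history: list[np.ndarray] = []
    shadow_max_history: list[float] = []
    Xv = X.values

    n_trials = 0
    for it in range(max_iter):
        active = decision != REJECTED
        if not np.any(decision == TENTATIVE):
            break
        idx = np.nonzero(active)[0]
        shadows = Xv[:, idx].copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        Xext = np.hstack([Xv[:, idx], shadows])
        forest = rf if rf is not None else _default_rf(int(rng.integers(2**31)))
        forest.random_state = int(rng.integers(2**31))
        forest.fit(Xext, y)
        imp = forest.feature_importances_
        real_imp = imp[: len(idx)]
        shadow_max = float(imp[len(idx):].max())
        shadow_max_history.append(shadow_max)
        full_imp = np.full(p, np.nan)
        full_imp[idx] = real_imp
        imp_history.append(full_imp)
        hits[idx] += (real_imp > shadow_max).astype(int)
        n_trials += 1
        if n_trials < 5:
            continue  # let counts accumulate before testing
        tent = np.nonzero(decision == TENTATIVE)[0]
        p_hi = stats.binom.sf(hits[tent] - 1, n_trials, 0.5)  # P(X >= hits) under H0
        p_lo = stats.binom.cdf(hits[tent], n_trials, 0.5)
        bonf = max(1, int(np.sum(decision != REJECTED)))
        decision[tent[p_hi * bonf < alpha]] = CONFIRMED
        decision[tent[p_lo * bonf < alpha]] = REJECTED

    # resolve remaining tentative features by median importance vs median best-shadow
    tent = np.nonzero(decision == TENTATIVE)[0]
    if tent.size and shadow_max_history:
        shadow_med = float(np.median(shadow_max_history))
        hist = np.vstack(imp_history)
        med_imp = np.nanmedian(hist[:, tent], axis=0)
        decision[tent[med_imp > shadow_med]] = CONFIRMED
        decision[tent[med_imp <= shadow_med]] = REJECTED

    confirmed = np.nonzero(decision == CONFIRMED)[0]
    hist = np.vstack(imp_history) if imp_history else np.zeros((1, p))
    med_all = np.nan_to_num(np.nanmedian(hist, axis=0))
    order = confirmed[np.lexsort((confirmed, -med_all[confirmed]))]
    ids = [cols[i] for i in order]
    return SelectionResult(ids, {cols[i]: float(med_all[i]) for i in order}, "boruta")


def rfe_select(
    X: pd.DataFrame,
    y: np.ndarray,
    rf: RandomForestClassifier | None = None,
    subset_sizes: tuple[int, ...] = (2, 5, 10, 25, 50, 100),
    cv_folds: int = 5,
    step: float = 0.1,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination with cross-validated subset-size choice.

    A random forest ranks features by importance; the lowest-ranked
    ``step`` fraction is dropped repeatedly to produce a full elimination
    ranking, then each candidate subset size is scored by stratified
    k-fold accuracy and the best (smallest on ties) is returned.
    """
    y = np.asarray(y)
    _check_two_classes(y)
    p = X.shape[1]
    sizes = sorted({s for s in subset_sizes if s <= p})
    if not sizes:
        raise ValueError(f"subset-size grid {subset_sizes} exceeds feature count {p}")
    rng = np.random.default_rng(seed)
    cols = list(X.columns)

    remaining = list(range(p))
    rank = np.zeros(p, dtype=int)  # 1 = kept longest
    while len(remaining) > 1:
        forest = rf if rf is not None else _default_rf(int(rng.integers(2**31)))
        forest.random_state = int(rng.integers(2**31))
        forest.fit(X.values[:, remaining], y)
        imp = forest.feature_importances_
        n_drop = max(1, int(np.floor(step * len(remaining))))
        n_drop = min(n_drop, len(remaining) - 1)
        # drop lowest importance; stable tie-break by column order
        order = np.lexsort((np.array(remaining), imp))
        dropped = [remaining[i] for i in order[:n_drop]]
        for d in dropped:
            rank[d] = len(remaining)
        remaining = [i for i in remaining if i not in set(dropped)]
    rank[remaining[0]] = 1

    ranked = np.argsort(rank, kind="stable")
    best_size, best_score = sizes[0], -np.inf
    n_splits = min(cv_folds, int(np.min(np.bincount(pd.factorize(y)[0]))))
    n_splits = max(2, n_splits)
    for s in sizes:
        subset = ranked[:s]
        forest = _default_rf(int(rng.integers(2**31)), n_estimators=rf.n_estimators if rf is not None else 200)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(rng.integers(2**31)))
        score = float(np.mean(cross_val_score(forest, X.values[:, subset], y, cv=skf, scoring="accuracy")))
        if score > best_score + 1e-12:
            best_score, best_size = score, s
    chosen = ranked[:best_size]
    ids = [cols[i] for i in chosen]
    return SelectionResult(ids, {cols[i]: float(rank[i]) for i in chosen}, "rfe")


def combine_selections(a: SelectionResult, b: SelectionResult) -> SelectionResult:
    """Set union ordered by the best (lowest) rank either method assigned."""
    best_rank: dict[str, int] = {}
    for sel in (a, b):
        for r, f in enumerate(sel.feature_ids):
            best_rank[f] = min(best_rank.get(f, len(a) + len(b)), r)
    ids = sorted(best_rank, key=lambda f: (best_rank[f], f))
    return SelectionResult(ids, {f: float(best_rank[f]) for f in ids}, "union")
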