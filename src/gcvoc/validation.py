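"""Cross-validation schemes and the six study group comparisons.

Three schemes are provided: plain k-fold CV, double (nested) CV in which
feature selection is repeated inside every outer training fold, and
leave-one-out CV.  Matched case–control pairs and baseline/follow-up
pairs are kept in the same fold for the k-fold schemes so that within-pair
correlation cannot leak across the train/test boundary; LOOCV is plain
leave-one-sample-out.  For CV and LOOCV the leakage policy (feature
selection inside vs outside the folds) is an explicit, required choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from gcvoc.classifiers import fit_classifier
from gcvoc.features import FeatureMatrix
from gcvoc.selection import SelectionResult

SCHEMES = ("CV", "DCV", "LOOCV")


@dataclass(frozen=True)
class ComparisonSpec:
    """One two-group comparison: which samples are cases and which referents."""

    name: str
    positive_groups: tuple[str, ...]
    negative_groups: tuple[str, ...]
    pairing: str = "matched"  # matched | paired-longitudinal | unpaired
    positive_timepoint: str = "baseline"
    negative_timepoint: str = "baseline"

    def __post_init__(self) -> None:
        if set(self.positive_groups) & set(self.negative_groups) and self.positive_timepoint == self.negative_timepoint:
            raise ValueError("positive and negative definitions overlap")


#: the six predefined study comparisons
STUDY_COMPARISONS: dict[str, ComparisonSpec] = {
    "IBD_vs_control": ComparisonSpec("IBD_vs_control", ("CD", "UC", "IBDU"), ("control",)),
    "CD_vs_control": ComparisonSpec("CD_vs_control", ("CD",), ("control",)),
    "UC_vs_control": ComparisonSpec("UC_vs_control", ("UC",), ("control",)),
    "UCIBDU_vs_control": ComparisonSpec("UCIBDU_vs_control", ("UC", "IBDU"), ("control",)),
    "CD_vs_UC": ComparisonSpec("CD_vs_UC", ("CD",), ("UC",), pairing="unpaired"),
    "baseline_vs_month3": ComparisonSpec(
        "baseline_vs_month3",
        ("CD", "UC", "IBDU"),
        ("CD", "UC", "IBDU"),
        pairing="paired-longitudinal",
        positive_timepoint="baseline",
        negative_timepoint="month3",
    ),
}


def select_samples(records: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Rows entering a comparison, with label (1=case) and fold-group id.

    For matched comparisons the referents are the matched controls of the
    selected cases; for the longitudinal comparison, the baselines of
    subjects that have a 3-month follow-up versus those follow-ups.
    """
    if spec.pairing == "paired-longitudinal":
        fu = records[(records["timepoint"] == "month3") & records["group"].isin(spec.negative_groups)]
        base = records[
            (records["timepoint"] == "baseline") & records["subject_id"].isin(fu["subject_id"])
        ]
        pos, neg = base.copy(), fu.copy()
        pos["label"], neg["label"] = 1, 0
        out = pd.concat([pos, neg])
        out["fold_group"] = out["subject_id"]
        out.attrs["pairing"] = spec.pairing
        return out
    pos = records[
        (records["timepoint"] == spec.positive_timepoint) & records["group"].isin(spec.positive_groups)
    ].copy()
    neg = records[
        (records["timepoint"] == spec.negative_timepoint) & records["group"].isin(spec.negative_groups)
    ].copy()
    if spec.pairing == "matched" and "control" in spec.negative_groups:
        neg = neg[neg["matched_pair_id"].isin(set(pos["matched_pair_id"].dropna()))].copy()
    pos["label"], neg["label"] = 1, 0
    out = pd.concat([pos, neg])
    if spec.pairing == "matched":
        out["fold_group"] = out["matched_pair_id"].fillna(out["subject_id"])
    else:
        out["fold_group"] = out["subject_id"]
    out.attrs["pairing"] = spec.pairing
    return out


@dataclass(frozen=True)
class CrossValidationPlan:
    scheme: str = "LOOCV"
    outer_folds: int = 5
    inner_folds: int = 5
    seed: int = 0
    selection_in_folds: bool = False  # leakage policy for CV/LOOCV; DCV always selects inside

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.scheme == "DCV" and self.inner_folds < 2:
            raise ValueError("DCV requires inner_folds >= 2")


@dataclass
class ValidationResult:
    """Out-of-fold training scores plus frozen-model validation scores."""

    comparison: str
    classifier: str
    scheme: str
    train_scores: pd.DataFrame  # sample_id, fold, score, truth
    val_scores: pd.DataFrame  # sample_id, score, truth
    selection: SelectionResult

    @property
    def oof(self) -> tuple[np.ndarray, np.ndarray]:
        return self.train_scores["score"].values, self.train_scores["truth"].values


def _outer_folds(plan: CrossValidationPlan, y: np.ndarray, groups: np.ndarray, pairing: str):
    n = len(y)
    if plan.scheme == "LOOCV" or plan.outer_folds == n:
        # k-fold with k = n coincides with leave-one-out
        return [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    k = plan.outer_folds
    if k > n:
        raise ValueError(f"fold count {k} exceeds n={n}")
    if pairing in ("matched", "paired-longitudinal"):
        cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=plan.seed)
        return list(cv.split(np.zeros(n), y, groups))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=plan.seed)
    return list(cv.split(np.zeros(n), y))


def run_validation(
    plan: CrossValidationPlan,
    fm: FeatureMatrix,
    comparison_df: pd.DataFrame,
    selector: Callable[[pd.DataFrame, np.ndarray], SelectionResult],
    classifier_kind: str = "SVML",
    hyperparams: dict | None = None,
    comparison_name: str = "",
) -> ValidationResult:
    """Train/validate one classifier under one CV scheme for one comparison.

    ``selector`` maps a (training) feature sub-matrix and labels to a
    SelectionResult.  With selection outside the folds (default for CV and
    LOOCV, matching a workflow in which the published model "includes the
    selected features"), selection runs once on the full training
    partition; DCV re-runs selection within each outer training fold so
    the outer accuracy estimate is leakage-free.  Every training sample
    receives exactly one out-of-fold score, and a final model fitted on
    the whole training partition scores every validation sample.
    """
    part = fm.partition
    df = comparison_df.set_index("sample_id")
    train_ids = [s for s in fm.sample_ids if s in df.index and part[s] == "training"]
    val_ids = [s for s in fm.sample_ids if s in df.index and part[s] == "validation"]
    Xt_full = fm.values.loc[train_ids]
    y_t = df.loc[train_ids, "label"].values.astype(int)
    groups = df.loc[train_ids, "fold_group"].values
    pairing = comparison_df.attrs.get("pairing", "matched")

    select_inside = plan.selection_in_folds or plan.scheme == "DCV"
    final_sel = selector(Xt_full, y_t)
    if len(final_sel) == 0:
        raise ValueError("selector returned no features")

    folds = _outer_folds(plan, y_t, groups, pairing)
    seen = np.concatenate([te for _, te in folds])
    if sorted(seen) != list(range(len(y_t))):
        raise AssertionError("every sample must appear in exactly one outer test fold")

    rows = []
    for fold_no, (tr, te) in enumerate(folds):
        sel = selector(Xt_full.iloc[tr], y_t[tr]) if select_inside else final_sel
        feats = sel.feature_ids if len(sel) else final_sel.feature_ids
        model = fit_classifier(
            classifier_kind, Xt_full.iloc[tr][feats].values, y_t[tr], hyperparams, seed=plan.seed + fold_no
        )
        sc = model.scores(Xt_full.iloc[te][feats].values)
        for i, s in zip(te, sc):
            rows.append(dict(sample_id=train_ids[i], fold=fold_no, score=float(s), truth=int(y_t[i])))
    train_scores = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)

    final_model = fit_classifier(
        classifier_kind, Xt_full[final_sel.feature_ids].values, y_t, hyperparams, seed=plan.seed
    )
    if val_ids:
        y_v = df.loc[val_ids, "label"].values.astype(int)
        sc_v = final_model.scores(fm.values.loc[val_ids, final_sel.feature_ids].values)
        val_scores = pd.DataFrame({"sample_id": val_ids, "score": sc_v, "truth": y_v})
    else:
        val_scores = pd.DataFrame(columns=["sample_id", "score", "truth"])
    return ValidationResult(
        comparison=comparison_name,
        classifier=classifier_kind,
        scheme=plan.scheme,
        train_scores=train_scores,
        val_scores=val_scores,
        selection=final_sel,
    )
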