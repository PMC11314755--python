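"""End-to-end study runner.

Wires the stages together: (synthetic or on-disk) cohort → joint
preprocessing with validation hold-back → wavelet feature matrix → the
six group comparisons through pipeline 1 (screen → boruta+RFE union →
classifier bank under CV/DCV/LOOCV) and pipeline 2 (two-step LASSO) →
a summary table of validated diagnostic performance per comparison and
method, plus the faecal-calprotectin comparator at 100 and 250 µg/g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from gcvoc.classifiers import CLASSIFIER_KINDS
from gcvoc.evaluation import DiagnosticEvaluation, boxplot_report, evaluate, fcp_evaluate, pca_report
from gcvoc.features import FeatureMatrix, WaveletConfig, build_feature_matrix
from gcvoc.lasso import LassoConfig, lasso_select, refit_and_score
from gcvoc.preprocess import Chromatogram, PreprocessConfig, co_process
from gcvoc.selection import (
    SelectionResult,
    boruta_select,
    combine_selections,
    rfe_select,
    univariate_screen,
)
from gcvoc.simulate import CohortConfig, generate_cohort
from gcvoc.validation import (
    STUDY_COMPARISONS,
    CrossValidationPlan,
    run_validation,
    select_samples,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectorConfig:
    screen_k: int = 100
    boruta_max_iter: int = 50
    boruta_alpha: float = 0.05
    rf_trees: int = 200
    rfe_subset_sizes: tuple[int, ...] = (2, 5, 10, 25, 50, 100)
    rfe_cv_folds: int = 5


@dataclass(frozen=True)
class StudyConfig:
    seed: int = 0
    cohort: CohortConfig | None = None  # None = default synthetic cohort at `seed`
    preprocess: PreprocessConfig = PreprocessConfig()
    wavelet: WaveletConfig = WaveletConfig()
    selector: SelectorConfig = SelectorConfig()
    leakage_policy: str = "outside"  # selection 'outside' or 'inside' CV/LOOCV folds
    schemes: tuple[str, ...] = ("CV", "DCV", "LOOCV")
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    outer_folds: int = 5
    inner_folds: int = 5
    comparisons: tuple[str, ...] = tuple(STUDY_COMPARISONS)
    pipelines: tuple[str, ...] = ("rf", "lasso")  # pipeline 1 (boruta+RFE bank) and/or 2
    lasso: LassoConfig = LassoConfig()
    lasso_input: str = "all"  # 'all' 3601 features or 'screened' 100
    fcp_cutoffs: tuple[float, ...] = (100.0, 250.0)
    min_class_size: int = 3

    def __post_init__(self) -> None:
        if self.leakage_policy not in ("outside", "inside"):
            raise ValueError("leakage_policy must be 'outside' or 'inside'")
        if self.lasso_input not in ("all", "screened"):
            raise ValueError("lasso_input must be 'all' or 'screened'")
        if not set(self.pipelines) <= {"rf", "lasso"}:
            raise ValueError("pipelines must be a subset of {'rf', 'lasso'}")


def _stage_seed(master: int, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence([master, zlib.crc32(stage.encode()) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_selector(cfg: SelectorConfig, seed: int):
    """Pipeline-1 selector: univariate screen then boruta ∪ RFE."""
    from sklearn.ensemble import RandomForestClassifier

    def selector(X: pd.DataFrame, y: np.ndarray) -> SelectionResult:
        screened = univariate_screen(X, y, k=cfg.screen_k)
        Xs = X[screened.feature_ids]
        rf = RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=seed, n_jobs=1)
        b = boruta_select(Xs, y, rf=rf, max_iter=cfg.boruta_max_iter, alpha=cfg.boruta_alpha, seed=seed)
        r = rfe_select(
            Xs, y, rf=rf, subset_sizes=cfg.rfe_subset_sizes, cv_folds=cfg.rfe_cv_folds, seed=seed
        )
        return combine_selections(b, r)

    return selector


def _memoised(selector):
    """Selections are deterministic in (rows, labels); cache across schemes/classifiers."""
    cache: dict = {}

    def wrapped(X: pd.DataFrame, y: np.ndarray) -> SelectionResult:
        key = (tuple(X.index), tuple(np.asarray(y)))
        if key not in cache:
            cache[key] = selector(X, y)
        return cache[key]

    return wrapped


def planted_peak_recovery(
    selected_ids: list[str],
    fm: FeatureMatrix,
    cohort_cfg: CohortConfig,
    peak_indices: tuple[int, ...] | None = None,
    tol_s: float = 5.0,
) -> float:
    """Fraction of planted effect peaks covered by the selected features.

    A peak counts as recovered when at least one selected wavelet
    coefficient's time support overlaps the peak's ±3-sigma elution
    window.  A level-ℓ coefficient's support is taken as its centre ±
    half the dilated filter length (db-family filter length 8).
    """
    if peak_indices is None:
        peak_indices = tuple(cohort_cfg.planted_effects())
    fmap = fm.fmap.loc[[f for f in selected_ids if f in fm.fmap.index]]
    fmap = fmap[fmap["band"] != "pad"]
    levels = fmap["band"].str.slice(1).astype(int)
    half = 0.5 * 8 * (2.0**levels) / 2.0  # seconds at 0.5 s ticks
    lo = fmap["time_centre_s"].values - half.values - tol_s
    hi = fmap["time_centre_s"].values + half.values + tol_s
    hit = 0
    for i in peak_indices:
        pk = cohort_cfg.peaks[i]
        a, b = pk.retention_time - 3 * pk.width, pk.retention_time + 3 * pk.width
        if np.any((lo <= b) & (hi >= a)):
            hit += 1
    return hit / len(peak_indices)


@dataclass
class ComparisonArtifacts:
    selection: SelectionResult
    score_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    pca_coords: pd.DataFrame | None = None
    pca_variance: np.ndarray | None = None
    boxplots: pd.DataFrame | None = None


@dataclass
class StudyResult:
    summary: pd.DataFrame  # validated performance, Table-2 shaped
    training_summary: pd.DataFrame  # out-of-fold training performance
    artifacts: dict[str, ComparisonArtifacts]
    feature_matrix: FeatureMatrix
    records: pd.DataFrame
    config: StudyConfig

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "summary.csv", index=False)
        self.training_summary.to_csv(outdir / "training_summary.csv", index=False)
        for name, art in self.artifacts.items():
            d = outdir / name
            d.mkdir(exist_ok=True)
            art.selection.to_frame().to_csv(d / "selection.csv", index=False)
            for tag, tbl in art.score_tables.items():
                tbl.to_csv(d / f"scores_{tag}.csv", index=False)
            if art.pca_coords is not None:
                art.pca_coords.to_csv(d / "pca.csv")
            if art.boxplots is not None:
                art.boxplots.to_csv(d / "boxplots.csv", index=False)
        with open(outdir / "manifest.txt", "w") as fh:
            for k, v in asdict(self.config).items():
                fh.write(f"{k}: {v}\n")


def build_features(
    chroms: dict[str, np.ndarray] | dict[str, Chromatogram],
    records: pd.DataFrame,
    pre_cfg: PreprocessConfig,
    wav_cfg: WaveletConfig,
    tick_s: float = 0.5,
) -> FeatureMatrix:
    """Joint preprocessing (validation held back) then wavelet features."""
    batch_of = dict(zip(records["sample_id"], records["batch"]))
    as_chrom = []
    for sid in records["sample_id"]:
        c = chroms[sid]
        if isinstance(c, Chromatogram):
            as_chrom.append(c)
        else:
            as_chrom.append(Chromatogram(sample_id=sid, tick_s=tick_s, values=c, batch=batch_of[sid]))
    training = [c for c in as_chrom if c.batch != "validation"]
    validation = [c for c in as_chrom if c.batch == "validation"]
    proc_t, proc_v = co_process(training, validation, pre_cfg)
    return build_feature_matrix(proc_t + proc_v, wav_cfg)


def _eval_or_none(scores, labels, comparison, model) -> DiagnosticEvaluation | None:
    if len(scores) == 0 or len(np.unique(labels)) < 2:
        return None
    return evaluate(np.asarray(scores), np.asarray(labels), comparison=comparison, model=model)


def run_study(
    config: StudyConfig,
    chroms: dict[str, np.ndarray] | None = None,
    records: pd.DataFrame | None = None,
) -> StudyResult:
    """Run every configured comparison through both pipelines and all schemes."""
    if chroms is None or records is None:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        chroms, records = generate_cohort(cohort_cfg)
    fm = build_features(chroms, records, config.preprocess, config.wavelet)

    rows, train_rows = [], []
    artifacts: dict[str, ComparisonArtifacts] = {}
    for name in config.comparisons:
        spec = STUDY_COMPARISONS[name]
        comp_df = select_samples(records, spec)
        comp_df = comp_df[comp_df["sample_id"].isin(fm.sample_ids)]
        tr_mask = comp_df["sample_id"].map(fm.partition) == "training"
        tr_counts = comp_df[tr_mask]["label"].value_counts()
        if len(tr_counts) < 2 or tr_counts.min() < config.min_class_size:
            logger.warning("skipping %s: fewer than %d samples per class", name, config.min_class_size)
            continue
        sel_seed = _stage_seed(config.seed, f"select:{name}")
        selector = _memoised(make_selector(config.selector, sel_seed))
        art = None
        for scheme in (config.schemes if "rf" in config.pipelines else ()):
            plan = CrossValidationPlan(
                scheme=scheme,
                outer_folds=config.outer_folds,
                inner_folds=config.inner_folds,
                seed=_stage_seed(config.seed, f"cv:{name}:{scheme}"),
                selection_in_folds=(config.leakage_policy == "inside"),
            )
            for kind in config.classifiers:
                res = run_validation(
                    plan, fm, comp_df, selector, classifier_kind=kind, comparison_name=name
                )
                if art is None:
                    art = ComparisonArtifacts(selection=res.selection)
                tag = f"{kind}_{scheme}"
                art.score_tables[tag] = res.train_scores
                ev_t = _eval_or_none(*res.oof, name, tag)
                if ev_t is not None:
                    train_rows.append(ev_t.to_row())
                ev_v = _eval_or_none(
                    res.val_scores["score"].values, res.val_scores["truth"].values, name, tag
                )
                if ev_v is not None:
                    rows.append(ev_v.to_row())

        df = comp_df.set_index("sample_id")
        tr_ids = [s for s in fm.sample_ids if s in df.index and fm.partition[s] == "training"]
        va_ids = [s for s in fm.sample_ids if s in df.index and fm.partition[s] == "validation"]

        # pipeline 2: two-step LASSO on the training partition
        if "lasso" in config.pipelines:
            Xt, yt = fm.values.loc[tr_ids], df.loc[tr_ids, "label"].values.astype(int)
            if config.lasso_input == "screened":
                scr = univariate_screen(Xt, yt, k=config.selector.screen_k)
                Xt = Xt[scr.feature_ids]
            lcfg = LassoConfig(**{**asdict(config.lasso), "seed": _stage_seed(config.seed, f"lasso:{name}")})
            lsel = lasso_select(Xt, yt, lcfg)
            if art is None:
                art = ComparisonArtifacts(selection=lsel)
            if va_ids:
                yv = df.loc[va_ids, "label"].values.astype(int)
                pv = refit_and_score(lsel, Xt, yt, fm.values.loc[va_ids, list(Xt.columns)])
                ev_l = _eval_or_none(pv, yv, name, "LASSO")
                if ev_l is not None:
                    rows.append(ev_l.to_row())
                art.score_tables["LASSO"] = pd.DataFrame(
                    {"sample_id": va_ids, "score": pv, "truth": yv}
                )

        if art is not None and len(art.selection) >= 2:
            all_ids = tr_ids + va_ids
            labels = df.loc[all_ids, "label"].values
            art.pca_coords, art.pca_variance = pca_report(
                fm.values.loc[all_ids, art.selection.feature_ids], labels
            )
            art.boxplots = boxplot_report(
                fm.values.loc[all_ids], pd.Series(labels, index=all_ids),
                art.selection.feature_ids, fm.partition,
            )
        if art is not None:
            artifacts[name] = art

    # faecal-calprotectin comparator on the baseline IBD-vs-control contrast
    base = records[(records["timepoint"] == "baseline") & records["fcp_ug_per_g"].notna()]
    for cutoff in config.fcp_cutoffs:
        for part in ("training", "validation"):
            sub = base[base["batch"] == part]
            if len(sub) and sub["group"].nunique() > 1:
                ev = fcp_evaluate(sub, cutoff, comparison="IBD_vs_control")
                row = ev.to_row()
                row["model"] = f"FCP>={cutoff:g}_{part}"
                (train_rows if part == "training" else rows).append(row)

    cols = list(DiagnosticEvaluation(
        "", "", 0.0, 1, 0, 1, 0, 1.0, (0, 1), 1.0, (0, 1), 1.0, (0, 1), 1.0
    ).to_row())
    summary = pd.DataFrame(rows, columns=cols)
    training_summary = pd.DataFrame(train_rows, columns=cols)
    return StudyResult(summary, training_summary, artifacts, fm, records, config)
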