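"""Thresholding, diagnostic rates with CIs, AUC, FCP comparator, PCA, boxplots."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gcvoc.evaluation import (
    binomial_ci,
    boxplot_report,
    evaluate,
    fcp_evaluate,
    optimal_threshold,
    pca_report,
)


def brute_force_threshold(scores, labels):
    """Exhaustive scan over all n+1 threshold positions."""
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best = None
    for t in cands:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / labels.sum()
        spec = np.sum(~pred & (labels == 0)) / (1 - labels).sum()
        j = sens + spec
        if best is None or j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12 and t > best[1]):
            best = (j, t)
    return best


class TestOptimalThreshold:
    def test_separated_toy(self):
        t = optimal_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert t == pytest.approx(0.5)
        ev = evaluate(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]), t)
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0

    def test_identical_scores_tie_rule(self):
        scores = np.full(6, 0.3)
        labels = np.array([0, 1, 0, 1, 0, 1])
        t = optimal_threshold(scores, labels)
        ev = evaluate(scores, labels, t)
        assert ev.sensitivity + ev.specificity == pytest.approx(1.0)
        assert t > 0.3  # tie broken toward higher specificity (all-negative call)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=200).round(2)  # force score ties
        labels = rng.integers(0, 2, 200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        t = optimal_threshold(scores, labels)
        j_best, t_best = brute_force_threshold(scores, labels)
        pred = scores >= t
        j = np.sum(pred & (labels == 1)) / labels.sum() + np.sum(~pred & (labels == 0)) / (1 - labels).sum()
        assert j == pytest.approx(j_best)
        assert t == pytest.approx(t_best)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestEvaluate:
    def test_confusion_arithmetic(self):
        # TP=3 FN=1 TN=2 FP=2
        scores = np.array([1, 1, 1, 0, 1, 1, 0, 0])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        ev = evaluate(scores, labels, threshold=0.5)
        assert (ev.tp, ev.fn, ev.tn, ev.fp) == (3, 1, 2, 2)
        assert ev.sensitivity == 0.75 and ev.specificity == 0.5
        assert ev.accuracy == pytest.approx(5 / 8)
        assert ev.n == 8

    def test_perfect_scores_auc_one(self):
        ev = evaluate(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert ev.auc == 1.0

    def test_label_swap_exchanges_sens_and_spec(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        ev = evaluate(scores, labels, threshold=0.0)
        sw = evaluate(-scores, 1 - labels, threshold=np.nextafter(0.0, 1))
        assert ev.sensitivity == pytest.approx(sw.specificity)
        assert ev.specificity == pytest.approx(sw.sensitivity)

    def test_auc_equals_rank_statistic(self):
        """AUC cross-checked against the Mann–Whitney U statistic."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        ev = evaluate(scores, labels, threshold=0.0)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        auc_rank = u / (labels.sum() * (1 - labels).sum())
        assert ev.auc == pytest.approx(auc_rank)

    def test_confusion_counts_conserve_n(self):
        rng = np.random.default_rng(5)
        scores, labels = rng.normal(size=33), rng.integers(0, 2, 33)
        labels[:2] = [0, 1]
        ev = evaluate(scores, labels)
        assert ev.tp + ev.fp + ev.tn + ev.fn == 33


class TestBinomialCi:
    def test_wilson_matches_closed_form(self):
        lo, hi = binomial_ci(5, 10, "wilson")
        z = stats.norm.ppf(0.975)
        p, n = 0.5, 10
        centre = (p + z**2 / (2 * n)) / (1 + z**2 / n)
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / (1 + z**2 / n)
        assert lo == pytest.approx(centre - half)
        assert hi == pytest.approx(centre + half)

    def test_clopper_pearson_upper_is_one_at_full_success(self):
        _, hi = binomial_ci(10, 10, "clopper-pearson")
        assert hi == 1.0

    def test_interval_widens_as_n_shrinks(self):
        w = [np.diff(binomial_ci(n // 2, n))[0] for n in (100, 40, 10)]
        assert w[0] < w[1] < w[2]

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(0, 0)


class TestFcpEvaluate:
    def _records(self, ibd, control):
        rows = [{"group": "CD", "fcp_ug_per_g": v} for v in ibd]
        rows += [{"group": "control", "fcp_ug_per_g": v} for v in control]
        return pd.DataFrame(rows)

    def test_cutoff_250_toy(self):
        ev = fcp_evaluate(self._records([300, 400], [40, 120]), 250)
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0

    def test_cutoff_100_toy(self):
        ev = fcp_evaluate(self._records([300, 400], [40, 120]), 100)
        assert ev.sensitivity == 1.0 and ev.specificity == 0.5

    def test_sensitivity_monotone_in_cutoff(self):
        rng = np.random.default_rng(1)
        rec = self._records(rng.lognormal(6, 1, 50), rng.lognormal(3.4, 1, 50))
        assert fcp_evaluate(rec, 100).sensitivity >= fcp_evaluate(rec, 250).sensitivity

    def test_missing_fcp_excluded(self):
        rec = self._records([300, np.nan], [40, 120])
        ev = fcp_evaluate(rec, 250)
        assert ev.n == 3


class TestPcaReport:
    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(20, 5))
        b = rng.normal(8, 1, size=(20, 5))
        X = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(40)])
        labels = np.repeat([0, 1], 20)
        coords, var = pca_report(X, labels)
        gap = abs(coords[coords.label == 1].PC1.mean() - coords[coords.label == 0].PC1.mean())
        within = coords.groupby("label").PC1.std().max()
        assert gap > 3 * within

    def test_duplicated_samples_identical_coordinates(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(5, 4))
        X = pd.DataFrame(np.vstack([base, base]), index=[f"s{i}" for i in range(10)])
        coords, _ = pca_report(X, np.zeros(10) + [0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        np.testing.assert_allclose(
            coords.iloc[:5][["PC1", "PC2"]].values, coords.iloc[5:][["PC1", "PC2"]].values, atol=1e-9
        )

    def test_variance_fractions_sum_below_one(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(15, 6)))
        _, var = pca_report(X, np.zeros(15))
        assert 0 < var.sum() <= 1.0 + 1e-12

    def test_too_few_features_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 1)))
        with pytest.raises(ValueError):
            pca_report(X, np.zeros(5))


class TestBoxplotReport:
    def _matrix(self):
        rng = np.random.default_rng(6)
        idx = [f"s{i}" for i in range(40)]
        X = pd.DataFrame(rng.normal(size=(40, 3)), index=idx, columns=["f1", "f2", "f3"])
        labels = pd.Series(np.tile([0, 1], 20), index=idx)
        X.loc[labels == 1, "f1"] += 3.0  # up-regulated in positives everywhere
        part = pd.Series(["training"] * 24 + ["validation"] * 16, index=idx)
        return X, labels, part

    def test_constant_within_group_zero_iqr(self):
        X = pd.DataFrame({"f1": [1.0] * 6}, index=[f"s{i}" for i in range(6)])
        rep = boxplot_report(X, pd.Series([0, 0, 0, 1, 1, 1], index=X.index), ["f1"])
        assert (rep.q3 - rep.q1 == 0).all()

    def test_planted_direction_consistent_across_partitions(self):
        X, labels, part = self._matrix()
        rep = boxplot_report(X, labels, ["f1"], part)
        assert rep[rep.feature_id == "f1"].direction_consistent.all()
        med = rep[(rep.partition == "training") & (rep.feature_id == "f1")].set_index("group")["median"]
        assert med[1] > med[0]

    def test_direction_flag_false_when_partitions_disagree(self):
        X, labels, part = self._matrix()
        val = part[part == "validation"].index
        X.loc[val.intersection(labels[labels == 1].index), "f1"] -= 10.0  # flip in validation
        rep = boxplot_report(X, labels, ["f1"], part)
        assert not rep[rep.feature_id == "f1"].direction_consistent.any()

    def test_unknown_feature_rejected(self):
        X, labels, part = self._matrix()
        with pytest.raises(KeyError):
            boxplot_report(X, labels, ["nope"], part)
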