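# gcvoc

Analysis pipeline for faecal volatile-organic-compound (VOC) profiles
recorded by a gas chromatograph coupled to a metal-oxide gas sensor.
The instrument reports a single resistance-vs-time trace per stool
sample (one reading every 0.5 s over a 40 min run); disease-associated
shifts in VOC abundance appear as amplitude changes of elution peaks.
The package targets the paediatric inflammatory-bowel-disease (IBD)
setting: distinguishing IBD (Crohn's disease, ulcerative colitis,
IBD-unclassified) from other gastrointestinal conditions in matched
case–control pairs, separating the CD and UC subtypes, and comparing
baseline with 3-month follow-up samples — with faecal calprotectin (FCP)
at its 100 and 250 µg/g cutoffs as the clinical comparator.

## What it does

1. **Synthetic cohort simulation** (`gcvoc.simulate`) — chromatograms
   with baseline drift, Gaussian elution peaks with retention jitter,
   group-specific planted peak effects, matched case–control pairing
   (age ±6 months, same sex and site), a two-batch structure with a
   sensor change (gain/offset/retention shift) between batches, and
   follow-up samples with attenuated effects. The default layout is a
   training batch of 48 IBD + 48 control baselines + 23 follow-ups and a
   validation batch of 28 matched pairs + 14 follow-ups.
2. **Preprocessing** (`gcvoc.preprocess`) — asymmetric-least-squares
   baseline correction, within-sample max-normalisation, cross-sample
   alignment by cross-correlation against the pooled median trace.
   Training and validation batches are processed jointly, then the
   validation set is held back from all model fitting.
3. **Wavelet features** (`gcvoc.features`) — each trace's first 1800 s
   is decomposed with a multilevel Daubechies-4 DWT and flattened to a
   fixed vector of 3601 coefficients.
4. **Pipeline 1** (`gcvoc.selection`, `gcvoc.classifiers`,
   `gcvoc.validation`) — Mann–Whitney univariate screen to 100 features,
   boruta ∪ recursive-feature-elimination selection under random
   forests, and a seven-classifier bank (KNN, PLS, RF, LDA, SVM with
   radial/linear/polynomial kernels) validated by CV, nested (double)
   CV, and leave-one-out CV.
5. **Pipeline 2** (`gcvoc.lasso`) — L1-penalised logistic regression for
   feature selection (penalty by cross-validated deviance), then an
   unpenalised logistic refit for classification.
6. **Reporting** (`gcvoc.evaluation`, `gcvoc.study`) — Youden-optimal
   thresholds (max sensitivity + specificity), accuracy/sensitivity/
   specificity with 95% Wilson CIs, rank-statistic AUC, PCA and boxplot
   summaries, and the FCP cutoff comparison.

## Worked example

```python
from gcvoc import CohortConfig, StudyConfig, run_study
from gcvoc.study import SelectorConfig

cfg = StudyConfig(
    seed=5,
    cohort=CohortConfig(
        seed=5,
        training_counts={"CD": 3, "UC": 3, "IBDU": 2},
        validation_counts={"CD": 2, "UC": 2, "IBDU": 2},
        n_followup={"training": 4, "validation": 3},
    ),
    selector=SelectorConfig(screen_k=30, rf_trees=30, boruta_max_iter=10,
                            rfe_subset_sizes=(2, 5), rfe_cv_folds=2),
    outer_folds=3, inner_folds=2, lasso_input="screened", min_class_size=2,
    comparisons=("IBD_vs_control",), schemes=("LOOCV",), classifiers=("SVML",),
)
result = run_study(cfg)
row = result.summary.query("comparison == 'IBD_vs_control' and model == 'SVML_LOOCV'").iloc[0]
print(f"accuracy {row.accuracy:.2f} ({row.accuracy_lo:.2f}-{row.accuracy_hi:.2f}), "
      f"sens {row.sensitivity:.2f}, spec {row.specificity:.2f}, AUC {row.auc:.2f}")
```

prints

```
accuracy 0.75 (0.47-0.91), sens 1.00, spec 0.50, AUC 0.69
```

All eight planted cases in the held-back validation batch are called
IBD (sensitivity 1.00), but at this miniature sample size (8 cases + 8
matched controls in training) half the controls are misclassified; the
wide Wilson interval (0.47–0.91) reflects the n = 16 validation set.
The full default layout (96 training + 56 validation baselines) gives
validated accuracies above 0.9 at the same planted effect sizes — that
number is recomputed by the acceptance script below.

`result.summary` holds one row per comparison × model (7 classifiers ×
3 CV schemes + LASSO, plus FCP rows at cutoffs 100 and 250 µg/g):
accuracy/sensitivity/specificity with Wilson 95% CIs, AUC, the applied
threshold and the confusion counts, all measured on the held-back
validation batch.

The same study runs from the shell:

```sh
gcvoc simulate --seed 5 --out cohort/
gcvoc run --cohort cohort/ --seed 5 --out results/ --comparison IBD_vs_control --scheme LOOCV
gcvoc report --results results/
```

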