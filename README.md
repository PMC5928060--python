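# mutload

Panel-based tumor mutational burden (TMB) estimation from somatic mutation
calls, and evaluation of the estimate as a predictor of cancer-immunotherapy
response.

## The problem

The mutation load of a tumor — the total number of nonsynonymous point
mutations in its exome — predicts response to immune-checkpoint blockade,
but whole-exome sequencing is too slow and expensive for routine clinical
use. `mutload` implements a framework for replacing the exome with a small
custom gene panel: from an exome-wide cohort it learns a sparse linear model
that estimates the full mutation load from the mutation counts of a few
dozen genes.

The estimator is

```
ŷ_m = c + Σ_i a_i · x_mi
```

where `x_mi` is the nonsynonymous point-mutation count of selected gene `i`
in patient `m` (SNP/DNP/TNP substitutions counted as 1/2/3), `a_i` is the
gene's weight and `c` the constant term. The pipeline:

1. **maf_io** — read MAF-style somatic mutation tables, keep missense /
   nonsense / nonstop point mutations, and build the genes × patients
   mutation matrix whose column sums are the actual loads `y_m`.
2. **gene_selection** — keep genes with mutation frequency ≥ 10 %, CDS
   length ≤ 15,000 nt, and a Bonferroni-corrected two-sided Wilcoxon
   rank-sum p < 0.05 for the load difference between mutated and wild-type
   patients.
3. **estimation** — fit weights by ordinary least squares and select the
   gene subset minimizing the Gaussian BIC
   `n·ln(RSS/n) + (genes+1)·ln(n)` (forward greedy search by default,
   exhaustive enumeration as a verification oracle for small candidate
   sets). Two published panels ship with the package: a 24-gene lung
   adenocarcinoma model (intercept 47.24) and a 22-gene melanoma model
   (intercept 18.17).
4. **evaluation** — R² between estimated and actual loads, ROC/AUC for
   durable-clinical-benefit (DCB/NDB) classification with a Youden-J
   optimal threshold, median-split survival with a log-rank test, and
   empirical p-values against 10,000 random same-size gene panels.
5. **simulate** — a synthetic cohort generator (heavy-tailed loads,
   CDS-scaled gene propensities with planted signal genes, exome-remainder
   background, logistic response and exponential survival models) so the
   whole pipeline is testable without any data downloads.

## Worked example

```python
import mutload as ml

cfg = ml.CohortConfig(n_patients=450, seed=7)          # synthetic cohort
cohort = ml.generate_cohort(cfg)
mat = ml.build_mutation_matrix(ml.filter_nonsynonymous(cohort.maf_records))
pids = cohort.clinical.patient_id.tolist()
train, valid = mat.subset_patients(pids[:300]), mat.subset_patients(pids[300:])

reports = ml.select_candidates(train, cohort.annotations)
cands = [r.gene_symbol for r in reports if r.is_candidate]
model, diag = ml.search_best_model(train, cands)

est = ml.predict_load(model, valid)
r2 = ml.r_squared(est, valid.loads().astype(float))
```

prints (via the summary statements in the example script):

```
matrix: 3151 genes x 450 patients
candidates: 74
model genes: 37, training R^2 = 0.9800
validation R^2 = 0.9617
AUC = 0.8685, optimal threshold = 160.50
sens = 0.7534, spec = 0.8831, acc = 0.8200
empirical p (R^2): < 0.001
```

Reading: out of 3151 genes mutated in the cohort, 74 pass the three
candidate filters; the BIC search keeps 37 of them; their counts estimate
the held-out patients' true loads with R² = 0.96; thresholding the estimate
at 160.5 classifies responders at 82 % accuracy; and the model's validation
R² exceeds that of all 1000 random 37-gene panels.

The published panels are available directly:

```python
model = ml.published_model("luad24")     # 24 genes, intercept 47.24
ml.predict_load(model, my_matrix)        # estimated loads per patient
```

A `mutload` command-line interface wraps the same steps
(`simulate`, `build-matrix`, `select-genes`, `fit`, `predict`, `evaluate`,
`verify-random`); every verb writes a JSON run manifest next to its outputs.

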