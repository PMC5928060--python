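# Methods

## Mutation counting and the mutation matrix

A variant call contributes to the mutation load only if its translational
effect is missense, nonsense or nonstop (matched case-insensitively against
the TCGA MAF spellings `Missense_Mutation`, `Nonsense_Mutation`,
`Nonstop_Mutation`) and its type is a point substitution: SNP, DNP or TNP,
counted as 1, 2 or 3 mutations — a di-/tri-nucleotide substitution changes
that many bases. Indels and other types surviving a kept classification are
skipped with a warning, never counted. Duplicate rows are each counted;
counting is defined as summation over records, and deduplication would
require variant coordinates the four required columns do not carry. Gene
symbols are uppercased and whitespace-stripped with no alias resolution, so
matrix construction is deterministic without an external symbol database.
Patient identity is a dialect rule: the TCGA dialect truncates
`Tumor_Sample_Barcode` to its first 12 characters, the generic dialect uses
the barcode verbatim. Multiple samples of one patient merge into a single
matrix column by summation. Gene and patient axes are sorted
lexicographically, making the matrix invariant to input row order.

## Candidate gene selection

Three independent filters, each evaluated and reported for every gene so a
report row documents *why* a gene failed:

- **frequency** ≥ 0.10 (inclusive) — fraction of patients with at least one
  nonsynonymous point mutation in the gene;
- **CDS length** ≤ 15,000 nt (inclusive) — longest-transcript coding length
  from an annotation table of BioMart-export shape; genes missing from the
  table fail this criterion with a warning rather than erroring, since real
  annotation exports are incomplete;
- **association** — two-sided Wilcoxon rank-sum comparison of total loads
  between mutated (count > 0) and wild-type (count = 0) patients,
  Bonferroni-corrected, strict `p_adj < 0.05`.

The rank-sum p-value is computed by full enumeration over all C(n, n_a)
labelings (midranks for ties) when both groups have ≤ 8 observations, and
by the tie-corrected normal approximation otherwise. A degenerate split
(gene mutated in everyone or no one) yields an undefined test and the gene
fails the association criterion. The Bonferroni family size defaults to the
number of genes with a well-defined test — the most conservative defensible
family — and can be overridden when a fixed family (e.g. all matrix genes)
is preferred.

## Model fitting and selection

Weights and intercept minimize the residual sum of squares; the solve is by
SVD with a condition-number threshold of 1e10, and a rank-deficient design
raises an error naming the collinear genes (located by pivoted QR). Subsets
are compared by the Gaussian-likelihood BIC with the variance profiled out,

    BIC = n ln(RSS/n) + k ln(n),    k = #genes + 1,

dropping constants that cancel across models; whether the error variance is
counted in k only shifts every BIC by ln(n) and cannot change the ranking,
so the intercept-counting convention is used. RSS = 0 (a perfect fit) has
no finite profile likelihood and is returned as −inf with a warning so it
wins any comparison.

The subset space over q candidates holds 2^q − 1 non-empty models —
astronomically many already at q = 62 — so the default search is forward
greedy selection: start from intercept-only, add the gene with the largest
BIC decrease, stop when no addition decreases BIC (or a gene cap is hit).
Exhaustive enumeration is available up to a configurable candidate limit
(default 20) and serves as the verification oracle for the greedy search in
the tests; ties are broken lexicographically by gene symbol in both.
Greedy selection is not guaranteed to find the global BIC minimum; on
well-separated planted-signal instances it provably coincides with the
exhaustive optimum, which the test suite checks up to 12 candidates.

Predictions are affine and not clamped by default — negative estimates are
possible for patients with zero counts under a negative-weight model and
are informative about miscalibration; a `clamp` flag floors them at zero.
Models serialize to JSON at full double precision. The two published panels
(24-gene lung adenocarcinoma, 22-gene melanoma) are packaged as JSON with
the printed weights, Entrez ids and constant terms.

## Evaluation

- **R²** defaults to the squared Pearson correlation between estimated and
  actual loads. On a validation cohort the model was not fitted to, the
  1 − RSS/TSS definition can go negative under calibration drift while the
  correlation form still measures ranking agreement, which is what a panel
  substituting for an exome must preserve; both definitions are offered.
- **ROC/AUC**: candidate thresholds are the unique observed scores with the
  inclusive rule "call DCB iff estimate ≥ threshold"; AUC is the tie-aware
  empirical AUC (equal to the Mann–Whitney U statistic over n₁n₂, an
  identity the tests assert). The optimal threshold maximizes Youden's J
  with ties broken toward the *higher* threshold, making the DCB call
  conservative.
- **Survival**: patients are split at the median estimate (ties to the low
  group; for even n with distinct values the split is n/2 vs n/2) and the
  two groups compared with the standard two-group log-rank test
  (lifelines), chi-square with 1 df.
- **Empirical nulls**: p random genes are drawn uniformly without
  replacement from the training matrix, fitted by least squares to the
  training loads, and evaluated on the validation cohort exactly as the
  model of interest is — including each random model's own ROC-derived
  threshold for its accuracy. Empirical p = (#null ≥ observed)/N at
  resolution 1/N, reported as "< 1/N" when no null value reaches the
  observed one. The generator seed is a required argument and the null is
  bit-reproducible given it. Random panels may include genes absent from
  the validation cohort (counted zero) or with degenerate scores; undefined
  metrics propagate as NaN and are excluded from the tail count.

## Synthetic cohorts

The generator produces the three files the pipeline consumes (MAF-style
mutation table, gene→CDS annotation TSV, clinical TSV) with the structure
the framework assumes:

- **loads**: per-patient true load ~ round(LogNormal(ln 150, 1.0)), the
  heavy-tailed regime of lung-adenocarcinoma exomes (median 150
  nonsynonymous mutations, occasional hypermutators).
- **allocation**: each load is decomposed into SNP/DNP/TNP events
  (default mix 0.95/0.04/0.01, SNV-dominated as in somatic data) whose
  weights sum to the load *exactly*, then assigned to genes by a
  categorical distribution with propensity ∝ CDS length × enrichment
  factor. Planting is by an 8× per-nucleotide enrichment for the signal
  genes: enough to place them in the recurrently-mutated band (roughly
  20–75 % of patients) where all three candidate filters can act; much
  higher enrichments saturate frequency at 100 %, which degenerates the
  mutated/wild-type association split, and lower ones leave short signal
  genes under the 10 % frequency bar.
- **exome remainder**: 3,000 background genes at 0.1× propensity soak up
  most of each load while being individually hit in only a few percent of
  patients. This mirrors a real exome-wide mutation matrix, in which the
  vast majority of genes are rarely mutated, and it is what makes the
  random-panel null meaningful: without it every simulated gene is a
  frequent, load-coupled predictor and a random panel estimates load
  nearly as well as a selected one.
- **outcomes**: P(DCB) is logistic in log-load deviation from the median
  (slope 2.0); survival is exponential with scale increasing in load
  (higher burden → longer progression-free survival) under independent
  exponential censoring calibrated to a 30 % censored fraction.
- `generate_from_model` instead draws model-gene counts as independent
  Poissons (rates 0.1–0.6 per patient) and constructs loads as the model's
  affine prediction plus Gaussian noise, recording the exact value in the
  clinical truth table; it is the fixture for parameter-recovery tests.
  Patients whose rounded load and all counts are zero emit no MAF rows and
  legitimately drop out of the matrix.

What passing tests on these cohorts do *not* show: the generator has no
mutational signatures, hotspots, gene–gene correlation beyond the shared
load, copy-number events or subclonality, and its response/survival links
to load are exact by construction; performance numbers on synthetic cohorts
therefore bound what the machinery can do when its assumptions hold, not
what any real cohort will yield.

## Problem sizes

End-to-end checks use a 450-patient cohort over 200 modeled + 3,000
background genes, split 300 training / 150 validation (a single generation
over a shared gene universe, split by matrix columns, since independently
seeded cohorts would draw disjoint gene sets), with 1,000-iteration
random-panel nulls; property checks enumerate rank-sum labelings up to
group sizes of 8, exhaust subset spaces up to 12 candidates, and use
10,000 label permutations for the log-rank comparison on ≤ 20 patients.

## Known limitations

- The forward search can miss the global BIC optimum on strongly collinear
  candidate sets; the exhaustive oracle is limited to small q.
- The Bonferroni family size depends on whether the association test runs
  before or after the frequency/CDS filters; both orderings are defensible
  and the family is configurable.
- Published-panel predictions on cohorts with different variant-calling
  pipelines inherit those pipelines' classification conventions; only the
  three nonsynonymous classes are counted regardless of caller.
- The exact rank-sum enumeration cost grows as C(n_a+n_b, n_a); the cutoff
  of 8 per group keeps it under ~13k labelings.
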