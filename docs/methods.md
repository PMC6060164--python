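# Methods

This note documents the statistical procedures implemented in `tegdist`,
the assumptions behind the synthetic-data generator, and the design
decisions taken where a published convention does not pin down every
detail. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model and conventions

Expression matrices are gene × sample, linear scale (RSEM-like
abundances or microarray intensities), with per-sample annotations
(tissue type, tumor/normal, cohort). Every matrix carries an explicit
scale flag (`linear` / `log2`) plus a centered flag; operations check
these flags so that double-transforming or feeding the wrong scale is a
hard error, not silent corruption. TSV files are tab-separated, UTF-8,
`.` decimal separator, `NA` for missing, no quoting of identifiers.
Grade is ordinal {G1, G2, G3/4} coded 1–3, stage {I, II, III/IV} coded
1–3; missing levels stay missing.

The default pseudocount before log2 is 1 for RSEM-like data (zeros are
common and log2(v+1) is the field convention); microarray intensities
distributed already in log space can be passed with the `log2` flag and
are used as-is.

## TEG screening

A gene is enriched in a tissue when, over non-tumor samples, its mean
linear-scale expression ranks first and (1) differs from the runner-up
tissue and (2) is at least `fold_threshold` (default 100) times the
largest mean among all remaining tissues. The significance test for
criterion 1 is not fixed by convention; we use a two-sided Mann–Whitney
U on the per-sample linear values of the top vs runner-up tissue at
α = 0.05 with no multiplicity correction (none is applied elsewhere in
the pipeline either). Scipy's exact p is used for small tie-free
samples, the tie-corrected normal approximation otherwise. Because the
test is rank-based and the fold ratio is a ratio of means, the entire
screen is invariant to global positive rescaling of the matrix.

Edge policies: a tie for first place is declared no enrichment (it
contradicts the ranking criterion); the fold denominator is floored at
1e−9 so an expressed gene on an all-zero background can pass; when the
two tissues' sample sizes make the minimal attainable two-sided exact
p ≥ α (e.g. 2 vs 2 gives 2/6), the record is flagged and cannot pass.

`compare_gene_sets` reports exact Venn-region counts for arbitrary
user-supplied lists (k-wise intersections and "in ≥ k sets" summaries);
no external database content is bundled.

## Prognostic screening

Each gene is split at its median over the screened tumor samples;
median-valued samples go to the low group (a documented, configurable
choice). Genes where either side of the split has fewer than two
samples are flagged unsplittable and never prognostic. The two groups
are compared with the standard log-rank test; direction
(high-expression protective vs adverse) comes from comparing restricted
mean survival up to the smaller of the two groups' largest observed
times — deliberately model-free so that the screen never fits anything.
Raw p < α (default 0.05) defines a prognostic gene, uncorrected.

## Survival primitives

* **Kaplan–Meier / log-rank** are delegated to lifelines
  (`KaplanMeierFitter`, `multivariate_logrank_test`); ties between an
  event and a censoring at the same time follow the events-first
  convention.
* **Concordance.** Harrell's C for a risk score (higher = higher risk):
  usable pairs are those orderable under right censoring (the earlier
  subject's event observed), tied scores count 1/2. The standard error
  is the Noether-type U-statistic estimator (Pencina–D'Agostino):
  per-subject averages of concordant and discordant pair indicators
  give an asymptotic variance for c = pc/(pc+pd); the 95% CI is normal,
  and the p-value is the two-sided test of c = 0.5. A percentile
  bootstrap CI is available as an alternative
  (`bootstrap_concordance_ci`). A naive binomial variance c(1−c)/N over
  the N pairs would badly understate the uncertainty because pairs
  sharing a subject are correlated; the U-statistic form accounts for
  that, and the test suite checks its null coverage empirically.
  The point estimate is cross-checked in the tests against both a
  pure-Python pair-enumeration oracle and scikit-survival.
* **Brier score.** The scalar risk score is first converted to
  per-subject survival probabilities by a single-covariate
  proportional-hazards fit (lifelines `CoxPHFitter`: Efron tie
  handling, Breslow baseline — matching the documented behaviour of the
  classical score-to-probability conversion used with this metric);
  the probabilities are then scored with the
  inverse-probability-of-censoring-weighted Brier score
  (scikit-survival `brier_score`, censoring weights from the
  Kaplan–Meier estimate of the censoring distribution), and an
  integrated score is the time-normalized trapezoid over the evaluation
  grid. Since no single evaluation time is canonical, callers get both
  the per-time scores and the integrated value; the evaluation helpers
  default to quartiles of observed follow-up. Non-convergence of the
  partial-likelihood fit raises with the underlying diagnostics.
* **Time-dependent ROC.** Cumulative-case / dynamic-control ROC at a
  horizon t with the Kaplan–Meier estimator of Heagerty, Lumley and
  Pepe: with S the overall KM curve and S_c the KM curve among subjects
  with score > c, TPR(c) = (1−S_c(t))·P(score>c)/(1−S(t)) and
  FPR(c) = S_c(t)·P(score>c)/S(t). AUC is the trapezoid over the ROC
  points traversed in natural path order (descending cutoff), which
  with no censoring reduces exactly to the Mann–Whitney statistic
  between cases and controls. Only this KM variant is implemented; the
  nearest-neighbor smoothed variant is out of scope.

## Profile and methylation analyses

Gene-set summaries are per-sample means (log2 scale for expression, raw
beta for methylation) compared across groups with the tie-corrected
Kruskal–Wallis test (its two-group special case covers differentiated
vs non-differentiated cell-line comparisons — Kruskal–Wallis on two
groups is the Mann–Whitney test up to tie handling, so no separate
operation exists). Grade trends are per-gene Spearman correlations
against the ordinal coding; "decreasing" means rho < 0 with p < 0.05,
and because that rule is a convention, the sign-only fraction (rho < 0
regardless of p) is reported alongside. Constant genes have no defined
correlation and are excluded from the denominators with a warning.
Methylation–expression correlation is Spearman per gene within the
normal (rn/pn) and tumor (rt/pt) strata after intersecting samples by
id; genes not covered by both matrices are skipped with a warning,
mirroring real methylation panels that cover only part of a gene set.

## Consensus clustering

Monti-style resampling: for each K in 2..k_max, `iterations` rounds
draw ⌊0.8·N⌋ samples without replacement and partition them with
k-means (Euclidean; greedy k-means++-style seeding, one restart per
round — the resampling already provides restarts; ≤ 100 Lloyd
iterations, tol 1e−6). The consensus entry for a sample pair is its
co-clustering count divided by its co-sampling count; never
co-subsampled pairs get 0 and a coverage tally (final label extraction
refuses to run on such matrices and advises more iterations). Defaults
follow the classical protocol: 1000 iterations, k_max 6, subsample
fraction 0.8.

Cluster-number selection is not canonical, so two rules are provided:
PAC (proportion of consensus entries in the ambiguous band 0.1–0.9;
minimized, ties to the smallest K with a flag) as the default, and the
delta-area-of-the-consensus-CDF rule (largest K whose relative area
increase exceeds 0.025) as the alternative; the chosen K is always
overridable, since in practice cluster counts are often fixed by
inspection. When PAC exceeds 0.5 for every K the result is flagged
ambiguous. Final labels cut an average-linkage hierarchical tree built
on 1 − consensus.

Randomness: one master seed; each K and each iteration derive their own
substream by counter, so results are reproducible and independent
across K.

## Mean expression distance

Implemented exactly as displayed in the README: per gene the RMS log2
difference between the tumor and *all* p normal samples (not matched
pairs), averaged over the n set genes, computed via moment expansion
(E[(y−x)²] = y² − 2y·mean(x) + mean(x²)) for speed. Properties relied
on elsewhere: med ≥ 0, med = 0 iff the tumor equals every normal on
every set gene; with pseudocount 0 the score is invariant to global
positive rescaling; with a single normal it reduces to the mean
absolute log2 difference. The default gene set is the full
tissue-enriched set; restricting to a prognostic subset is a caller
choice. Patients are ranked by increasing med and split into contiguous
blocks differing in size by at most one (remainder to the
smallest-distance groups), ties broken by sample id and flagged.

The Table-2-style association reports, per categorical level, counts
across the distance groups with row percentages (denominator = the row
total, rounded to one decimal) and a chi-square test without continuity
correction; 2×2 tables with any expected count < 5 fall back to Fisher's
exact test, larger sparse tables keep chi-square with a
low-expected-count flag (there is no standard r×c exact test in scipy).
Continuous variables get per-group mean/SD and a Kruskal–Wallis p.
Missing values are excluded per variable with counts recorded.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed once and mirror the structure of a
pan-tissue compendium with a liver-enriched set:

| parameter | default | meaning |
|---|---|---|
| n_tissues | 12 | non-tumor tissue types (first is `liver`) |
| samples_per_tissue | 10 | normals per tissue |
| n_genes | 1000 | genes simulated |
| n_planted_tegs | 50 | genes enriched in liver |
| planted_fold | 1000 | enriched-tissue mean / background mean |
| n_tumors | 300 | tumor cohort size |
| stage_effect | 1.0 | log2 downregulation of planted genes per stage step |
| methyl_coupling | 0.8 | fraction of planted genes with beta–expression coupling |
| hazard_coef | 2.0 | log-hazard per SD of true distance |
| censor_rate | 0.3 | expected censored fraction |
| noise_sd | 0.5 | log2-scale Gaussian noise |
| stage mix | 40/30/30 % | stages I / II / III-IV |

Expression is log-normal: per-gene log2 means ~ N(3, 1.5) shared across
tissues, planted genes shifted by log2(fold) in liver, i.i.d. N(0,
noise_sd) noise on the log2 scale — so fold planting is exact in
expectation and all values are strictly positive. Tumors copy the liver
profile; each tumor's planted genes are reduced by a continuous "true
downregulation" a_j = stage_index·stage_effect + N(0, 0.3) (clipped at
0), whose standardization z_j is the true linear predictor. Survival is
exponential with rate log(2)/1095 · exp(hazard_coef·z_j) (baseline
median ≈ 3 years); with probability censor_rate a subject is
right-censored uniformly on (0, T_j), which keeps censoring uniform and
makes the realized censored fraction equal censor_rate in expectation.
Methylation covers all planted genes plus 20% of background genes
(real methylation panels cover gene sets only partially); coupled genes
get beta = clip(b₀ + 0.1·(reference − log2 expression) + N(0, 0.02),
0, 1) so beta rises exactly when expression falls, within both strata.
Clinical covariates (AFP, gender, vascular invasion, age, weights,
grade) are generated from the same latent severity z_j with logistic or
linear links, so the association table has planted signal. Random
streams are split by named substream (expression / tumor / methylation
/ survival / clinical), making each component reproducible in
isolation. `simulate_subtypes` additionally plants K expression
subtypes as disjoint gene blocks shifted by a separation (default 2.5
log2 units), giving roughly equidistant centroids for validating
consensus clustering.

What the generator does **not** emulate: library-size or batch effects,
gene–gene correlation beyond the planted structure, heavy-tailed
expression noise, informative censoring, probe-level methylation, or
realistic marginal distributions of any specific platform. Passing
tests therefore demonstrate correctness of the algorithms under a
clean, known-truth model — not performance on any real cohort.

## Problem sizes in the checks

The automated checks run the generator at 500–1000 genes, 5–10 samples
per tissue, 100–300 tumors, and consensus clustering at 100 iterations
on 60 samples; brute-force oracles (pair enumeration, Venn bit
patterns, direct IPCW sums, hand O−E tables) operate on instances of
n ≤ 30 where exhaustive computation is exact. These sizes were chosen
as the smallest at which every planted effect is unambiguous.

## Known limitations

* The Brier conversion assumes proportional hazards for the scalar
  score; a badly miscalibrated score still yields a valid IPCW estimate
  of its own error but not of any other model's.
* The KM-based time-dependent ROC estimator is not guaranteed monotone
  for heavily censored subgroups (a known property of the estimator);
  points are clipped to [0, 1].
* Only k-means is available as the inner clustering; the configuration
  enum is deliberately extensible.
* No multivariable Cox modeling, no multiplicity correction anywhere
  (by design, matching the screening conventions above), and no
  download clients or probe-to-gene mapping for specific platforms.
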