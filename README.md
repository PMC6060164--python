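# tegdist

Tissue-enriched gene screening and expression-distance prognosis analysis
for tumor cohorts.

## The problem

Tissue-enriched genes (TEGs) are expressed far more highly in one tissue
than in any other and encode that tissue's specialized functions. In many
solid tumors — hepatocellular carcinoma is the motivating case — the
tissue-enriched set is progressively silenced as tumors advance in stage
and grade (dedifferentiation), partly through promoter hypermethylation,
and the *degree* of that silencing carries prognostic information. `tegdist`
packages the full analysis chain for this question:

1. **TEG screening** from a multi-tissue non-tumor expression matrix: a
   gene is enriched in a tissue when its mean linear-scale expression
   (a) ranks first and differs significantly from the runner-up tissue
   (two-sided Mann–Whitney U, α = 0.05) and (b) is ≥ 100× the largest mean
   among all remaining tissues.
2. **Prognostic screening**: every gene dichotomized at its median
   expression, groups compared by the log-rank test (raw p < 0.05).
3. **Profile analyses** of a gene set: per-sample set means across
   tumor/normal and stage groups (Kruskal–Wallis), per-gene Spearman trends
   against ordinal grade, gene–gene correlation, and methylation–expression
   correlation (beta values vs expression, per stratum).
4. **Consensus clustering** (Monti resampling: repeated subsampling +
   k-means, Euclidean distance; PAC / delta-area cluster-number selection).
5. **Mean expression distance**: for a gene set of *n* genes, *p* normal
   samples *x₍ᵢₖ₎* and tumor *j* with expression *y₍ᵢⱼ₎*,

   $$\mathrm{med}_j = \frac{1}{n}\sum_{i=1}^{n}
       \sqrt{\frac{1}{p}\sum_{k=1}^{p}
       \left(\log_2 y_{ij} - \log_2 x_{ik}\right)^2 }$$

   — per gene the root-mean-square log2 difference between tumor *j* and
   every normal sample, averaged over the set. Patients sorted by
   increasing med are split into equal tertiles (small / middle / large
   distance), and med is evaluated as a risk score with Harrell's C-index
   (with asymptotic CI and p), an IPCW Brier score (risk score → survival
   probabilities via a single-covariate proportional-hazards fit),
   time-dependent ROC/AUC, group-wise Kaplan–Meier curves with log-rank,
   and a contingency-style association table against clinical covariates.

Because the original cohorts are large public datasets, the package ships
a first-class synthetic-data generator with known ground truth (planted
TEGs, stage-coupled downregulation, methylation coupling, distance-driven
hazards) so that every stage of the pipeline is testable end to end.

## Worked example

```python
import numpy as np
import tegdist as td

cfg = td.SimConfig(seed=1)                      # 12 tissues, 1000 genes, 300 tumors
normals, truth = td.simulate_multitissue(cfg)
tumors, clin, meth, truth = td.simulate_tumor_cohort(cfg, normals, truth)

screen = td.screen_tegs(normals)                # fold >= 100, MWU p < 0.05
legs = screen.gene_sets["liver"]
print(f"liver-enriched genes: {legs.n} (of {cfg.n_planted_tegs} planted)")

liver = normals.subset_samples([s for s in normals.sample_ids
                                if s.startswith("liver")])
scores = td.mean_expression_distance(tumors, liver, legs, pseudocount=1.0)
groups = td.assign_groups(scores, n_groups=3)

t = clin.data["os_time_days"]
metrics = td.evaluate_distance_prognosis(scores, groups, clin,
                                         eval_times=np.quantile(t, [0.25, 0.5]))
c = metrics.concordance
print(f"C-index {c.c:.3f} (95% CI {c.ci_low:.3f}-{c.ci_high:.3f}, p = {c.p:.2e})")
print(f"integrated Brier score {metrics.brier.integrated:.3f}")
print(f"log-rank across distance groups: chi2 = {metrics.logrank.chi2:.1f}, "
      f"p = {metrics.logrank.p:.2e}")
```

prints

```
liver-enriched genes: 50 (of 50 planted)
C-index 0.849 (95% CI 0.826-0.872, p = 5.82e-188)
integrated Brier score 0.081
log-rank across distance groups: chi2 = 293.0, p = 2.40e-64
```

The screen recovers exactly the 50 planted liver-enriched genes; the
distance score strongly separates the simulated survival outcomes
(C-index 0.85 — the simulation plants a hazard slope of 2 per SD of true
distance, stronger than typical real cohorts), and the three distance
groups differ sharply in survival.

The same pipeline is available from the shell:

```sh
tegdist --seed 1 --out-dir out simulate
tegdist --out-dir out screen-tegs --expr out/normals.tsv --meta out/normals_meta.tsv
tegdist --out-dir out distance --tumors out/tumors.tsv --tumors-meta out/tumors_meta.tsv \
        --normals out/normals.tsv --normals-meta out/normals_meta.tsv \
        --genes out/tegs_liver.txt
tegdist --out-dir out evaluate --scores out/distance_scores.tsv --clinical out/clinical.tsv
```

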