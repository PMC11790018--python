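# methdep

Integrative pharmaco-epigenomic analysis for cancer cell-line panels: from
pooled CRISPR knockout screen counts to gene dependency scores, from
dose-response plates to IC50/AUC, and from multi-omics feature tables to a
nominated methylation biomarker of drug response.

The package is built for the setting where a genetic dependency (for
example, an anti-apoptotic gene such as *MCL1*) is enriched in one patient
group (pediatric versus adult tumors) and a correlated CpG cluster in a
partner gene (such as *BCL2L1*) predicts which models respond to a targeted
inhibitor. Every analysis stage is exercised end to end on synthetic
cohorts with planted ground truth, so estimator recovery, false-discovery
control and biomarker nomination can be tested quantitatively.

## What it computes

- **Dependency scores (β).** For each gene and cell line, the median over
  its sgRNAs of replicate-averaged log2 fold-changes of endpoint versus
  day-0 reference abundance, affinely anchored per cell line so that
  nontargeting controls score 0 and core-essential controls score −1.
  More negative β = stronger growth dependency. Hits are called at
  β ≤ −0.5.
- **Age-group differential dependency.** Per-gene unpaired Student's
  t-tests with Benjamini–Hochberg adjustment; a gene is
  pediatric-specific when Δ = mean β(adult) − mean β(pediatric) ≥ 0.1 at
  FDR < 0.05 (adult-specific for Δ ≤ −0.1), plus 2×2 exact-test
  prevalence comparisons and per-model dependency ranking.
- **Dose response.** Four-parameter logistic fits
  v(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill) (normalized model:
  top = 1, bottom = 0), right-censoring at the maximum dose, AUC of mean
  viability over log10 dose normalized so a nonresponder scores 1, and
  sensitive/resistant classification at IC50 < 2 μM.
- **Biomarker nomination.** Multi-omics feature assembly (expression,
  methylation, mutation, CNV, clinical one-hots), top-variance and top-400
  correlation prefilters, a seeded cross-validated random-forest response
  model with held-out permutation importances, importance normalization
  (score = importance / max importance, top features at score ≥ 0.3), and
  per-feature single-correlate (Pearson) waterfalls.
- **CpG cluster analysis.** Hierarchical clustering of locus CpG sites on
  1 − r correlation distance, exclusion of uniformly lowly methylated
  clusters, β-value binarization at a cutoff (methylated iff β ≥ 0.5), and
  exact-test scanning over candidate cutoffs to choose the threshold.
- **Synthetic cohorts.** A generator that plants a binary methylation
  state driving a co-methylated 10-of-44 CpG block, anti-correlated
  expression of the host gene (target r = −0.87), an age-group-specific
  dependency (pediatric-methylated effect −0.92 versus −0.18), negative
  binomial screen counts, and state-dependent IC50s — all returned
  alongside the ground truth for recovery testing.

## Worked example

```python
from methdep.synthetic import TruthConfig, generate_cohort
from methdep import screen, dose, methylation

tables, truth = generate_cohort(TruthConfig(seed=7))

norm = screen.normalize_counts(tables.counts)
betas = screen.compute_beta_scores(norm, tables.count_samples, tables.library)
diff = screen.differential_dependency(betas, tables.annotations["age_group"])
print(diff.loc["MCL1", ["mean_beta_adult", "mean_beta_pediatric", "delta", "fdr", "call"]])

hits = screen.call_hits(betas)
prev = screen.dependency_prevalence(hits.loc["MCL1"], tables.annotations["age_group"])
print(prev["percent"], "p = %.2g" % prev["p_value"])

fits = dose.fit_cohort(tables.dose_response).reset_index().set_index("cell_line")
print("sensitive lines:", int((fits["label"] == "sensitive").sum()), "of", len(fits))

scan = methylation.scan_threshold(tables.methylation.loc[truth.exemplar_cpg], fits["label"])
print("chosen beta cutoff:", scan.chosen_cutoff)
```

prints

```
mean_beta_adult                 -0.054846
mean_beta_pediatric             -0.568533
delta                            0.513687
fdr                              0.009226
call                   pediatric_specific
Name: MCL1, dtype: object
{'pediatric': 69, 'adult': 0} p = 3.6e-05
sensitive lines: 45 of 75
chosen beta cutoff: 0.5
```

Reading: on this 65 + 10 line synthetic cohort the focal gene is called a
pediatric-specific dependency (Δ ≈ 0.51 at FDR < 0.05), 69% of pediatric
versus 0% of adult lines are dependency hits (exact-test p = 3.6e-05),
45/75 lines are inhibitor-sensitive, and scanning methylation cutoffs on
the exemplar cluster CpG against those sensitivity calls recovers the
planted β ≥ 0.5 threshold.

The same pipeline runs from the shell:

```bash
methdep run-all --seed 7 --outdir out/
methdep simulate --seed 7 --outdir cohort/
methdep screen --counts cohort/counts.tsv --samples cohort/count_samples.tsv \
    --library cohort/library.tsv --groups groups.tsv --outdir screen_out/
```

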