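# Methods

This note documents the models, estimators and design choices behind
`methdep`, the parameters that matter, and what the synthetic-cohort tests
do and do not demonstrate about real data.

## Dependency scoring from pooled screens

Guide counts are normalized to counts-per-million, a pseudocount (default
1) added, and log2 taken. For each endpoint sample the guide-level log2
fold-change (LFC) is taken against the cell line's own day-0 reference
samples when present, otherwise against the shared plasmid reference pool;
LFCs are averaged over replicates and genes aggregated as the **median of
their guides' LFCs**. This is a deliberate simplification relative to
regression-based essentiality estimators (e.g. maximum-likelihood guide
models): the median is robust to single bad guides, fully specified, and
its behavior against planted truth is easy to audit. No copy-number
correction or guide-efficiency modeling is attempted.

Raw gene LFC scales are arbitrary, so each cell line is **control-anchored**:
an affine map sends the median nontargeting-control gene score to 0 and the
median core-essential-control gene score to −1. Anchoring fails loudly when
the two control medians coincide (a screen with no signal). After
anchoring, β = −1 means "as depleted as a core-essential gene" and β = 0
"no growth effect"; hits are β ≤ −0.5 (boundary inclusive). The anchoring
record (both raw medians) is retained per cell line.

Differential dependency between groups uses an unpaired two-sided
Student's t-test per gene (Welch available via `equal_var=False`),
Benjamini–Hochberg adjustment across all tested genes, and a two-part
call gate: |Δ| ≥ 0.1 (Δ = mean adult − mean pediatric β) and FDR < 0.05.
Genes with zero variance in both groups are reported with p = 1 and a
`degenerate` flag rather than raising, so screens with saturated guides do
not abort a cohort analysis.

Screen QC reports Pearson correlations of log-normalized counts for every
replicate pair within a (cell line, timepoint) and the per-sample fraction
of guides at or above a count floor (default 30); the screen passes when
all replicate correlations exceed 0.5.

## Dose-response quantification

The four-parameter logistic model
`v(d) = bottom + (top − bottom) / (1 + (d/IC50)^hill)` is fit by bounded
nonlinear least squares with the IC50 parameterized as log10(nM) and a
grid of 7 log-spaced IC50 initializations (best sum of squares wins).
Two model classes are offered:

- **normalized** (default): top = 1 and bottom = 0 fixed. Viability here
  is already a fraction of the untreated control, and the synthetic assays
  span complete kill curves, so this is the appropriate and far better
  identified model: at per-well noise sd 0.05 over a 12-point triplicate
  curve the IC50 is recovered to a typical ~5% relative error.
- **free**: all four parameters within bounds (hill 0.2–5, top 0.4–1.4,
  bottom −0.1–0.6). The free model is the right choice for partial
  responders, but its IC50 trades off against the asymptotes and is only
  identifiable to roughly ~12% at the same noise; use it deliberately.

A fit is **right-censored** when the fitted IC50 exceeds the maximum
tested dose or the fitted curve never reaches the half-response level
inside the tested range; censored fits report IC50 at the maximum dose and
classify as resistant. Sensitivity is IC50 strictly below 2 μM; the
log10(nM) form (threshold 3.3 ≈ 2 μM) is reported for reference.

**AUC** is the trapezoidal integral of mean replicate viability over
log10(dose) across the nonzero doses, divided by the log-dose span, so a
flat nonresponder scores exactly 1 and a complete responder 0. It is
computed from the raw measurements, not the fitted curve, so it stays
defined when fits fail; zero-dose wells are excluded from the integral
(they serve as the 100%-viability control upstream). Cohort AUCs can be
normalized to a named reference cell line sharing the dose grid.
Fold-sensitivity ratios of censored IC50s are flagged as bounds.

## Random-forest biomarker nomination

Feature assembly column-binds five modality blocks on the shared samples:
expression and methylation (each reduced to the top-k most variable
features, default k = 8,000 i.e. effectively all features at synthetic
scale, then z-scored), binary mutation and CNV tables (passed through),
and one-hot-encoded clinical categoricals. Samples missing from any block
are dropped with a warning; disjoint blocks are an error.

Before modeling, features are prefiltered to the top k = 400 by absolute
Pearson correlation with the continuous response (point-biserial for
binary features; zero-variance features score 0). The prefilter is
computed once on the full cohort, not within folds — its purpose here is
dimension reduction for the forest, and nominated biomarkers are judged by
planted-truth recovery, not by the out-of-fold performance estimate, which
this choice optimistically biases (recorded in provenance).

The response model is a seeded random forest (default 300 trees,
`max_features='sqrt'`, 5-fold shuffled CV) in regression mode on the
continuous AUC (primary) or classification mode on sensitive/resistant
labels. Raw importance is **permutation importance evaluated on each
held-out fold** and averaged (negative values clipped at zero); impurity
importance is selectable but biased toward high-cardinality continuous
features. The permutation computation is batched — all permuted copies are
scored in a single forest prediction — which is algebraically the standard
estimator but ~25× faster; it is cross-checked against the scikit-learn
reference implementation in the test suite.

Importance normalization ranks features by raw importance and reports
`normalized_score = importance / max importance`; features with score
≥ 0.3 are flagged top biomarkers. The slope of the least-squares line
through (rank, importance), with |slope| divided by (max importance × number
of features), is reported as a model-level **concentration** diagnostic:
near zero for flat importance profiles, larger when importance is carried
by few features. This reading keeps the 0.3 threshold well defined on
[0, 1]; the gradient quantity is deliberately model-level, since a
per-feature gradient-based score has no unambiguous definition.

Single-correlate analysis reports per-feature Pearson r against the
response with two-sided t-distribution p-values, BH adjustment, and a
waterfall ordering by signed r (most negative — strongest sensitivity
association when the response is AUC — first).

## CpG cluster and threshold analysis

Locus CpG sites are clustered on distance 1 − r (pairwise Pearson
correlation across samples) with average-linkage agglomeration and a fixed
tree cut at height 0.5, i.e. sites joining at average correlation above
0.5 share a cluster. A fixed cut height, rather than a fixed cluster
count, is what "find the tightly co-methylated block" means without
assuming how many blocks exist; both linkage and height are configurable.
Constant sites get correlation 0 to everything (logged). Cluster labels
are renumbered canonically so the assignment is invariant to row and
sample order. Clusters with mean β below 0.1 are flagged uniformly lowly
methylated and excluded from biomarker candidacy — 0.1 operationalizes
"uniformly lowly methylated", which is otherwise qualitative.

Binarization calls a sample methylated iff β ≥ cutoff (default 0.5,
boundary inclusive). The cutoff can be chosen by scanning a candidate grid
(default 0.1–0.9 in steps of 0.1): each cutoff's 2×2 table
(methylated/unmethylated × sensitive/resistant) gets a two-sided exact
test; cutoffs emptying a methylation row are degenerate (p recorded as 1);
the chosen cutoff minimizes p with ties resolved toward the smallest
cutoff. The per-cutoff p-values are **uncorrected for the selection over
cutoffs** — the scan is exploratory, and its output says so.

The exact test uses the probability-mass two-sided convention (sum of
hypergeometric point probabilities not exceeding the observed table's),
implemented via `scipy.stats.fisher_exact` and verified against full
enumeration in the tests; the odds ratio is the sample (a·d)/(b·c) with
0/0 flagged undefined. Age-group methylation summaries compare per-sample
statistics (mean β over a site set, or the global median β) between
samples below and at/above an age cutoff (default 21 years) with a
Student's t-test.

## The synthetic cohort: what it emulates

The generator produces a cohort of pediatric and adult tumor cell lines
(defaults 65 + 10) in which a **latent binary methylation state** is the
single upstream cause: it is more frequent in pediatric lines (75% versus
10%), drives a 10-site co-methylated block within a 44-CpG locus, sets the
host gene's expression (intercept − slope × mean cluster β + noise), sets
the focal gene's dependency effect (−0.92 in methylated pediatric lines,
−0.18 otherwise), and sets the true IC50 (lognormal around 10^2.6 ≈ 400 nM
when methylated; above a 50 μM floor otherwise, beyond the 20 μM dose
range).

Key parameter choices, with rationale:

- **Methylation states.** Cluster sites share a per-sample latent β drawn
  from Beta(64, 35) (methylated, mean 0.65) or Beta(35, 64) (unmethylated,
  mean 0.35), plus site-level Gaussian jitter (sd 0.05, clipped to [0, 1]).
  The two shapes are mirror images, so their densities cross exactly at
  β = 0.5: the planted binarization threshold genuinely is 0.5. They are
  deliberately concentrated near the boundary, because the threshold scan
  resolves cutoffs at 0.1 resolution with a smallest-cutoff tie-break —
  recovery of 0.5 requires both flanking bins (0.4–0.5, 0.5–0.6) to be
  reliably occupied while crossings of 0.5 stay rare. (A bin-occupancy
  versus crossing-rate calculation gives a combined site-level sd near
  0.06; simulation at these defaults recovers the 0.5 cutoff in ~99% of
  cohorts.) A separate Beta(1.5, 20) (mean ≈ 0.07) generates the
  uniformly lowly methylated "second cluster" sites; remaining locus and
  background sites are Beta(0.8, 0.8), the bimodal shape typical of array
  β-values.
- **Expression coupling.** The host gene's expression noise sd is
  calibrated analytically from the realized methylation values so the
  Pearson correlation with the exemplar cluster CpG approximates the
  target (default −0.87); with the target unset, `expr_noise_sd` is used
  directly, and zero noise gives correlation exactly −1 with the cluster
  mean.
- **Screen counts.** Negative binomial with variance μ + αμ² at 500
  reads/guide coverage (a 500× representation screen). Cell-passage
  samples use α = 0.05; the plasmid day-0 reference uses α = 0.005,
  reflecting that plasmid pools are sequenced without the transduction and
  growth bottlenecks that dominate endpoint overdispersion. Guide effects
  are the planted gene effect plus per-guide N(0, 0.1) jitter; non-focal
  target genes carry N(0, 0.4) gene-level effects so estimator recovery is
  measurable as a correlation; essential controls are fixed at −1 and
  nontargeting at 0, matching the anchoring convention. Under these
  defaults the β estimator recovers planted effects at Pearson r ≈ 0.93
  and replicate log-count correlations sit near 0.65–0.75.
- **Dose-response.** 12-point grid: 0 plus 11 half-log-spaced doses up to
  20 μM (the dose spacing inside the 0–20 μM range is a package choice);
  3 replicates; viability = 4PL(top 1, bottom 0, hill 1) plus N(0, 0.05)
  noise truncated to [0, 1.2] — assays do occasionally report >100%
  viability, and negative viability is unphysical.

**What passing tests do not show.** The generator has one latent cause and
clean conditional independence: no tumor-purity mixtures, no subtype
structure, no copy-number interactions with screen counts, no batch or
plate effects, no probe cross-reactivity, no partial dose-response
curves. Recovery results therefore demonstrate that the estimators are
correctly implemented and calibrated under their own assumptions — not
that real cohorts satisfy those assumptions. In particular, patient
tumors show lower overall methylation than cell lines (purity dilution);
no purity adjustment is implemented, and β cutoffs chosen on cell lines
should not be transferred to tissue data unadjusted.

## Numerical and interface choices

- All randomness flows from single integer seeds (`TruthConfig.seed`, the
  pipeline's global seed expanded per stage via `SeedSequence`); identical
  configuration and seed reproduce byte-identical output tables.
- Interchange is plain TSV/CSV with documented headers; readers validate
  column names, dtypes and value ranges and name the file, column and
  first offending row on failure. Every pipeline output directory
  contains the resolved configuration and a provenance record (package
  version, parameters, seed).
- Display percentages round half-up to integers
  (`decimal.Decimal`), so 49/65 prints as 75%.
- Ranking ties (gene ranks, feature ranks, variable selection) break
  lexicographically by identifier; the threshold scan breaks p-value ties
  toward the smallest cutoff.
- BH adjustment delegates to statsmodels, the exact test to scipy, the
  forest to scikit-learn, clustering to scipy's hierarchy module; each is
  cross-checked in the tests against an independent oracle (step-up
  enumeration, hypergeometric enumeration, the scikit-learn permutation
  reference, closed-form Pearson/t).

## Known limitations

- Gene aggregation by guide-median has no uncertainty estimate per β; the
  differential test treats cell lines, not guides, as replicates.
- The prevalence exact test treats hit calls as fixed, ignoring β
  estimation error near the −0.5 boundary.
- The top-400 correlation prefilter precedes cross-validation, so the
  out-of-fold Spearman/R² are optimistic as generalization estimates.
- The threshold scan's chosen cutoff is selection-biased (uncorrected);
  it nominates, it does not confirm.
- In vivo screen scales reporting positive essentiality scores are out of
  scope; the package reports signed β and ranks only.
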