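# Methods

This document records the statistical model behind each `mc5` module, the
default parameters and why they were chosen, the scope of the synthetic
cohort generator, and the numerical and design decisions that shape the
implementation.

## 1. Regulator catalog and cluster anchoring

The analysis operates on a catalog of 21 5mC-regulator genes: 4 writers
(DNMT1, DNMT3A, DNMT3B, DNMT3L), 3 erasers (TET1, TET2, TDG) and 14
readers (MBD1–4, MECP2, NEIL1, NTHL1, SMUG1, UHRF1, UHRF2, UNG and three
placeholder slots READER12–14). The three placeholders exist because the
source gene list underlying this catalog is not fully public; callers may
substitute their own symbols through `RegulatorCatalog`.

Consensus clustering returns arbitrary cluster numbers. All downstream
conventions — score orientation, the direction of "cluster-2-specific"
DMPs, mutation comparisons — assume **cluster 1 = better prognosis**, so
`relabel_by_prognosis` renumbers the two clusters by the sign of the log
hazard of cluster 2 versus cluster 1 from a univariate Cox fit. This
makes every reported direction deterministic and independent of the
clustering's internal label choice.

## 2. Consensus clustering (`mc5.cluster`)

Distance: 1 − Spearman rank correlation between sample columns over the
regulator genes (average ranks on ties). Partitioning: PAM k-medoids
(BUILD initialization plus full SWAP descent, lowest-index tie-breaking)
on the precomputed distance. Resampling: `reps = 1000` subsamples of
`p_item = 0.8` of samples and `p_feature = 0.8` of genes; the consensus
matrix entry M_k(i,j) is the fraction of co-sampled runs in which i and
j co-cluster. k ∈ {2, …, `max_k` = 6} is scored by PAC — the fraction of
off-diagonal consensus entries in the ambiguous band (0.1, 0.9) — with
the smallest PAC winning and ties resolved toward smaller k; the CDF
delta-area curve is reported as a diagnostic. Final assignments per k
come from average-linkage hierarchical clustering of 1 − M_k.

The 0.8/0.8/1000/6 defaults mirror the published analysis settings.
Subsample indices can be recorded (`record_subsamples=True`) so a test
can replay the bookkeeping exactly.

`purity_adjust` regresses each gene's log2 expression on tumor purity
and keeps residual + grand mean, supporting the purity-confounding
sensitivity analysis.

## 3. Differential expression (`mc5.diffexpr`)

Two-group comparison uses empirical-Bayes moderated t-statistics: per-gene
pooled variances s² are shrunk toward a prior s₀² with prior degrees of
freedom d₀ estimated by method of moments on log variances (trigamma
inverse via Newton). With d₀ = ∞ the posterior variance for every gene is
the across-gene mean of s² — i.e. the ordinary pooled-variance t — which
the tests exploit as an exact limit identity. Genes with zero residual
variance get t = 0, p = 1. P-values use the t distribution with
d₀ + d_residual df (normal when d₀ = ∞) and are Benjamini–Hochberg
adjusted by a hand-written step-up procedure (cross-checked against
statsmodels). DEGs require adjusted P < 0.001 **and** |log2FC| > 1.5,
both strict, matching the published thresholds.

## 4. 5mC score (`mc5.score`)

Signature genes are the DEGs whose univariate Cox Wald P < 0.05
(`cox_alpha`). The retained genes are z-scored (mean 0, sd 1 per gene);
the score is the projection onto the first principal component of the
gene–gene covariance of the z-scores — equivalently, score_j = Σ_g w_g
z_gj with unit-norm loadings w. Deterministic base sign: the loading
with the largest magnitude is made positive; the final orientation sign
is chosen so the mean score of cluster 1 is the higher one. Applying the
model to a new cohort re-standardizes genes within that cohort by
default (cross-platform comparability); `freeze_standardization=True`
reuses the training constants. Missing genes are imputed at standardized
0 with a warning, with > 50% missing an error.

## 5. Survival (`mc5.survstats`)

* Kaplan–Meier product-limit estimator; at tied times events precede
  censorings.
* k-sample log-rank test from the hypergeometric observed−expected
  decomposition, χ² with k−1 df.
* Cox proportional hazards by Newton–Raphson on the **Breslow**
  partial likelihood (tolerance 1e-8, ≤ 50 iterations). Risk-set sums
  are O(n) cumulative sums over samples sorted by decreasing time, with
  tied event times sharing the last tied index's sums. Monotone
  likelihood (perfect separation) is detected by a runaway step and
  returned as a flagged infinite-beta sentinel, not raised; the
  prognostic gene filter skips such fits. Multivariable fits one-hot
  encode categoricals (first level dropped) and reject rank-deficient
  designs, naming the aliased columns.
* Optimal score cutpoint: the maximally selected rank statistic — the
  standardized two-group log-rank statistic at every admissible midpoint
  between consecutive unique score values, both groups ≥ `minprop = 0.1`
  of the cohort, ties in |statistic| resolving to the lower cutoff. The
  selection P is deliberately not corrected for multiple cutpoints;
  downstream comparisons report the ordinary log-rank test on the
  resulting groups.

## 6. Enrichment (`mc5.enrich`)

ssGSEA follows the Barbie running-sum form: within each sample genes are
ranked by expression (average ranks on ties); walking genes in
decreasing-expression order, ES = Σ (P_in − P_out) where P_in is the
rank^α-weighted in-set ECDF (α = 0.25) and P_out the uniform out-of-set
ECDF. Scores are rank-based, hence invariant to monotone transforms of
expression. Normalization divides the whole signature-by-sample matrix
by its global max − min. The T-cell-inflamed score is a fixed-coefficient
weighted sum over 18 genes whose coefficients must be supplied (they are
proprietary to the original publication and never invented here).
Immunity-cycle step activity is ssGSEA(positive genes) − ssGSEA(negative
genes) from a signed GMT dialect (`gene|+1` / `gene|-1`). Group
comparisons use Welch's t when Shapiro does not reject normality in
either group (α = 0.05), Mann–Whitney U otherwise, and Fisher's exact
test for binary features, all BH-adjusted.

## 7. Methylation (`mc5.methyl`)

DMPs are tested with the moderated-t engine on β values directly
(optionally M-values, log2(β/(1−β)) with β clipped to [0.001, 0.999]);
significance is adjusted P < 0.01, strict. A significant probe is
cluster-2-specific hypermethylated when mean β > 0.5 in cluster 2 and
< 0.2 in cluster 1 (both strict), and symmetrically hypomethylated; the
same rule serves cancer-vs-normal and cluster-vs-cluster contrasts.
DMPs map to genes through promoter annotations (TSS1500, TSS200, 5′UTR,
1stExon). β-matrix consensus clustering reuses the expression machinery
on the probe subset without any log transform.

## 8. Evaluation (`mc5.evaluate`)

AUC uses the tie-corrected rank (Mann–Whitney) statistic, which equals
the trapezoidal area under the threshold-sweep ROC curve. Agreement
between two labelings is n minus the maximum agreement over all label
bijections (exhaustive permutation over ≤ 6 labels), making the
"reclassified" count invariant to renaming. Mutation comparisons report
per-gene and pooled (≥ 1 mutated set gene) rates per group with Fisher
exact P.

`run_pipeline` chains cluster → relabel → DEG → score → cutpoint/log-rank
→ enrichment → DMP → evaluation on one cohort, annotates any failure
with the stage name, and optionally writes all tabular artifacts plus a
manifest.

## 9. Synthetic cohort generator (`mc5.synthetic`)

The generator is the package's study system, not a test helper; its
defaults define the standard planted cohort (n = 200, seed-driven,
~2 s end to end):

* **Expression** — genes are Gaussian on the log2 scale (residual sd
  `noise_sd = 1`) and exponentiated to TPM. The 21 regulator genes are
  shifted between subtypes by `regulator_effect = 2` residual sd,
  applied symmetrically (±Δ/2 per subtype) with alternating sign across
  genes: a uniform same-direction shift would be invisible to the
  rank-correlation distance, and two-sided shifts keep both subtypes
  equally compact. Three 20-gene marker blocks (luminal-like up in
  subtype 1; basal-like and immune up in subtype 2) with log2 effect 2
  drive the enrichment and DEG stages, over 200 background genes.
* **Survival** — exponential event times with baseline hazard 1/1000
  per day and log hazard ratio 0.7 for subtype 2 (subtype 1 better,
  matching the anchoring convention). Censoring is Uniform(0, c_max)
  with c_max solved by Brent's method so the expected censoring fraction
  equals `censoring_rate = 0.3`.
* **Methylation** — Beta-distributed probes (concentration 50) with
  means 0.1/0.6 for the low/high states; 20 of 300 probes are
  cluster-specific, 95% of them hypermethylated in subtype 2, annotated
  to promoter regions of dedicated DMG genes; background probes are
  "Body".
* **Mutations** — Bernoulli per gene and subtype; defaults plant
  TP53-like (0.40 vs 0.55) and chemotherapy-response genes (RB1, ATM,
  ERBB2, ERCC2, FANCC; ~0.07–0.12 vs up to 0.27) enriched in subtype 2,
  echoing the magnitudes reported for the real cohorts, plus 10
  background genes at rate 0.05.
* **Purity** — Normal(0.75, 0.1) clipped to (0, 1]; `purity_slope`
  (default 0) adds a linear purity term to every gene for confounding
  experiments.

`truth_report` tabulates planted-versus-realized quantities so tests can
assert calibration within binomial bands.

## 10. Numerical choices

* All randomness uses `numpy.random.default_rng` seeded explicitly;
  consensus reps draw from `SeedSequence.spawn` children so rep order is
  reproducible and independent.
* PAM SWAP is fully vectorized (candidate costs via per-medoid removal
  distances), keeping 1000 reps at n = 200 in ~10 s.
* Cox cumulative risk-set sums are computed once per Newton iteration in
  O(n p²); linear predictors are clipped at ±500 before exponentiation.
* BH adjustment uses a reverse cumulative minimum over mergesort-ordered
  p-values (stable for ties).
* The trigamma inverse iterates Newton on the Stirling-based starting
  value; non-positive excess variance of log-s² falls back to d₀ = ∞.

## 11. Limitations

* The synthetic cohort is a deliberately low-dimensional caricature:
  independent Gaussian genes, exponential hazards, probe independence.
  It validates directions, calibration and exact bookkeeping — not the
  published cohort-specific headline numbers (401 DEGs, 135/265 split,
  etc.), which depend on unavailable data provenance.
* Three reader-gene slots in the catalog are placeholders pending a
  definitive public list.
* TIS coefficients must be supplied by the user; the package only
  enforces the 18-gene structure.
* The maximally selected cutpoint P-value is uncorrected by design;
  users should treat it as a selection statistic, not an inference.
* Proportional hazards and β-value homoscedasticity are assumed, not
  checked; M-value testing is available where variance stabilization
  matters.
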