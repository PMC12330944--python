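# Methods

This note documents the models and procedures implemented in `prostaxis`,
the defaults chosen where the design was genuinely open, the numerical
conventions, and what the synthetic study conditions do and do not emulate.

## Synthetic study conditions

`synthetic_cohort.SimConfig` defines the generative model. Expression for
gene $g$, sample $s$ in cohort $b$ is, in $\log_2$ space,

$$x_{gs} = \mu_g + \textstyle\sum_k L_{gk} a_{ks} + \gamma_{gb} + \delta_{gb}\,\varepsilon_{gs},$$

exponentiated and column-renormalized to $10^6$ (TPM). Components:

- **Baselines** $\mu_g \sim \mathcal N(4, 2^2)$ in $\log_2$ space — an
  arbitrary but fixed choice giving a realistic dynamic range.
- **Programs.** Five latent programs (luminal/AR, proliferation,
  mTOR/glycolysis, NEPC, immune/EMT) with activities
  $a_s \sim \mathcal N(0, \Sigma)$, $\Sigma$ a correlation matrix with
  modest structure (proliferation–NEPC $+0.3$, luminal anti-correlated with
  the adverse programs at $-0.2$ to $-0.3$); loadings $L$ are
  block-diagonal, 50 genes per program at magnitude 1.0, i.i.d. noise sd
  0.5. Program activities get additive shifts by biopsy site (primary
  biopsies more luminal, liver lesions more adverse) and histology (NEPC
  histology, 10% of samples: $+2$ on the NEPC program, $-1$ on luminal).
- **Cohorts.** Default sizes are the five aggregated cohorts' published
  counts (254, 49, 328, 240, 141; total 1012). Batch effects are the
  standard location/scale model in log space:
  $\gamma_{gb} \sim \mathcal N(0, 0.5^2)$,
  $\delta_{gb} \sim \mathrm U(0.8, 1.25)$ multiplying the noise.
- **Survival.** One record per patient from a Weibull proportional-hazards
  model with cohort-specific scale (24–36 months), shape 1.2, log-hazard
  $\beta^\top a$ over the four prognostic programs with default
  $\beta = (-0.5, 0.5, 0.4, 0.3)$ (luminal protective), administratively
  censored at 60 months. A non-positive censoring horizon, or a draw with
  zero events, raises a validation error rather than proceeding.
- **Paired samples.** For `n_pairs` (default 52) patients an on-treatment
  sample adds `treatment_shift` (default $(-1.0, -0.6, -0.6, 0, 0)$:
  luminal, proliferation and mTOR suppressed, NEPC untouched) plus
  between-biopsy noise (sd 0.5) to the program activities; without that
  biological variability a zero-shift configuration would produce
  identically zero paired differences and no null distribution.
- **Response.** PSA50-style response for `n_response` (default 142)
  patients is Bernoulli with
  $\mathrm{logit}\,P = 1.0 - 0.7 \cdot \mathrm{count}$, where count is the
  true adverse-feature count of the patient's activities.
- **Single cells.** Gamma–Poisson (negative-binomial) counts around a
  population profile derived from the same gene model; an optional HBB row
  holds a configurable fraction of each cell's counts, emulating
  hemoglobin-contaminated circulating-tumor-cell libraries.

Distinct sub-streams of the seed drive metadata, activities, batch
effects, noise, survival, pairing and response, so each generator is
reproducible independently of the others. What the generator does **not**
emulate: read-level noise (no FASTQ), gene-length and GC effects,
library-format differences between cohorts, copy-number or mutation
signal in expression, overlapping patients across cohorts, and informative
censoring. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artifact of real multi-cohort data.

## Harmonization

`rank_transform` replaces each sample's values by within-sample ranks
(average ranks at ties), making samples invariant to any strictly monotone
per-sample transform. `combat_adjust` is the parametric empirical-Bayes
location/scale adjustment: per gene, standardize by the sample-size
weighted grand mean and pooled residual variance (denominator $N$);
estimate per-batch location $\hat\gamma_{gb}$ (mean) and scale
$\hat\delta^2_{gb}$ (variance, $N-1$); estimate batch-level hyperpriors by
moments (normal prior on $\gamma$, inverse-gamma on $\delta^2$); iterate
the coupled posterior-mean updates to relative tolerance $10^{-4}$ (max
100 iterations); remove $\gamma^*$, divide by $\delta^*$, and
back-transform. Conventions:

- No biological covariates are preserved during adjustment.
- Ranks are treated as continuous inputs and are not re-ranked afterward;
  downstream enrichment runs on the adjusted ranks.
- Genes with zero variance within a batch have $\delta^2$ floored at
  $10^{-8}$ and are flagged on the returned model; if the scale estimates
  are identical across all genes (moment estimators undefined) scale
  shrinkage is skipped for that batch.
- A single batch passes through unchanged with a warning; a batch with one
  sample is an error naming the batch.

The implementation is cross-checked in the test suite against the
Bioconductor `sva::ComBat` reference on a fixture (agreement ~$10^{-6}$).
One caveat worth knowing: because the adjustment equalizes per-gene batch
means exactly on the full dataset, a cross-validated batch classifier on
adjusted data typically performs *below* chance (training-fold and
held-out-fold deviations are anti-correlated); accuracy near or below 0.5
is the expected signature of successful removal, not an artifact.

## Sample-level enrichment

`gsva_scores` follows the GSVA construction. Per gene, an across-sample
statistic: the empirical CDF (`kcdf_mode="empirical"`, the default —
appropriate for harmonized ranks, which already share a scale) or a
Gaussian-kernel CDF with bandwidth $s_g/4$ (`"gaussian_kernel"`, for raw
TPM such as single-cell profiles). Per sample, genes are ordered by
decreasing statistic; gene order is canonicalized lexicographically first,
so ties break identically regardless of input order. The walk accumulates
$|p/2 - r|^{\tau}$ (position $r$, $\tau = 1$ by default) inside the set,
normalized by the in-set total, against $1/(p-m)$ outside. The score is
the sum of the maximum positive and maximum negative deviations
(`diff_of_extremes`, default) or the signed largest-magnitude deviation
(`max_deviation`); both live in $[-1, 1]$. Sets are intersected with the
expression universe and must keep at least `min_set_size = 5` members
(named error otherwise); a set equal to the whole universe is rejected as
a degenerate walk. The exact parameterization is exposed because published
analyses rarely state it.

`preranked_gsea` scores externally ranked lists (e.g. genes by hazard
ratio) with the classic weighted-KS extremum statistic, a gene-label
permutation null, NES normalization by same-sign null magnitude, and
leading-edge extraction at the extremum.

`immune_marker_score` sums $\log_2(x + 1)$ over CD45, CD14, CD16, CD11b,
CD27 and CD3 (pseudocount 1; protein names resolve through a configurable
alias table, e.g. CD45→PTPRC, CD16→FCGR3A, CD3→CD3E/D/G).
`remove_gene_then_tpm` drops a contaminant (HBB) before TPM normalization.
`rescale_percent` min–max rescales each pathway to 0–100 over a reference
sample set, clamping values outside the reference range.

## Axes and composites

Pathways are correlated across samples (Pearson), clustered
agglomeratively on distance $1-r$ — average linkage by default
(configurable to complete/ward; the linkage used in published correlation
heatmaps is rarely stated), cut at exactly $k$ clusters ($k = 5$ by
default; the five-cluster structure is an empirical finding, so $k$ is a
parameter rather than a rule). Pathways are sorted lexicographically
before linkage and cluster ids relabeled by first member, making the
result invariant to input order. A composite axis is the unweighted mean
of a cluster's univariately prognostic members (BH-adjusted $p < 0.05$);
members enter unstandardized since enrichment scores share the $[-1,1]$
scale (a z-score option exists, off by default). Clusters with no
prognostic member yield no composite.

## Survival machinery

`cox_fit` maximizes the stratified Cox partial likelihood by
Newton–Raphson with step-halving (tolerance $10^{-8}$, max 50 iterations),
Efron tie handling by default (Breslow available; they coincide on
tie-free data). Strata without events are dropped with a warning; monotone
likelihoods (diverging coefficients) and singular information matrices
raise convergence errors; a design condition number above $10^8$ raises a
collinearity error naming near-duplicate terms. Wald statistics use the
inverse observed information. The fit is cross-checked against lifelines
and against a brute-force grid maximizer of the written-out partial
likelihood in the test suite.

The univariate screen fits one model per pathway (continuous score +
biopsy-site indicators with the most frequent site as reference, cohort
strata), BH-adjusts across the whole family, and labels direction by the
hazard-ratio sign. Per-pathway failures are recorded, not fatal. The
analysis subset takes, per patient, the earliest pre-treatment biopsy;
patients with only post-treatment samples are excluded with a logged
reason.

`wilcoxon_signed_rank` drops zero differences, computes the exact
two-sided p by enumerating all $2^n$ sign assignments of the tie-averaged
ranks for $n \le 12$, and uses the continuity-corrected normal
approximation above that. `cochran_armitage_trend` uses the adverse counts
themselves as ordinal weights (group-level weights can be passed
explicitly) with a standard-normal two-sided p and an optional permutation
p. `km_logrank` wraps the product-limit estimator and the $k$-group
log-rank test.

`adverse_feature_score` computes per-axis tertile thresholds as the
empirical 1/3 and 2/3 quantiles (linear interpolation) on a declared
reference population — by default the survival-analysis subset itself,
since the score stratifies that population; the full sample set can be
passed instead. Flags are boundary-inclusive toward the flagged side
(Luminal_AR $\le q_{33}$; each adverse axis $\ge q_{67}$), the count is
the number of flags, and groups are 0 / 1–2 / 3–4. On a continuous
reference of size $3m$ each tertile contains exactly $m$ patients.

## Genomic annotation rules

Variant retention keeps germline-subtracted records with
`FILTER == PASS`, DP ≥ 10, VD ≥ 3, AF ≥ 0.02 (all inclusive) that are
nonsynonymous and coding; drops are logged with the first failed
criterion, and the filter is idempotent and order-preserving. Copy-number
log-ratios map to deep deletion / deletion / copy-neutral / gain /
amplification at cutpoints $-1.1, -0.4, 0.3, 1.1$; a value exactly on a
shared boundary goes to the less extreme category (the printed wording
"below $-1.1$" / "above $1.1$" leaves interior endpoints open, so the
conservative reading was chosen). Samples need tumor content ≥ 15%.

## Validation checks and problem sizes

`prostaxis.validation` regenerates data and measures recovery end to end;
the sizes below were chosen to make each check statistically informative
while remaining desk-scale, and are used by both the test suite and
`scripts/acceptance.py`:

- **Cluster recovery**: 5 × 60 samples per seed, 4 signatures per program,
  20 seeds; adjusted Rand index of the 5-cluster cut against program truth.
- **Coefficient recovery**: orthogonal programs, hazard $\beta=(0,0,0,1)$,
  500 patients, 100 seeds; success means every axis within $\pm 0.15$ of
  its generative value in the joint model.
- **Null calibration**: 50 independent null pathways per repetition, 200
  patients per repetition (large enough that the Wald normal approximation
  holds, so the check measures the screen's calibration rather than
  small-sample asymptotics), 200 repetitions; BH-adjusted significance
  share and a KS test of raw-p uniformity. Two caveats apply to reading
  the KS p-value: it is itself a random draw, and the pooled p-values are
  not fully independent (the 50 pathways of a repetition share one
  survival draw) while Cox p-values are asymptotic — at 200 patients per
  repetition a small systematic excess below the nominal level (roughly
  5.4% of raw p below 0.05 rather than 5.0%, identical for Wald and
  likelihood-ratio variants) remains visible in large pooled samples.
  The BH-adjusted significance share, which is what the screen acts on,
  stays far below 5% throughout.
- **Harmonization efficacy**: two balanced cohorts of 100, identical
  latent draws with and without batch effects; 5-fold CV logistic
  batch-classification accuracy and the ratio of program-recovery
  correlations.
- **Adverse-group ordering**: default effect-linked conditions, 300
  patients, 50 seeds; strict decrease of Kaplan–Meier median survival
  across groups 0 / 1–2 / 3–4, where a median beyond the censoring
  horizon counts as larger than any reached median.

## Known limitations

- The harmonization removes per-gene location/scale batch structure only;
  rank-level distributional differences beyond that (e.g. cohort-specific
  zero inflation) are out of model.
- The Cox machinery offers no proportional-hazards diagnostics,
  time-varying covariates or competing risks.
- Nonparametric and reference-batch ComBat variants, and
  covariate-preserving adjustment, are not implemented.
- Gene-identifier handling is exact string matching plus a small alias
  table; no ontology-backed resolution.
- The permutation null of `preranked_gsea` permutes gene labels, not
  phenotypes; inter-gene correlation is therefore not reflected in its p.
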