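# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `longmeth`, in the order the
pipeline runs them.

## Probe-level filtering and value scale

All statistics operate on M-values (logit2 of the methylation fraction);
beta values are used only for the variability filter.  `beta_to_m` clamps
inputs outside (0, 1) to [1e-6, 1 − 1e-6] with a warning rather than
erroring, because boundary betas arise from rounding in upstream
normalization.  A probe enters analysis iff it is autosomal, not within 2 bp
of a known SNP, and its beta range is ≥ 3% on at least one of the two array
platforms — removal requires near-invariance on *both* platforms, matching
the convention for merged 450K/EPIC designs.

## The two mixed models

Both differential-methylation models share fixed effects for group
(reference level: maintainer), visit (reference: pre), age (years), sex,
platform, and six blood-cell proportions, plus a subject-level random
intercept.  Because the proportions sum to one they are collinear with the
intercept; the design is reduced to full rank by dropping trailing cell-type
columns (granulocytes first), which changes no testable quantity.  The
group-effect model adds two genetic-ancestry PCs and drops subjects missing
them (complete case, per probe and per model; no imputation).  The
interaction model is not ancestry-adjusted: it tests within-subject change,
which time-invariant confounders cannot distort.

**Fitting.**  With exactly two observations per subject, the
random-intercept ML is the compound-symmetry GLS with within-pair
correlation ρ = σ_u²/(σ_u² + σ_e²) ≥ 0.  The per-subject (sum, difference)/√2
transform de-correlates the data given ρ, so the profiled −2 log-likelihood,

    N log(RSS(ρ)/N) + n log(1 − ρ²) + const,

is one-dimensional and is minimized on a fixed grid (step 0.005 on
[0, 0.995], step 0.01 on [−0.5, 0)); for each grid point the whitened
regression is solved once by QR for *all* probes sharing the design, making
the fit vectorized across an array.  Allowing mildly negative ρ is the
compound-symmetry fallback for probes whose random-intercept variance would
pin at zero; such probes are flagged `cs_gls` rather than silently refit.
The grid resolution bounds the likelihood error at ~1e-4, which is
negligible against the 2-df test statistics; agreement with
`statsmodels.MixedLM` (ML) is verified in the test suite to 5e-3 in
log-likelihood and coefficients.

**The 2-df test.**  The group×visit interaction (or group main effect) is
tested with a Wald F-statistic on its two coefficients,
F = (Cβ̂)'[C(X'V⁻¹X)⁻¹C']⁻¹(Cβ̂) / (2σ̂²), referred to F(2, df₂) with a
containment denominator df: the subject count minus the rank of the
difference-transformed half-design for the (within-subject) interaction
test, or of the sum-transformed half-design for the (between-subject) group
test.  An ML likelihood-ratio test against χ²₂ was evaluated first and
showed the expected small-sample inflation (empirical size 5.7–6.2% at
α = 0.05 with 143 subjects); the F form is calibrated (4.4–6.0% across null
simulations) and matches the F-test framing of the overall group comparison.
Zero-variance probes are flagged and excluded from FDR; reported per-group
slopes are the model-implied post−pre changes (β_visit plus the group's
interaction coefficient), with standard errors from the GLS covariance using
σ̂² = RSS/(N − p).

## Region calling

The spatial combination follows the comb-p recipe with all pieces
implemented here:

* **ACF**: p-values are z-transformed via z = Φ⁻¹(1 − p) and the Pearson
  correlation of z over same-chromosome probe pairs is computed in distance
  bins (0, 50], (50, 100], …, (450, 500].  Bins with fewer than 10 pairs
  inherit the previous bin's value (0 for an under-filled first bin);
  constant-z bins get 0 with a warning.  The 50-bp step realizes the
  procedure's "step size" as the ACF bin width — the only referent the
  parameter has in this formulation.  Negative estimated correlations are
  clipped to 0 before use, and pair distances beyond the last bin reuse the
  last bin's value, keeping the combination variance valid.
* **Smoothing and peaks**: each probe is combined with its ±500 bp
  neighbourhood (isolated probes keep their raw p exactly); maximal runs of
  smoothed p < 0.1 with inter-probe gaps ≤ 500 bp become candidates.
* **Region p**: a single Stouffer–Liptak combination of the candidate's
  *raw* p-values — the smoothed values already average over neighbours, and
  combining them again would double-count evidence.  Extreme p-values are
  clamped to [1e-16, 1 − 1e-16] before the normal quantile.
* **Šidák**: p_sidak = 1 − (1 − p)^(coverage/width), computed with
  `expm1`/`log1p` for small-p accuracy, where coverage is the spanned extent
  (max − min position) of analysed probes summed over chromosomes.  Probe
  span matches the "genomic coverage" notion of the correction; a
  probe-count × step alternative could be configured by passing a different
  total to `sidak_adjust`.

Coordinates: manifests use 1-based point positions (array-manifest
convention); regions are carried and written 0-based half-open (BED), with
all conversion arithmetic in `longmeth.coords` and round-trip tested.
Leading probes are the smallest raw p, ties broken by lowest position.

## Retention rules

ΔDMRs are retained with ≥ 4 probes, Šidák p < 0.10, and at least one group
whose per-probe visit slopes are 100% sign-consistent; μDMRs analogously
with at least one unanimous pairwise contrast (P−R, R−M, P−M — orientation
affects median signs only).  Consistency is the share of probes carrying the
majority sign; a slope of exactly zero counts with the majority
(configurable), and a 50/50 split scores 0.5.  These summaries are invariant
to probe order and monotone: lowering Šidák p or raising a unanimous group's
consistency never un-retains a region.

## Region QTM

Per-CpG M-values are residualized on the model covariates by the same
two-visit mixed fitter; only the fitted *fixed* part is subtracted so
within-subject change survives.  Subject-level contrasts are post−pre deltas
for ΔDMR candidates and (post+pre)/2 means for μDMR candidates (μ-candidate
scores are additionally ancestry-adjusted and complete-case).  The region
score is the first principal component of the standardized subject×CpG
matrix, oriented to correlate positively with the across-CpG row mean so an
increasing score always means increasing methylation; flipping the
orientation flips every downstream statistic's sign and changes no p-value.
Zero-variance CpGs are dropped with a warning.

eQTM: Spearman correlation (t approximation with midranks; an exact
permutation p is available behind a flag for n ≤ 10) between the region
score and age/sex-residualized expression, for genes whose TSS lies within
±500 kb of the region midpoint; minus-strand genes take TSS = gene end.
FDR is applied across all region×cis-gene pairs of a candidate family (Δ
and μ separately).  metQTM: metabolites are Box-Cox transformed (λ by ML on
the fixed grid −2…2, step 0.1; nonpositive values shifted by 1 − min with a
warning), age/sex-residualized per visit, contrasted per subject (delta for
Δ candidates, mean for μ candidates; cross-combinations are not computed),
and regressed on the region score after z-scoring both sides, so the slope
is a 1-SD-per-1-SD standardized beta (numerically the Pearson r).  FDR is
stratified by panel.

## The synthetic cohort

The generator emulates the study conditions the pipeline is designed for:

* three groups of 60 (maintainer), 42 (progressor), 41 (reverter) subjects,
  two visits each (286 rows);
* lognormal ages with group×visit medians ordered progressor < reverter ≈
  maintainer (pre ≈ 2.2 / 6.0 / 5.7 years) and visits ~1.5–2.7 years apart;
* sex and platform Bernoulli(0.5) per subject (platform independent of
  phenotype — assignment was randomized in the emulated design), Dirichlet
  blood-cell proportions (concentration 60 × typical blood medians, summing
  to one per sample), standard-normal ancestry PCs with two subjects'
  ancestry nulled by default to exercise the complete-case rule;
* M-values as probe baseline N(0, 1.5) + per-probe covariate effects (age
  N(0, 0.004)/yr, sex and platform N(0, 0.05), cell coefficients N(0, 0.4))
  + per-probe subject random intercepts (SD 0.30) + planted effects +
  within-cluster spatial noise (SD 0.05, correlation exp(−0.01·distance),
  zero across clusters) + iid residual (SD 0.10);
* planted ΔDMR slopes default to (R +0.06, P +0.04, M −0.08) and μDMR
  offsets to (M 0, R +0.37, P +0.46) M-units — the magnitude scale of
  reported blood EWAS regions.  The within-visit noise total (~0.11
  M-units) is the level at which a single planted probe at the design's
  sample size reaches p < 1e-3, consistent with typical array technical
  noise;
* manifests place CpG clusters (intra-cluster spacing < 500 bp) separated
  by > 500 bp gaps with isolated singletons between them, so clusters are
  combinable into regions and singletons are not; a few probes carry
  near-SNP or low-variability flags to exercise the filter;
* linked omics: a linked gene's expression follows its region's
  subject-level contrast (delta signal for Δ regions, pre/post mean for μ
  regions — the same quantity the QTM stage tests, which keeps the target
  correlation well-defined end-to-end) at a target Spearman ρ via the
  bivariate-normal identity r = 2 sin(πρ_s/6); a linked metabolite's
  post−pre change follows the delta signal at a target standardized beta.
  Expression exists only at the post visit; metabolites at both visits,
  positive-valued around 100 so the Box-Cox step is exercised.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: probe-type (I/II) chemistry and
normalization artefacts, batch/plate layout effects, cell-composition
confounding correlated with phenotype, non-Gaussian methylation
distributions, genome-scale probe density, and LD-like long-range
correlation.  Null calibration and recovery results are statements about
the additive Gaussian model above.

**Measurement attenuation.**  A multi-CpG PC1 score is a noisy measurement
of the regional signal; with ~7 CpGs at the default noise levels it
correlates ~0.9 with the signal, and small-sample residualization (e.g. 13
covariate columns on 72 observations at n = 36) costs another ~10%.
Recovered link strengths through the full pipeline therefore centre ~15%
below their planted targets.  The link-recovery experiments in
`longmeth.validate` score regions by their mean CpG delta (a single-column
PC), which isolates link recovery from this attenuation; the attenuation
itself is visible in the pipeline-level tests.

## Validation experiments and problem sizes

`longmeth.validate` fixes the experiment scales used by the test suite and
the reproducibility script: null calibration on ~2,000 probes × 286 samples
(one cohort for the rejection rate, 20 for the BH zero-discovery share);
planted-region recovery over 50 replicates of a 2-chromosome, 20-cluster
manifest; link recovery over 40 replicates at overlap sizes n = 36
(expression) and n = 110 (metabolites).  These sizes keep each experiment
within a couple of minutes on one CPU while leaving the binomial tolerances
of the checks meaningful.

Note that two of the checked quantities sit at their theoretical expectation
by construction: with ~2,000 uniform p-values the probability that BH at
0.10 makes zero discoveries is ≈ 0.90, which is also the checked threshold,
so the per-cohort share fluctuates around it; and the Fisher-z band
(0.25, 0.80) for ρ = 0.55 at n = 36 is itself a ~95–98% interval checked at
a 95% rate.

## Known limitations

* The fitter requires the paired two-visit design; unbalanced longitudinal
  data would need a general mixed-model backend.
* ACF estimation pools all chromosomes; strong per-chromosome heterogeneity
  in spatial correlation is averaged over (as in the procedure emulated).
* The Šidák coverage definition makes region significance depend on the
  analysed probe span; sparse custom manifests change the effective
  multiple-testing burden.
* Batch/plate covariates are not modelled by default; the covariate lists
  in `PipelineConfig` accept extra sample-sheet columns for that purpose.
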