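# Methods

## Regional SC–FC coupling

For each region *i* of an *n*-region parcellation, coupling is the
Spearman rank correlation between the *i*-th row of the structural
connectome (SC) and the *i*-th row of the functional connectome (FC),
over the *n*−1 off-diagonal entries.  Rank correlation is used because
SC weights are non-Gaussian — sparse, non-negative and heavy-tailed —
and because it is invariant under strictly monotone transforms of
either row.  Ties (the abundant zeros of SC rows) receive average
ranks; any other tie rule would break monotone invariance.  The
implementation is "average-rank then Pearson", and every variant is
tested against an independent Spearman oracle to 1e−10.

Variants restrict the partner set: same network ("within"), other
networks ("between"), same hemisphere, or the full set with the
Euclidean distance between region centroids partialled out (all three
vectors rank-transformed, both connectivity rank vectors residualized
on the distance ranks by least squares, residuals correlated).  The
distance covariate is Euclidean between centroids; geodesic distance is
not attempted.  A region whose partner set leaves fewer than 3 entries,
or whose SC row is all-tied, is flagged undefined (NaN) rather than
zeroed, and is excluded listwise downstream — silent zeros would bias
network summaries.  If the residual of a rank vector after distance
removal is numerically null (relative norm < 1e−9), the partial
coupling is likewise flagged undefined instead of correlating
round-off noise.

Multiple FC measurements are averaged entrywise (Pearson values, not
z-transformed) before coupling for all analyses except heritability,
which uses each measurement separately — the repeated measures are what
identify the measurement-error variance.

Node strength is the row sum excluding the diagonal, with absolute
values for FC.

## Agreement statistics

Bland–Altman bias d̄ = Σdᵢ/n and 95% limits of agreement d̄ ± 1.96·S_d,
with S_d the sample SD (n−1 denominator) of the paired differences.
Differences are second argument minus first (retest − test,
replication − original); the direction is configurable.  Agreement is
computed on region-wise group-mean vectors (one point per region).
A Pearson correlation with one-sided permutation p accompanies it.

## Regional GLM

Per region, Fisher r-to-z-transformed coupling is regressed by OLS
(Gaussian GLM, identity link) on an intercept plus ten covariates: age,
sex (female = 0, male = 1), education years, total cognition score,
intracranial volume, mean framewise displacement, and the four products
age×cognition, sex×cognition, education×cognition, ICV×motion.  Main
effects are not centered before forming products (a centering flag is
available).  Coefficient tests are two-sided t with n−11 degrees of
freedom.  Benjamini–Hochberg FDR at α = 0.05 is applied across regions
separately per covariate, matching how per-covariate significance maps
are read; pooling across covariates would change the multiplicity
structure.  Handedness is deliberately absent from this design (it is a
heritability covariate only).  Regions with undefined coupling use
listwise deletion with adjusted degrees of freedom.  Internally the
regions are solved in batched closed form (grouped by missingness
pattern); statsmodels OLS serves as the independent oracle in the test
suite.

## Variance-components heritability

Phenotype y_ij of subject *i* at repeated measurement *j*:

    y_ij = x_ij′β + g_i + c_i + e_i + ε_ij

with g ~ N(0, σ²_A K), c ~ N(0, σ²_C Λ), e ~ N(0, σ²_E I_subj),
ε ~ N(0, σ²_M I_total).  K is the pedigree kinship kernel (1 for MZ
co-twins, ½ for DZ co-twins and full siblings, 0 across families; 1 on
the diagonal — the diagonal is required for a valid covariance even
though only off-diagonal entries define relatedness), Λ the
shared-parents indicator with unit diagonal.  Stacking with the
measurement-to-subject incidence T (n_total × n_subj):

    cov[y] = σ²_A T K Tᵀ + σ²_C T Λ Tᵀ + σ²_E T Tᵀ + σ²_M I.

Note the subject-level effects g, c, e enter at subject dimension and
are expanded by T; only the measurement error is at measurement
dimension.  This is the only dimensionally consistent assembly of the
four components.

Estimation is ReML: β is profiled out by generalized least squares and
the restricted log-likelihood
−½(log|V| + log|XᵀV⁻¹X| + yᵀPy) is maximized over the non-negative
variances.  Numerical scheme:

* Variances are optimized as log σ² with L-BFGS-B in bounds
  [log v − 22, log v + 5] (v the sample variance of y), from three
  starts — equal split, measurement-dominant, genetic-dominant —
  followed by a Nelder–Mead polish (function tolerance 1e−10).
  A variance at the lower bound (< 1e−6·v) is reported as a boundary
  zero with a flag; boundary solutions are genuinely common in ACE
  fits.  Estimates are therefore non-negative by construction and
  h² = σ²_A/(σ²_A+σ²_C+σ²_E) ∈ [0,1] whenever defined.
* The covariance is block-diagonal over families; families with an
  identical (relationship pattern, measurement counts) block share one
  Cholesky factorization and are solved in a single batched call.  A
  941-subject, 4-measurement fit takes on the order of a second on one
  CPU, and the block likelihood is verified against a dense
  implementation exactly.
* Identifiability: with one measurement per subject σ²_M is not
  separable from σ²_E and is dropped with a warning (flag
  `measurement_error_dropped`); an all-singleton pedigree leaves only
  σ²_A+σ²_C+σ²_E identified (flag `ace_inseparable`); a pedigree whose
  positive kinship entries take a single value (e.g. only MZ pairs)
  cannot separate A from C (flag `a_c_inseparable`).
* A constant phenotype is flagged degenerate with all variances zero
  and h² undefined (never silently 0).

For regional runs, each region's phenotype is z-scored across all
stacked measurements (configurable).  Fixed effects are age, sex and
handedness; the coupling model additionally includes the region's SC
and FC node strengths, with a single-measurement covariate (SC
strength) broadcast across the phenotype's repeated measurements.
Whether to standardize covariates is left to the caller; they enter as
provided.  No standard errors on h² are produced by default — regional
distributions (median/IQR) are the intended summary.

Known finite-sample behavior: at the default composition (116 MZ and
61 DZ pairs) the bounded A/C/E split tilts slightly toward A, so the
mean recovered h² at a true value of 0.40 is ≈ 0.44 with a per-fit SD
of ≈ 0.11; the total inter-subject variance is recovered accurately.
This is the estimator's honest behavior at this design size, not an
implementation artifact (the optimizer verifiably reaches the ReML
optimum).

## Network statistics

Regional maps are summarized per network by median and quartiles
(midpoint interpolation — the quantile convention is pinned by tests)
plus mean/SD.  Pairwise network contrasts use the pooled-variance
unpaired t (row network minus column network; the matrix is exactly
antisymmetric); Welch's t is available behind a flag.  One-sided
p-values come from shuffling region-to-network labels:
p = (1 + #{null t ≥ observed t}) / (1 + n_perm), which is never zero
and uniform under the null; BH-FDR is applied across the off-diagonal
contrasts.  Defaults: 1000 permutations for map-level t tests, 10000
for correlations.  Label permutation ignores spatial autocorrelation
and is anti-conservative on smooth real brain maps; the `surrogates`
argument accepts externally generated spatially matched null maps
(e.g. variogram-matched surrogates) and uses them as the null
distribution instead.

## Synthetic data

The generators emulate the study design so the pipeline is testable
end to end:

* **Pedigree** — default 116 MZ pairs, 61 DZ pairs, 455 full siblings,
  132 singletons (941 subjects).  Siblings are placed in sibships of
  2–4 drawn uniformly; the resulting family count (~460) is not forced
  to any particular total since the sibship-size distribution of the
  real cohort is unknown.
* **Covariates** — age truncated-normal 28.67 ± 3.70 on [22, 37],
  sex Bernoulli at 441/941 male, education ~N(14.9, 1.8²) years on
  [11, 17], cognition ~N(122, 10²), ICV ~N(1.55, 0.15²)×10⁶ mm³,
  motion log-normal around 0.13 mm, handedness a right-dominant
  mixture.  All covariates are drawn independently of family and of
  each other — real within-family and cross-covariate correlations
  (e.g. ICV–sex) are not emulated, so covariate-adjustment behavior on
  real data is not fully exercised by these tests.
* **ACE phenotypes** — sampled exactly from the model: per family,
  γ = g+c+e is drawn from N(0, σ²_A K_f + σ²_C Λ_f + σ²_E I) via an
  eigendecomposition (valid also for singular blocks, e.g. MZ pairs
  with σ²_E = 0), then i.i.d. measurement error per repeat.  The
  empirical covariance over replicates matches the assembled model
  covariance entrywise, and MZ/DZ intraclass correlations match their
  closed forms (σ²_A+σ²_C)/(σ²_A+σ²_C+σ²_E+σ²_M/m) and
  (σ²_A/2+σ²_C)/(·) — the Falconer-style checks in the test suite.
* **Connectome pairs** — a symmetric latent Gaussian edge score Z
  drives both matrices.  SC = exp(μ + sZ) thresholded to the requested
  density (zero-inflated log-normal, monotone in Z); FC = tanh of an
  affine map of W = rZ + √(1−r²)E.  The latent correlation r is set
  from the exact bivariate-normal relation ρ_S = (6/π)·asin(r/2),
  after correcting the target for the tie attenuation √(1−p0³) caused
  by the zero mass p0 (derived from the grade correlation of a
  tie-collapsed uniform margin).  Realized mean coupling tracks the
  target within ±0.02 at default density 0.35 (a realistic tractography
  sparsity).  A target of ±1 maps to r = ±1 (the noise-free path) and
  is exact when the SC is fully dense.  Per-region target vectors are
  honored approximately (each edge uses the mean of its two endpoint
  targets, which shrinks regional contrast toward the cohort mean);
  a constant target is exact.  `regional_coupling_profile` supplies a
  network-structured target map (sensory/subcortical high, limbic and
  default-mode low) so that simulated cohorts have a stable regional
  coupling topography — without it, group-mean maps would be spatially
  flat and agreement statistics would have nothing to measure.
  Repeated FC measurements share Z and redraw E, producing transient
  scan-to-scan coupling variation.
* What is *not* emulated: BOLD autocorrelation, tractography distance
  bias, hemispheric asymmetries, site/batch effects.  Passing tests
  demonstrate correctness of the estimators under the stated model,
  not robustness to these real-data features.

## Pipeline

`run_pipeline` executes simulate → couple → reliability → GLM →
heritability → network statistics from a single YAML config; every
output table carries a `# config_hash=… seed=…` provenance comment and
reruns are reproducible bit-for-bit given the same config.  The
reliability stage splits the repeated FC measurements into two halves
and compares group-mean coupling maps.  A subgroup filter (pandas query
on the cohort table) reruns heritability on a subject subset; twins
orphaned by the filter are re-coded as full siblings (if relatives
remain) or singletons, which is exactly how the kinship kernel treats
the survivors.  Problem sizes in the bundled example config (50
regions, 200 subjects, 500 permutations) are chosen so an end-to-end
run completes in about a minute on one CPU; all estimators scale to the
full 392-region, 941-subject design, which the acceptance script
exercises.

## Known limitations

* Label permutation as the default spatial null (see above).
* The A/C/E split is weakly identified at realistic twin counts; h²
  estimates carry substantial per-region noise and a small upward
  boundary bias (quantified above), which is why recovery is assessed
  by replicate means and rank correlations rather than single fits.
* Half-siblings, parent–offspring pairs and other relationships outside
  {MZ, DZ, full sibling, singleton} are rejected by design.
* The partial-distance variant assumes Euclidean centroid distance.
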