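# Methods

This note documents the models, decision rules, defaults and numerical
choices implemented in `readnet`, and what the synthetic-data generators do
and do not emulate.

## Phenotype residualization and banding

The comprehension phenotype is the residual of an OLS regression of the
comprehension score on age, performance IQ, two decoding measures
(pseudoword reading accuracy and fluency) and three word-recognition
measures. `residual_sd` is the in-sample SD (ddof = 0) of the residuals, so
z = residual / residual_sd is the distance from the regression line in SD
units. Banding: z ≤ −1 → UPC, z ≥ +1 → UGC, |z| ≤ 0.5 → EAC; the 0.5–1 SD
shell is UNCLASSIFIED. Boundary values are assigned inclusively toward the
extreme groups (z = −1 is UPC, z = 0.5 is EAC); this tie rule is arbitrary
but deterministic and documented. Two alternative bandings support the
sensitivity analysis: "contiguous" absorbs the shell into EAC (EAC =
|z| < 1), and "split" divides it outward at |z| ≥ 0.75. The main-cohort
fit uses age-normed standard scores; an imaging-subset variant on raw
scores is available through the `predictors` argument, since raw and
standard scores are both plausible readings of the intake format.

A fit with (numerically) zero residual SD raises rather than banding on
noise; rank-deficient designs raise an error naming the collinear columns.

## READ1 allele groups and carrier coding

Functional groups are defined by explicit allele-ID lists:
RU1-1 = {2, 3, 8, 12, 25, 27}, RU2Long = {5, 6, 13, 14, 19, 20, 22, 23},
RU2Short = {4, 10, 15, 16, 17, 21, 24, 26, 30, 37, 39}. The lists are the
operational definition; a copy-number rule engine (RU1 copies = 1 → RU1-1;
RU2 copies ≥ 8 → RU2Long; ≤ 6 → RU2Short) is provided for alleles outside
them and is flagged as an extrapolation. A subject carries a group if at
least one allele belongs to it. The READ1 microdeletion is coded by
treating a hemizygous subject as homozygous for the retained allele;
dual-deletion subjects are excluded from carrier analyses. Unknown allele
IDs map to UNGROUPED with a warning instead of failing, since rare alleles
outside the published lists occur in admixed cohorts.

## Association model

The carrier-by-group contingency table is tested with a Pearson chi-square
without continuity correction (df = 2 for 3 groups × carrier status). The
adjusted model is a maximum-likelihood multinomial logit with UPC as the
reference level, giving one coefficient vector per contrast (EAC-vs-UPC,
UGC-vs-UPC); continuous covariates are standardized by default so odds
ratios are per-SD. Confidence intervals are Wald on the log-odds scale.
Nagelkerke pseudo-R² = (1 − (L0/L1)^(2/n)) / (1 − L0^(2/n)). Separation is
detected from non-finite or diverging coefficients/SEs and reported with a
best guess at the offending predictor (a binary column with an empty cell
against an outcome level).

Missing covariates are imputed by chained equations (statsmodels MICEData,
OLS + predictive-mean-matching for every column, 10 burn-in cycles for the
first imputation and 2 between subsequent ones, seed-controlled), the model
is fit on each of m = 15 completed datasets, and estimates are pooled by
Rubin's rules: W the mean within-imputation variance, B the
between-imputation variance, T = W + (1 + 1/m)B. The fraction of missing
information uses the large-sample form γ = (1 + 1/m)B/T, and relative
efficiency is (1 + γ/m)^(−1); p-values use the Barnard–Rubin t reference
with df = (m − 1)(1 + W/((1 + 1/m)B))². With no missing data the pooled
result reduces exactly to the complete-data fit with RE = 1.

Sensitivity modes re-run the focal carrier model under (i) contiguous
re-banding, (ii) a linear model on the raw residual, and (iii,iv) exclusion
of bilingual or Spanish-home subjects.

## Population structure

SNP QC removes markers with > 5% missingness, Hardy–Weinberg p < 1e−4
(1-df chi-square against p̂², 2p̂q̂, q̂²; monomorphic SNPs are p = 1 by
convention — an exact test would also be defensible, but the chi-square has
a simple closed-form oracle), non-autosomal labels (autosomes are "1".."22"
by string), or MAF < 0.05. Sample QC removes subjects with > 3% missing
genotypes or a reported/inferred sex mismatch, where inferred sex
thresholds X-chromosome heterozygosity at < 0.05 (male) / > 0.15 (female);
subjects in between are flagged ambiguous and retained. The thresholds are
conventional, not estimated. QC is idempotent.

PCA standardizes each SNP by (g − 2p̂)/√(p̂(1−p̂)) after per-SNP mean
imputation of missing dosages, then takes the top-K left singular vectors
scaled by their singular values; K = 10 by default and is reduced with a
warning if it exceeds the rank bound. The genomic inflation factor is the
median association chi-square over 0.4549 (the 1-df null median). The
per-SNP association statistics residualize the trait and all dosages on
the covariates once (QR projection) and compute the partial-slope Wald
chi-square vectorized, which is algebraically identical to fitting each
SNP's OLS model separately.

## Motion QC and nuisance regression

Per-volume movement is the Euclidean norm of the change in the six
rigid-body parameters between consecutive volumes (translations in mm and
rotations in degrees enter on their native scales; the first volume is 0).
The outlier fraction is the share of in-mask voxels deviating more than
k = 3.5 robust SDs (1.4826·MAD) from their run median after linear
detrending — a stand-in for AFNI-style outlier counting, which is not
specified beyond "outlier voxels"; k is configurable. After dropping the
first six volumes of each run, a volume is censored iff movement > 0.3 mm
or outlier fraction > 0.10, both strict inequalities ("exceeds the
threshold"), and a subject is excluded iff retention across both runs
falls below 60%.

The nuisance GLM regresses out, per voxel over retained volumes: intercept,
6 motion parameters, their first differences, a discrete-cosine basis
spanning frequencies below 0.01 Hz, the first three principal components of
the (one-voxel-eroded) ventricle mask, and the mean (eroded) white-matter
signal. Drift is handled by regressors rather than filtering so that
censoring and drift removal commute. Collinear regressors are dropped with
a warning. Erosion that would empty a desk-scale mask falls back to the
un-eroded mask.

## Intrinsic connectivity distribution

For each gray-matter voxel the survival curve S(τ) is the fraction of
*other* gray-matter voxels whose correlation exceeds τ, computed on the
positive tail over the grid τ ∈ {0, 0.01, …, 0.99} (the bin width is a
package choice; the survival representation makes the result insensitive
to histogram binning). Zero-variance voxels are flagged and excluded from
both sides of every comparison. The curve is fit by nonlinear least
squares to S(τ) = exp(−(α·τ)^β), bounds α, β ∈ (0, 100], init (1, 1);
smaller α and larger β both indicate a heavier tail, i.e. a larger degree
at any threshold. The parameterization with α multiplying τ is fixed as
the primary form (consistent with "smaller scale ⇒ higher degree"); the
alternative exp(−(τ/α)^β) is available behind a flag. Non-converged fits
are flagged and left missing.

Parameter maps are smoothed with a 6 mm FWHM Gaussian restricted to the
mask (kernel renormalized at edges so constants are preserved). Group
inference is per-voxel OLS of the (β by default) maps on the comprehension
residual plus covariates — a single dependent parameter makes the
multivariate formulation equivalent to univariate OLS — with the focal
slope's t and two-sided p reported.

Cluster-extent correction estimates per-axis Gaussian FWHM from the model
residual maps by the first-difference estimator (ρ = 1 − var(Δ)/(2·var);
FWHM = Δx·√(2 ln 2 / −ln ρ)), simulates smoothed standardized null fields
in the exact analysis mask, thresholds two-sidedly at the voxel p, labels
clusters with 6-connectivity (faces touching; configurable), and takes the
smallest size s with P(null max cluster ≥ s) ≤ cluster p. Observed
clusters at least that large are reported with peak t and mm coordinates
via the volume affine. The threshold is monotone in the estimated FWHM.

Desk-scale calibration note: the voxelwise threshold must be scaled with
the mask. At p = .001 a few-thousand-voxel mask yields ~1–3 expected
suprathreshold voxels, the null max-cluster distribution degenerates to
{0, 1, 2}, and the attainable familywise alpha jumps far below .05, making
the correction look (and be) very conservative. The calibration suite
therefore uses p = .01 on a 3,072-voxel mask — matching the expected
suprathreshold count of p = .001 on a production-size (~50k voxel)
gray-matter mask — and measures a familywise error rate of 0.04 against
the nominal .05 over 200 null datasets at 1,000 iterations each.

Influence diagnostics for the focal regression report per-subject Cook's
distance and the focal-slope DFBETA, flag points at the conventional
cutoffs 4/n and 2/√n (the originally applied cutoffs are not recorded;
these are the standard defaults), refit without flagged points, and refit
restricting the phenotype to |residual| ≤ 20.

## Seed network

Seed connectivity maps are Pearson correlations of each voxel with the
mean seed time course on the unsmoothed residual data (computing the seed
course pre-smoothing is a package choice), Fisher-z transformed with |r|
clipped to 1 − 1e−7. The group network is a one-sample t-test across
subjects, masked at a configurable p on the positive side; the
production-scale default threshold (p < 1e−20) presumes very large t
statistics from n ≈ 60 real subjects and is relaxed in desk-scale runs.
Peaks are local maxima greedily thinned to a 30 mm (10-voxel) minimum
separation, larger values winning. Sphere ROIs include voxels whose
centers lie within 6 mm of the peak voxel center — 33 voxels on a 3 mm
grid; the continuous volume ratio is 33.5 voxel volumes, which is a
geometric identity, not a discrete count. Node values are arithmetic means
of z over the sphere.

Backward selection starts from the full covariate model (age, PIQ, sex,
maternal education, SES, 3 ancestry PCs), repeatedly removes the largest-p
covariate above α = .05 (refitting after each single removal; ties broken
by predictor order) and stops when all retained covariates meet the
criterion. The final per-node model is OLS of node connectivity on the
carrier indicator (always included) plus the retained covariates; retained
sets are reported per node rather than fixed.

## Synthetic data

The cohort generator draws group labels first (probabilities proportional
to the 216 / 530 / 223 classified group sizes of a 1,432-subject cohort,
remainder unclassified), then the residual z from a unit normal truncated
to the group's band, then RU2Short carrier status per group at frequencies
0.47 / 0.37 / 0.32 (0.37 for the unclassified shell). Covariates use the
published group summaries: age (143.8/131.2/148.2 months), male fraction
(.516/.55/.551), maternal education (13.3/13.2/14.4 years), low-SES
(.599/.535/.338), receptive vocabulary (87.2/93.0/105.0). Reading measures
share a latent decoding factor (loading 0.7) so the residualization design
has realistic collinearity. The comprehension score is constructed as a
linear function of the predictors plus z·residual_sd (default 2.9), so the
fitted residual model recovers the planted banding. Spanish-home (0.30)
and bilingual (0.35) rates are not published for this design and were
chosen once as plausible for a majority-Hispanic/African-American sample.
Carrier alleles are drawn from the RU2Short pool (4 and 10 most frequent),
non-carrier alleles from the RU1-1/RU2Long pools; a hemizygous deletion
(3%) replaces only the non-defining allele so planted carrier frequencies
survive the substitution coding, dual deletions occur at 0.2%, and calls
are missing at 1.3%. Missingness elsewhere is MCAR at 1.5% on the
vocabulary, maternal-education, SES and language columns (no mechanism
beyond "distributed across all datapoints" is recorded, so MCAR is the
minimal choice). Distributional forms are normal/binomial approximations
of the published summary statistics; the generator does not model
measurement floors/ceilings, site effects, or genotype-covariate
correlation beyond the group structure, so passing tests demonstrate
statistical correctness of the machinery, not robustness to those real-data
features.

The SNP generator is a two-population Balding–Nichols model: ancestral
frequencies uniform on (0.1, 0.9), population frequencies Beta with mean p
and variance Fst·p(1−p) (default Fst = 0.1), genotypes Binomial(2, p).
Optional X SNPs model male hemizygosity (dosage 0/2) to exercise the sex
check.

The BOLD generator builds band-limited latent node signals (white noise
low-passed below 0.1 Hz at TR = 1.55 s), orthonormalizes them and mixes by
a symmetric square root of the target correlation matrix, so each run
realizes the node correlation structure exactly at the latent level; the
designated seed-R_SMG entry is raised by +0.2 for carriers. Default
acquisition geometry: 3 mm isotropic grid, two 240-volume runs. Node
voxels (hard spheres, uniform weight) carry their node's signal; gray
background voxels carry independent band-limited noise; all brain voxels
add white noise and a shared slow drift; white matter adds its own drift
and the ventricle mixes three drift components, giving the nuisance
regression real structure to remove. Motion traces are small random walks
with isolated spikes of 0.35–1.0 mm at the configured rate. There is no
hemodynamic model, anatomy, or scanner artifact simulation. The default
simulated brain is an ellipsoid with central ventricle and deep
white-matter ball; planted node spheres are carved into the gray mask so
the analysis mask always contains the network.

## Problem sizes used in the test and acceptance suites

Law-of-large-number checks use n = 10,000 cohorts; OR recovery uses
n = 5,000; the carrier-connectivity detection runs 10 replicates of 60
subjects on a 12×14×12 grid with two 234-volume runs; cluster-correction
calibration uses 200 null datasets × 1,000 Monte-Carlo iterations; MICE
pooling uses the full m = 15 on n = 1,000. These sizes were chosen so each
statistical claim is measurably testable on a single CPU while remaining in
the asymptotic regime the claim concerns.

## Known limitations

- The imputation engine relies on statsmodels' MICEData, which draws from
  the numpy global RNG; `impute_and_pool` seeds it explicitly, so results
  are reproducible but the global RNG state is perturbed.
- ICD fitting is a per-voxel `curve_fit` loop; for production-size masks a
  vectorized or parallel fit would be needed.
- The cluster simulation uses a Gaussian autocorrelation model; long-tailed
  (non-Gaussian ACF) spatial correlation, which motivates mixed-ACF
  corrections in modern fMRI practice, is out of scope.
- Sphere ROIs snap peaks to voxel centers; sub-voxel peak interpolation is
  not attempted.
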