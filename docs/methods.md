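# Methods

This note records the models behind each stage of the pipeline, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerical decisions a maintainer would otherwise have
to reverse-engineer.

## Synthetic panels

**Allele frequencies.** Populations follow a two-level Balding–Nichols
hierarchy. Ancestral frequencies are Uniform(0.05, 0.95) per SNP. A group
(ecotype) frequency is drawn Beta(p(1−F_g)/F_g, (1−p)(1−F_g)/F_g) around
the ancestral value, and each population's frequency is drawn the same way
around its group value with the population's drift parameter F_k. The
hierarchy exists because a flat per-population parameterization cannot
produce the characteristic germplasm pattern — pairwise differentiation
~0.01 within an ecotype group alongside ~0.4 between groups — since a
pair's expected θ is approximately the mean of the two per-population
parameters. Draws that come out monomorphic in every population are
resampled, up to 100 attempts per site.

**Linkage disequilibrium.** Within haplotype blocks (default 500 bp) each
gamete copies the previous site's allele with probability `copy_prob`
(default 0.9) and draws fresh from the population frequency otherwise;
blocks are independent. Two properties motivated this mechanism over the
more obvious finite-founder haplotype pool: (i) the marginal frequency of
each site is a deterministic geometric smooth of the population
frequencies, identical for every gamete, so the mechanism adds **no drift
variance** and realized F_ST stays at its design value (a founder pool of
H haplotypes inflates every pairwise θ by roughly 1/2H, which destroys
0.01-level targets); (ii) r² between sites k markers apart decays
geometrically toward copy_prob^(2k), giving the LD-decay fit a true
exponential to recover. When LD is on, the Balding–Nichols drift quantile
is shared by all sites of a block (Beta quantile function evaluated at one
uniform per block), so linked sites drift in the same direction — without
this the within-block smoothing averages independent drift away and
realized between-group differentiation falls well short of its parameter.

**Families.** `PopulationDesign.family_size` organizes a population into
full-sib families: four parent haplotypes per family, progeny gametes
recombining them at block boundaries. This emulates the within-population
relatedness of polycross-derived seed lots and is what gives within-
population genomic prediction something to work with. It adds a small
amount of drift (~1/(2·haplotypes per population)), which is why small
family sizes (3) are used where 0.01-level differentiation targets matter.

**Admixture.** A hybrid cohort draws each gamete from one of its two
parent populations with the stated mixing proportion. Hybrids are
intermediate in expected allele frequency and land between their parents
on PC1.

**Traits.** QTL are sampled uniformly among SNPs with standard-normal
effects. The raw genetic value is split into its population-mean part and
its within-population deviation; the two parts are orthogonal in-sample by
construction, and each is rescaled so the realized variances equal the
`h2_across` / `h2_within` targets exactly (total phenotypic variance 1 on
the genotype-mean scale). Replicate phenotypes add Gaussian plot noise; if
no plot error SD is given it is set to √((1 − h²_across − h²_within)·n_reps)
so the genotype-mean residual variance equals the remaining variance.
Note the across part is the *realized* population-mean pattern of the QTL
genotypes: with strong family structure and few families, family sampling
can rotate that pattern away from the allele-frequency structure axes, in
which case a d-component partition will classify some of it as within.

**Missingness.** Calls are masked independently at the stated rate;
retained calls get depths from a Poisson truncated at ≥ 1. The depth model
is a stand-in — GBS depth distributions are not well standardized — and its
mean can be calibrated so that the depth-1 mass matches an observed
shallow-call rate (`mean_depth_for_depth1_fraction`).

## Genotype QC and imputation

The cascade runs in a fixed order: depth masking → individual missingness
→ site filters → complete-LD pruning. Thresholds use strict inequalities
throughout (mask depth < 2, remove individuals > 75% missing, remove
MAF < 0.025 or call rate < 50%), which makes rerunning the cascade on its
own output a no-op. Complete-LD pruning is within-chromosome, computes r²
on pairwise-complete observations, treats r² ≥ 1 − 1e−9 as complete, and
keeps the lowest map position of each equivalence group.

LD-kNN imputation selects, per target site, the `l` sites with highest r²
(pairwise-complete; ties broken toward lower map index), measures
individual distances as mean absolute dosage difference over the shared
non-missing profile entries, takes the `k` nearest donors with a known
target call (ties toward lower sample index), and rounds the
1/max(d, 1e−5)-weighted mean half-to-even into {0, 1, 2}. A target with no
usable profile (missing at all l sites) falls back to the unweighted mean
of the k donors. Every tie-break is deterministic, so imputation is
reproducible irrespective of the seed argument. The exact distance and
weighting variant of the published algorithm family is not pinned down by
its common description; the one implemented here is recorded above and
chosen for being the simplest member with the right contract.

Dosage polarity: VCF input is re-coded so dosage counts the minor allele
over the whole file, with the flip recorded per site so writers restore
REF/ALT orientation; sites at exactly 0.5 stay unflipped. A bare dosage
TSV carries no allele labels and is taken as already minor-coded.

## Population structure

F_ST uses the Weir–Cockerham variance components (a, b, c) per locus with
sample-size weighting, θ = Σa / Σ(a+b+c) over loci polymorphic in the
pooled pair — a ratio of sums, never a mean of ratios. The standard error
is a delete-one-locus jackknife, the standard choice for multi-locus θ
when no method is stated for the published SEs. Group comparisons (all
lowland vs upland) are relabeling followed by the same estimator.

PCA decomposes the column-centered dosage matrix (frequency scaling
optional, off by default since centered-unscaled is the minimal
convention); component signs are fixed by making the largest-magnitude
loading positive.

LD decay fits r²(d) = α·exp(−d/c) (optional asymptote) to raw pairs by
nonlinear least squares, initialized from a log-linear regression on
distance-bin means and restarted from perturbed values on failure. The
threshold distance solves the fitted curve against r² = 0.2; curves that
never cross report the side they sit on instead of a number.

## Quantitative genetics

Phenotype BLUPs come from the one-way random-genotype model fitted by
REML (statsmodels MixedLM); repeatability is H² = σ²_G/(σ²_G + σ²_e/n)
with n the arithmetic mean number of replicates per genotype (the average
is the stated convention; a harmonic-mean alternative would differ only
under unbalanced replication). Exactly noiseless data short-circuits to
group means with σ²_e = 0.

The GRM is A = WW′/2Σpᵢ(1−pᵢ) with W column-centered dosages;
monomorphic SNPs contribute to neither numerator nor denominator. Its
eigendecomposition drops the null direction introduced by centering
(n−1 components), sorts eigenvalues descending, and clips negatives below
1e−8·λ₁.

Single-kernel REML profiles the restricted likelihood over
δ = σ²_e/σ²_g on the rotated training data (25-point log-grid in
[1e−5, 1e5], then bounded scalar minimization around the best grid point);
estimates pinned at the bounds are flagged. Predictions for unphenotyped
individuals flow through A[:, train](A_tt + δI)⁻¹ applied to training
residuals. One property worth knowing: when the kinship eigenvalue
spectrum is flat (unstructured panels of unrelateds), δ is only weakly
identified and single noiseless draws can fit with substantial apparent
noise; families, clones or strong structure restore identifiability.

**Partition estimator.** The across/within sums need an estimate of the
unobservable α. The default evaluates them at the BLUP α̂ (REML variance
components, then α̂ᵢ = λᵢỹᵢ/(λᵢ+δ)); `estimator="posterior"` adds each
component's prediction-error variance (the posterior second moment
E[αᵢ²|y] = α̂ᵢ² + PEVᵢ). Both satisfy the additivity identities exactly.
The BLUP plug-in is the default: the posterior variant is unbiased per
component only when the common-σ²_G working prior is right, and in
simulations with trait-specific architectures its PEV term spread over the
~n trailing components systematically overstates the within component,
while the plug-in recovers balanced (0.25, 0.25) architectures to within
~0.05 at n = 400, m = 3000. d defaults to 3, the conventional choice when
the leading components visibly separate the populations; it is a parameter
because other designs need other values, and d = 0 is allowed as a
degenerate configuration (everything within).

## Prediction methods

kin-BLUP delegates to the spectral REML above. PLS is scikit-learn's
NIPALS with 15 latent variables by default, truncated to the predictor
rank with a warning. SPLS is implemented in-package (no sparse-PLS package
is part of the supported dependency set): direction vectors X′r are
soft-thresholded at η·max|X′r|, surviving markers accumulate into an
active set refitted by plain PLS, and (η, components) are selected by
seeded inner CV on MSE with ties broken toward the sparser model; η = 0
reproduces plain PLS to numerical precision. BayesB is a numba Gibbs
sampler over a point-mass/normal mixture with marker-specific
scaled-inverse-χ² variances (ν = 5); π is the probability a marker *has*
an effect. Hyper-scales put the residual prior mode at (1−R²)·var(y) and
spread R²·var(y) over the π·m expected contributing markers (R² = 0.5).
Posterior means use the thinned post-burn-in samples and the chain state
is fully determined by the seed.

## Cross-validation

Fold construction partitions the *target* population (or union) into
near-equal folds; the calibration set is always everyone else, across all
populations. The RNG stream is keyed by (seed, replication, target) so all
methods compared under one scheme see identical folds — necessary for
paired comparisons. Accuracy is the Pearson correlation of observed BLUPs
with predictions computed per fold and averaged over folds and
replications (fold-averaging rather than prediction-pooling; pooling is
available but mixes fold-specific calibrations). A zero-variance
prediction yields a missing r, never zero. Models are fully refitted —
variance components included — every fold.

## Problem sizes and runtime

Test-suite simulations use panels of roughly 100–400 individuals at
300–3000 SNPs, and the end-to-end script uses five populations of 70 at
1500 SNPs — sizes at which every estimator involved is well past its
small-sample regime while a full run stays in the minutes range on one
CPU. Parameter-recovery checks average over 10 seeds at the design points
stated in the tests.

## What the synthetic data does not emulate

Real GBS data has depth heterogeneity across individuals and loci
(library-size and restriction-site effects), allele-specific and
reference-alignment bias, genotyping error conditional on depth, and LD
generated by physical linkage with recombination-rate variation; none of
these are modeled. Tetraploid dosage is collapsed to diploid coding
{0, 1, 2}, matching the matrix conventions of the GBS pipelines this
package mirrors; tetrasomic inheritance is out of scope. Passing tests
demonstrate the estimators' internal correctness and their behavior under
the stated population-genetic models — not robustness to the error
structure of any particular sequencing platform.

## Known limitations

* The d-dominant-components definition of "across-population" variance is
  identified only insofar as population structure actually occupies the
  top d kinship eigenvalues; strong family structure produces eigenvalues
  that interleave with weak structure axes, and trait variance on a
  structure axis outside the top d is booked as within-population.
* BLUP plug-in sums shrink the weakly informed trailing components, so
  h²_gW carries a downward bias that grows as marker number or panel size
  falls.
* The SPLS inner CV optimizes MSE only; selection stability across seeds
  is not assessed.
* The Weir–Cockerham implementation covers the biallelic diploid-coded
  case used everywhere in the pipeline; haplotype or multi-allelic
  variants are not supported.
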