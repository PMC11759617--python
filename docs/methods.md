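# Methods

`pcmatch` implements a pipeline for running a case-control GWAS in a large,
ancestrally heterogeneous biobank cohort *after* genetically matching its
participants to a smaller disease cohort, then meta-analyzing the two
cohorts.  Because the cohorts this design targets are access-controlled,
the package ships a synthetic-data generator that reproduces the
statistical structure the method assumes, and every claim the package
makes about itself is demonstrated on that synthetic data by the test
suite and the acceptance script.

## Synthetic cohorts

**Genotypes.**  K ancestral populations are generated under the
Balding-Nichols model: each variant has a base frequency
p ~ Uniform(0.05, 0.5), and population k draws its frequency from
Beta(p(1−F)/F, (1−p)(1−F)/F) with differentiation F = Fst (default 0.1,
a typical between-continental-group value), clamped to
[10⁻⁴, 1−10⁻⁴].  Individual i with admixture proportions Qᵢ (Dirichlet)
has allele probability p_ij = Σₖ Q_ik p_kj and dosage
g_ij ~ Binomial(2, p_ij).  Variants are independent (no LD) by default;
`add_ld_copy` duplicates a variant's draw with a per-allele flip
probability to provide crude LD for prune/clump tests.  Variants sit on
one synthetic chromosome at 1 kb spacing, coordinates 1-based (VCF
convention).

**Two-cohort structure.**  The reference (disease-study) cohort draws
admixture from Dirichlet(8, 1, 1) — dominated by the first ancestral
population.  The target (biobank) cohort is a two-component mixture:
a 25% subgroup drawn from the *reference's* admixture distribution
embedded in a 75% majority from Dirichlet(2, 5, 5).  This is the
scenario the method exists for: a heterogeneous biobank that contains,
but is not composed of, participants genetically similar to the disease
cohort.  With a single divergent Dirichlet instead, the overlap would be
a thin density tail and "matching" would degenerate into tail selection.

**Phenotype.**  Disease liability is logistic:
logit P(case) = β₀ + Σ g·β_causal + Q·γ + β_age·std(age) + β_sex·sex,
with β₀ solved numerically (bisection on [−50, 50]) so the marginal case
probability equals the prevalence (default 0.111).  The ancestry offsets
γ (log-odds per unit admixture proportion) create confounding between
ancestry and disease when nonzero.  Ages are Uniform(55, 90) —
a dementia-study age range; the liability uses the standardized age.
A "by-proxy" status applies sensitivity/specificity to the clinical
label; real proxy phenotypes (diagnosis codes, affected relatives) are
not generatively modelled, only their misclassification consequence.

**What the generator does not emulate:** realistic LD maps, rare-variant
site-frequency spectra, pedigrees, genotyping error, sex chromosomes,
batch effects.  Passing tests therefore demonstrate the statistical
correctness of the machinery (calibration, matching behaviour, effect
recovery) under the stated model, not robustness to those features of
real data.

## Quality control

Filters follow the conventional cascade and thresholds: technical
replicates (metadata-declared, keep the fewest-missing member), sample
missingness > 5%, HET/HOM ratio outliers beyond 6 SD (denominator
floored at one call), relatedness, PC outliers beyond 6 SD on the top 10
PCs, variant missingness > 10% (strict inequalities: a variant exactly
at threshold survives), carrier/minor-allele-count < 20, and the
Hardy-Weinberg exact mid-p ≤ 10⁻¹⁵.

Kinship uses the KING-robust between-family estimator
φ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa⁽ⁱ⁾ + N_Aa⁽ʲ⁾) over mutually non-missing
sites (≥ 100 by default); duplicates give φ ≈ 0.5, parent-offspring
≈ 0.25.  Pairs at φ ≥ 0.0884 (= 2^−3.5, the standard second-degree
boundary) are pruned greedily: repeatedly drop the sample in the most
remaining pairs, ties broken by higher missingness then lexicographically
smaller id.

The HWE test enumerates every heterozygote count compatible with the
observed allele counts (log-gamma form of the conditional distribution,
cached per allele-count configuration) and applies the mid-p convention:
full probability for strictly less probable tables plus half for equally
probable ones (ties at 10⁻¹² relative tolerance).  The test suite checks
it against an independent recurrence-based enumeration for every
genotype table with up to 200 samples.

## PC space and projection

The reference cohort defines the coordinate system.  Its common variants
(MAF ≥ 1%, call rate ≥ 90%, HWE mid-p > 10⁻¹⁵) are LD-pruned in 100 kb
windows at r² > 0.1 (greedy left-to-right; the lower-MAF member of a
conflicting pair loses, the earlier variant wins ties).  Dosages are
standardized as (g − 2p)/√(2p(1−p)) with reference frequencies p,
residual missingness imputed to the mean dosage 2p, and a truncated SVD
gives k = 20 loadings.  Sign convention: the largest-magnitude loading
of each component is positive, making outputs reproducible across runs.

The target cohort is placed in the same space by least-squares
projection: standardize with the *reference* frequencies, multiply by
the loadings.  Out-of-sample projections contract toward the origin
relative to in-sample scores; the package estimates per-component
correction factors by 10-fold jackknife — project each held-out fold
with a model fit on the rest, take the ratio of mean in-sample to mean
projected score magnitude (ratio of means rather than mean of ratios,
which would blow up on near-zero projected scores), and floor at 1.
A full OADP projection (online augmentation, decomposition and
Procrustes) is not implemented; the jackknife correction addresses the
same shrinkage bias with a construction that can be verified directly
on held-out data.  All
jackknife quantities come from the sample-by-sample Gram matrix of the
standardized reference, so the ten fold models cost one dense
eigendecomposition each rather than ten passes over the genotypes.

Nearest-centroid ancestry labels (Euclidean distance in score space,
ties to the first label) stand in for the published multi-group
reference panel, which is not redistributable.  Jaccard PCs — top
eigenvectors of the double-centered rare-variant (MAF < 1%)
carrier-profile similarity matrix, scaled to unit variance — are
provided as the rare-variant covariate analogue.

## Matching

Cohort membership (reference = 1) is regressed on the 20 projected PCs
plus affection status — optionally age and sex — by maximum-likelihood
logistic regression (Newton/IRLS, tolerance 10⁻⁸; separation raises an
error that points at the Firth-penalized fallback).  Affection status is
deliberately included exactly as the design prescribes, even though it
conditions on outcome-adjacent information.

Subclassification uses quantiles of the *reference* cohort's propensity
scores as boundaries (500 subclasses by default; reduced when the
reference is smaller; subclasses that end up with no reference member
are merged downward).  Reference samples have weight 1; a target sample
in subclass s gets raw weight n_ref,s/n_target,s, and target weights are
rescaled to mean 1 over weighted target samples.  The "matched" target
cohort is all target samples with weight ≥ 1 (inclusive) — a
relative-density criterion: matched participants come from regions of PC
space where reference density is at least proportionally as high as
target density.  With a 25% reference-like subgroup this recovers
roughly that subgroup, mirroring how genetic matching is meant to
behave in a biobank.

## Association

Each variant is tested by full Newton-Raphson logistic regression of
case status on additive dosage (missing → mean) plus covariates, with
the covariate coefficients re-estimated per variant, and a Wald test on
the dosage term.  The implementation batches variants: for a block, the
per-variant information matrices X^T W_v X reduce to one dense product
between precomputed covariate pair-products and the weight matrix, and
Newton steps are solved with batched LAPACK.  Iterations start at the
covariate-only null fit; convergence is max |step| < 10⁻⁸ within 50
iterations; non-convergence or |β| > 10 flags the record.

Flagged records and Wald records with p < 0.01 and MAC ≥ 20 are refit
with Firth's Jeffreys-prior penalty (modified-score Newton with
step-halving) and a penalized likelihood-ratio p-value (the covariate-
only penalized fit is computed once per scan).  The PLRT is preferred
over a Wald test on the penalized estimate because it stays calibrated
at low minor-allele counts.  Genomic control is
λ = median(χ²)/0.4549364; the matched-cohort null scan must give
λ ≈ 1.00.

## Meta-analysis

Fixed-effect inverse-variance weighting: w = 1/se², combined β and se,
two-sided normal p, a per-study direction string (+/−/?), df = number
of contributing studies − 1, and the sample-size-weighted average
effect-allele frequency.  Alleles are harmonized by id with sign/
frequency flips for swapped records; strand-ambiguous pairs (A/T, C/G)
are kept only when |eaf − 0.5| > 0.1 in both the study and the reference
record and the orientations agree, otherwise dropped.  Post-filters:
frequency amplitude (max − min eaf) strictly < 0.4, df exactly 1
(variant present in both cohorts), and per-population HWE mid-p gates
when genotype tables are supplied.  Significant variants (p < 5×10⁻⁸)
are clumped greedily: lowest p seeds a locus and absorbs significant
variants within 1 Mb at r² > 0.01 (the r² threshold is the published
one; the window is this package's choice, as none was stated).

## Power

The additive model fixes penetrances f₁ = GRR·f₀, f₂ = (2·GRR−1)·f₀ with
f₀ set by the prevalence; case/control genotype frequencies follow by
Bayes' rule and collapse to case/control risk-allele frequencies; the
test is the 1-df two-proportion comparison.

Three power conventions are exposed.  ``cats`` is the textbook formula
(pooled-variance critical value, alternative-variance spread) and is
what the Monte-Carlo oracle in the test suite validates.  ``trend``
is the Cochran-Armitage analogue on genotype frequencies.  The default,
``calculator``, was fixed by calibration against the published
thresholds of the University of Michigan genetic-association power
calculator: those six GRR values (two sample sizes × three MAFs) all
satisfy |p_case − p_ctrl| = z₁₋α·SE_alt to printed precision — the
expected Wald allele statistic reaching the *one-sided* normal critical
value — which no textbook 80%-power formula reproduces (they deviate by
0.1–0.5 in GRR).  The default therefore models that tool's power curve
as a unit-slope normal ogive anchored to cross 80% at this criterion.
``min_grr_for_power`` bisects on [1, 50] (clipped to the
penetrance-feasible region f₂ ≤ 1) and reports the smallest two-decimal
GRR whose power still reaches the target, so the reported value always
attains the target while GRR − 0.01 does not.

## Problem sizes and numerical choices

The null-calibration and stratification scenarios run at 3 ancestral
populations, Fst 0.1, 4,000 reference + 20,000 target samples and
50,000 null variants (the stratification contrast in the test suite at
half scale: 2,000 + 10,000 samples, 25,000 variants — inflation grows
with n, so its λ > 1.05 bound only gets easier at full scale).  With
50,000 variants the sampling noise of a median-based λ is about ±0.01
(SD), which is the resolution limit of any two-decimal λ statement at
this problem size.  Genotypes are held as int8 dosages; PCA standardizes
in float64 (the projection identity holds to 10⁻⁸), while the Gram
matrix for the jackknife and the LD-prune correlations use float32.
Degenerate inputs are handled explicitly: monomorphic variants get HWE
p = 1; samples carrying no rare alleles get Jaccard similarity 0;
all-homozygous samples get a HET/HOM denominator floor; empty-of-
reference subclasses merge downward; distance ties in ancestry labels
go to the first label.

## Known limitations

Single-step covariate-adjusted regression stands in for the two-step
whole-genome-ridge / LOCO machinery of biobank GWAS tools; with
independent synthetic variants there is no polygenic background for
step 1 to absorb.  The matching weight normalization (mean 1 over
weighted target samples) is one reasonable reading of a procedure whose
normalization is not published.  Firth refitting is sequential and
dominates scan time when many variants fall below the fallback
threshold.  The synthetic-data caveats above bound what any green test
here says about real cohorts.
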