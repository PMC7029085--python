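# Methods

## Genotype model and orientation

Genotypes are ALT-allele dosages x ∈ {0, 1, 2} with a single MISSING
sentinel. All formulas are oriented by the ALT frequency p (MAF =
min(p, 1 − p)), so no downstream result depends on which allele a
caller labelled REF. Half-called genotypes ("./1") are treated as
missing because their dosage is undefined. Coordinates are 1-based as
in VCF; SNPs are treated as abstract unlinked biallelic markers with no
strand or position logic.

## Relationship matrices

Both GRMs use within-SNP standardization — each SNP is divided by its
own Hardy–Weinberg variance before averaging over loci:

- additive: A_g[i,j] = (1/m_ij) Σ_k (x_ik − 2p_k)(x_jk − 2p_k)/(2 p_k q_k)
- dominance: codes w(0) = −2p², w(1) = 2pq, w(2) = −2q², and
  D_g[i,j] = (1/m_ij) Σ_k w_ik w_jk/(2 p_k q_k)²

Both codings have zero mean under Hardy–Weinberg genotype frequencies
at every p. With true frequencies, E[A_g diagonal] = 1 + F,
E[θ] = E[A_g off-diagonal]/2 = kinship, and E[D_g off-diagonal] equals
the classical dominance relationship (1/4 for full sibs, 1/16 for
double first cousins) — these identities are what the test suite and
acceptance script verify by simulation.

**Missing data.** Accumulation is pairwise-complete: a locus missing in
either member of a pair is skipped for that pair and the pair-specific
locus count m_ij shrinks. With ≤ 4/43 missing per locus this is nearly
indistinguishable from mean imputation, but it introduces no imputation
bias and has an exact brute-force oracle (the tests compare against a
triple-loop summation to 1e-12).

**Allele frequencies.** By default p is estimated from all individuals,
which biases pairwise estimates slightly negative in small samples: for
n unrelated individuals the expected off-diagonal standardized product
is −1/(n − 1) because the focal pair is inside the frequency estimate.
This is deliberate — it reproduces the small negative between-group
coancestry means that sample-frequency GRMs show in practice — and the
null-calibration test demonstrates it (mean θ strictly negative with
sample frequencies, |mean θ| < 0.01 with true frequencies at n = 500).
A leave-pair-out option (`loo=True` / `--loo-freq`) removes that
inclusion bias; note it does not center the null at zero either, but
flips it to the +1/(n − 2) finite-sample variance term, which the test
suite checks against theory. True (simulation) frequencies can be
supplied directly and are used for all expectation-recovery validation.

**Negative values** of F, θ and D are never truncated; small negative
estimates are the expected behaviour of unbiased estimators around
zero.

## Inbreeding estimators

Two per-individual variants are reported:

- `grm_F` = A_g[i,i] − 1, the within-SNP-standardized homozygosity
  measure;
- `het_F` = (O_hom − E_hom)/(L − E_hom), the heterozygosity-excess
  method of moments, with E_hom = Σ_k [1 − 2 p_k q_k · Na_k/(Na_k − 1)]
  and Na_k the observed allele count (the small-sample correction on
  allele counts, the convention of the standard whole-genome toolkits).

Classification assigns each F to the nearest classical mating
expectation {0, 1/16, 1/8, 1/4} with midpoint boundaries; the window is
configurable because at ~15k SNPs the sampling SD of F (~0.02–0.03 plus
any structure-induced shift) makes the 1/16 and 1/8 classes overlap in
unlucky samples.

## Exact Hardy–Weinberg test

The locus filter uses the exact conditional test: given the allele
counts, the probability of each heterozygote count (same parity as the
rare-allele count) follows the standard one-parameter distribution, and
the two-sided p-value sums all configurations no more probable than the
one observed. No mid-p correction is applied. The implementation uses
the ratio recurrence from the observed count; an independent
log-factorial enumeration oracle in the tests agrees to 1e-12 for every
table with up to 50 individuals. Exact tests are conservative: under a
simulated null the rejection rate at 0.01 stays at or below ~1%.

## Locus filtering

Criteria (defaults QUAL ≥ 30, MAF ≥ 5%, HWE p ≥ 0.01, ≤ 4 individuals
missing) are evaluated in that fixed order on the original matrix in a
single pass, so the "first failed criterion" attribution is
well-defined and filtering is idempotent. A locus without a QUAL value
passes the QUAL criterion (simulated data carry none). The missingness
threshold is an absolute count by design, with a fraction-based
alternative on the CLI. Frequencies are not recomputed after removals.

## Method-of-moments IBD

For each pair, observed IBS class counts over jointly-called loci are
inverted against the expected IBS-class probabilities under IBD states
0/1/2. The expectations use the standard finite-sample corrections on
allele counts (products of ratios like (x−1)/x and Na/(Na−1), with x
the allele count and Na the total); Z0 is estimated from IBS0, Z1 from
the IBS1 residual, Z2 as the remainder, then the triple is clamped to
the probability simplex and PI_HAT = Z1/2 + Z2. The validation target
is pedigree-expectation recovery (parent–offspring Z1 ≈ 1, PI_HAT ≈
0.5; unrelated Z0 ≈ 1; monotone PI_HAT across relative classes;
PI_HAT ≈ 2θ), not bit-exact agreement with any particular external
program.

## Classical MDS

Double-center the squared distance matrix, eigendecompose, scale the
top-k eigenvectors by √λ. Eigenvalues are sorted descending with ties
broken by original index; axes with negative eigenvalues (non-Euclidean
input) are zeroed and the eigenvalues reported. The input distance is
d = 1 − DST. Axis signs are arbitrary, so tests compare reconstructed
distances or absolute coordinates, and the implementation is
cross-checked against an independent principal-coordinates routine.

## Population statistics

Group summaries use the sample SD (n − 1). Comparisons fit the one-way
fixed-effect model y = μ + population + e and test all pairwise
contrasts with the pooled residual variance; the default display uses
unadjusted contrasts at α = 0.05 (a Tukey HSD option is provided — the
choice is left open because marked-letter tables in the field often
omit the adjustment used). Letters come from an insert-and-absorb
compact-letter algorithm.

The distance regression is OLS of θ on |river-km difference| over
individual pairs (within-location distance 0). Pairs sharing an
individual are not independent, so a Mantel permutation test
(default 9,999 permutations, seeded, observed statistic included so
p ≥ 1/(nperm + 1)) accompanies the OLS p-value; both are reported.

## Pedigree simulator and oracle

Gene dropping: founder alleles are i.i.d. Bernoulli(p) per locus,
transmissions pick one parental allele uniformly, loci are unlinked, no
mutation or selection. Founder frequencies default to Uniform[0.1, 0.9]
so that post-filter MAF ≥ 5% survives sampling noise. A fixed seed
gives byte-identical output. Founder-origin labels are available so
realized IBD can be measured directly against the kinship expectation.

Exact expectations come from the tabular kinship recursion
f(i,j) = ½[f(sire_i, j) + f(dam_i, j)] with founder base cases, F_i =
f(sire_i, dam_i), and the classical dominance formula
d_ij = f(si,sj)f(di,dj) + f(si,dj)f(di,sj). The dominance formula
assumes non-inbred pair members; when a member is inbred the value is
flagged approximate rather than silently returned. A brute-force
transmission-pattern enumeration (2 bits per non-founder) verifies the
recursion on every built-in template.

## Study-scale fixture

`make_study_fixture` emulates the study conditions: 43 individuals in
three river locations (11 at km 5, 20 at km 17, 12 at km 25), two
founder pools (location A versus B+C, matching the two-subpopulation
structure of the real data) drifted from a common ancestral pool by a
Balding–Nichols model, embedded relatives (a half-sib pair in A, a
first-cousin pair in B) and inbred individuals (3 first-cousin-mating
offspring in A; half-sib-mating offspring: 2 in A, 2 in B, 1 in C —
the reported mix), ~2% missingness capped at 4 individuals per locus.

Two fixture constants were set once from the study's own reported
scale: the raw locus count (16,000, so the default filter retains
~15.4k loci, within 10% of the real 15,396-SNP panel) and the
Balding–Nichols drift (Fst = 0.06 per pool, which puts the within-A
mean coancestry near the reported ~0.06 and the between-pool means near
−0.04). What the fixture does **not** emulate: linkage, genotyping
error, allele-frequency spectra skewed toward rare variants, and
location-level substructure inside the B+C pool — so passing tests
demonstrate estimator correctness under the stated sampling design, not
robustness to those real-data features.

## Validation protocol and problem sizes

The expectation-recovery protocol (also run by `scripts/acceptance.py`)
uses 200 replicate pedigrees × 20,000 SNPs per relative class with true
founder frequencies; at that size the Monte-Carlo SE of the mean focal
statistic is ≈ 0.001–0.002, comfortably inside the ±0.01–0.015
verification bands. Unit tests use smaller sizes (tens of replicates,
a few thousand loci) with proportionally wider bands. The null
calibration uses 500 individuals × 20,000 SNPs.

## Numerical choices

- GRMs are symmetrized after accumulation to cancel float rounding;
  writers require symmetry within 1e-10 and round-trip to 1e-12.
- The HWE recurrence normalizes the whole conditional distribution at
  the end, and the "no more probable" comparison uses a 1e-12 relative
  guard against ties lost to rounding.
- mom-IBD requires ≥ 4 observed alleles per locus (the corrections
  divide by Na − 3) and errors on degenerate expected counts rather
  than returning NaN.
- Monomorphic loci are an error inside the GRM builders (the divisor is
  zero); `pair_table` drops them up front since they carry no pairwise
  information.
- Degenerate `het_F` (denominator zero) is NaN, not an exception.

## Known limitations

- All estimators assume unlinked markers; dense panels with LD would
  need pruning first.
- The one-way comparison model ignores the dependence between pairs
  sharing an individual (the Mantel test is the dependence-aware
  companion for the regression; no analogue is provided for the group
  comparisons, matching standard practice in the field's tables).
- The leave-pair-out frequency option removes the inclusion bias but
  not the finite-sample variance term; neither mode gives an exactly
  zero-centered null at small n.
- Dominance expectations for pairs with inbred members are outside the
  classical formula's guarantee and only flagged.
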