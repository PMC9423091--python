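# Methods

This note documents the models, algorithms, numerical choices, and the
synthetic-data design behind `pxgs`, and what the test suite does and does
not establish about real data.

## The polycross problem

A polycross trial crosses each female parent tree with a pooled mix of
known male pollens. The classical analysis treats each maternal family as
half-sibs with an expected additive relationship of 0.25 and assumes equal
male contribution. Real trials violate this: pollen mixes are deliberately
or accidentally unequal, maternal records carry mislabels, a mother tree
can contribute two genotypes (mislabeled clone, or a cone-bearing
rootstock), foreign pollen contaminates the mix, and self-compatible
species self. All of these bias variance components, breeding values,
expected gain, and diversity accounting. Dense SNP genotypes resolve the
problem two ways at once: the realized genomic relationship matrix can be
used directly in the mixed model (GBLUP), and it can be used to
reconstruct the true full-sib pedigree for pedigree-based analysis.

## Relationship matrices

**Genomic additive (G).** VanRaden's form: with dosages `x ∈ {0,1,2}` and
allele frequencies `p` computed from the analyzed sample (parents and
offspring jointly — the default of the common single-population
implementations), `W = X − 2p` column-wise and `G = WW'/(2Σ pₘ(1−pₘ))`.
Because `p` comes from the sample itself, the matrix is centered so the
average relationship of the sample is near zero; in a cohort of close
relatives every relationship class is shifted downward by roughly the mean
relatedness of the sample. At the scale this package targets (dozens of
parents, hundreds-plus offspring) the shift is a few hundredths and the
0.15 / 0.07 decision thresholds hold; in toy examples with a handful of
founders it can be large, which is why the test fixtures use realistic
parent counts.

**Genomic dominance (Gd).** Vitezica's orthogonal coding: per SNP with
frequencies `(p, q)` the dominance covariate is `−2q²`, `2pq`, `−2p²` for
dosages 0, 1, 2, and `Gd = HH'/Σ(2pₘqₘ)²`. Fractional (imputed) dosages
enter by linear interpolation of the three-point coding; the coding is
mean-zero under Hardy–Weinberg proportions.

**Pedigree additive (A).** The tabular method in double precision:
`a_ii = 1 + a_{fm}/2`, `a_ij = (a_{jf} + a_{jm})/2`, missing parents
contributing zero; the pedigree is topologically sorted first and cycles
or unknown labels raise errors.

**Pedigree dominance (Ad).** For two non-founders,
`d_ij = (a_{fi,fj} a_{mi,mj} + a_{fi,mj} a_{mi,fj})/4`; pairs involving a
founder are 0 and the diagonal is fixed at 1. This is the classical
non-inbred form; dominance relationships of inbred individuals are not
modeled (inbreeding enters the analysis through the A/G diagonals, not
through Ad).

**QC.** Individuals above the missingness ceiling are removed first
(default 40%), then SNP minor-allele-frequency (default 0.01) and
missingness (default 20%) filters are applied with frequencies recomputed
on the retained individuals. Imputation is mean (2p) by default; the EM
option iterates a rank-limited SVD reconstruction of the column-centered
matrix over the missing cells until relative change < 1e-6 (max 100
iterations), never touching observed entries. At sub-percent missingness
the choice is immaterial, which a property test asserts by comparing
RMSEs. Raw read-depth/quality/allele-balance filters are assumed already
applied to the incoming VCF, since they require FORMAT fields orthogonal
to the methods here.

## Pedigree reconstruction

Order of operations: duplicates → maternity → family splits → paternity
(including selfs) → contribution test → corrected pedigree. Decisions are
thresholded relationships, defaults: parent–offspring 0.15, half-sib 0.07,
duplicate 0.80 (midway between the full-sib expectation 0.5 and observed
duplicate values near 0.9), self-parent 0.70 (an outcrossed offspring
relates to its parent at ~0.5, a self at ~1), minimum split subgroup 5.

* **Maternity**: each offspring's candidate mother is the genotyped female
  with maximal relationship; confirmed if ≥ 0.15; disagreement with the
  record is a pedigree error; no female above threshold leaves the mother
  unassigned. Ties break to the lowest-sorting id with a warning.
* **Family splits**: within each (corrected) maternal family, offspring
  are partitioned by relationship to the genotyped mother. A hidden second
  mother genotype is declared only if both groups have ≥ 5 members, the
  mother-unrelated group is internally half-sib coherent (mean pairwise
  relationship ≥ 0.07), and at most 20% of its internal pairs fall below
  0.07 (no residual peak at zero relationship — the histogram diagnosis
  made algorithmic). The unrelated group is reassigned to a new founder
  label.
* **Paternity**: maximal-relationship male if ≥ 0.15, else pollen
  contaminant; a confirmation pass demotes offspring whose mean
  relationship to their assembled paternal half-sib family is < 0.07
  (mean, not minimum, so one noisy pair cannot demote a true member).
  Offspring at ≥ 0.70 to their mother without a distinct qualifying
  father are selfs.
* **Contribution test**: χ² goodness-of-fit of assigned-father counts
  (contaminants and selfs excluded) against equal expectation, df = males
  − 1.

## Mixed models

The multi-site individual-tree model is

    y = Xβ + Z₁ rs + Z₂ ibr + Z₃ a + Z₄ sa (+ Z₅ d + Z₆ sd) + e

with site means (plus optional covariates such as ring count or heartwood
width for wood traits) fixed; replicate-in-site and set-in-replicate
random; `a ~ N(0, σa² K)` for an additive kernel K (pedigree A or genomic
G); `sa` an independent realization of the additive effect per site
(block-diagonal covariance `σsa² K` within site — a compound
main-plus-interaction parameterization); dominance terms analogous with a
dominance kernel; and residuals heterogeneous by site. Wood-like traits
flagged lognormal are log-transformed before modeling.

**Estimation.** Average-information REML: `V = Σ θₖ Cₖ`, gradient
`−½(tr(PCₖ) − y'PCₖPy)`, AI matrix `½ y'PCₖPCₗPy`, with a step-halving
line search that never accepts a likelihood decrease; the first three
iterations and any failed AI step use the (monotone) EM update. Negative
proposals clamp to a floor of 1e-8 × the phenotypic variance and are
flagged as boundary; a component hugging the floor with a negative
gradient for two consecutive iterations is pinned there so the AI system
stays well conditioned. Convergence requires relative log-likelihood
change < 1e-8 and relative parameter change < 1e-6 (max 200 iterations).
Standard errors of components come from the inverse AI matrix; BLUPs are
`û = θ K Z'Py` with prediction-error variance `θK − θ²KZ'PZK` (identical
to the mixed-model-equations inverse), evaluated for every kernel
individual including unphenotyped parents.

**Derived quantities.**
`h² = σ̂a²/σ̂P²` and `H² = (σ̂a²+σ̂d²)/σ̂P²` with
`σ̂P² = σ̂a²+σ̂sa²+σ̂d²+σ̂sd²+σ̄e²` and `σ̄e²` the unweighted mean of the
per-site residual variances; this denominator reproduces the published
multi-site tables cell by cell, including the dominance models. Type-B
genetic correlation `r_B = σ̂a²/(σ̂a²+σ̂sa²)` (1 by definition when the
interaction term is absent). Both carry first-order delta-method standard
errors from the AI covariance. The LRT for a single dropped component
reports the plain χ²₁ p-value with the boundary-corrected
½χ²₀+½χ²₁ mixture alongside. Theoretical accuracy is
`√(1 − SE²/((1+F)σ̂a²))` clipped to [0,1], with `1+F` the kernel diagonal;
for cross-model comparisons `σa²` (and `σsa²`) may be supplied externally
or constrained during the fit. AIC counts only free, non-boundary variance
parameters, appropriate for comparing models with identical fixed parts.

**Bivariate genetic correlation.** Both traits are stacked with per-trait
site means, an unstructured 2×2 additive covariance sharing the kernel,
and an unstructured 2×2 residual covariance per site; cross-covariance
parameters are unconstrained in sign with the 2×2 blocks clamped inside
the PSD cone (|cov| ≤ 0.999·√(v₁v₂); a converged estimate on that clamp is
reported as ±1). Significance follows the "estimate at least twice its SE"
rule. Non-convergence (e.g. degenerate perfectly-correlated traits) falls
back to the correlation of univariate BLUPs with a warning. Multivariate
(>2 traits) models are out of scope; all pairwise correlations are
obtainable from bivariate fits.

## Selection accounting

Top-fraction selection sorts predicted breeding values with ties at the
cutoff broken by id (logged). Expected gain is
`100 × mean(BV of selected) / population phenotypic mean`, computed on the
modeling scale (log scale for log-modeled traits — the scale is recorded
with the report). Group coancestry `θ` is the mean over all ordered pairs
(self-pairs included) of the coancestry `= additive relationship / 2`, and
the status number is `Ns = 1/(2θ)`; for a single non-inbred tree `Ns = 1`,
for N unrelated trees `Ns = N`, and for a large full-sib family `Ns → 2`.
Corrected gain re-scores a model's selected set with a reference model's
breeding values (the genomic model by default) and reports the corrected
mean BV, corrected gain, percent overlap with the reference's own
selection, and the implied gain-overestimation percent. No diversity
constraint is applied during selection.

## Synthetic trials

The generator mirrors the structure the analysis assumes. Founders are
unrelated, non-inbred Hardy–Weinberg draws at per-SNP frequencies uniform
on the MAF range (default 0.05–0.5); loci are unlinked, since genome-wide
relatedness — not linkage — drives every method here. Defaults reproduce
the study conditions: 26 females × 21 males (optionally with shared
female/male roles), ~58 offspring per family, male contribution weights
drawn once per cohort from a symmetric Dirichlet(α=1) (strongly skewed;
the true distribution of contributions is unknown, only outcomes are),
12% maternal mislabels, 8/26 dual-genotype mothers whose hidden genotype
(an independent founder) truly mothers a Uniform(0.3, 0.7) share of the
recorded family so both clusters are populated, 5% pollen contamination by
freshly drawn foreign fathers never added to the candidate list, and 1%
selfing. Offspring genotypes are independent Mendelian gametes per SNP.
Field layout deals offspring round-robin over 3 sites, then replicates
(default 10 per site) and sets (default 3 per replicate) — single-tree
plots in incomplete blocks. Phenotypes follow the model above with `a`/`d`
drawn from the marker-derived true kernels (or pedigree kernels on
request), per-site interaction draws, heterogeneous residuals, optional
independent-Gaussian covariates with fixed coefficients, and
exponentiation for lognormal traits.

What the generator does **not** emulate: linkage disequilibrium and
realistic haplotype structure, historical relatedness among founders,
selection history, genotyping error (beyond what tests inject explicitly),
missing-data patterns correlated with genotype, spatial field trends, and
climate covariates. Passing tests therefore demonstrate the correctness of
the algorithms under the stated statistical model, and the power of the
reconstruction rules at realistic marker counts — not robustness to every
artifact of a real genotyping pipeline.

## Problem sizes and determinism

The acceptance suite runs the REML parameter-recovery check at one
simulated trial of ~1500 offspring × 2000 SNPs per replicate (10
replicates) and the reconstruction-recovery check at the full 26×21 / 2000
SNP design; these sizes make every relationship-threshold and
coverage-based criterion meaningful while keeping a full test run in the
low minutes on a single core. All randomness flows from explicit integer
seeds through `numpy.random.Generator`; the pipeline writes a manifest
with SHA-256 checksums of every output, and reruns with the same config
and seed are byte-identical.

## Known limitations

* Dominance relationships of inbred individuals use the non-inbred
  convention (diagonal 1).
* Sample-frequency centering of G biases relationship classes downward in
  very small cohorts; thresholds are calibrated for realistic parent
  counts.
* Bivariate REML with unstructured covariances can sit on the PSD boundary
  for near-degenerate trait pairs; the BLUP-correlation fallback is then
  reported with a warning.
* The heritability/type-B standard errors are first-order delta
  approximations from the AI covariance, adequate away from boundaries but
  optimistic when a component is pinned at zero.
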