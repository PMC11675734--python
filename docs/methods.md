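# Methods

## Problem and overall design

The package looks for genomic regions under divergent directional selection
between two *groups* of populations, each group containing several breeds.
The group contrast is the signal of interest; breed-to-breed differentiation
within a group is noise to be subtracted.  Two statistics with different
failure modes are combined:

* a **univariate scan** — per-SNP two-population Weir–Cockerham θ̂,
  LOWESS-smoothed along each chromosome, with one-sided per-chromosome
  outlier thresholds; and
* a **multivariate classifier** — stepwise discriminant selection of a
  full-rank marker subset followed by canonical discriminant analysis.

Final candidates are the markers flagged by *both* branches in the group
contrast and by *neither* within-group breed-pair contrast.

## Univariate branch

For one biallelic SNP and two populations of size n₁, n₂ with allele
frequencies p₁, p₂ and heterozygote proportions h₁, h₂, the Weir–Cockerham
variance components are (r = 2, n̄ = Σnᵢ/r, n_c = (rn̄ − Σnᵢ²/(rn̄))/(r−1),
p̄ and h̄ the sample-size-weighted means, s² the weighted between-population
variance of pᵢ):

    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − (2n̄−1)/(4n̄)·h̄]
    c = h̄/2,      θ̂ = a/(a+b+c)

θ̂ is undefined when a+b+c = 0 (both populations fixed for the same
allele); such SNPs never enter smoothing or outlier sets.  Small negative
θ̂ values are a normal property of the estimator and are kept.

**Smoothing.** Plain LOWESS (local linear fit, tricube weights, zero
robustness iterations by default) over the `window_snps = 20` nearest
neighbours, nearest measured on the bp axis (an index-based axis is
available).  Chromosomes are smoothed independently; windows truncate at
chromosome ends; undefined θ̂ positions are filled by linear interpolation
of the smoothed curve so every mapped SNP has a smoothed value, but only
defined-θ̂ SNPs can be flagged.

**Outliers.** Per chromosome, flag SNPs with smoothed value above
mean + 3·SD, where mean and SD are computed on the *smoothed* series of
that chromosome (a raw-θ̂ basis is available for sensitivity analysis).
The smoothed basis reproduces outlier rates around 1% of the panel on
drift-only data; the raw basis is far more conservative.

## Multivariate branch

**Wilks' Λ** for a variable subset is det(W)/det(T), the within-group over
total SSCP determinant ratio; Λ = 1 for the empty set, and for one variable
and two groups Λ = 1/(1 + t²/(n−2)) with t the pooled two-sample
t-statistic (this identity anchors the test suite).

**Stepwise selection (SDA).** At each step the partial F for entering
candidate v given the selected set S is

    F = ((n − g − q)/(g − 1)) · (1 − λ)/λ,   λ = Λ(S ∪ {v})/Λ(S),  q = |S|

computed for every candidate via conditional sums of squares (residual SS
of v on S in the within and total metrics), so one step costs O(q²p).  The
best candidate enters if significant; after each entry the weakest
non-forced selected variable is dropped if its partial F for removal has
p > `slstay` (removal uses the diagonal-of-inverse identity
SS(v|S∖v) = 1/[M⁻¹]ᵥᵥ, so it is O(q²)).  A collinearity guard requires the
candidate's residual total variance fraction (1 − R² against S) to be at
least `tolerance = 1e-7`.  Ties on F break to the lowest map position, so
runs are deterministic.

*Entry multiplicity.* `slentry` and `slstay` default to 0.15, the classical
stepwise defaults.  Applied per candidate while scanning thousands of SNPs,
however, a 0.15 entry threshold admits hundreds of expected false entries
per step — on drift-only panels the selection then always runs to its cap
(n − g − 2 markers) and the canonical distance explodes to numerically
meaningless magnitudes (D² ~ 10¹⁷).  The entry p-value is therefore
compared against `slentry / (number of candidates scanned at that step)`
(`entry_multiplicity = "bonferroni"`, the package default;
`"none"` restores the uncorrected classical rule).  With the correction,
selected-marker counts on realistic panels land in the tens, pure-noise
selections stop after a handful of entries, and canonical distances stay
interpretable.

**Hierarchical reduction.** Stepwise is run within each chromosome
(handling p ≫ n natively), survivors are pooled, and the pooled set is
re-run genome-wide while it still holds at least as many markers as
animals.  The per-pass cap is `max_selected = n − g − 2`.

**Canonical analysis (CDA).** For two groups the single canonical direction
is S_pooled⁻¹(m₂ − m₁) with S_pooled = W/(n−2); scores are scaled to unit
pooled within-group variance and sign-oriented so a designated reference
group (second label alphabetically unless configured) has a positive
centroid.  Mahalanobis D² = (m₁−m₂)ᵀS_pooled⁻¹(m₁−m₂); Hotelling's
T² = (n₁n₂/n)·D²; F = T²(n−p−1)/((n−2)p) on (p, n−p−1) df.  Assignment is
nearest-centroid on the canonical score with equal priors; the reported
error is resubstitution (no held-out data).  Missing genotypes are
mean-imputed per SNP before any discriminant computation; the F_ST branch
uses raw genotype counts and is unaffected by imputation.

## Study orchestration

One main group-vs-group contrast plus every within-group breed pair, all
with identical thresholds.  The exclusion set can be built from pairwise
contrasts in two modes: `common_only` (default — a marker must be flagged
by *both* branches of a pairwise contrast to be excluded) or
`union_both_methods` (flagged by either branch anywhere).  Union mode
excludes 3–5% of the panel on drift-only data, which measurably deletes
true group-level candidates by chance; the intersection mode keeps the
exclusion specific to genuine within-group differentiation, which is why
it is the default.  Every reported candidate is traceable to an outlier
record and a stepwise entry event, and the whole pipeline is deterministic
given dataset + configuration (sorted outputs, fixed tie-breaks, no
unseeded randomness).

## Stratification check

GRM per the GCTA estimator, including its distinct diagonal
1 + (1/m)Σᵢ[xᵢⱼ² − (1+2pᵢ)xᵢⱼ + 2pᵢ²]/(2pᵢ(1−pᵢ)) whose expectation is 1
under Hardy–Weinberg proportions.  Missing genotypes contribute zero with
per-pair denominators equal to the jointly called SNP count
(pairwise-complete; a global-m mode exists).  Monomorphic SNPs are skipped
with a warning.  The PCA eigendecomposes the GRM as given (no
re-centering, matching the GRM tool's behaviour); scores are
eigenvector·√eigenvalue by default; variance fractions floor negative
eigenvalues at zero in the denominator only.  Group location on a
component is compared with a Welch t-test (the unequal-variance choice is
deliberate: group sizes and spreads differ).

## Quality control

Fixed filter order, recorded per step in `QCReport`: (1) unmapped SNPs,
(2) animal call rate (strict >), (3) SNP call rate (strict >), (4) MAF
(inclusive ≥) on the remaining animals, (5) Hardy–Weinberg exact test
(Wigginton-style enumeration of Levene's conditional distribution; a SNP
is removed when p < threshold) on the pooled sample — pooling is the
default because group/breed structure is exactly what downstream stages
measure; a per-breed option exists.  QC on pooled multi-breed panels
removes some genuinely polymorphic SNPs through the Wahlund effect; this
is intended behaviour of the pooled test.

## Synthetic data

Hierarchical Balding–Nichols model: ancestral frequency p ~ U(0.10, 0.90);
group frequency ~ Beta(p(1−F_g)/F_g, (1−p)(1−F_g)/F_g) with F_g = 0.03;
breed frequency drawn the same way around its group frequency with
F_b = 0.02; genotypes ~ Binomial(2, p_breed); uniform missingness 1%.
Under this hierarchy Var(p_breed) = p(1−p)(F_g + F_b − F_g·F_b), which the
tests verify against simulation.  Selection is planted as clusters of
consecutive SNPs whose two group frequencies are pushed apart by ±δ/2
(clipped to [0.01, 0.99]) *before* breed drift, so all breeds of a group
share the signal and within-group contrasts see none of it.

Default study shape: 2 groups × 3 breeds × 30 animals, 5 chromosomes ×
2,000 evenly spaced SNPs, 3 planted clusters of width 20 at δ = 0.6.

*Fidelity limits.* No linkage disequilibrium (a cluster of independently
divergent SNPs stands in for a swept haplotype), even SNP spacing, no
genotyping-error model beyond uniform missingness, no demographic history.
Passing tests therefore demonstrate correct estimator algebra and sound
end-to-end logic under drift + divergence, not calibrated performance on
LD-structured real panels.

## False-positive behaviour

On drift-only (δ = 0) panels at the default shape the pipeline reports a
small but nonzero number of final candidates — typically 1–8 of 10,000
SNPs per replicate (a false-candidate rate of ~0.03%).  This is inherent
to intersecting the two branches: the most drift-differentiated SNPs are
simultaneously the best single-marker discriminators and the likeliest to
lift their own smoothed window above the chromosomal 3-SD threshold, so
the branch overlap exceeds the independence expectation severalfold.
Interpreting any candidate list therefore still requires the within-group
exclusion step and, on real data, external evidence; the pipeline reduces
false signals strongly but does not nullify them.

## Numerical choices and degenerate inputs

* Wilks' Λ ratios are clipped to [1e-12, 1]; a singular total SSCP raises
  rather than silently continuing.
* Selected-set Gram inverses fall back to pseudo-inverse only in the
  (degenerate) zero-within-variance case.
* CDA refuses p > n − 3 variables and reports a singular pooled covariance
  as an explicit error suggesting a smaller set.
* LOWESS breaks exactly tied positions by an infinitesimal stable offset;
  chromosomes with fewer defined values than the window pass through
  unsmoothed with a warning.
* A chromosome whose smoothed values have zero SD yields no outliers (not
  an error).
* Stepwise guards against enter/remove cycling by stopping on a repeated
  selected set.
* Coordinates are 1-based inclusive everywhere; BED export converts to
  0-based half-open; binary PLINK round trips are lossless, text round
  trips are stable under the documented first-encountered-allele
  convention.

## Problem sizes

The test suite and the acceptance script run the full study design at the
default desk-scale shape (180 animals × 10,000 SNPs; 7 contrasts per
study; ~2.5 s per study on one core), with 20 seeded replicates per
condition in the acceptance tests and 10 in the acceptance script.
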