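# Methods

This note documents the models, defaults and numerical choices behind
`tiermr`, what the synthetic-data generator does and does not emulate,
and the design decisions made where the design was genuinely open.

## Summary-statistic handling

A variant record carries identifier, chromosome, 1-based position,
effect and other allele (A/C/G/T), effect-allele frequency, additive
per-allele effect (log-odds for binary traits), positive standard error,
p-value in (0, 1], and sample size. Readers drop and count rows that
violate these invariants rather than failing the whole file.

**Harmonization.** Outcome effects are aligned to the exposure's effect
allele per variant. Swapped alleles flip the outcome beta's sign and
replace eaf by 1−eaf; strand complements are re-compared after
complementing (a complement-plus-swap also flips the sign). Palindromic
variants (A/T, C/G) cannot be strand-resolved from alleles alone: they
are dropped when either trait's eaf is missing or within 0.08 of 0.5
(i.e. eaf in [0.42, 0.58]), and otherwise oriented by whether the two
eafs fall on the same side of 0.5. The 0.08 window is the package's
default for the usual ambiguity zone; it is configurable. Harmonization
is idempotent: re-harmonizing kept pairs is a no-op.

**Clumping** is greedy: variants sorted by ascending p (ties broken
lexicographically on identifier, which makes the output independent of
input row order) are retained iff their r² with every already-retained
variant within the window (closed interval, |Δpos| ≤ window_kb·1000) is
below the threshold. Defaults r² < 0.01 within 10,000 kb. Variant pairs
absent from the LD matrix are treated as uncorrelated with a logged
warning. Instrument strength is the squared exposure z, F = (β/se)²,
with instruments at F ≤ 10 removed by default.

## Two-sample MR

Method policy: one instrument → Wald ratio; two → IVW; three or more →
IVW primary with MR-Egger and weighted-median sensitivity estimates.
IVW is fixed-effect by default, switching to a multiplicative
random-effects standard error max(1, √(Q/(n−1)))·se_fixed when
Cochran's Q has p < 0.05 ("auto" mode); both models can be forced.
Egger regression orients every pair so the exposure beta is positive
(the intercept is only meaningful under a fixed orientation) and uses a
t reference with n−2 df as a small-sample guard. The weighted median
weights per-SNP Wald ratios by inverse first-order delta-method
variances (both the outcome and exposure uncertainty terms) and
bootstraps its se parametrically (default 1000 draws, seeded).

The outlier screen replaces a full MR-PRESSO implementation: a global
test compares the observed leave-one-out weighted residual sum of
squares about the IVW fit with a parametric Monte-Carlo null (default
1000 simulations under the fitted homogeneous model), and per-SNP
leave-one-out residual contributions are flagged at
Bonferroni-corrected Monte-Carlo p < 0.05. Outlier flagging requires at
least 4 instruments; the global test runs from 2.

Odds-ratio reporting applies exp() uniformly to betas and 95% CIs,
treating binary-outcome betas as log-odds.

## SMR and HEIDI

SMR at the top cis-QTL: T_SMR = z²_x z²_y/(z²_x + z²_y) on χ²₁,
b_SMR = β_GWAS/β_QTL, se = |b|·√(1/z²_x + 1/z²_y). Benjamini–Hochberg
FDR is applied across genes within one analysis (one tissue/cohort) at
a time — the scope matching a column-wise evidence table.

HEIDI candidates are SNPs with |z_QTL| ≥ 3.16 (QTL p ≲ 1.6×10⁻³) and r²
with the top SNP in [0.05, 0.9], capped at 20 by descending |z_QTL| —
the conventional settings for this test, all configurable. For each
candidate, d_i = b_SMR(i) − b_SMR(top); the covariance of the d vector
is propagated from the LD correlation matrix and per-SNP sampling
variances by the first-order delta method (QTL and GWAS samples
independent). T_HEIDI = Σ z²_{d_i}. Fewer than 3 candidates → the
p-value is reported missing.

**Null distribution.** T_HEIDI is a weighted sum of 1-df chi-squares
with weights the eigenvalues of the correlation matrix of d. Under
strong LD this spectrum is dominated by one eigenvalue, a regime where
two-moment (Satterthwaite) matching misestimates mid-body probabilities
by up to ~0.07. The package therefore evaluates Imhof's
characteristic-function inversion integral numerically
(`scipy.integrate.quad`; exact up to quadrature error, verified within
0.006 of a 100,000-draw Monte-Carlo oracle on fixed 8-SNP regions),
falling back to a Liu-Tang-Zhang noncentral-chi-square moment match if
the quadrature reports trouble. The plain Satterthwaite variant remains
available as `smr.satterthwaite_p`.

## Colocalization

Wakefield log-ABF per SNP: 0.5[ln(V/(V+w)) + z²·w/(V+w)], V = se²,
with prior effect variance w = 0.2² for both traits (config-exposed;
the z/V formulation means rescaling betas and ses jointly leaves
posteriors unchanged only when w is rescaled by the same square).
Priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the standard single-causal-variant
convention; the evidence grades, not the priors, are the interface the
tiering consumes). All hypothesis mass is accumulated in log space with
log-sum-exp; the H3 cross-term S1·S2 − S12 is computed via
complementary sums and clamped at zero (with a warning) if cancellation
makes it negative. Grades: strong for PP4 > 0.8, moderate for
0.5 < PP4 ≤ 0.8 (printed "Weak" in some report styles), none otherwise;
boundaries strict.

## Mediation MR

Two-step product of coefficients: indirect = β_XM·β_MY, first-order
delta se √(β²_MY σ²_XM + β²_XM σ²_MY); a second-order flag adds the
σ²·σ² cross term. The proportion divides by the total exposure→outcome
MR estimate (not the step-wise sum), reported as a percentage;
negative or >100% proportions are reported verbatim with a note, never
truncated. The batch screen gates step 1 on BH-FDR (default q < 0.05)
and step 2 on nominal p < 0.05, both configurable, and sorts by
|proportion| descending. Proportion confidence intervals treat the
three inputs as independent estimates (delta method on the ratio),
which is adequate when the legs come from non-overlapping samples and
instrument sets.

## Evidence tiering

Criteria are (column, threshold, direction) triples; missing values
never satisfy a criterion. Each HEIDI criterion lists its paired SMR
criterion as a prerequisite: a non-rejected HEIDI test is only evidence
for a shared causal variant where there is an SMR association to
interrogate, so an isolated HEIDI "pass" above a failed SMR is not
credited. This conditional rule is what reproduces the published PDR
evidence table cell-for-cell (11/11 tier labels, 99/99 marks).

Tier 1 requires every criterion; Tier 2 at least four (the strict
"more than four" variant is selectable — under it, genes with exactly
four satisfied criteria drop out of Tier 2); Tier 3 exactly three;
anything weaker is unclassified. Assignment is invariant to gene input
order and monotone under threshold relaxation.

## Synthetic-data generator

Summary statistics are simulated directly from the multivariate-normal
model of marginal z statistics: z ~ N(√n·R·λ, R) for joint
(standardized-genotype) effects λ and LD correlation R, then
back-transformed to the per-allele scale with se = 1/√(2·maf·(1−maf)·n).
Binary outcomes are treated on the log-odds scale with an effective
sample size. This is desk-scale fast and exact for the marginal
distribution, but it does not emulate individual-level features:
no population structure, no imputation error, no missingness patterns,
no allele-frequency/effect-size coupling, and no case-control
asymmetries beyond effective-n scaling. Passing tests therefore
demonstrate correctness of the estimators under the stated sampling
model, not robustness to those real-data artifacts.

Reference panels have AR(1)-like LD r_ij = ρ^|i−j|, either analytic or
as the empirical correlation of n_ref simulated haplotype-dosage
vectors (latent Gaussians), which adds realistic finite-sample noise
without tetrachoric attenuation of the target ρ. Panels are checked
positive semi-definite; a nearest-PSD repair must move the matrix by
Frobenius norm < 10⁻⁶ or generation fails.

Scenario presets and their defaults (the study conditions for all
calibration results):

- **causal / null**: 50–100 independent SNPs, per-SNP standardized
  effects |λ| in [0.03, 0.06] with random signs, n = 100,000 per trait,
  causal effect β_XY = 0.2 (0 for null). Effects of this size give
  instrument F in the hundreds, so weak-instrument bias is negligible.
- **pleiotropy**: as causal, plus a constant offset (default scale
  0.02) added to each instrument's emitted per-allele outcome beta,
  signed with the exposure effect — directional pleiotropy is constant
  relative to the exposure-increasing allele, which is what makes the
  Egger intercept estimand well-defined under variable MAF.
- **shared / linkage**: one cis region of 40–100 SNPs, ρ = 0.9,
  n_ref = 5000; QTL causal effect 0.15 at n = 30,000 (top z ≈ 26),
  GWAS effect 0.036 at n = 50,000 (z ≈ 8) — magnitudes shaped on
  large eQTL panels and a FinnGen-scale binary outcome. Linkage places
  the two causal variants 5 SNPs apart (r ≈ 0.6).
- **mediation**: β_XM = 0.3, β_MY = 0.5, direct effect 0.1, hence
  total 0.25 and mediation proportion 60%; exposure and mediator get
  disjoint instrument sets so the three MR legs are independent.

Everything is deterministic under the mandatory seed; bundles serialize
to the same TSV formats the readers consume, with the ground truth as
JSON and a checksummed manifest.

## Problem sizes

The validation suite and the acceptance script use 500 replicates for
IVW coverage/type-I and for each HEIDI rejection rate, 300 for Egger
recovery and mediation coverage, 200 for the colocalization rate, and
30 end-to-end replicates of a 5-gene bundle (one causal, four decoys,
40-SNP regions) — sizes chosen so Monte-Carlo error is small relative
to the tolerance bands while the whole suite stays desk-scale.

## Known limitations

- Single-causal-variant colocalization only (no SuSiE-style multi-signal
  decomposition, no conditional analysis).
- SMR uses a single top cis-QTL per gene; no multi-SNP SMR.
- The outlier screen is not the published MR-PRESSO distortion test.
- No multivariable MR; the mediation "direct effect" is a generator
  concept, not an estimated quantity.
- LD is externally supplied (or simulated); the package computes no LD
  from genotype data and resolves no rsIDs.
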