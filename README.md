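# tiermr

Multi-omics Mendelian-randomization causal-gene prioritization for GWAS
summary statistics, built around the workflow used to nominate causal
genes for proliferative diabetic retinopathy (PDR): summary-data-based MR
(SMR) with the HEIDI linkage test, two-sample MR with sensitivity
analyses, Bayesian colocalization, two-step mediation MR, and a tiered
evidence-integration rule that reduces everything to a gene × criterion
matrix and a Tier 1/2/3 label per gene.

It is aimed at statistical geneticists and genetic epidemiologists who
work from published summary statistics (disease GWAS plus eQTL/pQTL/mQTL
panels) and want a tested, reproducible implementation of the whole
chain, including a ground-truth simulator for validating every stage
without any external downloads.

## The statistics

**Two-sample MR.** For instruments *j* with exposure effects β̂_Xj (se
σ_Xj) and outcome effects β̂_Yj (se σ_Yj), the package implements the
Wald ratio β̂_Y/β̂_X (single instrument), fixed-effect IVW

> β̂_IVW = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂²_Xj,  w_j = σ_Yj⁻²,

with multiplicative random-effects inflation max(1, √(Q/(n−1))) when
Cochran's Q indicates heterogeneity, MR-Egger regression (the intercept
estimates average directional pleiotropy), the weighted median, and a
simulation-based outlier screen. Instruments are selected at p < 5×10⁻⁸,
LD-clumped at r² < 0.01 within 10,000 kb, and screened at F > 10 with
F = (β̂_X/σ_X)².

**SMR + HEIDI.** At the top cis-QTL, T_SMR = z²_x z²_y/(z²_x + z²_y) is
referred to χ²₁; HEIDI tests whether the SMR ratio is constant across
SNPs in LD with the top SNP (a shared causal variant) or heterogeneous
(linkage), with the null distribution of the deviation statistic — a
weighted sum of χ²₁ — evaluated by Imhof's inversion integral.

**Colocalization.** Per-SNP Wakefield log approximate Bayes factors
0.5[ln(V/(V+w)) + z²w/(V+w)] are combined into posteriors PP0–PP4 over
the five sharing hypotheses; PP4 > 0.8 grades as strong evidence and
PP4 > 0.5 as moderate.

**Mediation.** Indirect effect β_XM·β_MY with delta-method se
√(β²_MY σ²_XM + β²_XM σ²_MY); the mediation proportion is the indirect
effect over the total exposure→outcome MR estimate, reported in percent.

**Tiering.** Nine criteria (three SMR/HEIDI pairs across discovery,
whole-blood and replication analyses, two MR p-values, and PP4 > 0.5)
are thresholded per gene; a HEIDI pass only counts when its paired SMR
criterion is met. Tier 1 = all criteria, Tier 2 = at least four,
Tier 3 = exactly three.

## Worked example

The packaged PDR candidate-gene evidence table ships with the package;
classifying it takes one command:

```
$ tiermr tier --out out/
Tier-1 genes: CTSH
```

`out/tier_report.tsv` contains the full matrix; the first data row is

```
gene  discovery cis pSMR-FDR  ...  coloc PP4  n_satisfied  tier
CTSH  0.0188 √                ...  0.67 √     9            tier1
```

CTSH (cathepsin H) satisfies all nine criteria — FDR-corrected SMR
p < 0.05 with HEIDI p > 0.05 in all three eQTL analyses, MR p < 0.05
against both outcome cohorts, and moderate colocalization (PP4 = 0.67)
— and is the unique Tier-1 gene; ten further genes land in Tiers 2–3.

The same chain runs end to end on simulated data with known truth:

```
$ tiermr simulate --scenario shared --seed 3 --out sim/
$ tiermr smr --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
             --ld sim/ld.tsv --gene GENE1 --out out_smr/
GENE1: b_smr=0.1942, p_smr=2.01e-21, p_heidi=0.495
$ tiermr coloc --trait1 sim/exposure.tsv --trait2 sim/outcome.tsv --out out_coloc/
PP4=1.0000 (strong), n_snps=100
```

Here the simulated region plants one variant causal for both the
molecular trait and the disease, so SMR is strongly significant, HEIDI
does not reject (consistent with a shared variant), and PP4 ≈ 1.

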