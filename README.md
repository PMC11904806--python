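# protmr

Proteome-wide **two-sample Mendelian randomization (MR)** in Python: does a
circulating protein causally influence a disease or cognitive phenotype?
`protmr` is aimed at statistical geneticists who have GWAS summary statistics
for protein levels (pQTLs, e.g. Olink or SomaScan panels) and for outcome
phenotypes (e.g. psychiatric-disorder case-control GWAS), and who want the
full workflow a modern pQTL-MR study runs: instrument selection,
harmonization, a pleiotropy-robust estimator battery, directionality
testing, cross-cohort meta-analysis, two-tier multiple-testing control, and
gene-set enrichment — plus a synthetic-data generator with known ground
truth so every stage is testable without restricted-access data.

## The model

For protein X and outcome Y, each genetic instrument j contributes summary
statistics (β̂_Xj, se_Xj) and (β̂_Yj, se_Yj) from two non-overlapping
samples. Under the instrumental-variable assumptions the per-variant Wald
ratio θ̂_j = β̂_Yj / β̂_Xj estimates the causal effect θ, and the primary
estimator is the inverse-variance-weighted (IVW) mean with delta-method
ratio variances:

    θ̂ = Σ_j w_j θ̂_j / Σ_j w_j,   w_j = 1 / var(θ̂_j),
    var(θ̂_j) = se_Yj²/β̂_Xj² + β̂_Yj² se_Xj² / β̂_Xj⁴   (second-order delta)

with multiplicative random-effects SE inflation max(1, √(Q/(J−1))) from
Cochran's Q. Because horizontal pleiotropy violates the exclusion
restriction, every run also reports a sensitivity battery — robust IVW
(Tukey biweight), MR-Egger with its intercept test for directional
pleiotropy, weighted median, weighted mode, the contamination mixture,
MR-PRESSO (global RSS test, outlier removal, distortion test), and
constrained maximum likelihood (cML) with BIC selection of the invalid
set — and the Steiger test, which compares the variance explained in
exposure vs outcome (r²_j = 2p_j q_j β_j² / (2p_j q_j β_j² + 2p_j q_j se_j² n))
to confirm the causal arrow points protein → phenotype.

Instruments are selected per protein at genome-wide significance
(p ≤ 5×10⁻⁸), classified cis (within ±1 Mb of the encoding gene) or trans,
greedily LD-clumped (r² < 0.01 within 10 Mb), and screened for strength
(F = (β/se)² ≥ 10). Cohorts are combined by fixed-effect meta-analysis;
significance is reported at a Bonferroni tier (α / tests per instrument
class) and a Benjamini–Hochberg FDR tier (within phenotype × class strata).

## Worked example

Simulate a small two-cohort study (3 proteins, 4 phenotypes, known true
effects) and run the full pipeline:

```bash
protmr simulate --out demo --seed 3 --n-proteins 3 --n-instruments 10
protmr run --config demo/config.yaml --out demo/out --seed 3
```

which prints the per-phenotype tallies (tested / FDR-significant /
Bonferroni-significant):

```
BIP: 6 tested, 5 FDR, 5 Bonferroni
CTP: 6 tested, 6 FDR, 6 Bonferroni
MDD: 6 tested, 4 FDR, 3 Bonferroni
SCZ: 6 tested, 4 FDR, 3 Bonferroni
results in demo/out
```

`demo/out/results.tsv` holds one row per protein × phenotype × cohort ×
instrument class with the primary estimate and the whole battery; the first
data row starts:

```
decode_P0000  GENE0000  BIP  decode  cis  10  ivw  -0.109439085316  0.0241781750003  ...  6.00087777999e-06  7.78177875202  0.556278595647
```

read as: protein P0000 on the deCODE-like platform, tested against BIP with
10 cis instruments; IVW estimates θ̂ = −0.109 (SE 0.024, p = 6.0×10⁻⁶) —
higher protein level lowers liability — with no heterogeneity signal
(Q = 7.78 on 9 df, p = 0.56). The simulation's truth table
(`demo/truth.tsv`) carries the generating θ for every such row.
Cross-cohort combination is available as `protmr meta` and gene-set
over-representation of significant proteins as `protmr enrich` (GMT input,
hypergeometric test, BH correction).

The same workflow is available as a library (`protmr.run_study`,
`protmr.run_protein_mr`, `protmr.estimators.*`), which is what the tests
and the acceptance script drive.

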