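# Methods

## Setting and model

`protmr` implements two-sample summary-data Mendelian randomization for
proteome-wide screens. The exposure is a circulating protein measured on a
proteomics platform in one cohort; the outcome is a phenotype GWAS in a
non-overlapping sample. Instruments are pQTLs — variants associated with
the protein at genome-wide significance — and the estimand θ is the effect
of a one-SD change in protein level on the outcome (log odds for binary
phenotypes).

The generative model behind both the estimators and the synthetic-data
module is, per instrument j:

    β̂_Xj ~ N(γ_j, se_Xj²)          SNP → protein
    β̂_Yj ~ N(θ γ_j + α_j, se_Yj²)  SNP → outcome

with α_j a horizontal-pleiotropy term (zero for valid instruments) and all
instruments mutually independent (post-clumping). Standard errors follow
the summary-statistics conventions for a unit-variance trait,
se = 1/√(2pq·n), and for a log-odds-scale case-control GWAS,
se = 1/√(2pq·n_case·n_control/n).

## Harmonization

Exposure and outcome records are aligned onto the exposure effect allele
allowing one allele swap (sign flip + frequency complement) and one strand
complement. Palindromic variants (A/T, C/G) carry no strand information in
their alleles, so they are kept only when both allele frequencies are
informative: present, outside [0.42, 0.58], and on the same side of 0.5
after textual alignment — otherwise dropped as `palindromic_ambiguous`.
This is the conservative standard policy; the 0.42 limit is configurable.
Missing outcome frequency is tolerated for non-palindromic variants.
Genome build is treated as free-text metadata the caller must keep
consistent; there is no liftover. A reported p-value that disagrees with
the two-sided normal p implied by |β/se| by more than 0.5 log10 units
triggers a warning, not a rejection (many GWAS report p from slightly
different tests); the check is skipped when the implied p underflows
float64.

## Instrument selection

Per protein and class: p ≤ 5×10⁻⁸ → cis/trans classification (cis = same
chromosome, within ±1 Mb of the gene body; window configurable) → greedy
best-p-first LD clumping (discard anything with r² > 0.01 within 10 Mb of
a retained variant; ties broken by (p, variant id); variants missing from
the LD panel are treated as unlinked and logged) → F = (β/se)² ≥ 10. The
(β/se)² form is the only F statistic available from summary data alone.
Selection is fully deterministic and reports per-stage retention counts.
Exclusion lists (confounder-GWAS hits, PheWAS hits) do not silently shrink
the main analysis: the pipeline reports the primary estimate both with and
without the listed variants.

## Estimators

* **Wald ratio** (J = 1): θ̂ = β̂_Y/β̂_X; first- or second-order delta SE.
* **IVW** (primary, J ≥ 2): inverse-variance-weighted mean of ratios with
  second-order delta weights by default (first-order by flag).
  Multiplicative random-effects inflation max(1, √(Q/(J−1))) — never
  deflation — is applied for J ≥ 4; fixed-effect for J < 4. Sums use
  exactly-rounded `fsum`, so instrument order cannot perturb the result.
* **Robust IVW**: IRLS Tukey-biweight (c = 4.685) through-origin
  regression of β_Y/se_Y on β_X/se_Y (whose OLS limit is first-order IVW),
  scale = rescaled MAD, sandwich SE. Zero-residual input degenerates
  gracefully to fixed-effect IVW.
* **MR-Egger**: instruments oriented to β_X ≥ 0, weighted regression with
  intercept (weights 1/se_Y²), multiplicative overdispersion floored at 1,
  t(J−2) inference. The intercept estimates the mean directional
  pleiotropy under InSIDE.
* **Weighted median**: interpolation of ordered ratios at standardized
  cumulative weight 0.5; SE by parametric bootstrap of (β̂_X, β̂_Y)
  (default 1000 draws, seeded). Note the bootstrap is mildly conservative
  for this order statistic: resample centers already contain one noise
  realization, which flattens the density at the median; measured type-I
  error at α = 0.05 is ≈ 0.029 under the null scenario below (mean-like
  estimators in the same runs sit at 0.03–0.05).
* **Weighted mode**: argmax of a weighted normal-kernel density over the
  ratios; bandwidth = φ · 0.9 · min(sd, 1.4826·mad) · J^(−1/5) (φ = 1
  default); two-stage grid search with a 10⁻⁴ final step; bootstrap SE.
* **Contamination mixture**: per grid θ each instrument takes the better
  of a valid component N(θ̂_j; θ, se_j²) and an invalid component
  N(θ̂_j; 0, se_j² + ψ²); ψ defaults to 1.5 × SD of the ratios; the 95% CI
  collects grid points within χ²₁(0.95)/2 log-likelihood of the maximum
  (may be disjoint; segment count reported). The default grid covers the
  ratio range +25% (at least [−2, 2]); a boundary maximum is logged. The
  reported SE is the CI width / (2·1.96) and the p-value is the normal
  approximation on that scale — an approximation, flagged here because the
  profile likelihood can be multimodal.
* **MR-PRESSO**: observed statistic = weighted RSS of outcome effects
  against leave-one-out IVW predictions; null distribution from n_sim
  parametric resimulations (leave-one-out fits recomputed per
  resimulation); per-instrument outlier p Bonferroni-corrected across J
  (note the smallest attainable corrected p is J/(n_sim+1), so flagging at
  α requires n_sim > J/α); corrected estimate = IVW on non-outliers;
  distortion p against removals of random same-sized subsets.
* **cML**: constrained Gaussian likelihood with exactly K free pleiotropy
  parameters; coordinate ascent (invalid set = K largest standardized
  residuals given θ; θ = WLS slope on the valid set given the invalid
  set) from multiple deterministic starts (full-data WLS, median ratio,
  every individual ratio) because the single-start alternation can stall
  in local optima under heavy contamination. K selected by
  BIC = 2·negloglik + K·log(n), with n the smaller GWAS sample size when
  known (the pipeline supplies it) and J otherwise. This is the
  BIC-selection variant: no model averaging or data perturbation.
* **Steiger**: per-variant r² = 2pq β²/(2pq β² + 2pq se² n) summed per
  side; direction = the side explaining more variance; inference by
  Fisher-z comparison of the two multiple correlations with the two
  sample sizes. The binary-outcome r² uses the observed-scale
  approximation and is flagged as such.

Battery minimum instrument counts: 2 (IVW), 3 (Egger, medians/modes,
ConMix, cML, robust IVW), 4 (PRESSO). A single-instrument run reports the
Wald ratio and an empty battery.

## Pipeline

Per protein × phenotype × cohort × class, the pipeline selects,
harmonizes, estimates, runs the battery, computes Steiger, and sets flags
(`single_instrument`, heterogeneity p < 0.05, Egger intercept p < 0.05,
Steiger p > 0.05, reverse-MR significant). Reverse MR (phenotype as
exposure, protein as outcome) is triggered for runs with an uncertain
Steiger verdict (configurable to always/never); the forward run's
instruments are excluded from the reverse candidate pool so the reverse
estimate is not driven by the very variants under scrutiny.

Cross-cohort meta-analysis is fixed-effect inverse-variance on the primary
estimates, keyed by gene symbol (platform assay ids differ); multi-aptamer
collisions keep the assay with the most instruments, logged. Significance
tiers: Bonferroni α = 0.05 / (tests actually run), counted separately for
cis and trans; BH-FDR within phenotype × class strata, with the realized
per-stratum threshold reported. Because the class-wide Bonferroni cut is
at most the stratum-wise α/m, Bonferroni ⇒ FDR holds structurally.
Per-unit random seeds derive from (master seed, protein, phenotype,
cohort, class) via CRC32, so results are bit-reproducible and adding units
never perturbs existing ones.

Enrichment is the hypergeometric upper tail (= one-sided Fisher) of a
query gene list against GMT sets with BH correction; the background
defaults to the proteins actually tested (the selection universe), not the
genome, to avoid inflating enrichment.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical skeleton of a two-platform
pQTL-MR study: per-protein independent instruments whose true effects are
rescaled to a target total variance explained; exposure/outcome sampling
noise from the se formulas above; pleiotropy regimes (balanced,
directional, correlated-with-strength/InSIDE-violating) on a configurable
fraction of instruments; binary outcomes on the log-odds scale with the
study's case/control counts (defaults: SCZ 67,323/93,456; BIP
40,463/313,436; MDD 166,773/507,679; CTP quantitative n = 215,333;
exposure panels n ≈ 34,600); two cohorts whose per-protein causal effects
are drawn equicorrelated (ρ_c, default 0.5, matching the moderate
cross-platform concordance such studies report) with platform-specific
variants; optional phenotype-own polygenic instruments and a
reverse-causal mode in which the protein responds to phenotype liability.

Design choices worth stating:

* **Per-variant effect law** — default `selected_normal`: N(0,1)
  conditioned on |·| ≥ 0.5, then rescaled. Instruments in this design are
  genome-wide-significant by construction, so near-zero effects cannot
  occur; an unconditioned normal admits them, and their random observed
  sign structurally attenuates the Egger intercept (a selection artifact
  the real study cannot exhibit). `normal` and `equal_r2` are available.
* **Directional pleiotropy orientation** — α is applied on the
  exposure-increasing allele (multiplied by sign(γ)); a nonzero α mean on
  an arbitrary allele orientation cancels in expectation.
* **No LD by default** — instruments are independent by construction,
  matching the post-clumping assumption of every estimator; an LD matrix
  path exercises clumping when supplied. No individual-level genotypes.

What passing tests therefore do **not** show about real data: robustness
to residual LD and proxy instruments, to winner's-curse bias from
selecting instruments in the same sample that estimated them, to sample
overlap between exposure and outcome GWAS, to population stratification,
or to assay-specific artifacts (epitope effects are modeled only as an
effect-size correlation < 1 between platforms).

## Simulation sizes and numerical choices

Property checks (tests/test_acceptance.py and scripts/acceptance.py) use:
null calibration θ = 0, J = 30, n = 30,000, r² = 0.05, 1000 reps (PRESSO
500 reps, n_sim = 1000); recovery θ = 0.3, J = 50, r² = 0.25 (mean F ≈
150 — "strong instruments" is taken to mean the 1/F attenuation intrinsic
to two-sample MR is negligible), 500 reps; pleiotropy-bias comparison 30%
invalid, α ~ N(0.05, 0.01²) oriented, 200 reps, PRESSO n_sim = 2000;
Egger-intercept recovery J = 100, all instruments pleiotropic, 200 reps;
planted invalid-set fixtures J = 12, maf 0.3–0.5, n = 500,000, pleiotropy
mean 0.5 (ratio SEs ≪ the pleiotropy offset, so exact recovery is a fair
ask); directionality r²_exposure = 0.05, n = 30,000, 200 reps each
direction; determinism on a 20-protein, 4-phenotype, 2-cohort bundle;
concordance on 300 proteins with ρ_c = 0.5. The bundled study runs the
battery with n_boot = 300 and PRESSO n_sim = 300; estimator defaults are
1000 both.

Degenerate inputs: zero β_X instruments are unusable for ratios and
excluded with the count visible; zero-residual robust IVW returns the
fixed-effect IVW; Egger with se = 0 and estimate 0 reports p = 1; empty
strata produce no FDR threshold and no error; a protein with no surviving
instruments yields a skip record, never a crash.

## Known limitations

ConMix p-values are normal approximations from a profile-likelihood CI.
The weighted-median test is mildly conservative (see above). cML here is
the BIC-selection variant, not the model-averaged/data-perturbation
variant. Reverse MR in a bundled synthetic study requires the outcome
table to contain phenotype instruments; with pQTL-only tables it reports
a skip. Bootstrap SEs of the stochastic estimators depend on the seed and
instrument ordering at O(n_boot^(−1/2)); point estimates do not.
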