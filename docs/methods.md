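# Methods

`genemeta` implements a complete case-control genetic-association
meta-analysis for a biallelic G>A variant: per-study 2x2 contrasts under
five genetic models, fixed- and random-effects pooling, heterogeneity,
Hardy-Weinberg checks, publication-bias diagnostics, leave-one-out
sensitivity and multiplicity adjustment. This note records the models,
the numerical choices, and what the synthetic-data generator does and
does not emulate.

## Genetic-model contrasts

Each study contributes genotype counts (GG, GA, AA) per arm. The five
contrasts map these to an exposed/unexposed 2x2 table with the usual
a/b/c/d cells (exposed cases, unexposed cases, exposed controls,
unexposed controls):

| model | exposed | unexposed |
|---|---|---|
| allele | A alleles = GA + 2·AA | G alleles = 2·GG + GA |
| dominant | GA + AA subjects | GG subjects |
| recessive | AA subjects | GA + GG subjects |
| homozygote co-dominant | AA | GG (GA excluded) |
| heterozygote co-dominant | GA | GG (AA excluded) |

The allele model treats alleles as independent observations (2n per
subject arm), the standard convention for this design. No additive /
log-additive trend model is provided.

A continuity correction of 0.5 is added to **all four cells** of a table
that contains a zero cell, and only to that table. Corrected tables feed
the per-study (inverse-variance) effects; the Mantel-Haenszel sums always
use the uncorrected counts, because the MH estimator is well defined with
zero cells. An all-zero table is rejected at construction (n > 0 is a
type invariant).

## Per-study effects and pooling

Per-study effect: y = ln(ad/bc) with Woolf standard error
se = sqrt(1/a + 1/b + 1/c + 1/d). 95% intervals are Wald,
exp(y ± 1.96·se); the literal 1.96 quantile is used throughout, matching
the convention of the standard meta-analysis packages at reporting
precision.

Fixed effect is Mantel-Haenszel: OR_MH = Σ(a_i d_i/n_i) / Σ(b_i c_i/n_i),
with the Robins-Breslow-Greenland variance for ln(OR_MH). RBG is the
consistent variance both in sparse-data and large-stratum limits and is
what Stata's `metan` and statsmodels' `StratifiedTable` use; our
implementation is cross-checked against the latter in the test suite.
Inverse-variance fixed pooling (w_i = 1/se_i²) is provided as a
cross-check and as the anchor for Cochran's Q.

Heterogeneity: Q = Σ w_i (y_i − ŷ_IV)² with inverse-variance weights
around the IV-fixed pooled estimate (the conventional pairing even when
the reported pooled OR is MH), df = k−1, I² = max(0, (Q−df)/Q)·100, and
the DerSimonian-Laird moment estimator
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)). Random-effects pooling re-weights
with w*_i = 1/(se_i² + τ²) and reduces exactly to IV fixed when τ̂² = 0.
For k = 1, Q = I² = τ² = 0 by convention.

Method selection follows the common I² rule: DL random effects when
I² strictly exceeds the threshold (default 50%), MH fixed otherwise. A
tie at exactly the threshold goes to fixed — the less-parameterised
default; in the bundled analysis every row is far from the boundary, so
the tie-break is never exercised there.

Significance of the pooled OR is the Wald Z test, p = 2(1−Φ(|z|)).
Power for a hypothesised log OR uses the noncentral-normal expression
(Hedges-Pigott): with λ = y/se, power = 1 − Φ(z₁₋α/₂ − λ) + Φ(−z₁₋α/₂ − λ).

## Hardy-Weinberg tests

The default test is the Pearson chi-square on the three genotype
classes against ((1−q)², 2q(1−q), q²) at the estimated allele frequency,
1 df (three classes minus one minus one estimated parameter), no
continuity correction — this reproduces the bundled table's printed
p-values at their 2-decimal precision. The exact conditional test
(heterozygote count given allele counts; p-value sums configurations no
more probable than the observed) is available as an option and agrees
with the chi-square on every significance call across the bundled
collection. Monomorphic arms are flagged, not errors (χ² = 0, p = 1).

## Publication bias and sensitivity

Egger's test is OLS of the standard normal deviate y_i/se_i on the
precision 1/se_i, intercept tested with t on k−2 df — algebraically the
classic weighted regression of y on se with weights 1/se². A degenerate
fit (constant deviate) returns a flagged result rather than an error.
Begg's test standardises deviates against the IV-fixed pooled value,
v_i = (y_i − ŷ)/sqrt(se_i² − se_pooled²) (variance differences are
floored at 1e−12 and flagged if clamped), and computes Kendall's tau by
explicit pair counting with tie correction; the default normal statistic
carries no continuity correction, with the |S|−1 corrected variant
available as a flag (published Begg p-values in this literature usually
correspond to the corrected form; both lead to the same qualitative
calls here). Both tests require k ≥ 3.

Leave-one-out sensitivity re-pools the remaining k−1 studies for each
omission, re-selecting the method by the I² rule each time.

Funnel data export gives the (y_i, se_i) points sorted by se and a
pseudo-95% envelope ŷ ± 1.96·se on an se grid from 0 (zero width) to the
largest observed se.

## Multiplicity

The adjustment family is the five genetic-model tests within one
population category (m = 5): Bonferroni (p·m capped at 1) and
Benjamini-Hochberg step-up FDR (min over j ≥ i of m·p₍ⱼ₎/j, capped,
mapped back to input order). This family definition is the one uniquely
consistent with the bundled analysis's published adjusted columns.
A run restricted to a subset of models reports raw p only. Note that
BH adjustment is not idempotent in general; the invariants that do hold
(raw ≤ FDR ≤ Bonferroni ≤ 1 elementwise; rank preservation) are tested.

## Reporting conventions

ORs and CI bounds are reported to 3 decimals, p-values to 3 decimals,
I² to 1 decimal — the precision at which such tables are conventionally
printed. Adjusted p-values in the pipeline are computed from the
*unrounded* raw p-values; reconstructing adjusted columns from an
already-rounded printed p column can therefore differ in the last digit
(e.g. 5 × 0.0339 = 0.169 vs 5 × 0.034 = 0.170). Subgroup bias tests are
computed for any category with k ≥ 3 and reported as NA below that.

## Synthetic-data generator

The generator emulates the genotype-count structure of an East-Asian
candidate-gene meta-analysis. Defaults: k = 12 studies, 500 subjects per
arm, control minor-allele frequency 0.25, null genotype effects, τ² = 0,
controls in HWE, no publication bias — sizes and MAF chosen to resemble
the bundled collection (studies of 161–3675 subjects, control MAF
0.15–0.36).

Controls are multinomial draws from HWE proportions, optionally
perturbed by an inbreeding-like coefficient F (P(GG) = (1−q)² + Fq(1−q),
P(GA) = 2q(1−q)(1−F), P(AA) = q² + Fq(1−q)). Cases are multinomial draws
from the control proportions re-weighted by (1, e^{ln OR_het + u},
e^{ln OR_hom + u}) and renormalised, where u ~ N(0, τ²) is a single
shared per-study shift. Because u enters both genotype log ORs equally,
the **dominant**-model log OR inherits the shift exactly (between-study
variance τ², the structure DL assumes); the allele-model log OR inherits
it only partially, through the carrier frequency. Parameter-recovery
tests therefore target the dominant contrast for τ² and the allele
contrast for the effect size under multiplicative effects
(OR_hom = OR_het²), where the allele-model OR equals the per-allele OR.

Publication bias is selection-on-significance thinning: candidate
studies whose dominant-model Z falls short of 1.96 are kept with
probability exp(−bias_strength · (1.96 − z)), and drawing continues
until k studies are retained. This thins small null studies, producing
the funnel asymmetry Egger's regression targets, while keeping the
mechanism one-parameter and reproducible. All randomness flows from the
single integer seed through one `numpy.random.Generator`.

Ways the generator is simpler than real data: no covariates or
gene-environment interaction (strata are label-only), no genotyping
error, no allele-frequency drift across countries, and selection acts
on a single model's Z score. Passing calibration tests therefore shows
the estimators behave correctly under the model's own assumptions, not
that those assumptions hold in any particular literature.

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to make Monte-Carlo noise small
relative to the asserted tolerance: HWE type-I error over 1000 simulated
arms; Egger type-I error over 1000 replicates of k = 15 studies with
sizes log-spaced 50–2000; effect recovery over 30–40 replicates of
k = 20–25 studies at 2000–4000 per arm. Thresholds on type-I error
([0.03, 0.08] for HWE, [0.02, 0.09] for Egger) bracket the nominal 5%
with the binomial noise of those replicate counts.

## Known limitations

- No Peto odds ratio, REML/Paule-Mandel τ², Hartung-Knapp adjustment, or
  trim-and-fill — the pipeline mirrors the classic Stata-style toolkit.
- Wald intervals and Z tests only; exact/profile CIs are out of scope.
- The bundled fixture carries a known source discrepancy: one study's
  case total is printed inconsistently in its source (697 vs 696); the
  genotype counts (totalling 696) are treated as ground truth and the issue is
  recorded in `BUNDLED_TABLE2_NOTES`.
- The dominant-model-only collapsed-count path cannot reproduce the
  source's stratified numeric results (those per-study counts were never
  published); it is validated by parameter recovery on synthetic strata
  instead.
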