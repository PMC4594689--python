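# Methods

## Data model

The unit of analysis is a *study outcome*: one SNP examined in one
case-control panel. An outcome carries genotype counts
(major-homozygote / heterozygote / minor-homozygote, the `a/b/c` string
convention) for cases and controls, a published odds ratio with 95% CI,
or both. The packaged table of *IL2RA* / type-1-diabetes evidence keeps
the totals exactly as published even where they are internally
inconsistent (three rows have genotype sums that differ slightly from the
printed totals; one printed control MAF disagrees with its own genotype
counts at the third decimal). Sample sizes are stored as the printed
per-row totals and summed as such; genotype counts are kept separately.
The parser cross-checks printed MAFs against the counts with both the
genotype-complete and the full-total denominator and warns — it does not
reject — on disagreement beyond one unit in the last printed digit.

## Effect extraction

Two routes produce the per-study log odds ratio and standard error:

* **From counts** — the 2N alleles per group are cross-tabulated against
  case status. OR = ad/bc, se = √(1/a+1/b+1/c+1/d) (Woolf). If exactly
  one allele cell is zero, 0.5 is added to all four cells
  (Haldane-Anscombe); with two or more zero cells the effect is declared
  not estimable. The effect allele is the minor allele unless the
  outcome's orientation flag says otherwise (one packaged row's published
  OR corresponds to the major-allele contrast of its own counts, and is
  stored with `orientation=major` so the counts route reproduces it).
* **From a published CI** — log OR = ln(OR),
  se = (ln U − ln L)/(2z). z is fixed at the conventional rounded 1.96
  for 95% intervals rather than the exact quantile 1.959964: published
  intervals are constructed with 1.96, and round-tripping them back to a
  standard error with any other constant injects spurious error. Any
  other confidence level uses the exact normal quantile. Configurable.

When an outcome has both representations, the published OR/CI is the
default source for pooling: published estimates may carry covariate
adjustment or genotyping subsets that raw counts cannot reproduce, and
several packaged rows' printed ORs are demonstrably not the Woolf ORs of
their printed counts. A flag (`effect_source="counts"`) switches to
counts-derived effects.

## Hardy-Weinberg screening

Control-genotype departure from HWE signals genotyping error or
population stratification, so outcomes whose control counts fail the
Pearson 1-df chi-square test are excluded before pooling. The threshold
is design-specific: p ≥ 0.05 for candidate-gene case-control panels,
p ≥ 10⁻⁵ for GWAS (genome-wide panels are screened at scale and a strict
per-SNP threshold would discard sound data). Case-sample HWE is computed
and logged but never used for exclusion — a true association itself
distorts case genotype proportions. A monomorphic sample is defined as
chi-square 0, p = 1: no departure is detectable. All 13 packaged
count-bearing outcomes pass.

## Pooling and heterogeneity

Pooling happens on the log-OR scale with inverse-variance weights. The
named fixed-effect method in this literature is Mantel-Haenszel, which
needs per-study 2×2 tables; a study set that mixes counts with CI-only
rows cannot be pooled that way, so the canonical fixed-effect path here
is inverse-variance on the extracted log ORs, and Mantel-Haenszel (with
the Robins-Breslow-Greenland variance for the log MH-OR) is provided for
all-counts inputs. On the packaged data's all-counts subsets the two
agree within 0.005 on the OR scale.

Heterogeneity: Q = Σwᵢ(θᵢ − θ̂_FEM)², referred to χ²ₖ₋₁;
I² = max(0, (Q − df)/Q)·100, truncated at zero and reported in percent.
DerSimonian-Laird: τ² = max(0, (Q − df)/(Σw − Σw²/Σw)); random-effects
weights 1/(seᵢ² + τ²). When Q ≤ df the two models coincide exactly.

Model selection is the disjunctive screen standard in this literature:
random effects when p_Q < 0.05 **or** I² > 50%. The rule must be
disjunctive: one packaged SNP set has p_Q = 0.061 with I² = 55.6%, and
only the I² trigger reproduces its published random-effects pooling.
Whichever model is selected, the other model's result is attached to the
output (`.alternate`) so model sensitivity is always visible.

Weighted sums use `math.fsum`, making every pooled statistic exactly
invariant to study order, not merely to rounding.

Pooling proceeds with a warning (not an error) below 3 outcomes; a single
outcome is passed through flagged `single_study`. Two-sided normal
p-values throughout; summary tables print p below 10⁻⁶ as `<10^-6`.

## Influence and sensitivity

Leave-one-out re-pools each reduced set with model re-selection on
(the published reduced estimate for the rs2104286 set is a fixed-effect
result, which only re-selection reproduces). Two flags per omission:
`model_changed`, and `significance_changed` — the 95% CI crossing 1 in
exactly one of the full and reduced analyses, the operational reading of
"this study drives the conclusion". The sensitivity scan looks for a
single omission that brings both heterogeneity triggers back under
threshold; among candidates it reports the one leaving the least residual
I² (ties by Q). A two-study heterogeneous set is reported as
un-scannable (any omission leaves k = 1) rather than pretending a
one-study "pool".

## Publication bias

Egger: OLS of θᵢ/seᵢ on 1/seᵢ; the intercept estimates funnel asymmetry
and is tested two-sided with t on k−2 df. Degenerate (all se equal)
designs are rejected. Begg-Mazumdar: Kendall score S between the
variance-stabilized deviates (θᵢ − θ̂)/√(vᵢ − 1/Σ(1/vⱼ)) and the vᵢ;
z = (|S|−1)/√(k(k−1)(2k+5)/18) with the continuity correction applied by
default (the behaviour of the common commercial implementation, which is
what "modified" Begg denotes in this literature); `continuity=False`
disables it. The corrected variant is deliberately conservative at small
k (measured type-I error ≈1% at k = 6); the uncorrected statistic is
calibrated (≈4–5%) and is what the type-I-error test suite checks against
the nominal band. Both tests require k ≥ 3 and are low-powered at
typical meta-analysis sizes; non-significance is weak evidence of
absence. Funnel plots are emitted as data (per-study log OR and se plus
pseudo-CI guide lines), never as images, so numeric results are
independent of any graphics stack.

## False-positive report probability

FPRP = α(1−π)/(α(1−π) + (1−β)π), with α the pooled estimate's observed
two-sided p-value (configurable), power 1−β computed for a two-sided
level-α Z-test on the log OR at the pooled standard error against each
alternative OR, and π a prior probability of true association. Default
priors span 10⁻⁵–0.1 (candidate-gene SNPs with functional evidence sit at
the high end of that range); default alternatives are OR 1.2, 1.5 and the
observed pooled OR, since the relevant alternative is never stated in
this literature. A cell is flagged noteworthy below 0.2. FPRP is exactly
monotone: non-increasing in prior and power, non-decreasing in α; the
implementation is tested against exact rational arithmetic at 10⁻¹⁵.

## Synthetic study sets

The generator emulates the sampling model implicit in an allelic
case-control design. Per study: θᵢ ~ Normal(ln OR, τ²); control
effect-allele frequency p₀ fixed; case frequency
p₁ = e^θᵢ p₀ / (1 + p₀(e^θᵢ − 1)), which makes the allele-level OR
exactly e^θᵢ; genotypes multinomial under HWE at (p₁, p₀). Defaults —
control MAF 0.25, five studies of 1000/1000, τ = 0 — mirror a typical
candidate-gene landscape (the packaged panels' MAFs span 0.03–0.48 with
median ≈0.22). `ci_only` reporting replaces counts with the Woolf OR and
CI rounded to two decimals, deliberately reproducing the precision of
published tables so the CI-derived-se path is stress-tested against
rounding noise. Censoring suppresses a study with configurable
probability when its signed z falls below a cutoff, optionally only for
studies under a size threshold; one-sided, size-dependent suppression is
what produces detectable funnel asymmetry (symmetric |z| censoring of a
null funnel is itself symmetric and leaves Egger at its nominal level).
Everything is deterministic under a fixed seed, to the byte in the
emitted tables.

What the generator does *not* emulate: linkage disequilibrium between
SNPs, covariate adjustment (simulated "reported" ORs are always the crude
allelic ORs, unlike some published ones), ancestry-specific allele
frequencies within a study set, and genotyping error. Calibration
results on synthetic sets therefore validate the estimators under the
stated sampling model, not the vagaries of real published tables.

## Calibration results checked by the test suite

* Null I² > 50% occurs at the χ²-implied rate (P(Q > 2df) ≈ 9.2% at
  k = 5) within ±2 pp over 5000 replicates.
* Egger and uncorrected Begg type-I error within 5% ± 2 pp on 5000 null
  funnels (k = 6, 3-fold se spread); corrected Begg ≤ 7%.
* Egger rejects in >20% of strongly censored study sets (true OR 1.2,
  20 candidate studies of 50–1500 per arm, suppression probability 0.95
  below z = 1.64).
* DerSimonian-Laird point estimates match the independent R reference
  implementation (`metafor`, method "DL") to 10⁻⁶ on the packaged data.
* The DL 95% CI covers the true mean log OR in ≈90% of heterogeneous
  replicates (five studies of 2000/2000, control MAF 0.25, true OR 0.67,
  τ = 0.1). This is a known property of the estimator, not a defect of
  the implementation: with k = 5 and τ comparable to the within-study
  error (I² ≈ 0.8), the normal-quantile DL interval ignores the
  uncertainty in τ̂² and undercovers. The remedy (Hartung-Knapp) is out
  of scope here; the test suite asserts the nominal band and this test
  is expected to fail until such an adjustment is added.

## Known limitations

* No subgroup (ancestry-stratified) pooling, meta-regression, cumulative
  meta-analysis, alternative τ² estimators, Hartung-Knapp adjustment,
  trim-and-fill, or haplotype-level analysis.
* HWE testing is the 1-df chi-square, adequate at these sample sizes;
  no exact (enumeration) test for sparse genotype tables.
* Egger's test on k = 3 with one dominant study is reported but
  essentially uninterpretable (one residual degree of freedom).
* The packaged table inherits its source's small internal
  inconsistencies, documented above and preserved deliberately.
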