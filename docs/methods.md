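# Methods

## The design and its statistics

The package analyses full sibling pairs selected for extreme discordance
in a quantitative trait (here blood pressure). At any locus a full-sib
pair shares 0, 1 or 2 alleles identically by descent (IBD) with prior
probabilities (¼, ½, ¼); the proportion shared, π = IBD/2, has null mean ½
and variance 0.125. If a locus contributes to the trait, pairs from
opposite tails of the trait distribution are enriched for low IBD there,
so E[π | extreme discordant] < ½. The package quantifies linkage three
ways:

1. **Haseman–Elston regression.** The squared within-pair difference of a
   phenotype (SBP, DBP or pulse pressure PP = SBP − DBP, in mmHg²) is
   regressed on the expected number of alleles shared IBD at a marker,
   f₁ + 2f₂ from the IBD posterior. Linkage predicts a negative slope;
   the one-sided p-value uses the t distribution on n − 2 df. Using the
   sharing proportion π̂ instead of the expected allele count doubles the
   slope and changes nothing else (tested).
2. **Pearson correlation.** The same pairs (y, x) summarised as r with the
   exact two-sided p from t = r√(n−2)/√(1−r²). At n = 24 this transform
   reproduces the printed reference values r = −0.51 → p = 0.011 and
   r = −0.44 → p = 0.031 to three decimals. A standardized multiple
   regression (marker sharing + pair mean age + number of male sibs)
   reports covariate-adjusted betas, per-term p-values and adjusted R².
3. **Allele-sharing likelihood-ratio test.** Each informative pair
   contributes prior-free weights w_k ∝ L_k (the genotype-pair likelihoods
   below, renormalized); the sharing distribution z = (z₀, z₁, z₂) is
   estimated by maximum likelihood of Π_pairs Σ_k z_k w_k over the
   simplex, and LR = 2[log L(ẑ) − log L(¼, ½, ¼)]. With
   `direction="deficit"` the MLE is constrained to z₀ ≥ ¼, z₂ ≤ ¼ (the
   one-sided alternative appropriate to discordant pairs — the lower edge
   of the "possible triangle" reasoning).

## IBD estimation without parents

Only offspring are genotyped. For a marker in Hardy–Weinberg equilibrium
with allele frequencies p_a, the likelihoods of an unordered sib genotype
pair given IBD state are closed forms: under IBD 0 the genotypes are
independent HWE draws; under IBD 1 one shared allele x is drawn from the
population and each sib completes its genotype with an independent draw,
L₁ = Σ_x p_x h(g₁, x) h(g₂, x); under IBD 2 identical genotypes occur with
their HWE probability. The posterior combines these with the (¼, ½, ¼)
prior. These forms are verified exhaustively (all genotype pairs at 2–4
allele markers, random frequency vectors) against an independent oracle
that enumerates every ordered parental genotype pair and all 16 equally
likely transmission patterns, to < 10⁻¹² absolute error.

Allele frequencies default to naive gene counting over all genotyped
individuals (two observations per non-missing genotype). Sib correlation
makes these counts mildly non-independent; the bias is second order and an
external frequency table can be supplied instead. A genotype containing an
allele absent from the table is an error, never silently smoothed; missing
genotypes make a pair uninformative at that marker (pairwise-complete
analysis).

## The synthetic cohort

`synthetic_data.simulate_families` draws, per family, two parents under
HWE at a biallelic QTL (high-allele frequency p_Q) and each marker, then
two offspring by gamete transmission that tracks grandparental origin
jointly at the QTL and every marker: a gamete recombines between QTL and
marker with probability θ, and markers are conditionally independent given
the QTL (single-point, matching the per-marker analysis; there is no
marker–marker map). True IBD at each locus is recorded from the origin
labels. Phenotypes are genotype mean (−a, d, +a for qq/Qq/QQ, mmHg) plus a
polygenic deviate (a shared N(0, σ²_A/2) component plus an independent
N(0, σ²_A/2) per sib, the standard full-sib additive covariance) plus an
individual environmental deviate; SBP and DBP environmental deviates are
bivariate normal with correlation 0.5 by default. PP = SBP − DBP exactly.
Parental genotypes exist internally and `mask_parents` removes them to
emulate an offspring-only study.

Defaults describe the cohort the package emulates: mean 125/77 mmHg, SD
18/13 mmHg, sib ages N(39.8, 7.8²) truncated at 18, sexes balanced. The
trait architecture is not identified by any published estimate, so the
default split — QTL 30%, polygenes 30%, environment 40% of variance, p_Q =
0.5, purely additive — is an illustrative choice made once;
`TraitModel.from_variance_fractions` builds any other split (the additive
effect solves V_QTL = 2p(1−p)a²). The simulator reproduces the marginal
moments and the (¼, ½, ¼) IBD prior (moment-matched in tests) but not
several features of real cohorts: no genotyping error, no microsatellite
mutation, no age/sex effects on BP, no treatment, and sibships fixed at
two. Passing tests therefore validate the statistical machinery, not
field performance on real pedigrees.

## Ascertainment

`classify_pair` applies strict inequalities as printed: extreme
discordance by the threshold rule (one sib SBP > 139 or DBP > 85; the
other SBP < 112 or DBP < 66 mmHg) or the difference rule (ΔSBP > 25 and
ΔDBP > 20 mmHg); the 15/14 screen defines plain discordance. The "25/20"
notation is read as requiring both margins (an `or_rule` switch relaxes
this, since the notation is ambiguous). The threshold rule is evaluated
first, so pairs satisfying both are attributed to it. The affected sib is
the higher-SBP sib, ties broken by DBP then id, for determinism. Centile
thresholds (nearest-rank percentiles of a reference sample, default
10th/90th) are available as an alternative classifier and are the default
selection in the power module, where the Risch–Zhang tail framing is the
natural one.

## Power module

`conditional_sharing` simulates pairs, applies the design's selection
(EDSP opposite-decile, ASP both-upper-tail, or the mmHg criteria) and
returns the moments of true π among retained pairs with a Monte-Carlo SE.
`required_pairs` uses the one-sided normal approximation for testing mean
sharing against ½ with fully informative markers,
n = ((z₁₋α√0.125 + z_pow√var(π̂)) / |½ − E[π̂]|)², rounded up (a
marker-informativeness deflation can be emulated by inflating the null
variance). An unselected design has E[π] = ½ exactly, so sizing it by mean
sharing is degenerate; its natural test is Haseman–Elston regression on
random pairs, sized by the Fisher-z approximation
n = ((z₁₋α + z_pow)/atanh|ρ|)² + 3 with ρ = corr(Δ², π) estimated in the
same Monte-Carlo run. `fold_reduction` is the ratio of the two (unrounded,
since integer ceilings would dominate when the EDSP design needs only a
handful of pairs). For a QTL explaining half the variance, decile EDSP
selection yields E[π̂] ≈ 0.18 and a ~20–35× saving over the unselected
design — consistent in direction and order of magnitude with the classical
extreme-selection argument.

A note on Haseman–Elston *within* the selected sample: selection
concentrates pairs at IBD 0 and restricts the range of the squared
difference, so the within-sample correlation between Δ² and π is only
about −0.19 even for a QTL explaining half the variance (measured on
3×10⁵ simulated pairs; analytically, cov(Δ², π) = −V_QTL·Var(π) for an
additive locus). At 24 pairs the one-sided HE test then rejects in roughly
13–15% of replicates and the slope is negative in ~71–75% — the sharing
deficit itself (mean π̂ ≈ 0.25) is far easier to detect with the
mean-sharing or LRT deficit test than with the within-sample regression.
The replicate experiments in `power.he_replicate_experiment` report all
three quantities.

## Numerical choices

- **LRT maximization:** EM on the mixture weights (monotone, handles
  boundary MLEs such as ẑ = (1, 0, 0) exactly); the deficit-constrained
  MLE falls back to SLSQP with bounds z₀ ∈ [¼, 1], z₂ ∈ [0, ¼] only when
  the EM solution violates the constraints. LR is clamped at 0.
- **Permutation null for the LRT:** each pair's weights are re-drawn as
  fully informative IBD states from the (¼, ½, ¼) prior (a closed-form
  multinomial statistic, vectorised). This is exact for highly polymorphic
  markers (the intended use: CA repeats with heterozygosity ≈ 0.9) and
  conservative for weakly informative ones, because observed weights are
  shrunk toward the prior while null draws are not. p = (1 + #{LR* ≥
  LR})/(B + 1), B ≥ 1000 by default, seeded.
- **Degenerate inputs:** constant sharing or constant phenotype raises an
  undefined-correlation error rather than returning r = 0; a perfect fit
  (zero residual) yields one-sided p ∈ {0, 1} by slope sign; collinear
  adjusted-regression designs (condition number > 10⁸ or a constant term)
  are an error naming the terms. Correlation tests need n ≥ 3 (df ≥ 1).
- **p-values:** raw, unadjusted p-values are primary; a Bonferroni column
  is emitted in the results table for reference but never used for
  gating. Tables round to 12 significant digits on disk; machine output
  keeps full precision.
- **Determinism:** every stochastic routine takes an explicit seed;
  pipeline reruns are byte-identical (tested).

## Problem sizes

The replicate experiments use 2,000 replicates × 24 pairs for null
calibration and 500 replicates for EDSP signal detection (pair pools of
~10⁴ per replicate, vectorised); power comparisons use 5×10⁴ simulated
pairs. These sizes give Monte-Carlo SEs below 0.005 on rejection rates
and below 0.002 on mean sharing, and run in seconds on one core.

## Known limitations

Single-point analysis only (no multipoint IBD); no genotyping-error or
mutation model; the permutation null is conservative for weakly
informative markers; gene-counting frequencies ignore sib correlation;
the sample-size formulas are normal approximations, crude below ~10
pairs; the affected/unaffected cohort summary assumes the pair-level
classification, not clinical diagnosis.
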