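# Methods

This note records the statistical models the package implements, the
conventions chosen where implementations in the field differ, what the
synthetic-data generators do and do not emulate, and known limitations.

## Instrument selection

Candidates from the exposure GWAS must pass a discovery p-value threshold
(default 1e-5, the "suggestive" convention used when exposure GWAS are small,
as is typical for microbial-taxon GWAS) and a frequency floor. The frequency
rule is applied to the **minor** allele, min(eaf, 1−eaf) > 0.01: an
effect-allele frequency of 0.995 denotes a variant as nearly monomorphic as
one at 0.005 and equally unusable as an instrument, so filtering on the
effect allele alone would be a loophole rather than a filter.

Clumping is greedy and PLINK-like: rank by ascending p-value (ties broken
lexicographically by variant id so results are deterministic), keep the best
remaining variant, remove every remaining variant on the same chromosome
within ±10,000 kb whose r² with it is ≥ 0.001, repeat. Pairs absent from the
supplied LD table count as unlinked. Proxy substitution (r² ≥ 0.8, same
chromosome, argmax over the outcome-present variants, ties again
lexicographic) is available but optional: without an LD resource, unresolved
instruments are dropped with a warning rather than looked up remotely.

Instrument strength uses the single-SNP approximation F ≈ (β/se)². The
R²-based formula needs per-SNP variance explained and exact sample sizes,
which are not uniformly available across heterogeneous source GWAS; the two
agree to first order.

## Harmonization

All orientation happens on the outcome side; exposure effects are never
altered, so instrument definitions stay stable across outcomes. Allele-label
matching handles swapped and strand-complemented records. Palindromic
variants (A/T, C/G) are resolved by allele frequency: if both sides'
frequencies are outside the ambiguous window 0.5 ± 0.08, the outcome effect
is oriented so the aligned frequencies fall on the same side of 0.5;
otherwise the variant is dropped (flagged, retained in the output table for
audit, excluded from estimation). The 0.08 half-width is the de-facto
community default and is an explicit parameter; setting it to 0 reproduces
the "always infer" behaviour, setting it near 0.5 the "always drop"
behaviour. A variant lacking an outcome frequency cannot be inferred and is
dropped. Harmonizing an already-harmonized pair is the identity
(`harmonize_involution_check` asserts this and is exercised property-style
in the tests).

## Estimators

* **Wald ratio** (1 instrument): β̂_Y/β̂_X with first-order SE se_Y/|β̂_X|,
  matching the weighting the IVW regression uses; a second-order SE
  (adding β̂_Y² se_X²/β̂_X⁴) is available by flag.
* **IVW** (≥ 2): weighted regression through the origin, weights 1/se_Y².
  Default is multiplicative random effects — SE inflated by
  max(1, √(Q/(J−1))) — because panel exposures routinely carry residual
  heterogeneity; fixed effects by flag. Cochran's Q is reported with
  df = J−1 and an upper-tail chi-square p.
* **MR-Egger** (≥ 3): weighted least squares with intercept after orienting
  all exposure effects non-negative (the model is not invariant to allele
  recoding). The intercept, its SE and p form the directional-pleiotropy
  test; slope SEs carry the same multiplicative inflation floor, Q has
  df = J−2.
* **Weighted median** (≥ 3): weights β̂_X²/se_Y² (inverse first-order ratio
  variance), cumulative-weight convention p_j = (S_j − w_j/2)/S_J with
  linear interpolation between the straddling order statistics — stated
  explicitly because published implementations differ here. SE by
  parametric bootstrap (β̂_X*, β̂_Y* redrawn from their normals; default
  1000 draws, explicit seed).
* **Mode-based** (≥ 3): normal-kernel density of the per-SNP ratios,
  bandwidth = factor × 0.9·min(sd, IQR/1.349)·J^(−1/5) (modified Silverman),
  weights 1/se_ratio² for the weighted variant; the estimate is the density
  argmax on a grid spanning the ratios ± 3 bandwidths (512 points; grid
  resolution is far below any bootstrap SE). If all ratios coincide the
  common ratio is returned directly.
* **MR-PRESSO** (≥ 4, ≥ 1000 simulations): observed residual sum of squares
  Σ w_j (β̂_Yj − θ̂_(−j) β̂_Xj)² with leave-one-out IVW predictions; the null
  distribution is parametric simulation under the no-pleiotropy model, and
  global p = (1 + #{RSS* ≥ RSS})/(n_sim + 1), so it is bounded below by
  1/(n_sim+1). Per-SNP outlier p-values are Bonferroni-corrected by
  instrument count at α = 0.05; the distortion test compares the
  raw-vs-corrected difference against 1000 random same-size removals.
  Both raw and corrected estimates are reported, since published tables do
  not always say which one they print.

Dispatch: 1 instrument → Wald only; 2 → IVW only; ≥ 3 adds Egger, weighted
median and both modes; ≥ 4 adds MR-PRESSO. CIs are Wald-type β ± 1.96·se
throughout, matching the symmetric OR intervals such studies print; OR
columns are exp-transformed only for binary outcomes.

## Panel screening and FDR

The screen runs selection → clumping → harmonization → primary estimate per
exposure and applies Benjamini–Hochberg step-up q-values across the panel.
The BH denominator m counts **all attempted exposures**, including those
yielding zero instruments: the family of hypotheses is the full taxon panel,
not the estimable subset. The full sensitivity battery is run for
FDR-significant taxa by default (configurable to all or none). Reverse-
direction MR re-runs the same pipeline with roles swapped and a genome-wide
instrument threshold (5e-8) for the outcome-as-exposure.

Sample-overlap bias between exposure and outcome GWAS is assessed with the
first-order approximation bias ≈ overlap × confounded-association / F̄, and
the implied type-1 error of the nominal 5% test from a bias-shifted normal.
Converting the bias into a type-1 error needs the causal estimate's SE; it
is a parameter with default 0.02, a typical screening-regime SE on the
log-odds scale. The exact formula behind web-based overlap calculators is
not published; this approximation is validated against a direct
overlapping-sample simulation in the tests (agreement within ~30% relative).

## Mediation

Two-step MR: β1 (taxon→mediator) and β2 (mediator→outcome) by IVW (Wald for
single-instrument sets), β3 the total effect from the screen. Proportion
mediated = β1β2/β3, exact by construction. Uncertainty is a parametric
bootstrap drawing the three coefficients as **independent** normals — they
come from non-overlapping two-sample fits; residual sample overlap between
the source GWAS is acknowledged, not modelled. The CI is the percentile
interval (ratio distributions are skewed; normal-theory intervals misbehave
when β3 is imprecise), and draws where β3* crosses zero are retained but the
result is flagged unstable when they exceed 1%. Mediators must pass a
risk-factor significance screen (p ≤ 0.005, a multiplicity-adjusted
threshold for a handful of candidate risk factors) before mediation is
attempted. MVMR fits outcome betas on the exposure-beta matrix without
intercept (weights 1/se_Y², SEs with the same multiplicative floor as IVW);
with one exposure it reduces to IVW exactly, and rank-deficient designs
raise an error naming the collinear exposures.

## Cohort stage

wt-GRS is the dosage-weighted sum of instrument effect sizes, with per-SNP
mean imputation of missing dosages (counted in the log). Prevalent cases —
events dated on or before recruitment — are excluded before fitting. The
Cox model uses Efron tie handling (ties are common at day resolution and
Efron is less biased than Breslow) via lifelines, with competing deaths
treated as censoring in the primary analysis; subdistribution-hazard
(Fine–Gray) sensitivity analysis is out of scope and documented as such.
The proportional-hazards check is the scaled-Schoenfeld-residual test with
rank time transform, reported for the score term; it is skippable per fit
because it costs several times the fit itself in replicate studies. The
hazard ratio is per score unit, with a flag to standardize the score to
unit SD. A score with zero variance returns a null association rather than
an error.

## Synthetic-data generators

`simulate_sumstats` draws, per SNP: maf ~ Uniform(0.05, 0.5); true exposure
effect γ ~ Normal(0, 0.15²); se = 1/√(2·maf(1−maf)·n) on each side; observed
effects normal around the truth; outcome truth Γ = θγ + α with α = 0
(none), Normal(0, sd²) (balanced) or Normal(mean, sd²) (directional).
Instruments are redrawn until their observed exposure p passes the
discovery threshold (1e-5), emulating how suggestive instruments are
ascertained — real instrument sets are conditioned on discovery and are
therefore strong (the resulting minimum F in a 207-taxon panel sits just
above 19, matching what a panel of suggestive instruments from a ~7,700-
sample GWAS looks like). Ascertainment can be disabled
(`instrument_p_threshold=None`) for calibration studies of the raw noise
model.

Default sample sizes mirror the motivating design: n_exp = 7,738 (a
microbiome-cohort GWAS) and n_out = 60,620, interpreted as the **effective**
sample size of a large binary-outcome meta-analysis (≈ the case count when
controls vastly outnumber cases), so that se = 1/√(2f(1−f)·n_out)
reproduces realistic log-OR standard errors. Binary outcomes are simulated
directly on the log-odds scale rather than via a liability threshold,
matching the summary-statistic level at which the pipeline operates. For
the estimator-validation scenarios with ~100 instruments (coverage and
type-I studies), the exposure side is set to a large-GWAS regime
(n_exp = 200,000): panels of a hundred suggestive instruments only arise
from large discovery GWAS, and the first-order IVW/Egger theory whose
calibration those studies measure assumes measurement error in β̂_X is
negligible (NOME). In the small-exposure regime that assumption degrades
gracefully (regression-dilution of order se_X²/γ̄², about 1–2% here), which
is the expected behaviour, not a defect.

`simulate_triangle` builds the mediation triangle with disjoint instrument
sets for taxon and mediator and total effect β3 = δ + β1β2 (defaults
β1 = 0.05, β2 = 0.336, δ = 0.123, i.e. a true proportion mediated of
12.0%). `simulate_cohort` draws binomial dosages, age/sex/batch/centre/PC
covariates, exponential event times with log-hazard linear in the wt-GRS
and covariates (default true HR 1.14 per score unit, baseline hazard
0.005/person-year ≈ a 5–6% event rate over a 13-year administrative
follow-up), independent exponential censoring, a competing-death process
recorded as event code 2, and a 3% prevalent fraction. All generators are
pure functions of (config, seed).

What the generators do **not** emulate: LD between instruments is off by
default (the post-clumping world) though clumping itself is exercised with
explicit LD matrices in the tests; no population structure, winner's-curse
effect-size inflation beyond the ascertainment conditioning, genotyping
error, or real ICD-based phenotyping. Passing tests therefore demonstrate
the statistical machinery is correct under the stated model, not that any
particular real-data finding is correct.

## Numerical choices and degenerate inputs

p-values printed as 0 are floored at 1e-300 to keep −log10 finite. Square
LD matrices may be asymmetric up to 1e-6 (averaged), beyond that they are
rejected. The Egger and MVMR fits solve the weighted normal equations
directly (tiny, well-conditioned systems). Bootstrap bandwidths in the mode
estimator are floored at 1e-12 against degenerate resamples. Cox durations
are floored at half a day so same-day events remain in the risk set. The
IVW random-effects inflation never deflates (max(1,·)), so random-effects
SEs are never tighter than fixed-effects ones. All stochastic operations
(bootstrap, PRESSO, generators, study driver) take explicit integer seeds
and record them in their outputs; the full-study driver's report bundle is
byte-identical across runs at a fixed seed.

## Limitations

Instrument selection is marginal (no conditional/joint analysis); no
Steiger directionality filtering; correlated-instrument IVW is not
implemented (instruments are clumped to near-independence upstream); proxy
lookup requires user-supplied LD (no remote reference-panel queries);
mediation treats one mediator at a time; the overlap-bias assessment is a
first-order approximation. Real summary files with exotic headers are
handled through the configurable column map, which is a mitigation, not a
guarantee, for the field's header heterogeneity.
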