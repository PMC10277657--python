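# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions and the open design choices of `mrbias`.

## Estimators

All estimators consume a harmonised instrument set: exposure effects
β̂\_Xj (se σ\_Xj), outcome effects β̂\_Yj (se σ\_Yj), aligned to the
exposure's effect allele.

**Wald ratio.** β̂\_j = β̂\_Yj/β̂\_Xj with first-order variance
(σ\_Yj/β̂\_Xj)² — exposure-side uncertainty is ignored.  This is standard
for strong instruments; it understates uncertainty when instruments are
weak, which matters mostly in the reverse ("no-relevance") direction where
disease instruments can have F in the tens.  The instrument-strength report
(per-variant F, mean F, total R² = Σ 2·eaf\_j(1−eaf\_j)β̂²\_Xj for a
standardised exposure) accompanies every run so this regime is visible.

**IVW.** Weighted regression of β̂\_Y on β̂\_X through the origin, weights
w\_j = 1/σ²\_Yj.  The fixed-effect se comes from that regression with the
residual variance forced to 1; Cochran's Q is the weighted residual sum of
squares with L−1 degrees of freedom.  The default multiplicative
random-effects (MRE) se multiplies the fixed se by √max(1, Q/(L−1)): the
inflation is floored at 1, so the MRE se never undercuts the fixed-effect
se and the two coincide when Q ≤ L−1.  The floor-at-1 convention follows
the usual MRE implementation; an unbounded variant would shrink the se when
instruments under-disperse, which we do not want.

**MR-Egger.** Rows are first oriented so all β̂\_X > 0 (both effects
negated where needed; β̂\_X = 0 rows dropped), then a weighted regression
with a free intercept is fitted.  The slope is the causal estimate; the
intercept estimates average directional pleiotropy; both ses are scaled by
√max(1, Q\_egger/(L−2)).  With the intercept constrained to zero the fit
reduces algebraically to fixed-effect IVW (kept as a debugging identity).
Egger inherits the "NOME" problem: when the spread of true instrument
effects is small relative to σ\_X, the slope dilutes and the intercept
drifts off zero.  The generator's effect-size distribution keeps
I²\_GX ≈ 0.95 (see below); the I²\_GX-corrected Egger is out of scope.

**Weighted median.** Ratios are sorted; with ratio-level weights
w\_j = β̂²\_Xj/σ²\_Yj, the standardised cumulative weight is
s\_j = (Σ\_{k≤j} w\_k − w\_j/2)/Σ w, and the estimate linearly
interpolates the ordered ratios at s = 0.5.  It is consistent while valid
instruments carry ≥ 50% of the weight.  The se is a parametric bootstrap
(default 1000 draws of (β̂\_X, β̂\_Y) from their sampling normals, seeded;
the seed is a required argument — there is no implicit global RNG).

**Difference test.** z = (β̂₁−β̂₂)/√(se₁²+se₂²), two-sided normal p.
Estimates are treated as independent; when two definitions share controls
(e.g. severity-vs-population and positivity-vs-population from one cohort)
the test is approximate, and the report says so rather than correcting it.

**MVMR.** Weighted multiple regression of β̂\_Y on the L×k matrix of
exposure effects, no intercept, weights 1/σ²\_Yj, over the union of the
per-exposure instrument sets; ses scaled by √max(1, Q/(L−k)).  Collinear
exposure columns raise an error carrying the condition number.  Covariables
are adjusted one at a time by default — joint adjustment is possible but
demands conditional instrument strength we do not certify (the per-exposure
marginal mean F overstates conditional strength, and the output warns
accordingly).

**95% CIs** use the normal quantile 1.959964 throughout.

## LD score regression

Under a polygenic model E[χ²\_j] = 1 + N·h²·ℓ\_j/M.  `fit_h2` regresses χ²
on x\_j = N\_j·ℓ\_j/M in two steps: an unweighted pass estimates h², then
weights 1/(1+N·ĥ²·ℓ\_j/M)² down-weight high-LD variants.  `fit_rg`
regresses z₁\_j·z₂\_j on √(N₁N₂)·ℓ\_j/M for the genetic covariance and
reports rg = ĝcov/√(ĥ²₁ĥ²₂).  Standard errors and p values come from a
delete-one block jackknife over contiguous variant blocks (200 blocks, or
max(20, n/10) when fewer than 2000 variants), rerunning the full rg
pipeline per deleted block.  rg estimates beyond ±1.25 are clipped to the
reporting window and flagged; sampling noise legitimately pushes weak
estimates outside [−1, 1].

Two special paths:

- **NA path.**  rg is reported missing when either trait's ĥ² is
  non-positive *or* below two jackknife ses — with h² indistinguishable
  from zero the ratio is meaningless (the "small heritability, cannot
  estimate" situation).  Fewer than 50 overlapping variants (configurable)
  refuses outright.
- **Constant LD scores.**  The cohort simulator generates unlinked
  variants, so every ℓ\_j = 1 and a free intercept is unidentifiable.  When
  the supplied ℓ has (numerically) zero variance, the χ² intercept is
  constrained to 1 and the cross-trait intercept to 0 — exact for
  non-overlapping samples with no confounding inflation, which is what the
  generator produces.  With any variable ℓ (the summary-level generator, or
  a real LD score table) the intercepts are estimated freely; no
  sample-overlap constraint is imposed, since overlapping real cohorts are
  the norm and the cross-trait intercept absorbs that.

## The synthetic-data generator

The generator emulates the structure of a selected-phenotype MR study: a
pre-pandemic quantitative exposure GWAS (BMI-like) from one cohort, and
case/control disease GWAS under seven definitions and up to four cumulative
releases from an independent cohort, so all analyses are genuinely
two-sample.

Structural model per individual (all coefficients config-exposed):

- genotypes G\_j ~ Binomial(2, maf\_j), independent across variants
  (unlinked by design, so distance pruning is a no-op and LD clumping is
  not emulated);
- SEP = Σ α\_j G\_j + ε, standardised; exposure X = Σ γ\_j G\_j + δ·SEP + ε,
  standardised (noise variances set to the residual after the genetic and
  SEP contributions, floored at 0.05);
- infection ~ Bernoulli(expit(a₀ + θ·X + a\_S·SEP + Σ β\_dis,j G\_j));
- hospitalised (among infected) and severe (among hospitalised) from
  logistic models in θ\_sev·X + b\_S·SEP, so severe ⇒ hospitalised ⇒
  infected by construction; severity score = infected + hospitalised +
  severe ∈ {0..3};
- tested ~ Bernoulli(expit(c₀(release era) + c\_S·SEP + c\_X·X +
  c\_sev·severity));
- laboratory confirmation requires infected ∧ tested; a symptom-predicted
  status (for the D1 definition) is a noisy classifier with configurable
  sensitivity (0.75) and specificity (0.95).

Case/control definitions: A1 severe vs confirmed-not-admitted; A2 severe vs
population; B1 admitted vs confirmed-not-admitted; B2 admitted vs
population; C1 confirmed vs tested-negative; C2 confirmed vs population; D1
symptom-predicted vs predicted-negative.  Population controls are "anyone
not a case", which deliberately includes infected-but-untested individuals
— the misclassification mechanism.

Per-variant GWAS are closed-form OLS (quantitative) or maximum-likelihood
logistic regressions (case/control), vectorised Newton–Raphson across
variants; variants that are monomorphic, have fewer than 5 minor-allele
carriers in the analysed sample, or fail to converge (separation) are
dropped and flagged.  Firth correction is not used; the hard minor-count
filter is the stated limitation.

**Default study size and architecture.**  n = 20 000 per cohort, m = 100
variants: 50 exposure variants with per-allele effects U(0.07, 0.30) SD
(random sign), 20 SEP variants U(0.12, 0.22), 10 disease variants
U(0.20, 0.35) log-odds, the rest null; maf U(0.10, 0.50).  These sizes
keep replicated property suites tractable on a single core while keeping
every instrument strong: per-variant F runs from ~30 to several hundred,
and the wide effect-size spread keeps I²\_GX ≈ 0.95 so MR-Egger is not
dominated by regression dilution.  Because 100 variants stand in for a
polygenic genome, the instruments' total R² (~0.5–0.7) is much larger than
any real single-trait instrument set; this concentrates the same
instrument strength into fewer variants and does not affect the estimands.
The disease's ten loci mirror the few-genome-wide-hits regime of early
pandemic GWAS, which is exactly the regime where the relaxed 5×10⁻⁶
threshold for reverse-direction instrument selection earns its keep.

**Scenarios.**  S0 null (near-universal random testing, no selection terms,
no pleiotropy, inert SEP) for calibration and false-positive rates; S1
collider selection (testing depends on exposure, severity and SEP, baseline
testing low); S2 pure misclassification (random but incomplete testing;
a grid of testing intercepts [3.0, 1.0, −0.5] raises the contaminated
fraction of population controls); S3 SEP-only selection with heritable SEP
affecting exposure (δ=0.45) and testing (c\_S=2.0), the MVMR recovery
scenario; S4 four cumulative releases with testing policy from highly
selective to near-universal; S5 the direct summary-level LDSC scenario
(h²=0.5/0.4, rg=0.3, M=5000, N=50 000).  Scenario coefficients are
illustrative: they were fixed once, during generator design, at values
where each mechanism's signature is detectable at the default study size,
and they are recorded in every TruthRecord.

**What passing tests do and do not show.**  The generator has no LD, no
population structure or relatedness, no imputation noise, perfectly known
trait types, and selection/misclassification mechanisms that match the
framework's assumptions by construction.  Green properties therefore
demonstrate that the estimators are implemented correctly and that the
framework detects these mechanisms when they are present at detectable
strength — not that it would detect every real-world selection process, nor
that real GWAS meta-analyses behave like these cohorts.

## Estimand oracles

IVW with a logistic-regression outcome GWAS does not target the conditional
liability coefficient θ: each instrument shifts the exposure by a small
amount, so the estimand is the derivative of the *population* case/control
log odds with respect to an exposure-specific shift, marginalised over
everything else (non-collapsibility), further modified by the scheme's
selection and misclassification rules.  `simulate.scheme_estimand` computes
this quantity by brute force: per-individual case/control probabilities
have closed forms over the four severity states and the state-dependent
testing probability, so a central finite difference (h = 0.02 SD) over a
400 000-draw covariate Monte-Carlo gives the estimand with negligible
noise.  Calibration and recovery properties compare estimators to this
oracle, never to θ itself; under S0 the oracle sits ~15–20% below θ purely
from non-collapsibility.  `simulate.scheme_log_or` (a direct logistic fit
of scheme labels on the exposure in a large phenotype-only draw) is kept as
an independent cross-check of bias directions.

## Numerical conventions and degenerate inputs

- Instrument selection: p < 5×10⁻⁸ default, 5×10⁻⁶ relaxed fallback for
  disease GWAS with no genome-wide hits (the threshold actually used is
  recorded); greedy distance pruning (250 kb) keeps the smallest-p variant
  per window; an empty selection raises a distinct error so callers can
  relax deliberately.
- Harmonisation: palindromic variants are resolved by allele-frequency
  concordance only when both frequencies are at least 0.08 from 0.5 and
  both are present; otherwise dropped (conservative).  Non-palindromic
  alleles are compared directly, then after strand complementation;
  irreconcilable variants are dropped and flagged.
- Degenerate simulations (a flag with prevalence 0 or 1) raise an error
  naming the responsible coefficient; schemes with zero cases or controls
  are carried as "not estimable" rather than erroring the whole run.
- Reports serialise with sorted keys and no timestamps, so identical
  inputs, config and seed give byte-identical JSON.

## Framework decision thresholds

The five approaches are qualitative in origin; `FrameworkConfig` makes the
decisions explicit and reportable: definition divergence flags require
> 20% change on the log-effect scale *and* difference-test p < 0.05 (so
noise alone is not flagged); the no-relevance flag is a reverse IVW 95% CI
excluding zero; the genetic-correlation flag is |rg| > 0.2 with p < 0.05;
schemes with fewer than 500 cases (or nothing estimable) are reported as
underpowered.  When approaches disagree, per-scheme evidence lines are all
retained and the overall flag follows a fixed, documented precedence
(underpowered > misclassification > selection > none) — a reporting choice,
not a claim about which evidence is more trustworthy.

## Known limitations

- First-order Wald variances understate reverse-direction uncertainty with
  weak disease instruments (mean F is reported as the caveat trigger).
- MR-PRESSO, mode-based estimators, Steiger filtering, I²\_GX-corrected
  Egger, MVMR-Egger and conditional F statistics are out of scope.
- LDSC here is observed-scale only (no liability conversion, no partitioned
  heritability), and the constant-ℓ constrained mode is specific to the
  unlinked simulator design.
- The difference tests ignore control-sharing between definitions.
- Distance pruning is not LD clumping; real-data replication should expect
  (and the driver reports) instrument-set differences against published
  analyses.
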