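# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `marelife`. It is written for users who want to know
exactly what is computed, and what passing the test suite does and does
not demonstrate about real studbook data.

## The trait and its two-step construction

The lifetime foaling rate is `LFR = foals at the 6th breeding season / 6`.
Six seasons is a fixed endpoint for a successful reproductive career in a
heavy draught breed that first foals at 3–4 years; other breeds can use a
different denominator. Because waiting six seasons per mare delays
evaluation, the analysis is two-step:

1. **Training / validation.** On mares with complete careers, predict the
   foal count at season 6 from the count after k = 3, 4, 5 seasons plus
   the age-at-first-foaling (AF) class, and score the predictions.
2. **Full analysis.** Build LFR for every mare with ≥ 3 consecutive
   seasons — actual counts where available, otherwise projected — and
   estimate genetic parameters for the four trait expressions (two
   projection methods × linear/arcsine scale).

### Projection methods

* *Coefficients*: ordinary least squares on an additive two-factor design
  — one effect per foal-count class (0..k) plus one AF contrast, no
  interaction. Predictions are fitted cell values; a foal-count class
  unseen in training falls back to a straight line fitted through the
  estimated class effects.
* *Equations*: ordinary least squares of the season-6 count on the
  numeric season-k count plus an AF contrast.

Predictions are kept fractional (no rounding) and clamped to
`[foals_after(k), 6]`: a projection can never undo foals already born nor
exceed the number of opportunities.

The coefficients design strictly nests the equations design, so comparing
them *in sample* is vacuous (the class model always fits at least as
well). Predictive ability is therefore measured **out of sample**: the
complete careers are split once into a fit set and a holdout set, and
PSB/MAD/SDR are computed on the holdout's actual counts. The acceptance
experiment uses a 20/80 fit/holdout split: the quality difference between
a 7-parameter and a 3-parameter predictor is an overfitting penalty
proportional to `n_holdout/n_fit`, so a small fit set amplifies the
signal while the large holdout keeps the comparison precise.

### Arcsine expression

The arcsine traits are `arcsin(p)` in radians (not `arcsin(√p)`). The
delta method decides the reading: a proportion trait with mean 0.700 and
SD 0.142 maps under `arcsin(p)` to mean ≈ 0.78 and SD
`0.142/√(1−0.70²) ≈ 0.199`, consistent with a transformed summary of
0.794 ± 0.195, whereas `arcsin(√p)` would center near 0.99. The √-variant
remains available behind the `sqrt_variant` flag. `arcsin` is strictly
increasing on [0, 1], so phenotype *ranks* are identical between the
linear and arcsine expressions by construction.

### Validation statistics

`PSB = 100·Σ(y−ŷ)²/Σy²` (scale-invariant under common rescaling),
`MAD = Σ|y−ŷ|/n`, `SDR = sd(y−ŷ)` with the n−1 denominator. Each is zero
iff prediction is perfect; PSB is undefined (raises) when all actuals are
zero. Note `E|r| ≤ √(E r²)` always, so MAD can only exceed SDR when
residuals carry a systematic bias.

## Editing rules

Applied per mare, with a per-rule removal report: born strictly after the
cutoff year (default 1990); both parents known; seasons in consecutive
calendar years (a gap disqualifies the career — "subsequent" seasons are
required, no imputation); first registered event at 36–59 months (the
3- and 4-year-old first-foaling classes; the 4-year class is capped at 59
months, just below age five); at least 3 (full) or 6 (training) seasons,
with only the first six counting toward the endpoint. The
foaling-interval rule (11–17 months) is applied between *adjacent
registered events that are both foalings*: it is a data-completeness
check — two consecutive registered foalings 24 months apart imply an
unregistered season — and deliberately does not skip over registered
abortion/open seasons, which would otherwise discard every mare with a
non-foaling season between two foalings. The EU-BY minimum-record filter
(≥ 2) runs after the mare-level filters and iterates to a fixed point,
since removing a mare can drop another level below the minimum. AF class
is taken from the age at the first *foaling* event, falling back to the
first registered event for careers without a foaling.

## Pedigree machinery

* **A** (numerator relationship matrix): tabular method,
  `a_jj = 1 + a_{s_j d_j}/2`, `a_ij = (a_{i s_j} + a_{i d_j})/2`,
  vectorized row-wise; stored dense. Practical to ~8,000 animals
  (memory grows quadratically); the studbook scales targeted here stay
  well inside that.
* **F** (inbreeding): `diag(A) − 1`. Unknown parents contribute zero
  relationship — they are treated as unrelated, non-inbred founders; no
  genetic-group machinery is attempted.
* **A⁻¹**: Henderson's sparse rules with the Mendelian-sampling variance
  `m_x = 1 − 0.25(1+F_s) − 0.25(1+F_d)` (unknown-parent terms dropped).
* **D** (dominance relationships): the classical non-inbred approximation
  `d_ij = 0.25(a_{s_i s_j} a_{d_i d_j} + a_{s_i d_j} a_{d_i s_j})`,
  `d_ii = 1`, zero off-diagonals for animals with an unknown parent.
  The exact theory for inbred dominance is unsettled; the approximation
  is verified by gene-dropping only on non-inbred pairs. Dominance
  levels are individual animals (not parental subclasses).

Both A/F and D are verified against Monte-Carlo gene dropping (unique
founder alleles, 2·10⁵ drops) on textbook pedigrees, and classical
path-counting values (full sibs a = 0.5, d = 0.25; half sibs a = 0.25,
d = 0; offspring of full-sib or parent–offspring matings F = 0.25).

## REML and BLUP

The analysis model per trait is
`y = Xβ + Z_h h + Z_a a + Z_d d + e` with X = intercept + AF contrast +
inbreeding covariate, herd = EU-BY levels with identity covariance,
additive with A, dominance with D, residual identity. Phenotypic variance
is the sum of the four components; `h² = σ²_a/σ²_p`.

**Estimation** maximizes the restricted likelihood of the phenotyped
mares' marginal covariance

    V = S σ²_h + A_m σ²_a + D_m σ²_d + I σ²_e,

where `A_m`, `D_m` are the relationship matrices restricted to phenotyped
mares and S the herd-block indicator. Marginalizing the unphenotyped
random-effect levels out of a zero-mean Gaussian is exact, so this is the
same REML optimum as the full mixed-model-equation formulation at one
n×n factorization per iterate. Updates:

* EM step (monotone by EM theory):
  `σ²_i ← σ²_i + (σ⁴_i/q_i)(yᵀP V_i P y − tr(P V_i))`.
* AI acceleration: Newton step with the average-information matrix
  `AI_ij = ½ yᵀP V_i P V_j P y`, solved by a Hermitian pseudo-inverse on
  the *active* components (those off the variance floor or pushing away
  from it), with step fractions 1, ½, ¼, 0.1, 0.05, 0.02 and acceptance
  only if the log-likelihood does not decrease; otherwise the EM step is
  taken. The whole iteration history is therefore monotone in logL, and
  the estimator asserts this.
* Floors and stopping: components floored at 10⁻⁸ of the phenotypic
  variance; convergence at relative parameter change < 10⁻⁸ (default) or
  a full accepted Newton step with relative logL change < 10⁻⁹. The
  larger simulation studies pass `tol = 10⁻⁶, max_iter = 80`, which the
  recovery experiments show is ample at their problem sizes.

`AIC = −2·logL_R + 2·(number of variance components)` (= 8 for the full
model; fixed effects are identical across the compared models). AIC
values for linear vs arcsine expressions are reported but are not
likelihood-comparable across measurement scales.

The standard error of h² is the delta-method form
`SE = h²·√(Var(σ²_a)/σ⁴_a + Var(σ²_p)/σ⁴_p − 2 Cov(σ²_a, σ²_p)/(σ²_a σ²_p))`
with the sampling (co)variances from the inverse AI matrix at
convergence (`Var(σ²_p)` is the sum of all entries, the covariance a row
sum). A reference variant of this formula with a positive covariance
term and a squared outer factor cannot yield sub-unity standard errors
for these magnitudes; the minus/√ form is the standard ratio delta
method and is what this package computes.

**BLUP** solutions come from Henderson's mixed-model equations assembled
sparsely — variance ratios `λ = σ²_e/σ²_u` on the identity (herd), A⁻¹
over the whole pedigree (additive: EBVs for every animal including
unphenotyped ancestors), and `D_m⁻¹` over phenotyped mares (dominance;
marginal-equivalent for the other effects). Systems up to 20,000
equations are densified and solved directly; the relative residual of
the solve must be < 10⁻⁶. The solutions are verified against an
independent dense generalized-least-squares + BLUP oracle
(`β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y`, `û = G Zᵀ V⁻¹(y − Xβ̂)`) on toy data.

## EBV post-processing

Standardized EBV = (EBV − mean EBV of recorded mares born in the base
year) / genetic SD, with genetic SD = √σ̂²_a of the same trait's fit. The
base year defaults to 2000 (an intermediate cohort); the pipeline falls
back to the nearest populated cohort in small simulations and records
the substitution. Stallion accuracy uses the progeny-test approximation
`r = √(n/(n + (4−h²)/h²))` from n half-sib daughter records; note that at
h² ≈ 0.24 nine daughters give r ≈ 0.60, so the operational selection rule
is the daughter count itself (≥ 9 recorded daughters, configurable) —
the two rules are cross-checked for equivalence in the tests. Rank
correlations are Spearman with average ranks for ties. Genetic trends
average standardized EBVs per birth-year cohort over the 15 years ending
at the latest cohort that exceeds the group threshold (> 100 recorded
mares, > 15 stallion sires by default).

## The synthetic studbook generator

The generator is the package's study population: all acceptance-level
claims are statements about data it produces.

**Pedigree.** Founders (30% male) plus `n_generations` cohorts; each
offspring draws a sire from a per-generation pool
(`sires_per_generation`) and a dam by cycling a shuffled pool of females
from the previous three generations. A dam with a previous offspring is
covered by the same stallion again with probability
`repeat_mating_prob = 0.5` — repeat matings are common stud practice and
produce the full-sib pairs without which dominance variance is
unidentifiable. Recorded mares are a seeded sample of females with both
parents known born from `recording_from_year` (1990); the pedigree file
is their ancestor closure, the way a studbook extract traces back from
the animals under evaluation. The default configuration lands close to
the reference population shape: ≈ 6,000 pedigree animals, 3,000 recorded
mares, ≈ 600 sires with ≈ 5 recorded daughters each.

**Genetic values.** Founder breeding values are N(0, σ²_a); offspring get
the parent average plus Mendelian sampling with variance
`½(1 − (F_s + F_d)/2)σ²_a`. Dominance deviations of recorded mares are
drawn with the pedigree covariance `D_m σ²_d` (Cholesky); this matters —
drawing them independently leaves the analysis model misspecified and
noticeably biases recovered heritability downward, because σ²_d then
absorbs A-correlated structure. Herd effects are N(0, σ²_h) per EU-BY
level; EU assignment is uniform over `eu_count = 9` units (3 areas × 3
rearing systems).

**Careers** (event level). Each recorded mare first breeds at 3
(probability 0.41, matching a 43.9-month mean first-event age given
class means of 36.6 and 49.0 months) or 4 years, for a career of 3–6
consecutive annual seasons (default mass {3: 0.16, 4: 0.15, 5: 0.12,
6: 0.57}, mirroring the actual/projected mix of the reference full
dataset). The per-season foaling probability is the mare's liability

    clamp(0.70 + AF effect − 0.1·F + herd + BV + dominance + residual, 0, 1)

with a post-partum carryover: after a foaling the next season's
probability drops by `0.35·(1 − liability)`-scaled alternation
(`p = clip(liab + 0.35·(liab − prev))`), emulating the under-dispersion
real careers show relative to i.i.d. seasons. Non-foaling seasons are
labelled abortion with probability 0.15, else open (the split is a free
parameter the analysis never uses downstream). Ages advance by 12 ± 1
months per season, so registered foaling intervals respect the editing
window.

**Trait-level phenotypes.** `simulate_phenotypes` returns the Gaussian
liability itself (no clamping, no season sampling) as the phenotype.
This is the route for variance-component recovery studies: the realized
6-season Bernoulli mean carries irreducible season-sampling variance of
about `p(1−p)/6 ≈ 0.035` — larger than the entire reference phenotypic
variance of 0.020 — so the reference variance decomposition is a
statement on the trait scale, and only the trait-scale generator can
embody it exactly. Career-level analyses (projection validation,
distribution shape, rank correlations) use the event route.

**What the generator does not emulate.** Within-season covariates
(stallion, semen type, mating month), culling informative of fertility
(career length is independent of the mare's liability), genetic trends
from actual selection, and — important for two shape-sensitive checks —
the fine shape of the real LFR distribution near its upper boundary.
With a Bernoulli career model at mean 0.70, about 6% of mares realize
LFR = 1.0 exactly. `arcsin` has infinite derivative at 1, so that
boundary atom becomes an isolated spike at π/2: the arcsine transform
then *raises* kurtosis instead of lowering it, and the linear-vs-arcsine
phenotype correlation (and hence the EBV rank correlation between the
expressions, ≈ 0.97–0.98 here) falls short of the reference ≈ 0.995
level. The reference moments imply the real data had almost no mass at
the boundary; reproducing that within a Bernoulli season model at the
same mean would require per-season dynamics strong enough to contradict
the population's own mean and interval structure. The corresponding two
acceptance checks are left failing by design, with the analysis above;
passing the remaining suite demonstrates parameter recovery, ordering
and sign properties, not boundary-shape fidelity.

## Problem sizes and determinism

The heritability-recovery experiment runs at 2,000 recorded mares on a
≈ 3,800-animal pedigree, 10 replicates in the test suite (seeds 1–10)
and 30 in `scripts/acceptance.py`; mean recovered h² over seeds 1–10 is
0.248 against the generating 0.242. The projection-ordering experiment
uses 2,200 complete careers per replicate, 50 replicates. All randomness
flows from explicit integer seeds through `numpy.random.SeedSequence`;
rerunning any configuration with the same seed reproduces outputs
bit-identically, which the pipeline tests assert by hashing output
files.

## Known limitations

* Dense A limits pedigrees to a few thousand animals; no genomic
  relationships, unknown-parent groups, or multi-trait models.
* Dominance uses individual-animal levels and the non-inbred D
  approximation; parental-subclass coding (which real dominance software
  often uses, and which explains level counts exceeding the pedigree
  size in large-scale dominance evaluations) is not implemented.
* REML on the dense marginal covariance scales as n³ per iteration in
  the number of phenotyped mares; comfortable to ~3,000, not designed
  for 10⁵-record national evaluations.
* The σ²_d/σ²_e split is weakly identified in populations with few full
  sibs; estimates of the two components individually can ride a
  likelihood ridge even when their sum — and hence h² — is stable.
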