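# Methods

## The animal model

For an n-vector of phenotypes (cyanogen concentration, % of dry mass)
the core model is

    y = X b + Σ_k u_k + e,   u_k ~ N(0, σ²_k K_k),   e ~ N(0, σ²_R I)

where the covariance structures K_k are: the additive relationship
matrix **A** for the individual genetic effect ("animal"); and
incidence-based block structures (Z Zᵀ) for maternal identity or brood.
Model 1 is `animal` only with fixed effects of sex and larval feeding
treatment; Model 2 adds `maternal_identity`. Because a design dominated
by full-sib families cannot separate additive from dominance, epistatic
or maternal variance, the `animal` component is interpreted as a
broad-sense genetic variance V_G.

**A matrix.** Built by the tabular method on a topologically ordered
pedigree: `A_ii = 1 + ½A_{dam,sire}`, `A_ij = ½(A_{j,dam_i} + A_{j,sire_i})`,
with founders non-inbred and mutually unrelated (the parental generation
comes from a large outbred stock). Broods with an unidentified father
get a distinct phantom founder sire — one per brood, reflecting single
matings in cages — so their members are full sibs and unrelated to other
broods. All entries are dyadic rationals, so double-precision tabular
arithmetic is exact; an independent exact-rational kinship recursion is
kept in the package solely to cross-check this (A = 2 × kinship). The
matrix is stored dense: at n ≈ 350 dense algebra is simple and exact,
and no sparse-inverse machinery is warranted.

**REML.** Variance components maximize the restricted log-likelihood

    ℓ_R = −½ [ log|V| + log|XᵀV⁻¹X| + yᵀPy + (n−p) log 2π ].

The residual variance is profiled out analytically, leaving a search
over component-to-residual variance ratios on the log scale. With a
single structured component (Model 1) the problem is rotated into the
eigenbasis of K, making V diagonal and the criterion one-dimensional —
a bounded scalar search converges to ~1e-12. With several components,
Nelder–Mead runs from three starting ratios, and boundary candidates
(each component forced to zero, the rest refit) are compared explicitly;
estimates below 1e-6 of the phenotypic variance are projected to zero.
Component standard errors come from the observed information (numerical
Hessian of ℓ_R on the variance scale); they are reported as NaN at a
boundary, where the asymptotic approximation fails. Degenerate input
(zero phenotypic variance) short-circuits to an all-zero decomposition
with a flag.

**Fixed-effect variances.** The variance "explained" by sex or treatment
is the population variance, across observations, of that effect's fitted
contribution to the linear predictor (for two equal-frequency sexes with
contrast d this is d²/4). The reported V_P is the sum of all components
including V_sex and V_trm.

**Testing a component.** Dropping one variance component puts the null
on the boundary of the parameter space, so the LRT statistic is referred
to the 50:50 mixture ½χ²₀ + ½χ²₁; p = ½·P(χ²₁ ≥ 2Δℓ_R), giving p = 0.5
at Δ = 0. REML likelihoods are comparable here because the fixed-effect
structure is held fixed.

## Derived metrics

- **Heritability.** H² = V_G / V_P. By the text convention (default) the
  denominator includes V_sex but excludes V_trm, since an imposed diet
  contrast is not natural phenotypic variance; the `full` option uses
  the sum of all components. Both are exposed because published V_P
  values are ambiguous about the convention at the rounding level.
- **Evolvability.** e_μ = 100·V_G/µ², with µ the trait mean of the
  common-garden data — the expected percent change of the trait mean per
  generation under unit-strength selection (selection on the trait as
  strong as selection on fitness). Scale-invariant: rescaling phenotypes
  leaves H² and e_μ unchanged.
- **Repeatability.** R = σ²_brood/(σ²_brood+σ²_res) from a Gaussian
  random-intercept model. The random-intercept REML is implemented
  directly on the block-diagonal structure (per-group Woodbury
  identities; one profiled variance ratio), which makes a single fit
  ~10⁻³ s and the 1000-replicate parametric bootstrap cheap. Agreement
  with statsmodels `MixedLM` (an independent implementation) and with
  the closed-form balanced ANOVA ICC is enforced in the tests. The
  bootstrap simulates new group effects and residuals from the fitted
  model and refits; SE is the bootstrap SD, the CI the 2.5/97.5
  percentile interval, and the p-value the boundary-mixture LRT of
  σ²_brood = 0.
- **Parent–offspring regressions.** Offspring phenotype on maternal,
  paternal or midparent phenotype, fitted as a random-intercept mixed
  model with brood as the grouping factor; slope inference uses a t
  statistic on n−2 residual degrees of freedom. Under purely additive
  inheritance each single-parent slope estimates h²/2 and the midparent
  slope h². The midparent and father–offspring regressions are
  restricted to broods with an identified, phenotyped sire, so their
  brood subsets differ from the mother–offspring regression — this is
  reported, not hidden, because it is a property of the design.
- **Maternal-effect coefficient.** Under Falconer's dilution model the
  offspring phenotype depends linearly on the maternal phenotype beyond
  transmitted genes; m = β_mo − β_fo. The CI is a brood-level (cluster)
  bootstrap, percentile method, refitting both regressions jointly per
  resample; the bootstrap is seeded and reproducible. The analysis
  default is 1000 resamples.
- **Response projections.** The compound projection is
  100·((1 + e_μ/100·β_μ)^g − 1); with e_μ = 1.55%, β_μ = 100% and six
  generations this is 9.7% per year. The maternal-effect trajectory
  iterates R_t = h²S + m·R_{t−1} (the minimal phenotype-transmission
  recursion; alternative recursions with maternal–additive covariance
  terms can be plugged in through the `recursion` argument). Its
  per-generation response approaches h²S/(1−m); at m = 0.25 the
  long-run cumulative excess over the m = 0 trajectory is ≈33%
  (4/3 − 1). Published claims of excesses up to ~50% rest on richer
  recursions than the default; with the default form 33% is the
  asymptote, which is why both the trajectory and its ratio to the
  m = 0 baseline are returned rather than a single headline number.

Note on one published inconsistency: the study prints m = 0.261 for
total cyanogens while its printed slopes give 0.181 − (−0.122) = 0.303.
The slope subsets (20 broods for mothers vs 14 sire-identified broods
for fathers) likely differ, and the package surfaces both regressions
and their subsets rather than asserting either number.

## Field statistics

Wild-caught concentrations are right-skewed with many near-zero values,
so group comparisons square-root-transform before one-way ANOVA, and the
same transformed scale is used for Tukey–Kramer all-pairs comparisons
(valid for the unequal site samples, e.g. 34/28/30 butterflies and
20/11/20 plants). Raw-scale group means/SDs are reported alongside. The
greenhouse host-plant experiment is a 2×2 origin × watering factorial
analyzed with a type-II two-way ANOVA with interaction. Effect size
between generations uses Hedges' g with the exact gamma-function
small-sample correction.

Distributions are summarized with a zero-truncated Gaussian KDE: each
kernel is renormalized by its mass on [0, ∞) (divide by Φ(x_i/h)), so
the estimate integrates to one despite the boundary; observation weights
are normalized to sum to one. The default bandwidth is the normal
reference rule h = 0.9·min(SD, IQR/1.34)·n^(−1/5) computed on the
unweighted sample. Skew summaries report the fractions of observations
in the lower and upper quarters of the observed *range* (a quantile
reading would trivially give 25%), plus the fraction under an absolute
threshold (default 0.5 % dry mass); constant data have no range and are
rejected.

## The synthetic-data generator

`SimulationConfig` defaults mirror the empirical study's conditions: 20
broods — six large treatment broods of 29 offspring split evenly across
four host-plant types and fourteen broods of 8 — one paternal half-sib
brood pair (two dams sharing a sire), six broods with phantom
(unidentified) sires, µ = 0.772 % dry mass, V_A = 0.0093,
V_R = 0.0703, a male–female contrast of 0.059 (contributing ≈0.0009 of
variance, matching V_sex/V_P ≈ 0.011) and treatment shifts
(0, 0.04, −0.04, 0.06) of a similar order. This yields 319 phenotyped
individuals including parents (the study had 322; the exact per-brood
offspring counts were not published, only the averages 8 and 29 and the
total, so the defaults reproduce the averages).

Phenotypes are µ + sex + treatment + breeding value + maternal term +
residual. Breeding values are multivariate normal with covariance V_A·A
(Cholesky of the exact A). The two maternal modes are mutually
exclusive: a dam-level normal deviate with variance V_mat, or Falconer
transmission m·(dam phenotype − µ), for which founders are phenotyped
first so every dam's phenotype exists. Concentrations are floored at
zero (at study-scale defaults the raw normal dips below zero with
probability ≈0.3%, a negligible distortion), and the total is split into
linamarin and lotaustralin by a per-individual Beta(≈0.75·50, 0.25·50)
share, giving the observed strong linamarin–lotaustralin correlation and
an exactly additive total. One integer seed drives all stages through
independent spawned streams, so identical configurations reproduce
byte-identical tables.

Field populations draw totals from a gamma or log-normal law
parameterized by mean and SD, with an optional point mass at zero for
below-detection samples (stored as exact zeros, as in surveys where many
individuals lack both compounds). Host-plant tables draw gamma per site
or per origin × treatment cell.

What the generator does **not** emulate: age structure (wild toxicity
accumulates with age), sequestration vs biosynthesis trade-offs,
measurement error of the NMR/LC-MS assays, shared-cage environmental
covariance beyond the brood term, and non-Gaussian breeding values.
Passing recovery tests therefore demonstrate that the estimators are
correct and unbiased under the stated generative model — not that the
model captures every feature of real common-garden data.

## Problem sizes and numerical choices in the test suite

The recovery suite runs 100 replicates of a 20-brood × 16-offspring
design (the study's brood count with a balanced size near its mean) and
checks that mean V_G, H², e_μ and R sit within two empirical standard
errors of truth. The bootstrap-coverage check for m uses a 40-brood ×
12-offspring design with 500 resamples per replicate: percentile
cluster bootstraps are known to undercover with only ~20 clusters
(measured here at ≈88% for a nominal 95% interval at the study's brood
count — a limitation of the design size, documented rather than patched),
so the coverage property is asserted where the method operates in its
validity regime. Random-probe dominance of the REML optimum uses 1000
uniform probes of the restricted likelihood on a small pedigree; the
A-vs-kinship identity is checked exactly on 50 random pedigrees.

Other numerical conventions: optimizer tolerances 1e-9..1e-12 on the
profiled criterion; ties between an interior optimum and a boundary
candidate resolve to the boundary (the more parsimonious model); the
KDE mass check tolerance is 1e-3 over [0, ∞); repeatability CIs are
clipped to [0, 1]; exact-fit regressions (zero residual) floor the RSS
at 1e-12·yᵀy so the slope is still reported with a near-zero SE.
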