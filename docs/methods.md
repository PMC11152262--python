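# Methods

## The wellbeing index

Each of the three instruments is scored by a distance-based composite
index. For a scale with items $j = 1,\dots,k$, raw response $A_j$ on
$[m_j, M_j]$ becomes $d_j = (A_j - m_j)/(M_j - m_j)$, reflected
($d_j = (M_j - A_j)/(M_j - m_j)$) for items keyed so that a low response is
good. The aggregate is

$$\mathrm{MWI} = \tfrac12\big[\lVert d\rVert_2/\sqrt{k} + 1 -
\lVert \mathbf 1 - d\rVert_2/\sqrt k\big].$$

This is the two-component normalized-Euclidean form used in the
financial-inclusion index literature: the mean of (a) the distance from the
all-worst corner and (b) one minus the distance from the all-best corner,
each normalized by the diagonal length $\sqrt k$. It is the unique simple
aggregate that is simultaneously unit free, bounded on $[0,1]$ with the
corners attained exactly, strictly monotone on the interior, and invariant
to affine remapping of any item's response grid; it additionally satisfies
the complement symmetry $\mathrm{MWI}(d) + \mathrm{MWI}(1-d) = 1$. All of
these are property tests in the suite, with an explicit-summation oracle on
a $0.1$ grid for $k \le 3$.

**Item orientation.** The shipped codebook orients every item so larger
$d$ = better wellbeing: CASP-19 and Satisfaction-with-Life items are
higher-is-better, WHO-5 lower-is-better (its scale runs 1 "All of the
time" to 6 "At no time" over positively worded feelings). Orientation is a
per-item codebook attribute, not a hard-coded rule, because which items a
given deployment reverse-scores varies between studies; re-analyses may
need to toggle orientations per item.

**Missing items.** Default policy `strict`: any missing item makes that
scale's score missing, keeping $k$ fixed at the instrument length (the
index formula fixes $k$). A `rescale` policy (score over observed items
with $k$ = observed count) is available for sensitivity analysis; it
changes the meaning of $k$ and is therefore not the default.

## Recoding

Index quartiles use linear-interpolation sample percentiles (25/50/75);
values exactly on a breakpoint fall into the lower quartile. This tie rule
is deterministic and order-preserving; when all scores coincide the
partition degenerates to Q1 and a warning is raised. Other rules: child
counts band as 0 / 1–3 / >3; activity counts binarize at "two or more";
health collapses to good = {good, very good}, relationships to good =
{good, excellent}, work to yes = {working, part-time, ad-hoc, freelance},
education to more-than-secondary vs secondary-or-less. Rows with a missing
learning attitude are retained through recoding — each downstream stage
applies its own complete-case rule, so the row-count audit stays attached
to the stage that drops rows.

## Multiple correspondence analysis

Indicator-matrix MCA (not the Burt variant): with $Z$ the respondents ×
categories one-hot matrix over $Q$ active variables and $J$ total
categories, $P = Z/\text{total}$, row/column masses $r, c$, the SVD of
$S = D_r^{-1/2}(P - rc^\top)D_c^{-1/2}$ gives principal inertias (squared
singular values, totalling $(J-Q)/Q$), category principal coordinates
$D_c^{-1/2}V\Sigma$ and respondent coordinates $D_r^{-1/2}U\Sigma$. New
respondents are projected by the transition formula (profile × category
coordinates / singular value).

Numerical choices: complete-case rows only (dropped rows are counted and
logged); a variable with a single observed level is rejected rather than
silently carried as a zero-variance block; SVD signs are fixed by orienting
each dimension so its highest-contribution category is positive — signs are
arbitrary in the factorization, so any published map orientation is
recovered by relabeling, not asserted. Raw inertia proportions are the
default report; Benzécri-adjusted proportions
$\big(\tfrac{Q}{Q-1}(\lambda - \tfrac1Q)\big)^2$ for $\lambda > 1/Q$ are
also emitted because raw indicator-MCA proportions are known to understate
structure (on the synthetic default the first two dimensions carry ~17% raw
but ~88% adjusted inertia). Tests verify the total-inertia identity, the
closed form $(1\pm\phi)/2$ for two binary variables, mass-weighted
orthogonality of dimensions, transition-formula consistency at $10^{-8}$,
and agreement at $10^{-6}$ with an independent eigendecomposition route.

## Regression trees

Standard CART for a continuous outcome: recursive binary splitting
maximizing SSE reduction. Numeric predictors split at midpoints between
consecutive distinct values; multi-level categoricals are ordered by
within-level mean outcome and cut along the ordering (optimal for a single
squared-error split). Pre-pruning, not post-pruning: nodes with fewer than
`min_node = 20` observations are leaves, and a split must gain at least
`min_gain_frac = 1%` of the root SSE. The minimum-node rule alone produces
much deeper trees than are useful at n = 300; the relative-gain floor
mirrors the complexity-parameter default of the classical CART
implementations and both knobs are exposed. Ties break by column order then
smaller threshold, making the tree a deterministic function of its input.
Complete cases per tree (no surrogate splits); dropped rows are counted.
Node labels follow the usual display: mean outcome to 2 decimals over share
of the root sample to whole percents.

## Regressions

One OLS per index on the shared predictor set (learning-attitude dummy,
class/place counts, disability, mobility, health/family/friends dummies,
retired, female, married, more-than-secondary education, number of
children, intercept) with listwise deletion. Variance is the White sandwich
estimator; HC1 (the $n/(n-k)$ degrees-of-freedom variant that the common
econometrics packages print) is the default, HC0/HC2/HC3 available since
the variant is a convention, not a substantive choice. P-values use the
normal approximation by default with a t option. The estimation is
delegated to statsmodels; tests check it against an explicit-summation
sandwich oracle on a handmade 6-point dataset and the elementwise identity
$\mathrm{HC1} = \mathrm{HC0}\sqrt{n/(n-k)}$.

## Synthetic survey generator

The generator makes the pipeline's modelling assumption literal so recovery
tests have an exact target. Per respondent, covariates are drawn from
configurable marginals; latent wellbeing per domain is
$W_h = \alpha_h + x^\top\beta_h + \varepsilon_h$ with
$\varepsilon_h = \sigma_h(\sqrt f\, z_0 + \sqrt{1-f}\, z_h)$, where $z_0$
is a person-level factor shared across domains ($f = 0.5$ by default) —
without it the three indices would correlate only through the shared
covariates, far below what real multi-instrument data show. $W$ is squashed
to $[0,1]$ (identity-with-clipping by default, so planted effects pass
through undistorted; logistic optional) and treated as the target
normalized response; each item adds independent noise
(`item_noise_sd = 0.12`), clips, and inverse-maps onto its ordinal grid
honouring orientation. Because the index of a constant response vector
$(w,\dots,w)$ equals $w$, a planted coefficient is, up to discretization
noise, exactly what the downstream OLS estimates — the suite verifies a
planted quality-domain effect of 0.0611 is recovered within ±0.01 at
n = 5000 over 20 seeds.

Defaults are the study conditions the pipeline targets: n = 300 with 8
missing learning attitudes and a 205:87 yes:no attitude split; class
participation 147/118/27 (none/one/two-plus) with exercise the most common
class; place visits 225/52/15 with the library most visited; demographic
marginals with 2 children and primary education modal, 76% retired, 63% in
good health, 43/300 educated beyond secondary. The effect matrix defaults
to coefficients of the magnitude the regressions are expected to find
(learning attitude ~0.06 on quality; class count 0.05–0.08 across domains;
health ~0.10; family ~0.05–0.13), and the residual scales
(0.13/0.17/0.19) put $R^2$ near 0.25–0.33 and the cross-index correlations
near 0.55–0.6.

**What the generator does not emulate:** within-instrument item structure
beyond a single latent per domain (no item difficulties, no local
dependence), joint dependence among demographics (covariates are drawn
independently), acquiescence or other response styles, and any missingness
outside the attitude question. Passing recovery tests therefore shows the
pipeline is correct under its own linear-latent assumptions, not that those
assumptions hold in any particular field sample.

## Problem sizes and determinism

The test suite runs on fixtures of 4–300 respondents plus recovery runs at
n = 2000–5000; the full suite completes in well under a minute on one core.
All randomness — generator, fixtures, property tests — flows from explicit
integer seeds; two runs of any pipeline configuration produce byte-identical
output bundles, which the tests assert.

## Known limitations

* The analysis is associative throughout; nothing identifies causal effects
  of learning on wellbeing.
* Quartile tags depend on the sample at hand; scores near breakpoints can
  change tags between samples.
* The MCA active-variable set is a configuration choice; different sets
  change coordinates (the defaults use every coded categorical field).
* With heavy clipping (large effects or noise under the identity squash)
  the generator's planted effects attenuate near the index boundaries;
  recovery tests use interior intercepts for this reason.
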