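# Methods

This note documents the models and procedures implemented in `fohi`, the
defaults chosen where the design was genuinely open, and what the bundled
synthetic instance does and does not demonstrate.

## Indicator hierarchy

A composite index is a three-level tree: categories (here External,
Internal and Core Drivers, coded A/B/C), key indices (13), and indicators
(34). Each indicator carries measurement metadata:

- **value kind** — numeric, binary (yes/no), or ordinal (levels 1..L;
  the bundled web-presence scale C1.5 has L = 4);
- **polarity** — `higher_better` or `higher_worse`; 11 bundled numeric
  indicators (A1.2, A3.1, B1.3, C2.2–C2.5, C3.1, C5.1–C5.3) are
  `higher_worse` and reverse-scored. Binary and ordinal indicators are
  coded so higher is better, so polarity reversal applies to numeric
  indicators only;
- **coverage** — `per_unit`, `regional:<scheme>` (measured once per region
  and broadcast: C2.2–C2.5 over 12 public-health-center districts, C3.3
  over 9 food-chain districts), or `monitoring_sites` (observed only where
  a site exists: A1.2 at 17 of 60 units, C5.3 at 12 of 60).

The real municipality→district rosters are not public; the bundled
`synthetic_region_maps` partitions the 60 units into contiguous blocks and
must be replaced (a two-column CSV / the `region_maps` section of the
hierarchy YAML) for any analysis of real data.

## Standardization

Numeric vectors are transformed in three steps, estimated over observed
values:

1. robust scaling `(x − median)/IQR × 100` (quantiles by linear
   interpolation between order statistics; median of an even count is the
   midpoint — the common scientific-computing convention, fixed here for
   reproducibility);
2. min–max rescaling mapping observed min → 0 and observed max → 100.
   Note the ×100 factor in step 1 is absorbed by this affine map
   (regression-tested), as is any affine transform of the raw data;
3. for `higher_worse` indicators, reversal `100 − x` — the unique
   order-reversing affine map fixing [0, 100].

**Monitoring indicators** are completed by observed-mean imputation. The
median/IQR and min/max anchors are estimated from the observed subset and
then applied to the completed vector. Estimating them after imputation
would be ill-posed: with 43 of 60 entries set to one constant the IQR is
0 and the robust scale undefined. All imputed units therefore share one
score, the transform of the observed mean, and the imputation is recorded
per indicator in the provenance sidecar.

**Degenerate scales.** If the IQR is 0 but the range is not (more than
half the values tied), robust scaling is skipped and the raw values are
min–max rescaled (`minmax_raw` fallback). If all values are equal the
indicator is uninformative and every unit receives the midpoint 50
(`constant_midpoint` fallback). Both fallbacks are flagged in provenance.

**Discrete indicators.** Binary yes/no → 100/0. Ordinal level l of L →
100·(l−1)/(L−1), reported to one decimal (0, 33.3, 66.7, 100 for four
levels) to match conventional score printing; pass `decimals=None` for
full precision.

## Expert weighting (FAHP)

Each comparison level (the 3 categories; the key indices within each
multi-index category) is a forced-choice questionnaire answered by n
experts (bundled default n = 23). The count a_ij of experts preferring i
over j, clamped to [0.5, n − 0.5] so unanimous counts never produce a zero
or infinite entry (a half-vote perturbation), fills the judgment matrix;
the diagonal is n/2 (indifference to oneself). Two reciprocal conventions
are implemented for the opposite entry:

- `ratio_reciprocal` (default): a_ji = n / a_ij, so a_ij·a_ji = n;
- `complement`: a_ji = n − a_ij, forced-choice complementarity.

Weights are row geometric means of the unit-scale matrix (entries divided
by n), diagonal included, normalized to sum to 1. The diagonal constant
and the overall scale provably cancel in the normalization (tested).
Indicators receive equal weights within their key index, reflecting the
expert-consensus design of the bundled instance.

**A caution on the ratio rule.** The two conventions are not equivalent.
Under `complement`, the matrix is determined by the preference
probabilities alone; under `ratio_reciprocal`, which entry of a pair holds
the raw count and which holds n/a_ij changes the weights — an indifferent
panel does not produce equal weights, and the derived weight of the
strongest item is exaggerated relative to the generating preferences. The
implementation therefore keys the matrix on the stored orientation of each
vote pair (making relabeling permute weights identically), and the bundled
simulated panels store each pair with the consensus-stronger item first,
the orientation in which the rule behaves sensibly. Behavioral recovery
properties (indifference → equal weights; ordering recovery) hold exactly
in complement mode and are tested there.

**Consistency.** λ_max of the positive reciprocal ratio matrix
r_ij = a_ij/a_ji is computed by power iteration (start vector of ones,
tolerance 1e−10, cap 10 000 iterations; cross-checked against a full
eigensolver in tests). CI = (λ_max − n)/(n − 1), CR = CI/RI(n) with
Saaty's classical random-index table (RI undefined below n = 3; CR is 0 by
convention for n ≤ 2, since two-item comparisons are always consistent).
Both the strict 0.10 and secondary 0.15 acceptability flags are reported.
Note that under the ratio rule r_ij = a_ij²/n, so Bradley–Terry-consistent
panels still show nonzero CR; under complement, r_ij is the preference
odds and CR reflects sampling noise only — small CRs (≈ 0.03–0.13) are
expected there.

## Aggregation and reporting

Key-index scores are weighted sums of their indicators, category scores of
their key indices, and the overall score of the three categories. All
weights are normalized per level, so each aggregate is a convex
combination bounded by its inputs; the whole tree flattens to a single
per-indicator dot product (the oracle used in tests, agreement 1e−10).

Summaries report mean, sample SD (n − 1 denominator; a single value
reports SD = 0), min, median and max, rounded to 2 decimals for printing
with full precision retained internally. Rankings are descending with
competition ("min") ranks for ties, stable by unit id. The heat-map export
is the units × (13 key indices + 3 categories) matrix with constant
columns flagged so plotting layers can omit them (a key index whose
indicators are at full score for every unit, like the bundled animal-
health surveillance pair, is such a column).

## Reliability

Cronbach's alpha over the three category scores against the composite:
raw α = k/(k−1)·(1 − Σvar_i/var_total) with (n−1) variances, and
standardized α = k·r̄/(1 + (k−1)·r̄) from the mean pairwise correlation
(cross-checked against pingouin in the test suite). Items with (floating-
point) zero variance make the correlations undefined; they are flagged and
the standardized alpha reported as NaN. Sub-level reliability is out of
scope by design: key indices are constructed to capture complementary
constructs, not a single underlying one.

## Latent class analysis

Category scores are rounded to 2 decimals (the reporting precision) and
binned into four groups — ≤ 40.00, 40.01–50.00, 50.01–60.00, > 60.00; the
rounding makes the groups exhaustive, closing the (40.00, 40.01) and
(50.00, 50.01) gaps the labels would otherwise leave for unrounded scores.
The three binned items per unit are modeled as a K-class multinomial
mixture P(x) = Σ_k π_k ∏_j ρ_{k,j,x_j}, fit by EM:

- multi-start (default 50 starts) with Dirichlet(1) random initialization
  of π and each ρ row; best final log-likelihood kept;
- convergence when the log-likelihood gain falls below 1e−8 (cap 1000
  iterations); the log-likelihood is asserted non-decreasing at every
  iteration;
- ρ cells floored at 1e−6 and renormalized to avoid zero-probability
  degeneracy on sparse cells;
- classes reordered by descending prevalence, so reported parameters are
  deterministic given the seed; K = 1 is supported for testing.

Model selection minimizes BIC = −2·loglik + p·ln(n) with
p = (K−1) + K·Σ_j(C_j−1) over K = 2..6 (per-K seeds spawned from one run
seed). Units take their modal posterior class, ties to the lower class
index.

## Synthetic data generator

The generator reproduces the structure the pipeline assumes, not any real
marginal distribution:

- **numeric indicators**: log-normal (default μ = 2, σ = 0.6 on the log
  scale) — municipal counts and rates are right-skewed, which is precisely
  the motivation for robust scaling over raw min–max;
- **shared capacity factor**: a per-unit N(0, 0.3) deviate added on the
  log scale to every per-unit numeric indicator, sign-flipped for
  `higher_worse` ones. It models the empirical fact that well-run units
  tend to do well across domains and gives the bundled instance a
  realistic positive inter-category correlation (raw alpha ≈ 0.5–0.6);
  without it the three category scores would be independent and the
  reliability stage meaningless;
- **binary rates**: 1.0 for the prefecture-wide surveillance pair
  B2.1/B2.2 (hence the constant heat-map column), 0.15 for the rare
  council policy agreement C1.1, 0.6 for declarations C1.2, 0.8 for AMR
  surveillance C4.1, 0.5 otherwise; ordinal C1.5 is skewed toward absence
  (0.4/0.3/0.2/0.1);
- **coverage**: regional indicators drawn once per district and broadcast;
  monitoring indicators missing for exactly round(n·fraction) random units
  (43/60 for A1.2, 48/60 for C5.3);
- **planted classes** (optional, on by default): a two-class structure
  (45/55 mixing) shifting the per-unit numeric External-Drivers indicators
  by ∓0.6 on the log scale, mirroring municipal profiles that separate on
  external drivers; the true labels are emitted alongside the table;
- **expert panels**: Bradley–Terry responses — an expert prefers i over j
  with probability w_i/(w_i + w_j) — so pairwise counts are binomial and
  true weights are recoverable in expectation. The bundled true weights
  are the published expert consensus of the Fukuoka instance (categories
  22.5/36.6/40.9%; key-index weights per category).

Everything is a pure function of (inputs, seed).

What passing tests on this instance do **not** show: agreement with any
real municipality's scores (the marginals are synthetic), the behavior of
the imputation under informative missingness (sites are missing at
random here), or latent structure beyond the planted two-class shift.
Full-pipeline LCA on the bundled instance recovers a two-class solution
whose labels agree only partially with the planted ones — the 4-bin
profiles are coarse and the capacity factor adds within-class spread — so
parameter-recovery claims are established on directly planted multinomial
data (n = 600) in the acceptance suite instead.

## Problem sizes and defaults

The bundled instance is 60 units × 34 indicators with 23-expert panels;
recovery simulations use n = 600 (LCA) and panels up to 2300 experts
(weighting); the EM multi-start default is 50 (20 in the heavier test
loops). These sizes keep the full test suite and the acceptance script at
around a minute each on one CPU while leaving the stochastic checks
signal-dominated.

## Known limitations

- The ratio-reciprocal judgment rule is orientation-dependent (above);
  comparisons across datasets should fix an orientation convention or use
  complement mode.
- Observed-mean imputation removes all between-unit variation in imputed
  entries; with 70%+ missingness (A1.2, C5.3) those indicators contribute
  essentially a constant to most units' scores. No model-based or
  multivariate imputation is provided.
- Min–max anchoring to the observed best/worst makes scores relative to
  the cohort: adding a unit can change every score.
- BIC selection with 3 four-category items can only distinguish limited
  structure (63 possible patterns); with 60 units the selected K is
  typically small.
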