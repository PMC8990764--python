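# Methods

This note records the statistical model behind `mixtrial`, the defaults and
their rationale, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer should know about.

## Trial model

The design is a split plot: within each season and replicate block, the
cropping system (wheat monoculture, pea monoculture, wheat–pea mixture) is
the main plot and the wheat entry the randomized subplot. The default design
carries 2 seasons × 4 blocks × 15 entries; the pea monoculture main plot has
a single subplot (one pea cultivar), and mixture plots produce two records,
one per species. Observations are one row per plot × species with yields at
14% grain moisture (`normalize_moisture` conserves dry matter:
`y14 = raw·(1−m)/0.86`), quality traits from the wheat rows, plot-level weed
cover and lodging, two dated NGLA assessments, and 0–3 stem-base disease
scores for a subset of entries.

## Indices

All mixture indices are computed per block, pairing each mixture plot with
the same-entry wheat-monoculture plot and the pea-monoculture plot of its
block; this matches the per-plot response-ratio models downstream and keeps
block-level environment shared between numerator and denominator.

- Expected mixture yield, yield gain and LER follow the density-weighted
  definitions given in the README. Undefined cases (zero monoculture yield)
  raise or are skipped with a logged count — never silently imputed. This is
  why lodging, typically zero in wheat plots, never enters as an RME and is
  reported as absolute per-system means instead.
- Two routes to a "relative yield gain" coexist and are labelled
  distinctly: `yg_rel` (ratio of season/cell means, the worked-example
  route) and `rme_yield_gain` (mean of per-plot ratios). They differ by
  Jensen-type gaps of a few tenths of a percent at these noise levels.
- AUNGLA integrates the NGLA series trapezoidally over days; because only
  day differences enter, using assessment dates or days since sowing is
  equivalent.
- The foot-disease index is the standard weighted severity on 0–100 with
  maximum class 3: `DIA = 100·(n1 + 2·n2 + 3·n3)/(3·N)`. The joint index
  needs per-tiller maxima across pathogens, so plot tables carry a dedicated
  `fd_joint_*` count block (the simulator derives it from per-tiller draws);
  tables without it leave the joint index missing.
- Quality classes cut protein at 10% and 11%, with both boundaries assigned
  to the middle (second-class baking) class, reading the conventional
  "10–11%" band as closed.

## Inference

Per season (seasons are analysed separately; mixing them raises), the
split-plot model is

    R ~ system*entry + replicate + (1 | replicate:mainplot)

with replicate fixed, exactly as conventionally written for this design.
For balanced complete data the two error strata are estimated in closed
form: the main-plot stratum is the system × replicate mean square with
(a−1)(r−1) degrees of freedom, the subplot stratum the residual mean square
with a(r−1)(b−1). Under balance this reproduces the REML solution whenever
the main-plot variance component is interior, and is the classical
exact-coverage analysis when that component is estimated at zero (the fit
then carries a `boundary` flag instead of being silently refit). Unbalanced
data fall back to statsmodels MixedLM (REML) with Wald inference and
explicit flagging of unestimable cells.

Contrast variances are assembled from the two mean squares: a contrast
constant within main plots uses the main-plot stratum df, a within-system
entry contrast the subplot df, and mixed contrasts (e.g. mono vs mixture
within one entry) get Satterthwaite degrees of freedom from the two
components. System F-tests use the main-plot stratum as denominator; entry
and interaction tests the subplot stratum — with 2 systems, 4 blocks and 15
entries this yields the familiar F(1,3), F(14,84) layout. The multiple-
testing family is the requested pairwise set within one response × season
(default: mono-vs-mixture within each entry), Holm-adjusted by the in-house
step-down implementation.

Entry-level models for per-block metrics (YG, LER) are `R ~ entry +
(1 | replicate)`; per-entry means carry the block variance component
(Satterthwaite df across the block and residual mean squares, F with
(k−1)(r−1) denominator df — F(14,42) at the default size), and the
robustness verdict is purely the CI against the metric's null (0 for
YG/RME, 1 for LER). The response-ratio (RME) model fits each response on
its own variance — the per-response weighting collapses to the unweighted
one-sample block-mean analysis when responses are homoscedastic — with
df = r−1 and an effect-present flag when the CI excludes zero.

Lodging percentages (many zeros) are rounded to integers and fitted with a
Poisson GLM (log link) on system, giving rate ratios against the mixture;
an all-zero response returns an intercept-only summary with a degenerate-fit
warning rather than a −∞ intercept.

Confidence level defaults to 0.95 and is configurable via the design.

## GGE and genotype-by-trait analysis

The genotype × environment table holds block means with environments
labelled `season:system` over the two wheat systems. Columns are centered by
environment means (removing the environment main effect, retaining G+GE);
GGE uses no scaling by default while the genotype-by-trait analysis
standardizes columns to unit variance (zero-variance traits are dropped with
a warning). Singular values are partitioned symmetrically by default (each
side carries √λ, the "SVP = symmetric" convention); genotype- and
environment-focused partitionings are available. The SVD sign ambiguity is
resolved by making the largest-magnitude environment loading of each
component positive, so coordinates are reproducible run to run; numerically
null singular values (< 1e−12 of the largest) are zeroed. Explained
variances are 100·λ²ₖ/Σλ², reported jointly for the first two components in
the drivers. Mean-vs-stability projects 2-D genotype scores on the unit
vector toward the mean environment score (AEA); the orthogonal norm is the
instability distance, and a zero-length average environment vector raises.
Trait-vector cosines are computed in V·Σ geometry, where the full-rank
cosine of standardized columns equals the Pearson correlation — the rank-2
biplot cosine is its visual approximation.

## Synthetic trials

Continuous responses are drawn as
`mean(season, system) + entry + interaction + block + mainplot + residual`,
with block effects shared by all plots of a (season, block), main-plot
effects by all subplots of a (season, block, system), and a configurable
mixture/monoculture residual-SD ratio (default 1; the magnitude of the
heteroscedasticity implied by weighted response-ratio modelling is not
identifiable from published summaries, so it is a dial, not a default).
Lodging is Poisson with per-system intensity, emergence and pea winter
survival binomial, NGLA read off a logistic curve pinned exactly through
two (day, value) points per season × system plus Gaussian noise, and the
realised harvest index varies around its season × system level (SD 0.015)
so biomass is not a deterministic function of grain. Out-of-range
percentage draws are truncated to [0, 100] and logged. One seed drives one
generation; per-response sub-streams are spawned from a sorted name list so
adding a response never reshuffles another's draws. `zero_noise(config)`
switches every random component off (count draws become their means), which
makes the pipeline exactly recover configured cell means — the basis of the
recovery tests.

The default (`reference_config`) encodes the reference trial's two realised
seasons: wheat 4.2/3.2 and 5.8/5.3 t/ha (mono/mixture), pea 2.0/1.5 and
2.7/0.5 t/ha, protein 10.8/12.3 and 12.9/13.7%, lodging intensities 75 vs 3
and 29 vs 1.6%, NGLA means 4.2→17.7 / 3.6→13.2 (season one) and 7.4→37.3 /
6.5→29.6 (season two), sowing dates giving 224 and 208 mean days to
heading. Entry and interaction shifts sum to zero within each response and
mirror the published ranges and the Hungarian-entry yield-gain pattern
(largest configured gains: Kolompos, Elit CCP, Nemere). SDs (e.g. yield:
block 0.15, main plot 0.10, residual 0.30 t/ha) are plausible organic-trial
magnitudes chosen once.

What the generator does not emulate: spatial field trend, weather-driven
responses, genotype evolution within heterogeneous populations, and any
correlation between responses beyond the shared design effects. Passing
tests therefore demonstrate that the estimators recover the additive
split-plot structure they assume — not that real wheat–pea data satisfy
that structure.

## Problem sizes and numerical choices

The default simulated trial is the full reference layout (368 records).
Monte-Carlo checks use 200–300 replicates on reduced designs (5–15 entries,
one season), enough for coverage assertions with ±3-percentage-point bands;
the acceptance script's coverage check uses 300 replicates. Zero mean
squares are guarded (F defined as 0 when the numerator is also ~0, infinite
otherwise; zero-width CIs when a variance is exactly 0). Variance components
are truncated at zero, as REML would, and flagged as boundary fits.
Delimited output writes floats via Python's shortest round-trip
representation, so write → read is bit-exact.

## Known limitations

- The split-plot machinery requires one observation per system × entry ×
  block cell for the exact-strata path; unbalanced data take the MixedLM
  fallback with conservative contrast SEs.
- Pea responses are not fitted with the full system × entry formula (the
  pea monoculture has no wheat-entry structure); pea comparisons run through
  the RME machinery and per-entry mixture models.
- The joint foot-disease index cannot be recovered from per-pathogen counts
  alone; it needs the per-tiller joint block.
- `service_report` assumes every RME response is mapped to exactly one
  service class and fails loudly otherwise; this is a feature, not a bug.
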