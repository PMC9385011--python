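# Methods

## Framework

The pipeline couples three strands into a single community-level score:

1. **Ecological risk** (per species): how strongly projected ocean change
   pushes conditions inside a species' range outside what the species has
   historically experienced (exposure), and how narrow that historical
   experience is (sensitivity).
2. **Community risk**: ecological risk weighted into each community by its
   revenue dependence on each species (exposure), combined with its overall
   economic reliance on commercial fishing (sensitivity).
3. **Adaptive capacity**: a rank-based composite of 15 social indicators,
   oriented so 1 = least able to adapt.

Each combination step is a Euclidean distance from the origin of a plane
whose axes are scaled to [0, 1] (exposure–sensitivity for species risk,
E–S for community risk, R–AC for vulnerability), so both axes contribute
equally and larger always means worse. The assessment is deliberately
direct-effects only: indirect food-web responses, range shifts, and
seasonal/migratory range structure are outside the model.

## Species-level scoring

For each species, model, and variable, historical and future values are
pooled over every (cell, month) in the species' core range (occurrence
probability ≥ 0.4, inclusive) intersected with the analysis domain mask.
No area or probability weighting is applied: each retained cell-month is
one draw from the "climate experienced". Monthly pooling is the default; an
annual-mean switch (`policies.pooling`) exists because either reading of
"values experienced in the range" is defensible, and the choice only damps
within-year variance.

- Exposure = 100 − % of future values within the historical [P5, P95]
  band. Percentiles use linear interpolation between order statistics and
  band membership is inclusive at both bounds (the most common convention;
  any fixed convention differs only at ties of measure zero).
- Sensitivity = 1 / (P95 − P5) of the historical values. A zero breadth
  (constant conditions) is flagged and assigned the largest finite
  sensitivity in its (model, variable) slice: constant experienced
  conditions are maximal sensitivity under this proxy, and failing the run
  for a degenerate cell would be worse than a flagged imputation.

Raw scores are log10-transformed (zero exposure floored at ε = 0.01 percent
first; the floor preserves ordering) and min–max scaled to [0, 1] within
each (model, variable) slice across species. Scaling within model — and
taking the Euclidean minima within model — keeps each ensemble member's
geometry self-contained before the final averaging; alternative scaling
orders change results only marginally and are not exposed beyond the
documented switches. A slice with a single species scales to 0 with a
warning. The four variables are averaged with equal weight; species missing
a variable average over what they have (warned), species with nothing are
dropped (warned).

θ is computed per model from the across-species minima and averaged into
θ̄. Ensemble disagreement is reported two ways: the cross-model standard
deviation of ē per species, and the pairwise Spearman correlation of the
per-model θ rankings.

## Landings preparation

The filter cascade, in order: aggregate receipts over the analysis years;
remove communities whose confidential weight share is strictly greater
than 20% (a community at exactly 20% stays) and drop confidential rows from
survivors; drop "other/miscellaneous" rows below 5% of community weight —
at or above 5% they are retained and flagged for review rather than
silently dropped or kept, since no defensible automatic rule exists;
expand unidentified-group rows into member species by a configurable split
table (equal splits by default), conserving weight and revenue exactly;
retain per community the smallest weight-sorted prefix of species reaching
90% cumulative weight share (boundary species included, ties broken by
identifier). Shares p_{i,c} are then computed from revenue over the
retained, climate-scored species and renormalized to 1; a switch computes
weight-based shares for the robustness comparison. Retention is by weight
but shares by revenue on purpose: weight tracks what the community catches,
revenue what it earns from.

## Percent ranks

One shared routine is used everywhere a percentile rank appears:
rank(v) = (# communities with strictly smaller value) / (n − 1), ties
sharing the value. This maps a tied minimum to exactly 0 — required so
that all communities with the lowest reliance score S = 0 — and a unique
maximum to 1. An alternative /n denominator is available behind the same
interface.

## Adaptive capacity

Tract metrics are averaged to communities unweighted (population weighting
is available as a config option but not default, since tract–community
intersection without population counts is the base case). The 15 metrics in
4 themes (socioeconomic; household composition/disability; minority
status/language; housing/transportation) are each percent-ranked across
communities; per-capita income — the one metric where larger is better —
has its rank reversed (1 − rank). Ranks are summed and the sum is
percent-ranked again into AC ∈ [0, 1]. Theme sums and the Pearson
correlation of AC with every ranked metric and theme are retained as
diagnostics. Worsening any single metric of one community can only raise
(never lower) its AC, because ranks are monotone in the raw values.

## Vulnerability and diagnostics

V = √(R² + AC²). Quadrant labels split the R × AC plane at configurable
thresholds, defaulting to the midpoint of each axis's observed range (no
principled absolute split exists; the default is declared, not fitted).
Ranks use 1 = worst, ties sharing the worst rank of the block with
identifier-deterministic ordering; the rank difference
(vulnerability rank − risk rank) is negative for communities that look
worse once the social axis is included. The regional summary reports, per
region, the percentage of its communities at or above the across-community
90th-percentile value of R and of V.

## Synthetic generator

The generator's job is to produce inputs with enough real-data structure to
exercise every rule in the pipeline, while keeping the right answers
derivable:

- **Climate fields**: a smooth latitudinal gradient plus iid per-cell
  Gaussian noise, monthly over 10 years, on a 30 × 100 coastal grid with a
  land strip. Gradients are concave (∝ √latitude), so a fixed-width range
  band spans less of the gradient the further north it sits: niche breadth,
  and hence sensitivity ordering, is set by geometry rather than by
  min–max-amplified sampling noise. The future period adds a mean shift in
  units of the per-cell temporal standard deviation (defaults: +1 sd
  temperature, −1 sd pH and oxygen, −0.5 sd chlorophyll — a moderate
  mid-century signal), scaled per earth-system model over 0.8–1.2 to
  emulate ensemble spread. Scenario shift multipliers modulate the shift
  within each species' band.
- **Species ranges**: contiguous latitudinal bands; occurrence probability
  decays linearly from 0.9 at the band centre by 0.3 per row, making the
  core-cell (≥ 0.4) count analytically exact.
- **Landings**: one composition per port group (sparse Dirichlet over ~6
  species plus small miscellaneous and unidentified-group slices), copied
  identically to every member community — matching port-group-level
  reporting and making E provably constant within a group. Revenue is
  weight × a per-species log-normal price, so weight- and revenue-based
  shares genuinely differ. Confidential fractions split rows exactly.
- **Reliance**: log-normal with ~20% exact zeros, so the tied-minimum rank
  rule is exercised by default.
- **Social indicators**: a latent per-community severity in [0, 1]; tracts
  add a shared per-theme effect (σ = 0.08, correlating metrics within a
  theme) and metric noise (σ = 0.05). All metrics are adverse percentages
  except per-capita income, which decreases with severity.

Defaults (20 species, 25 communities in 8 port groups, 3 tracts each,
3-model ensemble, 10 years of monthly data) are the conditions of the
recovery experiments and keep a full run to a few seconds on one CPU. One
RNG stream per generator, derived from the master seed, so regenerating one
input never perturbs another; identical configuration and seed reproduce
byte-identical files.

What the generator does **not** emulate: real oceanography (no upwelling,
fronts, or interannual modes), spatially realistic ranges or coastlines,
price dynamics, or the empirical covariance of social indicators. Passing
tests therefore demonstrate that the machinery is correct and that designed
structure is recovered under realistic noise — not that any particular real
coastline's communities would rank in a given order.

## Numerical conventions and edge cases

- Occurrence threshold inclusive (≥ 0.4); a species with no core cell in
  the domain is excluded with a warning, not an error.
- Exposure with fewer than 20 historical values is flagged low-sample.
- A community with no scored retained revenue is dropped with a warning;
  removed-for-confidentiality communities keep computable sensitivity and
  adaptive capacity.
- Constant metric or θ vectors yield rank 0 / missing correlation with a
  warning rather than NaN propagation.
- All CSV output uses a fixed float format; JSON is key-sorted; the run log
  carries no timestamps — determinism is a contract, checked by test.

## Limitations

Species risk treats the range as static and climate-only; dependence uses a
recent-years snapshot of landings composition; adaptive capacity inherits
the census-indicator view of adaptability (no cultural or institutional
capacity, no Indigenous-specific indicators). Percent ranks make every
score relative to the assessed set: adding or removing communities changes
everyone's E, S, and AC.
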