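# Methods

This note documents the models, conventions and numerical choices behind
`cardlink`, what the synthetic data generator does and does not emulate,
and the limits of what the test suite shows.

## The linked-card state model

The engine keeps one shared state — dataset, filter cards, selection — and
derives everything else from it. The **active row set** is defined as

> a row is active iff it satisfies *every* filter card; within a
> checked-set card the checked values combine by disjunction; a row whose
> value is missing on a filtered variable fails that filter.

Conjunction across cards is the only composition offered (no OR-of-cards,
no negation); it matches the intuition of progressively narrowing a cohort
and makes the active set anti-monotone in the filter set, a property the
tests assert. The missing-fails rule is the safe default for density-style
measurements — a row without a value cannot be shown to satisfy a range —
and can be flipped per board with `keep_missing=True`.

Coordination uses a publish/subscribe bus. Mutating operations publish
exactly one typed event after the state is consistent, so a subscriber that
recomputes on receipt can never observe a stale active set. Subscribers run
in registration order; a subscriber that raises is logged and skipped, the
rest still run. Determinism follows from the absence of any other source of
ordering: identical mutation sequences produce identical states.

Selection (highlighting) is deliberately orthogonal to filtering: it flags
rows for emphasis and travels on its own event type, never removing rows
from any view.

### Variable trichotomy and inference

Columns are typed from their values, ignoring missing cells: all-numeric
columns are **ordinal** when every value is integral and the number of
distinct values is at most `max_ordinal_levels` (default 10; a slider over
a handful of integer levels behaves like an ordered scale), otherwise
**quantitative**; anything else is **categorical**. Ordinal categories sort
numerically; categorical categories keep first-appearance order — both
deterministic. The rule is idempotent, and any automatic decision can be
overridden by recasting (e.g. a string-coded scale such as Braak
"I-II"/"III-IV"/"V-VI" loads as categorical and may be recast to ordinal
with an explicit category order). Missing-cell spellings recognised on
load: empty cell, `NA`, `NaN`, `null` (case-insensitive).

Range filters on ordinal variables compare raw values when the categories
are numeric (the slider shows the values themselves) and category ranks for
string-coded scales. Range bounds are inclusive at both knobs.

Merging two tables ("add to current") is an outer union: rows concatenate,
variables union, absent cells become missing, and a shared variable whose
kinds disagree is re-typed by running inference on the merged column (with
a warning). Keyed joins are out of scope.

## View specifications

Builders are pure functions returning JSON-serialisable specs
(`spec_version: 1`); rendering, if wanted, consumes specs only.

* **Parallel coordinates** — quantitative axes scale positions to the full
  column extent (stable axes under filtering); categorical/ordinal axes
  place categories evenly. Missing values become gaps, not zeros. Axis
  brushes are ordinary range-filter cards with ids `brush:<variable>`, so
  brushing an axis updates every linked card; removing a brushed axis
  discards its filter (logged) and can only enlarge the active set.
* **Parallel sets** — computed over active rows complete in every tier
  variable; widths are `fractions.Fraction`s, so the conservation laws
  (tier widths sum to 1; each bar equals the sum of incident ribbons;
  ribbons sum to 1) hold exactly, not to tolerance. Quantitative variables
  are refused with advice to recast: no binning rule is guessed on the
  user's behalf.
* **Radar** — per-axis min–max normalisation over *active* rows, keeping
  polygons comparable within the current filter context; a degenerate axis
  (min = max) maps everything to 0.5. Only rows complete in all axes yield
  polygons.
* **Scatter** — pairwise-complete rows only; the tooltip payload carries
  the full record.
* **Box plot** — Tukey convention: hinges are medians of the lower/upper
  halves (median included in both when n is odd), fences at 1.5·IQR beyond
  the hinges, whiskers clamped to the most extreme data inside the fences,
  outliers listed individually. Interpolated percentiles are available via
  `interpolated_quartiles=True` for users who prefer the numpy convention.

## Statistics cards

`alpha` (default 0.05) applies to every gate; `min_n` (default 3) is the
smallest usable sample or group.

* **Normality gate** — one-sample Kolmogorov–Smirnov against a normal law
  with mean and SD estimated from the sample. Because the parameters are
  estimated, the naive K-S p-value is anti-conservative; p-values therefore
  carry the Lilliefors correction by default
  (`statsmodels.stats.diagnostic.lilliefors`, table method for n ≥ 4), with
  `lilliefors=False` restoring the naive variant. Zero-variance samples are
  declared non-normal with a warning.
* **Homoscedasticity** — Levene's test centred on the median, robust to
  the non-normality the other gate tolerates.
* **Correlation card** — pairwise-complete observations; Pearson's r is
  reported iff both variables pass the normality gate, Spearman's ρ always.
* **Comparison of means** — groups in category order (μ₁ is the first
  group's mean); groups under `min_n` are excluded with a warning. The
  decision tree is total: 2 groups → Student's t / Welch's t / two-sample
  K-S (Mann–Whitney U selectable via `nonparametric="mannwhitney"`);
  more groups → one-way ANOVA when all-normal and homoscedastic, else
  Kruskal–Wallis. For two groups all three alternatives are reported; the
  one-sided K-S p-values come from the one-sided K-S statistics (sample 1
  stochastically larger means its empirical CDF lies below sample 2's).
  One-sided tabs are marked not-applicable for ANOVA and Kruskal–Wallis.
  No multiple-testing correction is applied across the three tabs — all
  three raw p-values are shown and the narrative says so explicitly.

Every card emits a narrative: the ordered list of gates, their p-values and
the resulting decision, so a report can be read without re-deriving the
logic.

## Spatial image filters

Annotations are sidecar JSON polygons in pixel space (origin top-left).
Polygons need ≥ 3 vertices; regions may overlap, resolved by listed order
(first hit wins — deterministic and user-controlled); boundary points count
as inside so border clicks act; polygons reaching outside the image are
clipped to the frame with a warning. Point-in-polygon uses shapely's
`covers`. A convenience importer converts small indexed-PNG label masks to
polygons by unioning pixel squares. One spatial association per image; an
image is referenced by path and never embedded in a session, keeping
session files small. Clicking toggles the hit region's value in the
image's spatial filter card; an empty selected-value set on such a card
means "no region chosen" and passes all rows (clicking a region twice
returns to pass-all), unlike a plain checked-set card where an empty set
matches nothing.

## The synthetic cohort generator

The generator emulates the *shape* of a clinical–histopathological AD
study — no real cohort values are targeted. One row per patient ×
hippocampal subfield (DG, CA1, CA2, CA3, SUB), AD patients listed first
(`Az1…`). Choices:

* **Densities are lognormal** with region-specific control means (NeuN:
  DG 110, CA1 85, CA2 95, CA3 90, SUB 75 density units; log-scale
  σ = 0.18): positive and right-skewed like biological volume densities,
  but mild enough that small per-group samples usually pass the normality
  gate — so the parametric branch of the means card is the common path,
  while strongly non-normal inputs (exponential, uniform) exercise the
  nonparametric branch in tests.
* **The AD deficit is exact by construction**: every AD NeuN draw is
  shifted down by `effect_sd` × the theoretical pooled control SD (the SD
  of the equal-weight lognormal mixture over regions, ≈ 20.3 units at the
  defaults). The pooled standardised effect therefore equals `effect_sd`
  (default 1.0) without simulation calibration, which the generator
  self-consistency test confirms empirically (±0.1 SD).
* **Braak stage** is generated as the grouped stages I-II / III-IV / V-VI,
  a deterministic monotone function of disease progression (AD progression
  ~ Gamma(4, 2) years, clipped to [0.5, 20]; controls 0 years, stage I-II);
  Tau and Aβ densities scale with stage (×1 / ×2.5 / ×5), giving the
  positive association the correlation card should find.
* **Missingness** (default 2%) is injected only into the four histological
  density columns; identity columns (Patient, Region, Condition) and
  per-patient clinical values stay complete, mirroring how missingness
  arises in section-level measurements.
* A **section-image generator** draws one blob per region on a ring
  (pairwise disjoint, inside the frame by construction) and writes a
  byte-stable annotation JSON, so spatial filtering is testable without any
  real histology.

What passing tests on this generator do **not** show: robustness to
real-world messiness (typos, mixed decimal separators, multi-sheet
workbooks), to non-monotone stage–pathology relationships, or to images
where regions genuinely interleave; the generator's regions are convex-ish
and disjoint.

## Problem sizes and seeds

The statistical properties are checked at the sizes their guarantees are
stated at: 200 random datasets for filter-oracle equivalence; 2,000
replicates for type-I calibration (n = 30 per group); 200 replicates each
for correlation recovery (n = 500, ρ = 0.8) and the normality gate
(n = 1,000); 1,050 fixtures for view conservation; 500 random points for
spatial hit-testing; 500 replicates for the cohort power property (15
values per condition: 3 patients × 5 regions). Note two of these sit at
their theoretical margins by design: the gate's accuracy on normal data has
expectation 1−α = 95%, and the two-sided t power at a pooled effect of 1 SD
with n = 15 per group is ≈ 0.76, so measured values hover near the 95% and
75% lines. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the acceptance script derives independent
substreams from its single `--seed` via `SeedSequence`.

## Known limitations

* XLSX round-trips drop trailing all-missing rows (indistinguishable from
  sheet padding); CSV round-trips keep them.
* One spatial association per image; multi-variable spatial filters would
  need one image card per variable.
* No undo/redo, OR-of-cards or NOT filters; no multi-factor ANOVA, paired
  tests, post-hoc comparisons or effect-size confidence intervals.
* Sessions store datasets by reference: moving the data file requires the
  `--dataset` override on restore.
* The mask importer unions per-pixel squares and is meant for small masks,
  not megapixel segmentations.
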