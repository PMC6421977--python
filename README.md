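# cardlink

Headless, scriptable **linked-card exploratory analysis** for tabular
(neuro)science data. `cardlink` re-creates the analytical core of
coordinated-multiple-view dashboards — composable filters, six linked
views, image-region spatial filters and statistics cards with automatic
test selection — as an importable Python library plus a thin CLI, with no
browser, server or database.

It is aimed at scientists who hold one-row-per-observation tables (for the
bundled synthetic example: Alzheimer's-disease patients × hippocampal
subfields, with neuronal and plaque densities, Braak stage, age and disease
progression) and want to slice, view and sanity-test them interactively
from scripts or a shell, with every widget guaranteed to show the same
filtered data.

## The model

**Variables** are typed by a trichotomy — *categorical*, *ordinal*,
*quantitative* — inferred automatically on load and correctable by recast.
**Filter cards** hold one predicate each: a checked set of category values,
an inclusive dual-knob range, or a clickable image-region selection. The
**active row set** is the conjunction over cards (disjunction within a
card's checked values); rows missing a filtered value drop out. A
**publish/subscribe event bus** broadcasts `filter_changed`,
`selection_changed`, `schema_changed` and `data_changed` events so every
subscribed card rebuilds from the same state — senders never address
receivers.

**View builders** are pure functions emitting renderer-agnostic JSON specs
for parallel coordinates (with axis brushes that are ordinary range
filters), parallel sets (exact rational bar/ribbon fractions: per tier
Σ widths = 1 and each bar equals the sum of its incident ribbons), radar
charts (per-axis min–max normalisation over active rows), scatter plots,
Tukey box plots (median-of-halves hinges, 1.5·IQR fences) and the raw
table.

**Statistics cards** narrate their decisions. The correlation card gates
Pearson's *r* behind a Kolmogorov–Smirnov normality check
(Lilliefors-corrected, since μ and σ are estimated) and always reports
Spearman's ρ. The comparison-of-means card applies the decision tree

| groups | normal | equal variances | test |
|-------:|:------:|:---------------:|------|
| 2 | yes | yes | Student's *t* |
| 2 | yes | no  | Welch's *t* |
| 2 | no  | –   | two-sample K–S (or Mann–Whitney U) |
| >2 | yes | yes | one-way ANOVA |
| >2 | otherwise | | Kruskal–Wallis |

and, for two groups, reports all three alternatives (μ₁≠μ₂, μ₁>μ₂, μ₁<μ₂)
with raw p-values. Homoscedasticity uses Levene's test centred on the
median.

**Images** (PNG/JPEG/TIFF/BMP) register with tags and associations to
categorical values; a *spatial association* maps annotated polygon regions
to the values of one variable, so clicking inside a region toggles it in a
filter. **Sessions** serialise the whole state to versioned JSON and
restore it bit-for-bit.

## Worked example

```python
from cardlink import Board, CheckedSet, generate_clinical_dataset, means_comparison_card
from cardlink.fixtures import FixtureConfig

ds = generate_clinical_dataset(FixtureConfig(seed=3, missing_rate=0.0))
rep = means_comparison_card(ds, "Neuronal density per volume (NeuN)", "Condition")
for line in rep.narrative:
    print(line)
```

prints

```
Group 'AD': n=40, mean=70.74, sd=22.33; normality (lilliefors_ks) p=0.9817 -> normal at alpha=0.05.
Group 'Control': n=20, mean=91.45, sd=18.75; normality (lilliefors_ks) p=0.1897 -> normal at alpha=0.05.
Homoscedasticity (Levene, median-centred): statistic=1.1345, p=0.2912 -> equal variances at alpha=0.05.
Decision: 2 groups, all normal, homoscedastic -> student_t.
...
student_t [two_sided]: statistic=-3.5632, p=0.0007406.
student_t [less]: statistic=-3.5632, p=0.0003703.
```

Both gates pass, so Student's *t* is chosen; the two-sided tab rejects
equality of mean NeuN density and the μ₁<μ₂ tab shows the AD mean sits
below the Control mean — the one-SD deficit the synthetic cohort builds
in. The `examples/` directory holds one short script per capability
(loading/filtering, linked views, statistics cards, spatial image filters,
sessions); each prints the numbers it computes and what they mean.

## Command line

```sh
cardlink fixtures clinical --n-ad 8 --n-control 4 --seed 7 --out data.csv
cardlink load data.csv
cardlink filter add Region --checked CA1
cardlink view pcp --axes "Patient,Region,Neuronal density per volume (NeuN)" --out spec.json
cardlink stats means "Neuronal density per volume (NeuN)" --group Condition
```

Commands compose against a session file (`--session`, default
`session.cardlink.json`) and are transactional: a failing command leaves
the session untouched.

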