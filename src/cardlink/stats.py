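"""Statistics cards with automatic test selection.

Three cards mirror a preliminary exploratory workflow:

* **column statistics** — mean, sample SD, n, min, max of one column;
* **correlation card** — normality-gated: Pearson *and* Spearman when both
  variables pass a Kolmogorov–Smirnov goodness-of-fit gate, Spearman only
  otherwise;
* **comparison of means** — unpaired comparison of a quantitative variable
  across the groups of a categorical variable.  Number of cases, normality
  and homoscedasticity gates choose among Student's t, Welch's t, two-sample
  Kolmogorov–Smirnov, one-way ANOVA and Kruskal–Wallis; for two groups the
  two-sided and both one-sided alternatives (μ1≠μ2, μ1>μ2, μ1<μ2) are all
  reported.

Every card records a narrative — the ordered list of decisions it took and
the p-values behind them — so the analysis can be communicated verbatim.

Normality uses the one-sample K-S statistic against a normal law with mean
and SD estimated from the data; p-values carry the Lilliefors correction by
default, since the naive K-S p-value is anti-conservative when parameters
are estimated.  Homoscedasticity uses Levene's test centred on the median,
robust to the non-normality the other gate tolerates.  No multiple-testing
correction is applied across the three alternative tabs; all three raw
p-values are shown, and the narrative says so.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats as sps

from .dataset import Dataset, SchemaError, is_missing

__all__ = [
    "StatsConfig",
    "ColumnStats",
    "NormalityResult",
    "CorrelationReport",
    "MeansComparisonReport",
    "column_statistics",
    "ks_normality",
    "correlation_card",
    "select_means_test",
    "means_comparison_card",
]

Alternative = Literal["two_sided", "greater", "less"]
ChosenTest = Literal["student_t", "welch_t", "ks_two_sample", "mann_whitney_u", "one_way_anova", "kruskal_wallis"]


@dataclass(frozen=True)
class StatsConfig:
    """Shared knobs of the statistics cards.

    alpha: significance level applied to every gate and test (0 < alpha < 1).
    min_n: minimum usable sample size per column/group.
    lilliefors: if False, use the naive K-S p-value (parameters treated as
        known) instead of the Lilliefors-corrected one.
    nonparametric: two-group fallback when normality fails — the two-sample
        Kolmogorov–Smirnov test by default, Mann–Whitney U as alternative.
    """

    alpha: float = 0.05
    min_n: int = 3
    lilliefors: bool = True
    nonparametric: Literal["ks", "mannwhitney"] = "ks"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        if self.min_n < 1:
            raise ValueError("min_n must be >= 1")


@dataclass(frozen=True)
class ColumnStats:
    mean: float
    sd: float  # sample SD (n-1 denominator); 0 with a warning for n=1
    n: int
    min: float
    max: float

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "n": self.n, "min": self.min, "max": self.max}


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    is_normal: bool
    test_name: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "p_value": self.p_value,
            "is_normal": self.is_normal, "test_name": self.test_name,
        }


@dataclass
class CorrelationReport:
    normality_x: NormalityResult
    normality_y: NormalityResult
    pearson: dict | None  # {"r", "p"} — present iff both variables normal
    spearman: dict        # {"rho", "p"}
    n: int
    narrative: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "normality_x": self.normality_x.to_dict(),
            "normality_y": self.normality_y.to_dict(),
            "pearson": self.pearson,
            "spearman": self.spearman,
            "n": self.n,
            "narrative": list(self.narrative),
        }


@dataclass
class MeansComparisonReport:
    groups: list  # [{"value", "stats": ColumnStats}]
    normality: dict  # group value -> NormalityResult
    homoscedasticity: dict  # {"test_name", "statistic", "p", "holds"}
    chosen_test: ChosenTest
    results: dict  # alternative -> {"statistic", "p"} | {"not_applicable": reason}
    excluded_groups: list = field(default_factory=list)
    narrative: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "groups": [{"value": g["value"], "stats": g["stats"].to_dict()} for g in self.groups],
            "normality": {str(k): v.to_dict() for k, v in self.normality.items()},
            "homoscedasticity": self.homoscedasticity,
            "chosen_test": self.chosen_test,
            "results": self.results,
            "excluded_groups": list(self.excluded_groups),
            "narrative": list(self.narrative),
        }


# ---------------------------------------------------------------------------


def _clean(values) -> np.ndarray:
    return np.asarray([float(v) for v in values if not is_missing(v)], dtype=float)


def column_statistics(values) -> ColumnStats:
    """Descriptive statistics over non-missing values only."""
    arr = _clean(values)
    if arr.size == 0:
        raise ValueError("column statistics need at least one non-missing value")
    if arr.size == 1:
        warnings.warn("n=1: sample SD undefined, reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(np.std(arr, ddof=1))
    return ColumnStats(
        mean=float(np.mean(arr)), sd=sd, n=int(arr.size),
        min=float(np.min(arr)), max=float(np.max(arr)),
    )


def ks_normality(values, config: StatsConfig = StatsConfig()) -> NormalityResult:
    """K-S goodness-of-fit gate against a fitted normal distribution.

    ``is_normal`` is ``p >= alpha``.  Degenerate (zero-variance) samples are
    declared non-normal with a warning.
    """
    arr = _clean(values)
    if arr.size < config.min_n:
        raise ValueError(f"normality gate needs n >= {config.min_n}, got n={arr.size}")
    mu, sd = float(np.mean(arr)), float(np.std(arr, ddof=1))
    if sd == 0 or not math.isfinite(sd):
        warnings.warn("degenerate sample (zero variance): treated as non-normal", stacklevel=2)
        return NormalityResult(statistic=float("inf"), p_value=0.0, is_normal=False,
                               test_name="ks_degenerate")
    if config.lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lilliefors

        method = "table" if arr.size >= 4 else "approx"
        stat, p = _lilliefors(arr, dist="norm", pvalmethod=method)
        name = "lilliefors_ks"
    else:
        stat, p = sps.kstest(arr, "norm", args=(mu, sd))
        name = "ks_naive"
    p = float(min(max(p, 0.0), 1.0))
    return NormalityResult(statistic=float(stat), p_value=p, is_normal=p >= config.alpha, test_name=name)


def correlation_card(x, y, config: StatsConfig = StatsConfig()) -> CorrelationReport:
    """Normality-gated correlation of two paired numeric columns.

    Works on pairwise-complete observations.  Pearson's r is reported only
    when both variables pass the normality gate; Spearman's rho is always
    reported.
    """
    pairs = [(a, b) for a, b in zip(x, y) if not is_missing(a) and not is_missing(b)]
    if len(pairs) < config.min_n:
        raise ValueError(f"correlation needs n >= {config.min_n} pairwise-complete pairs, got {len(pairs)}")
    xs = np.asarray([float(a) for a, _ in pairs])
    ys = np.asarray([float(b) for _, b in pairs])
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")

    nx = ks_normality(xs, config)
    ny = ks_normality(ys, config)
    narrative = [
        f"n = {len(pairs)} pairwise-complete observations.",
        f"Normality of x ({nx.test_name}): statistic={nx.statistic:.4f}, p={nx.p_value:.4g} -> "
        f"{'normal' if nx.is_normal else 'NOT normal'} at alpha={config.alpha}.",
        f"Normality of y ({ny.test_name}): statistic={ny.statistic:.4f}, p={ny.p_value:.4g} -> "
        f"{'normal' if ny.is_normal else 'NOT normal'} at alpha={config.alpha}.",
    ]
    rho, p_s = sps.spearmanr(xs, ys)
    spearman = {"rho": float(rho), "p": float(p_s)}
    if nx.is_normal and ny.is_normal:
        r, p_r = sps.pearsonr(xs, ys)
        pearson = {"r": float(r), "p": float(p_r)}
        narrative.append(
            "Both variables compatible with normality: Pearson's r and Spearman's rho are both reported."
        )
        narrative.append(f"Pearson r={pearson['r']:.4f} (p={pearson['p']:.4g}).")
    else:
        pearson = None
        narrative.append("Normality not met: only Spearman's rank correlation is reported.")
    narrative.append(f"Spearman rho={spearman['rho']:.4f} (p={spearman['p']:.4g}).")
    return CorrelationReport(
        normality_x=nx, normality_y=ny, pearson=pearson, spearman=spearman,
        n=len(pairs), narrative=narrative,
    )


# ---------------------------------------------------------------------------
# Comparison of means


def select_means_test(
    n_groups: int, all_normal: bool, homoscedastic: bool,
    nonparametric: Literal["ks", "mannwhitney"] = "ks",
) -> ChosenTest:
    """The decision tree choosing the comparison test.

    ========  ==========  ===============  ==================
    n_groups  all_normal  homoscedastic    chosen test
    ========  ==========  ===============  ==================
    2         yes         yes              Student's t
    2         yes         no               Welch's t
    2         no          (ignored)        two-sample K-S (or Mann-Whitney U)
    >2        yes         yes              one-way ANOVA
    >2        otherwise                    Kruskal-Wallis
    ========  ==========  ===============  ==================
    """
    if n_groups < 2:
        raise ValueError("comparison of means needs at least 2 groups")
    if n_groups == 2:
        if not all_normal:
            return "ks_two_sample" if nonparametric == "ks" else "mann_whitney_u"
        return "student_t" if homoscedastic else "welch_t"
    if all_normal and homoscedastic:
        return "one_way_anova"
    return "kruskal_wallis"


def _two_group_results(chosen: ChosenTest, g1: np.ndarray, g2: np.ndarray) -> dict:
    """All three alternatives for a two-group comparison.

    Alternatives are keyed symbolically: two_sided (μ1≠μ2), greater (μ1>μ2),
    less (μ1<μ2), with group 1 and 2 in group-category order.
    """
    out = {}
    for alt in ("two_sided", "greater", "less"):
        scipy_alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alt]
        if chosen == "student_t":
            stat, p = sps.ttest_ind(g1, g2, equal_var=True, alternative=scipy_alt)
        elif chosen == "welch_t":
            stat, p = sps.ttest_ind(g1, g2, equal_var=False, alternative=scipy_alt)
        elif chosen == "ks_two_sample":
            # K-S alternatives speak about CDFs: sample 1 stochastically
            # larger (mu1 > mu2) means its CDF lies BELOW sample 2's.
            ks_alt = {"two_sided": "two-sided", "greater": "less", "less": "greater"}[alt]
            stat, p = sps.ks_2samp(g1, g2, alternative=ks_alt)
        elif chosen == "mann_whitney_u":
            stat, p = sps.mannwhitneyu(g1, g2, alternative=scipy_alt)
        else:  # pragma: no cover - guarded by caller
            raise AssertionError(chosen)
        out[alt] = {"statistic": float(stat), "p": float(p)}
    return out


def means_comparison_card(
    dataset_or_values,
    value: str | None = None,
    group: str | None = None,
    filter_state=None,
    config: StatsConfig = StatsConfig(),
    groups: dict | None = None,
) -> MeansComparisonReport:
    """Compare a quantitative variable's mean across unpaired groups.

    Two calling styles:

    * ``means_comparison_card(dataset, "NeuN density", "Condition", filter_state)``
      — group the active rows of a dataset;
    * ``means_comparison_card(None, groups={"AD": [...], "Control": [...]})``
      — pre-split numeric samples.

    Gates: per-group K-S normality and Levene (median-centred)
    homoscedasticity at ``config.alpha``; groups below ``config.min_n``
    usable values are excluded with a warning.  For two groups all three
    alternatives are reported; with more, only the two-sided hypothesis
    applies.
    """
    if groups is None:
        dataset: Dataset = dataset_or_values
        value_var = dataset.variable(value)
        if value_var.kind != "quantitative":
            raise SchemaError(f"comparison of means needs a quantitative variable, {value} is {value_var.kind}")
        group_var = dataset.variable(group)
        if group_var.kind == "quantitative":
            raise SchemaError(f"grouping variable must be categorical/ordinal, not {group}")
        active = filter_state.active_rows if filter_state is not None else set(dataset.row_ids())
        groups = {}
        for cat in group_var.categories or ():
            vals = [
                r.values.get(value)
                for r in dataset.rows
                if r.row_id in active and r.values.get(group) == cat and not is_missing(r.values.get(value))
            ]
            if vals:
                groups[cat] = vals

    usable, excluded = {}, []
    for cat, vals in groups.items():
        arr = _clean(vals)
        if arr.size < config.min_n:
            excluded.append(cat)
            warnings.warn(f"group {cat!r} excluded: n={arr.size} < min_n={config.min_n}", stacklevel=2)
        else:
            usable[cat] = arr
    if len(usable) < 2:
        raise ValueError(f"comparison of means needs >= 2 usable groups, got {len(usable)}")

    narrative = []
    group_stats, normality = [], {}
    for cat, arr in usable.items():
        cs = column_statistics(arr)
        group_stats.append({"value": cat, "stats": cs})
        nr = ks_normality(arr, config)
        normality[cat] = nr
        narrative.append(
            f"Group {cat!r}: n={cs.n}, mean={cs.mean:.4g}, sd={cs.sd:.4g}; "
            f"normality ({nr.test_name}) p={nr.p_value:.4g} -> "
            f"{'normal' if nr.is_normal else 'NOT normal'} at alpha={config.alpha}."
        )
    all_normal = all(nr.is_normal for nr in normality.values())

    lev_stat, lev_p = sps.levene(*usable.values(), center="median")
    homoscedastic = bool(lev_p >= config.alpha)
    homo = {
        "test_name": "levene_median", "statistic": float(lev_stat),
        "p": float(lev_p), "holds": homoscedastic,
    }
    narrative.append(
        f"Homoscedasticity (Levene, median-centred): statistic={lev_stat:.4f}, p={lev_p:.4g} -> "
        f"{'equal variances' if homoscedastic else 'UNEQUAL variances'} at alpha={config.alpha}."
    )

    chosen = select_means_test(len(usable), all_normal, homoscedastic, config.nonparametric)
    narrative.append(
        f"Decision: {len(usable)} groups, "
        f"{'all normal' if all_normal else 'normality violated'}, "
        f"{'homoscedastic' if homoscedastic else 'heteroscedastic'} -> {chosen}."
    )

    samples = list(usable.values())
    if len(usable) == 2:
        results = _two_group_results(chosen, samples[0], samples[1])
        order = list(usable)
        narrative.append(
            f"Alternatives reported with mu1 = mean({order[0]!r}) and mu2 = mean({order[1]!r}): "
            "mu1 != mu2 (two_sided), mu1 > mu2 (greater), mu1 < mu2 (less). "
            "All three raw p-values are shown; no multiple-testing correction is applied across tabs."
        )
    else:
        if chosen == "one_way_anova":
            stat, p = sps.f_oneway(*samples)
        else:
            stat, p = sps.kruskal(*samples)
        results = {
            "two_sided": {"statistic": float(stat), "p": float(p)},
            "greater": {"not_applicable": f"one-sided alternatives are undefined for {chosen}"},
            "less": {"not_applicable": f"one-sided alternatives are undefined for {chosen}"},
        }
    for alt in ("two_sided", "greater", "less"):
        r = results[alt]
        if "p" in r:
            narrative.append(f"{chosen} [{alt}]: statistic={r['statistic']:.4f}, p={r['p']:.4g}.")

    return MeansComparisonReport(
        groups=group_stats, normality=normality, homoscedasticity=homo,
        chosen_test=chosen, results=results, excluded_groups=excluded, narrative=narrative,
    )
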