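"""Group-level statistical design for cohort tables.

The omnibus test for each measure is a mixed-design ANOVA with one
between-subjects factor (group) and one two-level within-subjects factor
(period), followed by pairwise t-tests whose p-values are adjusted with
the Holm-Bonferroni step-down correction.  Stimulus-evoked transients
are tested one-tailed (an increase over basal activity is the
hypothesis); all other tests are two-tailed.  With unequal group sizes,
independent-sample t-tests are Welch-adjusted.  The association between
the post-context change in spontaneous event rate and the activity
elicited by the visual danger stimulus is quantified with a Pearson
correlation.

Sums of squares use the classical univariate mixed-model decomposition
with weighted (cell-size) means; because every subject contributes both
within-factor levels, the five components add up to the total sum of
squares exactly, also for unequal group sizes:

    SS_total = SS_group + SS_subjects(group)
             + SS_period + SS_group×period + SS_period×subjects

Each F ratio uses the error term of its stratum — subjects-within-group
for the between factor, period×subjects for the within factor and the
interaction — giving F(1, N−k) for every effect in the 2×2 design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "EffectRow",
    "AnovaTable",
    "TestResult",
    "CohortReport",
    "validate_cohort_table",
    "mixed_anova_2x2",
    "t_test",
    "holm_bonferroni",
    "pearson_correlation",
    "analyze_cohort",
]


@dataclass(frozen=True)
class EffectRow:
    ss: float
    df: int
    df_error: int
    f: float
    p: float


@dataclass
class AnovaTable:
    """Mixed-design decomposition: effects plus their error strata."""

    effects: Dict[str, EffectRow]
    ss_subjects_within_group: float
    ss_period_by_subjects: float
    ss_total: float

    def to_dict(self) -> dict:
        return {
            "effects": {
                name: {"SS": e.ss, "df": [e.df, e.df_error], "F": e.f, "p": e.p}
                for name, e in self.effects.items()
            },
            "SS_subjects_within_group": self.ss_subjects_within_group,
            "SS_period_by_subjects": self.ss_period_by_subjects,
            "SS_total": self.ss_total,
        }


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    tail: str
    paired: bool
    welch: bool

    def to_dict(self) -> dict:
        return {
            "t": self.statistic,
            "df": self.df,
            "p": self.p,
            "tail": self.tail,
            "paired": self.paired,
            "welch": self.welch,
        }


def validate_cohort_table(
    table: pd.DataFrame, within_levels: Sequence[str]
) -> pd.DataFrame:
    """Check the (animal, group, period, value) long-format contract."""
    required = {"animal", "group", "period", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing column(s) {sorted(missing)}")
    groups_per_animal = table.groupby("animal")["group"].nunique()
    offenders = groups_per_animal[groups_per_animal > 1]
    if len(offenders):
        raise ValueError(
            f"animal(s) {offenders.index.tolist()} appear in more than one group"
        )
    counts = table.groupby(["animal", "period"]).size()
    if (counts > 1).any():
        raise ValueError("duplicate (animal, period) rows in cohort table")
    for animal, sub in table.groupby("animal"):
        have = set(sub["period"])
        if not set(within_levels) <= have:
            raise ValueError(
                f"animal {animal!r} is missing period(s) "
                f"{sorted(set(within_levels) - have)}"
            )
    return table


def mixed_anova_2x2(
    table: pd.DataFrame,
    within_levels: Tuple[str, str] = ("pre", "pos"),
) -> AnovaTable:
    """Mixed ANOVA: between factor = group, within factor = period (2 levels).

    ``table`` is long-format with columns animal, group, period, value;
    every animal must carry both within levels.  Group sizes may differ.
    """
    validate_cohort_table(table, within_levels)
    sub = table[table["period"].isin(within_levels)]
    wide = sub.pivot(index="animal", columns="period", values="value")[
        list(within_levels)
    ]
    group_of = sub.groupby("animal")["group"].first().loc[wide.index]
    y = wide.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing cells in the animal × period table")
    groups = group_of.to_numpy()
    group_levels = list(pd.unique(groups))
    k = len(group_levels)
    if k < 2:
        raise ValueError("need at least two groups")
    n_total = y.shape[0]
    if n_total <= k:
        raise ValueError("need more animals than groups")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    d = y[:, 1] - y[:, 0]  # within-subject difference scores

    ss_total = float(((y - grand) ** 2).sum())
    ss_group = 0.0
    ss_subj = 0.0
    ss_inter = 0.0
    ss_err_w = 0.0
    dbar = d.mean()
    for g in group_levels:
        idx = groups == g
        n_g = int(idx.sum())
        ss_group += 2.0 * n_g * (subj_means[idx].mean() - grand) ** 2
        ss_subj += 2.0 * ((subj_means[idx] - subj_means[idx].mean()) ** 2).sum()
        dbar_g = d[idx].mean()
        ss_inter += n_g * (dbar_g - dbar) ** 2 / 2.0
        ss_err_w += ((d[idx] - dbar_g) ** 2).sum() / 2.0
    ss_period = n_total * dbar**2 / 2.0

    df_between_err = n_total - k
    df_within_err = n_total - k

    def row(ss: float, df: int, ss_err: float, df_err: int) -> EffectRow:
        ms, ms_err = ss / df, ss_err / df_err
        if ms == 0:  # a literally zero effect, regardless of the error term
            return EffectRow(float(ss), df, df_err, 0.0, 1.0)
        f = ms / ms_err if ms_err > 0 else np.inf
        p = float(_stats.f.sf(f, df, df_err)) if np.isfinite(f) else 0.0
        return EffectRow(float(ss), df, df_err, float(f), p)

    effects = {
        "group": row(ss_group, k - 1, ss_subj, df_between_err),
        "period": row(ss_period, 1, ss_err_w, df_within_err),
        "interaction": row(ss_inter, k - 1, ss_err_w, df_within_err),
    }
    return AnovaTable(effects, float(ss_subj), float(ss_err_w), ss_total)


def t_test(
    x,
    y,
    paired: bool = False,
    tail: str = "two",
    welch: bool = False,
) -> TestResult:
    """t-test wrapper with the design's conventions.

    ``tail`` is "two", "greater" (x > y expected) or "less".  ``welch``
    applies the Welch-Satterthwaite adjustment (independent samples only).
    Identical paired samples give t = 0, p = 1 (a zero effect measured with
    zero noise); zero variance in both independent samples with equal means
    leaves the statistic undefined and raises.
    """
    alternatives = {"two": "two-sided", "greater": "greater", "less": "less"}
    if tail not in alternatives:
        raise ValueError(f"tail must be one of {sorted(alternatives)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        if x.size < 2:
            raise ValueError("paired test needs n >= 2")
        if np.all(x - y == 0):
            return TestResult(0.0, float(x.size - 1), 1.0, tail, True, welch)
        res = _stats.ttest_rel(x, y, alternative=alternatives[tail])
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("independent test needs n >= 2 per sample")
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
            raise ValueError(
                "both samples constant with equal means: t statistic undefined"
            )
        res = _stats.ttest_ind(x, y, equal_var=not welch, alternative=alternatives[tail])
    return TestResult(
        float(res.statistic), float(res.df), float(res.pvalue), tail, paired, welch
    )


def holm_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Holm-Bonferroni step-down: (reject flags, adjusted p-values).

    Sort p ascending and compare p(i) with alpha/(m−i+1), stopping at the
    first failure; adjusted p-values are the running maximum of
    (m−i+1)·p(i), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if p[order[i]] < alpha / (m - i):
            reject_sorted[i] = True
        else:
            break
    reject = np.zeros(m, dtype=bool)
    adjusted = np.zeros(m)
    reject[order] = reject_sorted
    adjusted[order] = adjusted_sorted
    return reject, adjusted


def pearson_correlation(x, y) -> Tuple[float, float]:
    """Product-moment r with the n−2 df t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_correlation needs equal-length samples, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input: correlation undefined")
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# full cohort battery


@dataclass
class CohortReport:
    """The full statistics battery for one simulated or recorded cohort."""

    rate: Optional[dict] = None
    vds: Optional[dict] = None
    mec: Optional[dict] = None
    correlation: Optional[dict] = None

    def to_dict(self) -> dict:
        out = {}
        for name in ("rate", "vds", "mec", "correlation"):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        return out


def _difference_scores(table: pd.DataFrame, within_levels) -> pd.DataFrame:
    wide = table.pivot(index="animal", columns="period", values="value")
    wide["delta"] = wide[within_levels[1]] - wide[within_levels[0]]
    wide["group"] = table.groupby("animal")["group"].first()
    return wide


def _check_group_sizes(table: pd.DataFrame) -> None:
    sizes = table.groupby("group")["animal"].nunique()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(
            f"group(s) {small.index.tolist()} have fewer than 2 animals; "
            "the statistics are undefined"
        )


def _omnibus_with_posthoc(
    table: pd.DataFrame,
    within_levels: Tuple[str, str],
    tail: str,
    alpha: float,
) -> dict:
    """One measure's battery: omnibus ANOVA + Holm-corrected post hoc tests.

    The Holm family is the set of pairwise tests that follow this omnibus:
    one paired test per group (level 2 vs level 1) plus the independent
    Welch test comparing the groups' difference scores; membership is
    recorded in the output.
    """
    _check_group_sizes(table)
    anova = mixed_anova_2x2(table, within_levels)
    wide = _difference_scores(table, within_levels)
    groups = list(pd.unique(table["group"]))
    tests: Dict[str, TestResult] = {}
    for g in groups:
        sub = wide[wide["group"] == g]
        tests[f"{g}:{within_levels[1]}-vs-{within_levels[0]}"] = t_test(
            sub[within_levels[1]], sub[within_levels[0]], paired=True, tail=tail
        )
    if len(groups) == 2:
        a, b = groups
        da = wide.loc[wide["group"] == a, "delta"]
        db = wide.loc[wide["group"] == b, "delta"]
        welch = len(da) != len(db)
        tests[f"{a}-vs-{b}:delta"] = t_test(da, db, tail="two", welch=welch)
    family = list(tests)
    reject, adjusted = holm_bonferroni([tests[n].p for n in family], alpha)
    posthoc = {
        name: {
            **tests[name].to_dict(),
            "p_holm": float(adjusted[i]),
            "reject": bool(reject[i]),
        }
        for i, name in enumerate(family)
    }
    means = (
        table.groupby(["group", "period"])["value"].agg(["mean", "sem", "count"])
    ).reset_index()
    return {
        "anova": anova.to_dict(),
        "posthoc": posthoc,
        "holm_family": family,
        "cell_stats": means.to_dict(orient="records"),
    }


def analyze_cohort(
    rate_table: Optional[pd.DataFrame] = None,
    vds_table: Optional[pd.DataFrame] = None,
    mec_table: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
) -> CohortReport:
    """Reproduce the full statistical battery on cohort tables.

    * event rates: 2×2 mixed ANOVA (group × pre/pos), two-tailed post hocs;
    * vds and mec evoked sums: 2×2 mixed ANOVA (group × bas/stim) with
      one-tailed paired post hocs (stimulus > basal is the hypothesis);
    * Pearson correlation of per-animal (pos − pre) rate change against the
      vds (stim − bas) evoked delta.
    """
    report = CohortReport()
    if rate_table is not None:
        report.rate = _omnibus_with_posthoc(rate_table, ("pre", "pos"), "two", alpha)
    if vds_table is not None:
        report.vds = _omnibus_with_posthoc(vds_table, ("bas", "stim"), "greater", alpha)
    if mec_table is not None:
        report.mec = _omnibus_with_posthoc(mec_table, ("bas", "stim"), "greater", alpha)
    if rate_table is not None and vds_table is not None:
        rate_delta = _difference_scores(rate_table, ("pre", "pos"))["delta"]
        vds_delta = _difference_scores(vds_table, ("bas", "stim"))["delta"]
        common = rate_delta.index.intersection(vds_delta.index)
        if len(common) >= 3:
            r, p = pearson_correlation(
                rate_delta.loc[common].to_numpy(), vds_delta.loc[common].to_numpy()
            )
            report.correlation = {"r": r, "p": p, "n": int(len(common))}
    return report
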