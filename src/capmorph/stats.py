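"""Cohort-level statistical battery on subject summaries.

The battery mirrors a multi-study cross-sectional design:

* normality screening of every morphometric data set (Lilliefors-corrected
  Kolmogorov–Smirnov and Shapiro–Wilk) before testing;
* within-study pre/post-training comparisons by Student's t-test (paired by
  subject by default, since the same subjects were biopsied before and after
  training; an unpaired variant is available);
* 2 × 2 two-way ANOVA (phenotype × training) for the responder and the
  hypertension studies, with Tukey HSD over the four cells when the omnibus
  test is significant;
* cross-study one-way ANOVA comparing each untrained patient group
  (hypertensives, diabetics, claudicants) against the pooled untrained
  healthy participants, with Tukey HSD pairwise comparisons when significant;
* Spearman rank correlation of every index with age over the pooled healthy
  participants.

Normality failures are reported but do not switch tests to nonparametric
alternatives, and p-values are not adjusted across indices (only within an
ANOVA via Tukey); both choices are deliberate and documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .annotation_io import HEALTHY_POOL_GROUPS
from .summaries import SUMMARY_VALUE_COLUMNS

ALPHA_LEVELS = (0.05, 0.01, 0.001)


def significance_stars(p: float, alphas: Sequence[float] = ALPHA_LEVELS) -> str:
    if not np.isfinite(p):
        return ""
    return "*" * sum(p < a for a in sorted(alphas, reverse=True))


@dataclass
class ComparisonResult:
    design: str
    index_name: str
    groups: tuple[str, ...]
    statistic: float = np.nan
    p_value: float = np.nan
    post_hoc: list[dict] | None = None
    normality: dict | None = None
    note: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    @property
    def degenerate(self) -> bool:
        return bool(self.note) and not np.isfinite(self.p_value)


class DegenerateDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Normality
# ---------------------------------------------------------------------------

def normality_suite(values: Sequence[float]) -> dict:
    """Lilliefors-corrected KS and Shapiro–Wilk statistics and p-values."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise DegenerateDataError(f"normality tests need n >= 4, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant vector: normality is undefined")
    lf_stat, lf_p = lilliefors(x, dist="norm", pvalmethod="table")
    sw_stat, sw_p = sps.shapiro(x)
    return {
        "lilliefors_stat": float(lf_stat), "lilliefors_p": float(lf_p),
        "shapiro_stat": float(sw_stat), "shapiro_p": float(sw_p),
        "lilliefors_method": "table",
    }


def _normality_or_note(values) -> dict | None:
    try:
        return normality_suite(values)
    except DegenerateDataError:
        return None


# ---------------------------------------------------------------------------
# Within-study tests
# ---------------------------------------------------------------------------

def within_study_test(
    pre_values: Sequence[float],
    post_values: Sequence[float],
    design: str = "paired_t",
    index_name: str = "",
    groups: tuple[str, str] = ("pre", "post"),
) -> ComparisonResult:
    """Student's t-test between two arms of one study."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    pre = pre[np.isfinite(pre)] if design == "unpaired_t" else pre
    post = post[np.isfinite(post)] if design == "unpaired_t" else post
    res = ComparisonResult(design=design, index_name=index_name, groups=groups)
    res.normality = {
        groups[0]: _normality_or_note(pre), groups[1]: _normality_or_note(post)
    }
    if design == "paired_t":
        if len(pre) != len(post):
            raise ValueError("paired design requires equal-length arms")
        ok = np.isfinite(pre) & np.isfinite(post)
        d = post[ok] - pre[ok]
        if len(d) < 2:
            res.note = "fewer than 2 complete pairs"
            return res
        if np.ptp(d) == 0:
            if np.all(d == 0):
                res.statistic, res.p_value = 0.0, 1.0
                res.note = "identical arms"
            else:
                res.note = "degenerate: constant non-zero paired differences"
            return res
        t, p = sps.ttest_rel(post[ok], pre[ok])
    elif design == "unpaired_t":
        if len(pre) < 2 or len(post) < 2:
            res.note = "fewer than 2 observations in an arm"
            return res
        if np.ptp(np.concatenate([pre, post])) == 0:
            res.statistic, res.p_value = 0.0, 1.0
            res.note = "identical arms"
            return res
        t, p = sps.ttest_ind(post, pre, equal_var=True)
    else:
        raise ValueError(f"unknown design {design!r}")
    res.statistic, res.p_value = float(t), float(p)
    return res


# ---------------------------------------------------------------------------
# ANOVA designs
# ---------------------------------------------------------------------------

def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "phenotype",
    factor_b: str = "training",
    index_name: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-factor ANOVA with interaction on subject-level values.

    Requires a full 2 × 2 cell structure with at least two subjects per cell.
    Type-II sums of squares are used (the hypertension study is unbalanced:
    10 normotensive vs 9 hypertensive subjects).  Tukey HSD over the four
    cell means is run when any omnibus effect is significant.
    """
    df = table[[value, factor_a, factor_b]].dropna().copy()
    levels_a = sorted(df[factor_a].unique())
    levels_b = sorted(df[factor_b].unique())
    if len(levels_a) != 2 or len(levels_b) != 2:
        raise ValueError("two_way_anova expects exactly 2 levels per factor")
    counts = df.groupby([factor_a, factor_b])[value].count()
    if len(counts) < 4 or counts.min() < 2:
        raise ValueError("empty or single-subject cell in the 2x2 design")
    model = ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    effects = {
        factor_a: aov.loc[f"C({factor_a})"],
        factor_b: aov.loc[f"C({factor_b})"],
        "interaction": aov.loc[f"C({factor_a}):C({factor_b})"],
    }
    extra = {
        name: {"F": float(r["F"]), "p": float(r["PR(>F)"]), "df": float(r["df"])}
        for name, r in effects.items()
    }
    p_min = min(v["p"] for v in extra.values())
    res = ComparisonResult(
        design="two_way_anova",
        index_name=index_name,
        groups=tuple(f"{a}:{b}" for a in levels_a for b in levels_b),
        statistic=float(extra[factor_a]["F"]),
        p_value=float(extra[factor_a]["p"]),
        extra=extra,
    )
    res.normality = {
        f"{a}:{b}": _normality_or_note(g[value])
        for (a, b), g in df.groupby([factor_a, factor_b])
    }
    if p_min < alpha:
        cells = (df[factor_a].astype(str) + ":" + df[factor_b].astype(str)).to_numpy()
        res.post_hoc = _tukey(df[value].to_numpy(), cells)
    return res


def _tukey(values: np.ndarray, labels: np.ndarray) -> list[dict]:
    from itertools import combinations

    tk = pairwise_tukeyhsd(values, labels)
    pairs = list(combinations(tk.groupsunique, 2))
    return [
        {"pair": (str(a), str(b)), "adjusted_p": float(p), "mean_diff": float(d)}
        for (a, b), p, d in zip(pairs, tk.pvalues, tk.meandiffs)
    ]


def cross_study_anova(
    patient_groups: Mapping[str, Sequence[float]],
    pooled_healthy: Sequence[float],
    index_name: str = "",
    alpha: float = 0.05,
    healthy_label: str = "healthy_pool",
) -> ComparisonResult:
    """One-way ANOVA of untrained patient groups against pooled healthy.

    ``patient_groups`` maps group labels (e.g. hypertensive_pre, diabetic_pre,
    ic_pad) to subject-level values; ``pooled_healthy`` pools the untrained
    control groups of the constituent studies.  Tukey HSD pairwise
    comparisons are run when the omnibus F is significant.
    """
    samples = {healthy_label: np.asarray(pooled_healthy, dtype=float)}
    for k, v in patient_groups.items():
        samples[k] = np.asarray(v, dtype=float)
    samples = {k: v[np.isfinite(v)] for k, v in samples.items()}
    for k, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 subjects")
    f, p = sps.f_oneway(*samples.values())
    res = ComparisonResult(
        design="one_way_anova_cross_study",
        index_name=index_name,
        groups=tuple(samples),
        statistic=float(f),
        p_value=float(p),
        normality={k: _normality_or_note(v) for k, v in samples.items()},
    )
    if p < alpha:
        values = np.concatenate(list(samples.values()))
        labels = np.concatenate([[k] * len(v) for k, v in samples.items()])
        res.post_hoc = _tukey(values, labels)
    return res


def age_correlation(
    ages: Sequence[float], values: Sequence[float], index_name: str = ""
) -> ComparisonResult:
    """Spearman rank correlation of an index with age (ties: average ranks)."""
    a = np.asarray(ages, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(a) & np.isfinite(v)
    a, v = a[ok], v[ok]
    if len(a) < 5:
        raise DegenerateDataError(f"Spearman correlation needs n >= 5, got {len(a)}")
    rho, p = sps.spearmanr(a, v)
    return ComparisonResult(
        design="spearman", index_name=index_name, groups=("age",),
        statistic=float(rho), p_value=float(p),
    )


# ---------------------------------------------------------------------------
# The full battery
# ---------------------------------------------------------------------------

#: Within-study pre/post comparisons run with a t-test.
T_TEST_DESIGNS = [
    ("endurance", "endurance_pre", "endurance_post"),
    ("diabetes", "diabetic_pre", "diabetic_post"),
]
#: The claudication study compares different subjects (controls vs patients).
UNPAIRED_DESIGNS = [("claudication", "ic_control", "ic_pad")]
#: Two-way designs: (study, {group label: (phenotype level, training level)}).
TWO_WAY_DESIGNS = [
    ("responders", {
        "ar_pre": ("AR", "pre"), "ar_post": ("AR", "post"),
        "nr_pre": ("NR", "pre"), "nr_post": ("NR", "post"),
    }),
    ("hypertension", {
        "normotensive_pre": ("normo", "pre"), "normotensive_post": ("normo", "post"),
        "hypertensive_pre": ("hyper", "pre"), "hypertensive_post": ("hyper", "post"),
    }),
]
#: Untrained patient groups entering the cross-study one-way ANOVA.
CROSS_STUDY_PATIENT_GROUPS = ("hypertensive_pre", "diabetic_pre", "ic_pad")


@dataclass
class StatConfig:
    paired: bool = True
    alphas: tuple[float, ...] = ALPHA_LEVELS
    indices: tuple[str, ...] = tuple(SUMMARY_VALUE_COLUMNS)

    def __post_init__(self) -> None:
        if list(self.alphas) != sorted(self.alphas, reverse=True):
            raise ValueError("alpha levels must be strictly decreasing")


def run_full_stat_battery(
    subject_table: pd.DataFrame, config: StatConfig | None = None
) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """Run every designed comparison for every index.

    Per-comparison failures are recorded in the result's ``note`` and never
    abort the battery.  Returns the result list and a long-format table with
    significance stars.
    """
    cfg = config or StatConfig()
    results: list[ComparisonResult] = []

    def guarded(fn, design, index, groups):
        try:
            results.append(fn())
        except (ValueError, KeyError) as exc:
            results.append(ComparisonResult(
                design=design, index_name=index, groups=groups,
                note=f"not computed: {exc}",
            ))

    by_group = dict(tuple(subject_table.groupby("group")))

    def values(group, index):
        grp = by_group.get(group)
        if grp is None:
            raise KeyError(f"group {group!r} missing from subject table")
        return grp.sort_values("subject_id")[index].to_numpy(dtype=float)

    for index in cfg.indices:
        if subject_table[index].dropna().empty:
            results.append(ComparisonResult(
                design="all", index_name=index, groups=(),
                note="not computed: empty index column",
            ))
            continue

        design = "paired_t" if cfg.paired else "unpaired_t"
        for study, g_pre, g_post in T_TEST_DESIGNS:
            guarded(
                lambda s=study, a=g_pre, b=g_post: within_study_test(
                    values(a, index), values(b, index),
                    design=design, index_name=index, groups=(a, b)),
                design, index, (g_pre, g_post))
        for study, g_a, g_b in UNPAIRED_DESIGNS:
            guarded(
                lambda s=study, a=g_a, b=g_b: within_study_test(
                    values(a, index), values(b, index),
                    design="unpaired_t", index_name=index, groups=(a, b)),
                "unpaired_t", index, (g_a, g_b))
        for study, mapping in TWO_WAY_DESIGNS:
            def _run(study=study, mapping=mapping):
                frames = []
                for label, (pheno, training) in mapping.items():
                    grp = by_group.get(label)
                    if grp is None:
                        raise KeyError(f"group {label!r} missing from subject table")
                    frames.append(pd.DataFrame({
                        "value": grp[index].to_numpy(dtype=float),
                        "phenotype": pheno, "training": training,
                    }))
                res = two_way_anova(pd.concat(frames, ignore_index=True),
                                    index_name=index)
                res.extra["study"] = study
                return res
            guarded(_run, "two_way_anova", index, tuple(mapping))

        def _cross():
            healthy = np.concatenate([
                values(g, index) for g in HEALTHY_POOL_GROUPS
            ])
            patients = {g: values(g, index) for g in CROSS_STUDY_PATIENT_GROUPS}
            return cross_study_anova(patients, healthy, index_name=index)
        guarded(_cross, "one_way_anova_cross_study", index,
                ("healthy_pool",) + CROSS_STUDY_PATIENT_GROUPS)

        def _age():
            healthy = pd.concat(
                [by_group[g] for g in HEALTHY_POOL_GROUPS if g in by_group],
                ignore_index=True)
            return age_correlation(
                healthy["age_years"], healthy[index], index_name=index)
        guarded(_age, "spearman", index, ("age",))

    return results, results_table(results, cfg.alphas)


def results_table(
    results: Sequence[ComparisonResult],
    alphas: Sequence[float] = ALPHA_LEVELS,
) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "design": r.design,
            "index": r.index_name,
            "groups": "|".join(r.groups),
            "statistic": r.statistic,
            "p_value": r.p_value,
            "stars": significance_stars(r.p_value, alphas),
            "post_hoc": "; ".join(
                f"{a} vs {b}: p={p['adjusted_p']:.4g}"
                for p in (r.post_hoc or []) for a, b in [p["pair"]]
            ),
            "note": r.note,
        })
    return pd.DataFrame(rows, columns=[
        "design", "index", "groups", "statistic", "p_value", "stars",
        "post_hoc", "note",
    ])


def write_stats_results(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, encoding="utf-8", float_format="%.6g")
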