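"""Between-group statistical comparisons of the survey indicators.

Proportion indicators (antibiotic/injection encounters; generic, EML,
dispensed, labelled medicines) are compared with Pearson chi-square tests
on k×2 event/non-event tables (no continuity correction by default; the
Yates variant is available for 2×2 tables).  Medicines per encounter are
compared with a pooled-variance two-sided Student t test for two groups
or one-way ANOVA for three or more.  Encounters are treated as
independent; clustering by outlet and district is ignored, so p-values on
clustered data are anti-conservative — see the methods note.

No multiple-testing correction is applied by default (survey reports of
this kind publish unadjusted p-values); pairwise annotation offers a
Bonferroni option.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SurveyDataset
from .indicators import (StratifiedIndicators, encounter_counts_by_group,
                         stratify)


@dataclass
class ComparisonResult:
    indicator: str
    groups: tuple[str, ...]
    statistic: float
    df: float
    p_value: float
    test: str                      # chi_square | t_test | anova
    warnings: list[str] = field(default_factory=list)


def chi_square_proportions(counts, groups: Sequence[str] = (),
                           indicator: str = "", yates: bool = False,
                           ) -> ComparisonResult:
    """Pearson chi-square on a k×2 table of (event, non-event) per group.

    ``df = k - 1``.  Continuity correction is off by default; ``yates``
    enables it for 2×2 tables.  Tables with an expected cell below 1 get a
    warning attached but still return a result; a degenerate table (an
    all-zero margin) returns statistic 0, p 1 by convention.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError("counts must be a k×2 table with k >= 2")
    if (table < 0).any():
        raise ValueError("cell counts must be non-negative")
    k = table.shape[0]
    groups = tuple(groups) or tuple(f"group{i + 1}" for i in range(k))
    warn: list[str] = []
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        warn.append("degenerate table (zero margin); statistic set to 0")
        return ComparisonResult(indicator, groups, 0.0, k - 1, 1.0,
                                "chi_square", warn)
    res = stats.chi2_contingency(table, correction=yates)
    if res.expected_freq.min() < 1:
        warn.append("expected cell count below 1; chi-square approximation "
                    "unreliable")
    return ComparisonResult(indicator, groups, float(res.statistic),
                            float(k - 1), float(res.pvalue), "chi_square",
                            warn)


def compare_means(samples: Mapping[str, Sequence[float]],
                  mode: str | None = None, indicator: str = "",
                  ) -> ComparisonResult:
    """Two-sided pooled-variance Student t (2 groups) or one-way ANOVA (>=3).

    ``mode`` may force ``"t_test"`` or ``"anova"``; by default it follows
    the number of groups.  When every observation is identical the
    statistic is 0 and p is 1 by convention (rather than 0/0).
    """
    groups = tuple(samples)
    arrays = [np.asarray(samples[g], dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    if mode is None:
        mode = "t_test" if len(arrays) == 2 else "anova"
    if mode == "t_test" and len(arrays) != 2:
        raise ValueError("t_test mode requires exactly two groups")

    pooled = np.concatenate(arrays)
    warn: list[str] = []
    if np.ptp(pooled) == 0:
        warn.append("all observations identical; statistic set to 0")
        df = (len(pooled) - 2 if mode == "t_test"
              else len(arrays) - 1)
        return ComparisonResult(indicator, groups, 0.0, float(df), 1.0,
                                mode, warn)
    if mode == "t_test":
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        df = len(arrays[0]) + len(arrays[1]) - 2
        stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(stat):  # zero pooled variance, distinct means
            stat, p = float(np.inf), 0.0
            warn.append("zero within-group variance; p set to 0")
    else:
        res = stats.f_oneway(*arrays)
        df = len(arrays) - 1
        stat, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(stat):
            stat, p = float(np.inf), 0.0
            warn.append("zero within-group variance; p set to 0")
    return ComparisonResult(indicator, groups, stat, float(df), p, mode, warn)


# --------------------------------------------------------------------------
# Pairwise annotation
# --------------------------------------------------------------------------

_PROPORTION_INDICATORS = {
    # indicator -> (numerator counts key, denominator attribute)
    "pct_antibiotic": ("antibiotic", "n_encounters"),
    "pct_injection": ("injection", "n_encounters"),
    "pct_generic": ("generic", "n_medicines"),
    "pct_eml": ("eml", "n_medicines"),
    "pct_dispensed": ("dispensed", "n_medicines"),
    "pct_labelled": ("labelled", "dispensed"),
}


def _event_nonevent(iset, num_key: str, den_key: str) -> tuple[int, int]:
    num = iset.counts.get(num_key, 0)
    den = (iset.counts.get("dispensed", 0) if den_key == "dispensed"
           else getattr(iset, den_key))
    return num, den - num


def pairwise_comparisons(dataset: SurveyDataset, key: str = "pharmacy_category",
                         dedupe: bool = True,
                         strat: StratifiedIndicators | None = None,
                         ) -> list[ComparisonResult]:
    """All pairwise group comparisons for every indicator.

    Proportion indicators use pairwise chi-square; medicines per encounter
    uses pairwise pooled t tests on the per-encounter counts.  The test
    family matches the omnibus test for the same indicator.
    """
    strat = strat or stratify(dataset, key, dedupe)
    counts_by_group = encounter_counts_by_group(dataset, key, dedupe)
    results: list[ComparisonResult] = []
    names = list(strat.groups)
    for a, b in itertools.combinations(names, 2):
        results.append(compare_means(
            {a: counts_by_group[a], b: counts_by_group[b]},
            indicator="medicines_per_encounter"))
        for ind, (num_key, den_key) in _PROPORTION_INDICATORS.items():
            table = [_event_nonevent(strat.groups[g], num_key, den_key)
                     for g in (a, b)]
            results.append(chi_square_proportions(table, (a, b), ind))
    return results


def omnibus_comparisons(dataset: SurveyDataset, key: str = "pharmacy_category",
                        dedupe: bool = True,
                        strat: StratifiedIndicators | None = None,
                        ) -> list[ComparisonResult]:
    """One omnibus test per indicator across all groups of ``key``."""
    strat = strat or stratify(dataset, key, dedupe)
    counts_by_group = encounter_counts_by_group(dataset, key, dedupe)
    results = [compare_means(counts_by_group,
                             indicator="medicines_per_encounter")]
    names = list(strat.groups)
    for ind, (num_key, den_key) in _PROPORTION_INDICATORS.items():
        table = [_event_nonevent(strat.groups[g], num_key, den_key)
                 for g in names]
        results.append(chi_square_proportions(table, names, ind))
    return results


def annotate_table(dataset: SurveyDataset, key: str = "pharmacy_category",
                   alpha: float = 0.05, bonferroni: bool = False,
                   dedupe: bool = True,
                   strat: StratifiedIndicators | None = None,
                   ) -> tuple[dict[str, dict[str, str]],
                              list[ComparisonResult]]:
    """Pairwise significance symbols for an indicator table.

    For each indicator, every significant pair of groups receives the next
    letter symbol, appended to both groups — groups sharing a symbol in a
    row are significantly different from one another at ``alpha``
    (Bonferroni-divided across the pairs of that indicator when
    ``bonferroni``).
    """
    strat = strat or stratify(dataset, key, dedupe)
    results = pairwise_comparisons(dataset, key, dedupe, strat)
    n_pairs = max(1, len(list(itertools.combinations(strat.groups, 2))))
    threshold = alpha / n_pairs if bonferroni else alpha
    marks: dict[str, dict[str, str]] = {}
    symbol_counter: dict[str, int] = {}
    for res in results:
        if res.p_value >= threshold:
            continue
        i = symbol_counter.get(res.indicator, 0)
        symbol_counter[res.indicator] = i + 1
        sym = chr(ord("a") + i % 26)
        row = marks.setdefault(res.indicator, {})
        for g in res.groups:
            row[g] = row.get(g, "") + sym
    return marks, results


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "indicator": r.indicator,
        "groups": " vs ".join(r.groups),
        "test": r.test,
        "statistic": r.statistic,
        "df": r.df,
        "p_value": r.p_value,
        "warnings": "; ".join(r.warnings),
    } for r in results])
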