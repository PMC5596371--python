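"""Comparison of asymmetry-index means across taxonomic groups.

One-way fixed-effects ANOVA on per-taxon index values grouped by a label
(e.g. subfamily), followed by Tukey-Kramer pairwise comparisons with a
compact letter display (groups sharing a letter are not significantly
different at the chosen alpha).  Groups of size one are legitimate here
(single-representative subfamilies occur); they contribute to the
between-group sum of squares and are handled by the Tukey-Kramer unequal-n
form, though a ``min_group_size`` filter is available because a singleton
group adds no within-group information and can dominate the contrast.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "TukeyResult",
    "GroupSummary",
    "summarize_by_group",
]


def _split(values, groups, min_group_size: int):
    s = pd.Series(np.asarray(values, dtype=float), name="value")
    g = pd.Series(list(groups), name="group")
    if len(s) != len(g):
        raise ValueError("values and groups differ in length")
    keep = s.notna()
    s, g = s[keep], g[keep]
    sizes = g.value_counts()
    ok = sizes[sizes >= min_group_size].index
    mask = g.isin(ok)
    return s[mask].to_numpy(), g[mask].to_numpy()


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    group_means: dict[str, float]
    n_used: int


def one_way_anova(values, groups, *, min_group_size: int = 1) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    Sums of squares are computed directly (between: group sizes times
    squared deviations of group means from the grand mean; within: squared
    deviations from the own group mean).  ``min_group_size`` drops groups
    with fewer observations before testing (set to 2 to exclude
    single-representative groups).
    """
    v, g = _split(values, groups, min_group_size)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for ANOVA")
    n = len(v)
    if n <= len(labels):
        raise ValueError("need more observations than groups")
    grand = v.mean()
    ssb = ssw = 0.0
    means = {}
    for lab in labels:
        x = v[g == lab]
        m = x.mean()
        means[str(lab)] = float(m)
        ssb += len(x) * (m - grand) ** 2
        ssw += float(((x - m) ** 2).sum())
    dfb = len(labels) - 1
    dfw = n - len(labels)
    if ssw == 0.0:
        # all values identical within groups: F undefined or infinite;
        # the all-identical case is reported as no effect
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, dfb, dfw, 0.0, 0.0, means, n)
        return AnovaResult(np.inf, 0.0, dfb, dfw, ssb, 0.0, means, n)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), p, dfb, dfw, float(ssb), float(ssw), means, n)


@dataclass(frozen=True)
class TukeyResult:
    pairwise: pd.DataFrame
    letters: dict[str, str]
    alpha: float
    singleton_groups: tuple[str, ...]


def _letter_display(labels: list[str], differs) -> dict[str, str]:
    """Compact letter display by insertion and absorption.

    Starts from one letter covering all groups; every significant pair
    splits the letters that contain both; duplicate/contained letter sets
    are absorbed.  Groups are assumed ordered (here: by mean) so letters
    read naturally.
    """
    lettersets: list[set[str]] = [set(labels)]
    for a, b in differs:
        for ls in list(lettersets):
            if a in ls and b in ls:
                lettersets.remove(ls)
                for drop in (a, b):
                    new = ls - {drop}
                    if new and not any(new <= other for other in lettersets):
                        lettersets.append(new)
        lettersets = [
            ls
            for ls in lettersets
            if not any(ls < other for other in lettersets)
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, ls in enumerate(lettersets):
        for lab in labels:
            if lab in ls:
                out[lab] += alphabet[i]
    return out


def tukey_hsd(values, groups, *, alpha: float = 0.05,
              min_group_size: int = 1) -> TukeyResult:
    """Tukey-Kramer pairwise comparisons plus a compact letter display.

    Unequal group sizes are supported (Tukey-Kramer form, via
    statsmodels); singleton groups are included with the pooled variance
    and reported in ``singleton_groups``.
    """
    v, g = _split(values, groups, min_group_size)
    res = pairwise_tukeyhsd(v, g, alpha=alpha)
    pairs = list(itertools.combinations(res.groupsunique, 2))
    table = pd.DataFrame(
        {
            "group1": [str(a) for a, _ in pairs],
            "group2": [str(b) for _, b in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "lower": res.confint[:, 0],
            "upper": res.confint[:, 1],
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )

    means = pd.Series(v).groupby(pd.Series(g)).mean().sort_values()
    ordered = [str(x) for x in means.index]
    differs = [
        (str(r["group1"]), str(r["group2"]))
        for _, r in table.iterrows()
        if r["reject"]
    ]
    letters = _letter_display(ordered, differs)
    sizes = pd.Series(g).value_counts()
    singles = tuple(str(x) for x in sizes[sizes == 1].index)
    return TukeyResult(
        pairwise=table, letters=letters, alpha=alpha, singleton_groups=singles
    )


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    min: float
    max: float
    mode: float


def summarize_by_group(values, groups, *, precision: int = 2) -> list[GroupSummary]:
    """Per-group mean, range and mode (mode at the given rounding
    precision, ties resolved to the smallest value)."""
    v, g = _split(values, groups, 1)
    out = []
    for lab in pd.unique(g):
        x = v[g == lab]
        rounded = np.round(x, precision)
        vals, counts = np.unique(rounded, return_counts=True)
        mode = float(vals[counts == counts.max()].min())
        out.append(
            GroupSummary(
                group=str(lab),
                n=len(x),
                mean=float(x.mean()),
                min=float(x.min()),
                max=float(x.max()),
                mode=mode,
            )
        )
    return out
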