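"""Group summaries and significance testing of the feature table.

Per-region feature values are summarised as mean ± sample SD per group
(normal, EH = hyperplasia without atypia, AH = atypical hyperplasia,
EC = endometrial cancer), compared by one-way ANOVA (two-sided, α = 0.05),
and followed up with Tukey-HSD pairwise comparisons encoded as stars
(* p < 0.05, ** p < 0.01, *** p < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

__all__ = [
    "GROUP_LEVELS",
    "GroupSummary",
    "summarize",
    "anova_oneway",
    "pairwise_posthoc",
    "stars",
    "group_summary_table",
]

GROUP_LEVELS = ("normal", "EH", "AH", "EC")

ALPHA = 0.05


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive statistics and tests for one feature."""

    feature: str
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    anova_F: float
    anova_p: float
    pairwise: tuple[tuple[str, str, float, str], ...]  # (a, b, adj p, stars)


def summarize(values_by_group: Mapping[str, Sequence[float]]) -> tuple[
    dict[str, int], dict[str, float], dict[str, float]
]:
    """Per-group n, mean and sample SD (n−1 denominator; SD is NaN when
    n = 1).  NaN observations are dropped per group."""
    n: dict[str, int] = {}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for g, vals in values_by_group.items():
        v = np.asarray(list(vals), dtype=float)
        v = v[np.isfinite(v)]
        n[g] = int(v.size)
        mean[g] = float(v.mean()) if v.size else float("nan")
        sd[g] = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    return n, mean, sd


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    arrs = [a[np.isfinite(a)] for a in arrs]
    if len(arrs) < 3:
        raise ValueError(
            "one-way ANOVA here compares three or more groups; "
            "use a two-group test for two samples"
        )
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least 2 observations")
    return arrs


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    All groups identical gives F = 0, p = 1; F is invariant to shifting
    all observations by a constant or rescaling by a positive factor.
    """
    arrs = _validate_groups(groups)
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


def pairwise_posthoc(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> tuple[tuple[str, str, float, str], ...]:
    """All pairwise comparisons with Tukey-HSD family-wise adjustment."""
    arrs = _validate_groups(groups)
    labels = list(labels) if labels is not None else [str(i) for i in range(len(arrs))]
    res = sps.tukey_hsd(*arrs)
    out = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            p = float(res.pvalue[i, j])
            out.append((labels[i], labels[j], p, stars(p)))
    return tuple(out)


def group_summary_table(
    table: pd.DataFrame,
    unit: str = "region",
    posthoc: bool = True,
) -> list[GroupSummary]:
    """Summarise a feature table (columns: specimen, group, roi, region,
    plus the eight features) into per-feature group statistics.

    ``unit`` chooses the unit of analysis: ``"region"`` uses every region
    row; ``"specimen"`` first averages regions within a specimen, which
    avoids treating within-specimen regions as independent replicates.
    """
    if unit not in ("region", "specimen"):
        raise ValueError("unit must be 'region' or 'specimen'")
    df = table.copy()
    if unit == "specimen":
        df = (
            df.groupby(["specimen", "group"], as_index=False)[list(FEATURE_NAMES)]
            .mean()
        )
    out: list[GroupSummary] = []
    groups_present = [g for g in GROUP_LEVELS if g in set(df["group"])]
    for feat in FEATURE_NAMES:
        by_group = {g: df.loc[df["group"] == g, feat].to_numpy()
                    for g in groups_present}
        n, mean, sd = summarize(by_group)
        arrs = [by_group[g] for g in groups_present]
        try:
            F, p = anova_oneway(arrs)
            pw = pairwise_posthoc(arrs, groups_present) if posthoc else ()
        except ValueError:
            F, p, pw = float("nan"), float("nan"), ()
        out.append(GroupSummary(feature=feat, n=n, mean=mean, sd=sd,
                                anova_F=F, anova_p=p, pairwise=pw))
    return out
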