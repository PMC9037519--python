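"""Alpha-diversity (Simpson's evenness), prevalence summaries and the
two-group Mann-Whitney comparison.

Simpson's evenness of an abundance vector p is defined here as the inverse
Simpson index divided by the observed richness,

    E = (1 / sum_i p_i^2) / S,     sum over the S taxa with p_i > 0,

which is 1 exactly when all present taxa are equally abundant and tends to
1/S-scaled values for strongly dominated communities.  The alternative
reading 1 - sum p_i^2 is Simpson *diversity*, not evenness, and is not used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import TAXON, FeatureTable


def simpson_evenness(abundances) -> float:
    """Inverse-Simpson evenness of one abundance vector.

    The vector is renormalized internally, so any positive rescaling of the
    input gives the same value.  Raises on all-zero or negative input.
    """
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("negative abundances")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = p[p > 0] / total
    s = p.size
    return float((1.0 / np.sum(p**2)) / s)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U the statistic of ``group_a``.  The p-value is
    computed by exact enumeration when both groups are small (min n <= 20)
    and tie-free, and by the normal approximation with midrank tie
    correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = min(a.size, b.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class DiversityResult:
    """Per-sample evenness with a two-group comparison."""

    evenness: pd.Series
    groups: pd.Series
    statistic: float
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.groups, "evenness": self.evenness}
        ).rename_axis("sample_id")


def evenness_comparison(table: FeatureTable, groups: pd.Series) -> DiversityResult:
    """Simpson's evenness per sample and its Mann-Whitney group comparison.

    ``groups`` maps sample id to one of exactly two labels.
    """
    groups = groups.reindex(table.sample_ids)
    if groups.isna().any():
        raise ValueError("groups must cover all samples")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected 2 groups, got {levels}")
    ev = pd.Series(
        [simpson_evenness(row) for row in table.values],
        index=table.sample_ids,
        name="evenness",
    )
    u, p = mann_whitney(ev[groups == levels[0]], ev[groups == levels[1]])
    return DiversityResult(ev, groups, u, p)


@dataclass
class PrevalenceResult:
    """Per-group feature prevalence and the distribution comparison."""

    prevalence: pd.DataFrame  # features x groups, values in [0, 1]
    statistic: float
    p_value: float


def prevalence_distribution(
    table: FeatureTable, groups: pd.Series
) -> PrevalenceResult:
    """Fraction of samples per group in which each taxon is present (> 0).

    The two per-group prevalence distributions are compared by a
    Mann-Whitney test, mirroring the usual presence/absence summary of
    case-control microbiome cohorts.
    """
    if not (table.blocks == TAXON).all():
        raise ValueError("prevalence_distribution requires a taxon table")
    groups = groups.reindex(table.sample_ids)
    if groups.isna().any():
        raise ValueError("groups must cover all samples")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected 2 groups, got {levels}")
    cols = {}
    for level in levels:
        sub = table.data.loc[groups == level]
        if sub.shape[0] == 0:
            raise ValueError(f"empty group {level!r}")
        cols[level] = (sub > 0).mean(axis=0)
    prev = pd.DataFrame(cols)
    u, p = mann_whitney(prev[levels[0]], prev[levels[1]])
    return PrevalenceResult(prev, u, p)
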