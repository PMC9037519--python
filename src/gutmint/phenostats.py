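"""Univariate screening of phenotype variables against consensus clusters
with Hommel family-wise multiple-testing correction.

Continuous and binary variables are compared across clusters with rank
tests -- Kruskal-Wallis when there are more than two clusters, Mann-Whitney
for two -- on non-missing samples only (pairwise-complete, no imputation).
Binary variables are encoded 0/1 and use the same rank tests; nominal
categorical variables fall back to a chi-square contingency test and are
flagged distinctly.  Raw p-values are adjusted with the Hommel (1988)
step-up procedure, which equals closed testing with Simes local tests and
controls the family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import mann_whitney
from .tables_io import PhenotypeTable


def kruskal_wallis(values_by_cluster) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank tie correction) and chi-square p-value.

    By convention, groups whose pooled values are all identical give
    ``(0.0, 1.0)`` rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_cluster]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size < 2:
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def pairwise_mwu(values_by_cluster) -> pd.DataFrame:
    """Mann-Whitney p for every cluster pair (raw, for later correction).

    Pairs involving an empty cluster are kept with ``skipped=True``.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_cluster]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two clusters")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            if groups[i].size == 0 or groups[j].size == 0:
                rows.append(
                    {"a": i, "b": j, "U": np.nan, "p": np.nan, "skipped": True}
                )
                continue
            u, p = mann_whitney(groups[i], groups[j])
            rows.append({"a": i, "b": j, "U": u, "p": p, "skipped": False})
    return pd.DataFrame(rows)


def hommel_adjust(p_values) -> np.ndarray:
    """Hommel step-up adjusted p-values (order matches the input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="hommel")[1]


@dataclass
class ClusterPhenoResult:
    """Tidy screening table plus the per-variable pairwise p-values."""

    table: pd.DataFrame
    pairwise: dict[tuple[str, str], pd.DataFrame]
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _test_one(values: pd.Series, labels: np.ndarray, vtype: str):
    """Test one variable; returns (test_name, statistic, p, summaries)."""
    groups = []
    levels = np.unique(labels)
    for g in levels:
        groups.append(values[labels == g].to_numpy(dtype=float))
    nonempty = [g for g in groups if g.size > 0]
    if len(nonempty) < 2:
        return "skipped", np.nan, np.nan, {}
    summaries = {
        int(g): {
            "n": int(arr.size),
            "mean": float(np.mean(arr)) if arr.size else np.nan,
        }
        for g, arr in zip(levels, groups)
    }
    if vtype == "categorical":
        obs = pd.crosstab(values.to_numpy(), labels)
        if obs.shape[0] < 2:
            return "skipped", np.nan, np.nan, summaries
        chi2, p, _, _ = stats.chi2_contingency(obs.to_numpy())
        return "chi2", float(chi2), float(p), summaries
    pooled = np.concatenate(nonempty)
    if np.unique(pooled).size < 2:
        return ("kruskal_wallis" if len(nonempty) > 2 else "mann_whitney"), 0.0, 1.0, summaries
    if len(nonempty) == 2:
        u, p = mann_whitney(nonempty[0], nonempty[1])
        return "mann_whitney", u, p, summaries
    h, p = kruskal_wallis(nonempty)
    return "kruskal_wallis", h, p, summaries


def screen_phenotypes(
    pheno: PhenotypeTable,
    labels,
    alpha: float = 0.05,
    family: str = "per_configuration",
    include_pairwise: bool = True,
) -> ClusterPhenoResult:
    """Screen every phenotype variable against cluster labels.

    Parameters
    ----------
    pheno
        Typed phenotype table (missing cells allowed; tested
        pairwise-complete).
    labels
        Either a single labeling (array or Series over the phenotype
        samples) or a mapping ``configuration name -> labeling`` to screen
        several cluster configurations jointly.
    family
        ``"per_configuration"`` adjusts p-values with Hommel separately
        within each configuration (one family per dataset x k
        configuration); ``"global"`` uses a single family across all
        configurations.
    """
    if family not in ("per_configuration", "global"):
        raise ValueError("family must be 'per_configuration' or 'global'")
    if not isinstance(labels, dict):
        labels = {"clusters": labels}
    configs: dict[str, np.ndarray] = {}
    for name, lab in labels.items():
        if isinstance(lab, pd.Series):
            lab = lab.reindex(pheno.sample_ids).to_numpy()
        else:
            lab = np.asarray(lab)
        if len(lab) != len(pheno.sample_ids):
            raise ValueError(f"labeling {name!r} does not cover all samples")
        configs[name] = lab

    rows = []
    pairwise: dict[tuple[str, str], pd.DataFrame] = {}
    for name, lab in configs.items():
        k = int(np.unique(lab).size)
        for var in pheno.variables:
            col = pheno.data[var]
            keep = col.notna().to_numpy()
            values = col[keep]
            sub = lab[keep]
            test, statistic, p, summaries = _test_one(
                values, sub, pheno.types[var]
            )
            rows.append(
                {
                    "configuration": name,
                    "variable": var,
                    "k": k,
                    "test": test,
                    "statistic": statistic,
                    "p_raw": p,
                    "n_nonmissing": int(keep.sum()),
                    "summaries": summaries,
                }
            )
            if include_pairwise and test == "kruskal_wallis":
                groups = [
                    values[sub == g].to_numpy(dtype=float)
                    for g in np.unique(sub)
                ]
                pairwise[(name, var)] = pairwise_mwu(groups)
    table = pd.DataFrame(rows)
    table["p_hommel"] = np.nan
    if family == "global":
        families = [np.ones(len(table), dtype=bool)]
    else:
        families = [
            (table["configuration"] == name).to_numpy() for name in configs
        ]
    for fam_mask in families:
        mask = fam_mask & table["p_raw"].notna().to_numpy()
        if mask.any():
            table.loc[mask, "p_hommel"] = hommel_adjust(
                table.loc[mask, "p_raw"].to_numpy()
            )
    table["significant"] = table["p_hommel"] < alpha
    return ClusterPhenoResult(table=table, pairwise=pairwise, alpha=alpha)
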