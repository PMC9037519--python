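"""Feature/phenotype table containers, TSV I/O, taxonomic aggregation,
train-only auto-scaling and multivariate outlier screening.

Tables are thin wrappers around :class:`pandas.DataFrame` with samples as
rows.  Feature tables carry a per-feature *block* label (``"taxon"`` or
``"metabolite"``) so that multi-omics concatenations remember which block
each feature came from, and taxon tables additionally carry the taxonomic
rank of their features.

Conventions fixed here and documented in ``docs/methods.md``:

* auto-scaling means per-feature mean-centering followed by division by the
  population standard deviation (``ddof=0``); features with zero training
  SD are *degenerate* and map to 0,
* taxon relative abundances may be given as fractions (rows sum to 1) or
  percentages (rows sum to 100); they are normalized to fractions on read,
* phenotype tables use the empty TSV field as the missing-value marker;
  feature tables must be complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
LINEAGE_RANKS = RANKS[:-1]

TAXON = "taxon"
METABOLITE = "metabolite"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Sample x feature numeric matrix with per-feature block labels.

    Parameters
    ----------
    data
        Numeric values, indexed by sample id, one column per feature.
    blocks
        Feature id -> block label (``"taxon"`` | ``"metabolite"``).  A plain
        string may be given and is broadcast to all features.
    rank
        Taxonomic rank of the features when they are taxa, else ``None``.
    """

    data: pd.DataFrame
    blocks: pd.Series | str = TAXON
    rank: str | None = None

    def __post_init__(self) -> None:
        self.data.index.name = "sample_id"
        if isinstance(self.blocks, str):
            self.blocks = pd.Series(self.blocks, index=self.data.columns)
        self.blocks = self.blocks.reindex(self.data.columns)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.blocks.isna().any():
            missing = list(self.blocks.index[self.blocks.isna()])
            raise ValueError(f"features without block label: {missing}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("feature table contains non-finite values")
        taxon_cols = self.blocks.index[self.blocks == TAXON]
        if len(taxon_cols) and (self.data[taxon_cols].to_numpy() < 0).any():
            raise ValueError("taxon abundances must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.blocks.copy(), self.rank)


@dataclass
class PhenotypeTable:
    """Sample x variable table with declared types and explicit missingness.

    ``data`` uses NaN as the missing marker.  ``types`` maps each variable to
    ``"continuous"``, ``"binary"`` or ``"categorical"``; types are declared,
    never silently inferred.
    """

    data: pd.DataFrame
    types: pd.Series

    VALID_TYPES = ("continuous", "binary", "categorical")

    def __post_init__(self) -> None:
        self.data.index.name = "sample_id"
        self.types = self.types.reindex(self.data.columns)
        if self.types.isna().any():
            missing = list(self.types.index[self.types.isna()])
            raise ValueError(f"variables without declared type: {missing}")
        bad = sorted(set(self.types) - set(self.VALID_TYPES))
        if bad:
            raise ValueError(f"unknown variable types: {bad}")
        for var in self.types.index[self.types == "binary"]:
            levels = self.data[var].dropna().unique()
            if len(levels) > 2:
                raise ValueError(
                    f"binary variable {var!r} has {len(levels)} observed levels"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)


class TaxonLineage:
    """Species id -> (kingdom .. genus) lookup.

    Stored as a DataFrame indexed by species id with one column per lineage
    rank.  Family labels must be non-empty.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [r for r in LINEAGE_RANKS if r not in table.columns]
        if missing:
            raise ValueError(f"lineage table lacks rank columns: {missing}")
        if table.index.has_duplicates:
            raise ValueError("duplicate species in lineage")
        fam = table["family"].astype(str)
        if (fam.str.len() == 0).any() or fam.isna().any():
            raise ValueError("empty family labels in lineage")
        self.table = table[list(LINEAGE_RANKS)].copy()

    @property
    def species_ids(self) -> list[str]:
        return list(self.table.index)

    def labels_at(self, rank: str) -> pd.Series:
        if rank == "species":
            return pd.Series(self.table.index, index=self.table.index)
        return self.table[rank]


@dataclass
class ScalerParams:
    """Per-feature training mean and population SD for auto-scaling."""

    mean: pd.Series
    sd: pd.Series
    degenerate: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = self.sd == 0.0
        if (self.sd < 0).any():
            raise ValueError("negative SD")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.mean.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
            "features": self.feature_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        payload = json.loads(Path(path).read_text())
        idx = pd.Index(payload["features"])
        return cls(
            mean=pd.Series(payload["mean"]).reindex(idx),
            sd=pd.Series(payload["sd"]).reindex(idx),
        )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as TSV (``sample_id`` first column)."""
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_feature_table(
    path: str | Path,
    block: str = TAXON,
    rank: str | None = None,
    normalize: bool = True,
) -> FeatureTable:
    """Read a TSV feature table.

    Taxon tables whose rows sum to ~100 are treated as percentages and
    normalized to fractions (``normalize=True``).
    """
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df = df.astype(float)
    if block == TAXON and normalize and df.shape[1] > 0:
        sums = df.sum(axis=1)
        if np.allclose(sums, 100.0, rtol=1e-3):
            df = df / 100.0
    return FeatureTable(df, blocks=block, rank=rank)


def write_phenotype_table(pheno: PhenotypeTable, path: str | Path) -> None:
    """Write phenotype values (empty field = missing) plus a sidecar
    ``<path>.types.tsv`` with the declared variable types."""
    out = pheno.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="")
    types = pheno.types.rename("type").to_frame()
    types.index.name = "variable"
    types.to_csv(f"{path}.types.tsv", sep="\t")


def read_phenotype_table(
    path: str | Path, types_path: str | Path | None = None
) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if types_path is None:
        types_path = f"{path}.types.tsv"
    types = pd.read_csv(types_path, sep="\t", index_col="variable")["type"]
    return PhenotypeTable(df, types)


def write_lineage(lineage: TaxonLineage, path: str | Path) -> None:
    out = lineage.table.copy()
    out.index.name = "species_id"
    out.to_csv(path, sep="\t")


def read_lineage(path: str | Path) -> TaxonLineage:
    return TaxonLineage(pd.read_csv(path, sep="\t", index_col="species_id"))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def aggregate_to_rank(
    table: FeatureTable, lineage: TaxonLineage, rank: str
) -> FeatureTable:
    """Sum species abundances within each group at the requested rank.

    Per-sample totals are conserved.  ``rank="species"`` returns the input
    unchanged (a copy).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if not (table.blocks == TAXON).all():
        raise ValueError("aggregate_to_rank requires a taxon table")
    if rank == "species":
        out = table.copy()
        out.rank = "species"
        return out
    missing = [s for s in table.feature_ids if s not in lineage.table.index]
    if missing:
        raise KeyError(f"species missing from lineage: {missing}")
    labels = lineage.labels_at(rank).reindex(table.feature_ids)
    grouped = table.data.T.groupby(labels.to_numpy()).sum().T
    grouped = grouped[sorted(grouped.columns)]
    return FeatureTable(grouped, blocks=TAXON, rank=rank)


def fit_scaler(train: FeatureTable | pd.DataFrame) -> ScalerParams:
    """Estimate per-feature auto-scaling parameters from training data only.

    Uses the population SD (``ddof=0``).  Features with SD 0 are recorded as
    degenerate and later map to 0.
    """
    df = train.data if isinstance(train, FeatureTable) else train
    if df.shape[0] == 0:
        raise ValueError("empty training table")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    return ScalerParams(mean=mean, sd=sd)


def apply_scaler(params: ScalerParams, table: FeatureTable | pd.DataFrame):
    """Auto-scale a table with previously fitted training parameters."""
    df = table.data if isinstance(table, FeatureTable) else table
    if list(df.columns) != params.feature_ids:
        raise ValueError("feature ids do not match scaler parameters")
    sd = params.sd.replace(0.0, 1.0)
    scaled = (df - params.mean) / sd
    scaled.loc[:, params.degenerate[params.degenerate].index] = 0.0
    if isinstance(table, FeatureTable):
        return FeatureTable(scaled, table.blocks.copy(), table.rank)
    return scaled


@dataclass
class HotellingResult:
    """Hotelling T² outlier screen on leading principal-component scores."""

    t2: pd.Series
    threshold: float
    outliers: list[str]
    n_components: int
    alpha: float


def _t2_scores(X: np.ndarray, a: int) -> np.ndarray:
    pca = PCA(n_components=a)
    scores = pca.fit_transform(X)
    lam = pca.explained_variance_  # score variances, ddof=1
    lam = np.where(lam <= 0, np.inf, lam)
    return (scores**2 / lam).sum(axis=1)


def _t2_threshold(n: int, a: int, alpha: float, familywise: bool) -> float:
    level = 1.0 - (alpha / n if familywise else alpha)
    return a * (n - 1) / (n - a) * stats.f.ppf(level, a, n - a)


def hotelling_outliers(
    table: FeatureTable | pd.DataFrame,
    n_components: int = 2,
    alpha: float = 0.05,
    familywise: bool = True,
    iterative: bool = True,
) -> HotellingResult:
    """Flag multivariate outliers via Hotelling's T² on PCA scores.

    T² for sample *i* is ``sum_a t_ia^2 / lambda_a`` over the leading
    ``n_components`` principal components.  The threshold is the
    F-distribution form ``a (n-1) / (n - a) * F_{1-alpha'}(a, n-a)``.  With
    ``familywise=True`` (default) ``alpha' = alpha / n`` so that *alpha*
    bounds the probability of flagging any sample of an outlier-free table;
    ``familywise=False`` uses the classical per-sample limit at ``1 -
    alpha`` (whose threshold tends to 0 as ``alpha -> 1``).

    With ``iterative=True`` (default) every sample over the threshold is
    removed and the PCA refitted until no further sample exceeds it: gross
    outliers inflate the leading eigenvalues and can mask each other in a
    single pass.  The reported T² values and threshold are those of the
    first pass.

    Heavy-tailed intensity tables should be log-transformed by the caller
    first; the screen is calibrated for roughly Gaussian scores.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    n, p = df.shape
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_components >= min(n, p):
        raise ValueError("n_components must be < min(n_samples, n_features)")
    if n < n_components + 2:
        raise ValueError("need at least n_components + 2 samples")
    X = df.to_numpy(dtype=float)
    a = n_components
    t2_first = _t2_scores(X, a)
    thr_first = _t2_threshold(n, a, alpha, familywise)
    if not iterative:
        flagged = list(df.index[t2_first > thr_first])
    else:
        keep = np.arange(n)
        flagged_idx: list[int] = []
        while len(keep) >= n_components + 2:
            t2 = _t2_scores(X[keep], a)
            thr = _t2_threshold(len(keep), a, alpha, familywise)
            over = np.flatnonzero(t2 > thr)
            if over.size == 0:
                break
            flagged_idx.extend(int(i) for i in keep[over])
            keep = np.delete(keep, over)
        flagged = [df.index[i] for i in sorted(flagged_idx)]
    t2_series = pd.Series(t2_first, index=df.index, name="t2")
    return HotellingResult(t2_series, float(thr_first), flagged, a, alpha)


def concat_blocks(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Horizontally concatenate feature tables sharing the same samples.

    Feature ids colliding across blocks are prefixed with their block label.
    """
    if len(tables) == 0:
        raise ValueError("no tables to concatenate")
    ref = tables[0].sample_ids
    for t in tables[1:]:
        if t.sample_ids != ref:
            diff = sorted(set(t.sample_ids) ^ set(ref))
            raise ValueError(f"sample mismatch between blocks: {diff[:10]}")
    seen: dict[str, int] = {}
    frames, block_parts = [], []
    for t in tables:
        data = t.data.copy()
        blocks = t.blocks.copy()
        renames = {}
        for fid in data.columns:
            if fid in seen:
                renames[fid] = f"{blocks[fid]}::{fid}"
        if renames:
            data = data.rename(columns=renames)
            blocks = blocks.rename(index=renames)
        for fid in data.columns:
            seen[fid] = 1
        frames.append(data)
        block_parts.append(blocks)
    data = pd.concat(frames, axis=1)
    blocks = pd.concat(block_parts)
    rank = tables[0].rank if len(tables) == 1 else None
    return FeatureTable(data, blocks=blocks, rank=rank)
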