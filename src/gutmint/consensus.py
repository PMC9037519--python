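"""Unsupervised patient subtyping: kernel-t-SNE embedding ensembles,
k-means with a WSS elbow, proximity-matrix consensus and hierarchical
extraction of robust groups with a minimum size.

Pipeline (three steps, run over ``n_models`` embeddings differing only by
seed):

1. embed the auto-scaled feature matrix to 2-D with t-SNE and attach a
   Gaussian-kernel least-squares map from input space to the embedding
   (the "kernel t-SNE" construction, enabling out-of-sample projection),
2. k-means the embedding for k = 1..k_max, record the within-cluster sum of
   squared errors (WSS) per k and pick k* by the largest second-order WSS
   difference on the across-model mean curve,
3. accumulate, per k, a sample x sample proximity matrix (co-clustering
   frequency across models), hierarchically cluster distance 1 - proximity
   into k groups and merge any group smaller than ``min_size`` into its
   highest-average-proximity neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

_MAX_SEED = 2**31 - 1


# ---------------------------------------------------------------------------
# kernel t-SNE
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingRun:
    """One 2-D t-SNE embedding plus its kernel out-of-sample map."""

    embedding: np.ndarray  # (n, 2)
    seed: int
    perplexity: float
    bandwidth: float
    centers: np.ndarray = field(repr=False, default=None)  # type: ignore
    coefficients: np.ndarray = field(repr=False, default=None)  # type: ignore

    def project(self, X) -> np.ndarray:
        """Project new points through the Gaussian-kernel regression map."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = (
            (X**2).sum(axis=1)[:, None]
            + (self.centers**2).sum(axis=1)[None, :]
            - 2.0 * X @ self.centers.T
        )
        K = np.exp(-np.maximum(d2, 0.0) / (2.0 * self.bandwidth**2))
        return K @ self.coefficients


def ktsne_embed(
    scaled_features,
    seed: int = 0,
    perplexity: float = 30.0,
    bandwidth_factor: float = 1.0,
    max_iter: int = 1000,
) -> EmbeddingRun:
    """t-SNE embedding with a Gaussian-kernel least-squares projection map.

    The map solves ``K c = Y`` in the least-squares sense, where ``K`` is
    the Gaussian kernel matrix of the training points with bandwidth
    ``bandwidth_factor`` x the median pairwise distance; projecting a
    training point reproduces its embedded location up to the residual of
    that fit, and duplicate inputs always project identically.
    """
    X = np.asarray(scaled_features, dtype=float)
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"need >= 3 * perplexity samples (n={n}, perplexity={perplexity})"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=int(seed) % _MAX_SEED,
        init="random",
        learning_rate="auto",
        max_iter=max_iter,
        # exact gradients are faster than Barnes-Hut below a few hundred
        # samples and remove the approximation as a source of variation
        method="exact" if n < 500 else "barnes_hut",
    )
    Y = tsne.fit_transform(X)
    dists = pdist(X)
    med = float(np.median(dists)) if dists.size else 1.0
    bandwidth = bandwidth_factor * (med if med > 0 else 1.0)
    d2 = squareform(dists**2)
    K = np.exp(-d2 / (2.0 * bandwidth**2))
    coef, *_ = np.linalg.lstsq(K, Y, rcond=None)
    return EmbeddingRun(
        embedding=Y,
        seed=int(seed),
        perplexity=perplexity,
        bandwidth=bandwidth,
        centers=X.copy(),
        coefficients=coef,
    )


# ---------------------------------------------------------------------------
# k-means / WSS / elbow
# ---------------------------------------------------------------------------


def kmeans_wss(
    embedding,
    k_max: int = 10,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[dict[int, float], dict[int, np.ndarray]]:
    """k-means for k = 1..k_max on a 2-D embedding.

    Returns ``(wss, labels)`` keyed by k; WSS is the sum of squared
    Euclidean distances to the assigned centroid (k-means inertia), run
    with ``n_init`` restarts.
    """
    Y = np.asarray(embedding, dtype=float)
    n = Y.shape[0]
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds n={n}")
    wss: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % _MAX_SEED)
        lab = km.fit_predict(Y)
        wss[k] = float(km.inertia_)
        labels[k] = lab
    return wss, labels


def elbow_k(curve: dict[int, float]) -> int:
    """k with the highest second-order WSS difference (ties -> smallest k).

    ``curve`` must cover a contiguous k = 1..k_max with k_max >= 3; the
    candidate range is k in [2, k_max - 1] since the second difference
    needs both neighbors.
    """
    ks = sorted(curve)
    if len(ks) < 3:
        raise ValueError("WSS curve needs at least 3 points")
    if ks != list(range(ks[0], ks[0] + len(ks))) or ks[0] != 1:
        raise ValueError("WSS curve must cover contiguous k starting at 1")
    best_k, best_val = None, -np.inf
    for k in ks[1:-1]:
        d2 = curve[k - 1] - 2.0 * curve[k] + curve[k + 1]
        if d2 > best_val:
            best_k, best_val = k, d2
    return int(best_k)


# ---------------------------------------------------------------------------
# proximity consensus
# ---------------------------------------------------------------------------


@dataclass
class ProximityMatrix:
    """Sample x sample co-clustering frequencies across an ensemble."""

    matrix: np.ndarray
    n_models: int

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ValueError("proximity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("proximity diagonal must be 1")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValueError("proximity entries must lie in [0, 1]")


def build_proximity(labelings) -> ProximityMatrix:
    """Fraction of models in which each sample pair shares a cluster."""
    labelings = [np.asarray(l) for l in labelings]
    if not labelings:
        raise ValueError("no labelings")
    n = labelings[0].size
    for l in labelings:
        if l.size != n:
            raise ValueError("labelings cover inconsistent sample sets")
    acc = np.zeros((n, n))
    for l in labelings:
        acc += l[:, None] == l[None, :]
    return ProximityMatrix(acc / len(labelings), len(labelings))


def consensus_groups(
    prox: ProximityMatrix,
    k: int,
    min_size: int = 5,
    method: str = "average",
) -> np.ndarray:
    """Hierarchical consensus groups of minimum size from a proximity matrix.

    Average-linkage (``method``) hierarchical clustering on distance
    1 - proximity, cut at ``k`` groups; any group smaller than ``min_size``
    is merged into the group with the highest average proximity to it,
    repeated until all groups reach the minimum size (the final group count
    may therefore be below k).  Labels are renumbered 0..G-1 by group size.
    """
    P = prox.matrix
    n = P.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if min_size * k > n:
        raise ValueError(f"min_size * k = {min_size * k} exceeds n = {n}")
    D = 1.0 - P
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    while True:
        groups, sizes = np.unique(labels, return_counts=True)
        small = groups[sizes < min_size]
        if small.size == 0 or groups.size == 1:
            break
        # merge the smallest offender first
        g = small[np.argmin(sizes[np.isin(groups, small)])]
        members = labels == g
        best_other, best_prox = None, -np.inf
        for h in groups:
            if h == g:
                continue
            avg = P[np.ix_(members, labels == h)].mean()
            if avg > best_prox:
                best_other, best_prox = h, avg
        labels[members] = best_other
    # stable renumbering: largest group first
    groups, sizes = np.unique(labels, return_counts=True)
    order = groups[np.argsort(-sizes, kind="stable")]
    remap = {g: i for i, g in enumerate(order)}
    return np.array([remap[g] for g in labels])


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class ConsensusClusters:
    """Full subtyping output: per-k consensus and the elbow-selected k*."""

    wss_mean: dict[int, float]
    k_star: int
    proximity: dict[int, ProximityMatrix]
    consensus_labels: dict[int, np.ndarray]
    labels: np.ndarray
    n_models: int
    min_size: int

    @property
    def group_sizes(self) -> dict[int, int]:
        groups, sizes = np.unique(self.labels, return_counts=True)
        return {int(g): int(s) for g, s in zip(groups, sizes)}


def run_subtyping(
    scaled_features,
    n_models: int = 1000,
    k_max: int = 10,
    min_size: int = 5,
    seed: int = 0,
    perplexity: float = 30.0,
    bandwidth_factor: float = 1.0,
    max_iter: int = 1000,
    n_init: int = 10,
) -> ConsensusClusters:
    """Run the full three-step consensus subtyping ensemble.

    ``n_models`` kernel-t-SNE embeddings (seeds spawned from ``seed``) are
    clustered with k-means for k = 1..k_max; the elbow k* is taken on the
    across-model mean WSS curve; per-k proximity matrices are condensed
    into consensus groups of minimum size ``min_size``.
    """
    X = np.asarray(scaled_features, dtype=float)
    n = X.shape[0]
    model_seeds = (
        np.random.SeedSequence(seed).generate_state(n_models) % _MAX_SEED
    )
    wss_acc = {k: 0.0 for k in range(1, k_max + 1)}
    labelings: dict[int, list[np.ndarray]] = {
        k: [] for k in range(2, k_max + 1)
    }
    for m, ms in enumerate(model_seeds):
        try:
            run = ktsne_embed(
                X,
                seed=int(ms),
                perplexity=perplexity,
                bandwidth_factor=bandwidth_factor,
                max_iter=max_iter,
            )
            wss, labels = kmeans_wss(
                run.embedding, k_max=k_max, seed=int(ms), n_init=n_init
            )
        except ValueError as err:
            raise ValueError(f"model {m}: {err}") from err
        for k in wss_acc:
            wss_acc[k] += wss[k]
        for k in labelings:
            labelings[k].append(labels[k])
    wss_mean = {k: v / n_models for k, v in wss_acc.items()}
    k_star = elbow_k(wss_mean)
    proximity = {k: build_proximity(labelings[k]) for k in labelings}
    consensus = {
        k: consensus_groups(proximity[k], k, min_size=min_size)
        for k in labelings
        if min_size * k <= n
    }
    return ConsensusClusters(
        wss_mean=wss_mean,
        k_star=k_star,
        proximity=proximity,
        consensus_labels=consensus,
        labels=consensus[k_star],
        n_models=n_models,
        min_size=min_size,
    )
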