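"""Resampled linear-SVM ensemble with tracked splits, cost tuning,
recursive feature elimination and AUC evaluation.

The protocol, repeated over many random 80:20 train/test resamples that are
*tracked* (the identical split sequence is reused by every model being
compared):

1. auto-scale features with training statistics only,
2. grid-search the SVM cost over 13 log-spaced values (0.001 .. 1e9) by
   stratified 5-fold cross-validated accuracy (ties -> smallest cost),
3. fit the linear model and record the test AUC (pre-RFE),
4. run recursive feature elimination on the training data -- repeatedly drop
   the 10% of remaining features with the smallest absolute weight -- and
   keep the subset size maximizing internal 5-fold CV AUC (ties -> smaller),
5. re-tune the cost on the selected subset, refit, and record the post-RFE
   test AUC, signed feature weights and test decision scores.

The sign of a feature weight encodes which class the feature is associated
with.  Test samples never influence scaling, tuning or feature selection.
Binary phenotypes reuse the classification path unchanged; continuous
phenotypes swap in an epsilon-insensitive linear regressor with Pearson r
as the quality metric.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.svm import LinearSVC, LinearSVR

from .tables_io import FeatureTable, TaxonLineage, aggregate_to_rank, RANKS

_MAX_SEED = 2**31 - 1


def default_cost_grid() -> np.ndarray:
    """13 cost candidates from 0.001 upward in decade steps."""
    return 0.001 * 10.0 ** np.arange(13)


def _check_grid(grid) -> np.ndarray:
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 1 or not (np.diff(g) > 0).all():
        raise ValueError("cost grid must be strictly increasing")
    return g


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Tracked train/test partitions shared across all compared models."""

    sample_ids: list[str]
    splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    test_fraction: float
    stratified: bool
    plan_id: str

    @property
    def n_resamples(self) -> int:
        return len(self.splits)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def make_splits(
    labels,
    n_resamples: int = 1000,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> SplitPlan:
    """Draw ``n_resamples`` random train/test partitions.

    ``labels`` may be a pandas Series (its index supplies sample ids) or any
    array-like.  Stratified plans preserve class proportions in the test set
    to within one sample (largest-remainder quotas).
    """
    if isinstance(labels, pd.Series):
        sample_ids = list(labels.index)
        y = labels.to_numpy()
    else:
        y = np.asarray(labels)
        sample_ids = [str(i) for i in range(len(y))]
    n = len(y)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ValueError("test_fraction leaves an empty train or test set")
    classes, counts = np.unique(y, return_counts=True)
    if stratify:
        if (counts < 2).any():
            small = classes[counts < 2]
            raise ValueError(f"classes with < 2 samples: {list(small)}")
        quota_f = counts * test_fraction
        quota = np.floor(quota_f).astype(int)
        rem = n_test - quota.sum()
        order = np.argsort(-(quota_f - quota))
        for j in order[: max(rem, 0)]:
            quota[j] += 1
        class_idx = [np.flatnonzero(y == c) for c in classes]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    splits = []
    for _ in range(n_resamples):
        if stratify:
            test_parts = []
            for idx, q in zip(class_idx, quota):
                perm = rng.permutation(idx)
                test_parts.append(perm[:q])
            test = np.sort(np.concatenate(test_parts))
        else:
            perm = rng.permutation(n)
            test = np.sort(perm[:n_test])
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        splits.append((np.flatnonzero(mask), test))
    h = hashlib.sha1()
    h.update(
        repr(
            (seed, n_resamples, test_fraction, stratify, sample_ids)
        ).encode()
    )
    return SplitPlan(
        sample_ids=sample_ids,
        splits=splits,
        seed=seed,
        test_fraction=test_fraction,
        stratified=stratify,
        plan_id=h.hexdigest(),
    )


# ---------------------------------------------------------------------------
# model primitives
# ---------------------------------------------------------------------------


def _fit(X, y, cost: float, classifier: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if classifier:
            model = LinearSVC(C=cost, dual="auto", tol=1e-3, max_iter=5000)
        else:
            model = LinearSVR(
                C=cost,
                epsilon=0.1,
                loss="epsilon_insensitive",
                dual=True,
                tol=1e-3,
                max_iter=5000,
            )
        model.fit(X, y)
    if not np.isfinite(model.coef_).all():
        raise ValueError("non-finite model weights")
    return model


def _scores(model, X, classifier: bool) -> np.ndarray:
    return model.decision_function(X) if classifier else model.predict(X)


def auc(scores, binary_labels) -> float:
    """Probability that a random positive outscores a random negative.

    Ties count one half; equals U / (n+ * n-) of the Mann-Whitney statistic.
    """
    y = np.asarray(binary_labels)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, s))


def _pearson(pred, y) -> float:
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1])


def _metric(scores, y, classifier: bool) -> float:
    return auc(scores, y) if classifier else _pearson(scores, y)


def _folds(y, cv: int, seed: int, classifier: bool):
    """Stratified (classification) or plain (regression) CV folds.

    Refolds with a new internal seed when a training fold is single-class,
    erroring after three attempts.
    """
    n = len(y)
    if classifier:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < cv:
            raise ValueError(
                f"need >= {cv} training samples per class for {cv}-fold CV"
            )
    for attempt in range(3):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, attempt])
        )
        if classifier:
            folds = [[] for _ in range(cv)]
            for c in np.unique(y):
                idx = rng.permutation(np.flatnonzero(y == c))
                for f, part in enumerate(np.array_split(idx, cv)):
                    folds[f].extend(part)
            folds = [np.sort(np.array(f)) for f in folds]
        else:
            perm = rng.permutation(n)
            folds = [np.sort(f) for f in np.array_split(perm, cv)]
        ok = True
        for f in folds:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            if classifier and np.unique(y[mask]).size < 2:
                ok = False
        if ok:
            return folds
    raise ValueError("degenerate single-class training fold after 3 refolds")


def tune_cost(
    train_features,
    train_labels,
    grid=None,
    cv: int = 5,
    seed: int = 0,
    classifier: bool = True,
    balanced: bool = False,
) -> float:
    """Return the grid cost maximizing mean CV accuracy (ties -> smallest).

    Classification tunes by accuracy (``balanced=True`` switches to balanced
    accuracy); regression tunes by CV Pearson r.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    g = default_cost_grid() if grid is None else _check_grid(grid)
    folds = _folds(y, cv, seed, classifier)
    n = len(y)
    scores = np.zeros(g.size)
    for j, cost in enumerate(g):
        vals = []
        for f in folds:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            model = _fit(X[mask], y[mask], cost, classifier)
            if classifier:
                pred = model.predict(X[f])
                if balanced:
                    accs = [
                        np.mean(pred[y[f] == c] == c) for c in np.unique(y[f])
                    ]
                    vals.append(float(np.mean(accs)))
                else:
                    vals.append(float(np.mean(pred == y[f])))
            else:
                vals.append(_pearson(model.predict(X[f]), y[f]))
        scores[j] = np.mean(vals)
    best = np.flatnonzero(scores == scores.max())[0]
    return float(g[best])


@dataclass
class RfeResult:
    """Elimination order (first-eliminated first) and the CV-chosen subset."""

    elimination_order: list[int]
    selected: list[int]
    cv_scores: dict[int, float]

    @property
    def ranking(self) -> list[int]:
        """Feature indices, longest-surviving first."""
        return list(reversed(self.elimination_order))


def rfe(
    train_features,
    train_labels,
    cost: float,
    step_fraction: float = 0.1,
    cv: int = 5,
    seed: int = 0,
    classifier: bool = True,
) -> RfeResult:
    """Recursive feature elimination by absolute linear-SVM weight.

    Each step drops ``ceil(step_fraction * remaining)`` features (at least
    one) with the smallest ``|w|`` until one remains; the returned subset is
    the survivor prefix whose size maximizes internal 5-fold CV AUC
    (classification) or CV Pearson r (regression), ties toward the smaller
    subset.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    p = X.shape[1]
    if p < 2:
        raise ValueError("need at least 2 features for RFE")
    active = list(range(p))
    order: list[int] = []
    sizes = [p]
    while len(active) > 1:
        model = _fit(X[:, active], y, cost, classifier)
        absw = np.abs(model.coef_).ravel()
        k = min(max(1, ceil(step_fraction * len(active))), len(active) - 1)
        drop = np.argsort(absw, kind="stable")[:k]
        for j in sorted(drop, reverse=True):
            order.append(active.pop(j))
        sizes.append(len(active))
    order.append(active[0])
    ranking = list(reversed(order))

    folds = _folds(y, cv, seed, classifier)
    n = len(y)
    cv_scores: dict[int, float] = {}
    for s in sizes:
        feats = ranking[:s]
        vals = []
        for f in folds:
            mask = np.ones(n, dtype=bool)
            mask[f] = False
            model = _fit(X[np.ix_(mask, feats)], y[mask], cost, classifier)
            vals.append(
                _metric(_scores(model, X[np.ix_(f, feats)], classifier), y[f], classifier)
            )
        cv_scores[s] = float(np.mean(vals))
    best = max(cv_scores.values())
    best_size = min(s for s, v in cv_scores.items() if v == best)
    return RfeResult(
        elimination_order=order,
        selected=sorted(ranking[:best_size]),
        cv_scores=cv_scores,
    )


# ---------------------------------------------------------------------------
# the resampled ensemble
# ---------------------------------------------------------------------------


@dataclass
class EnsembleResult:
    """Per-resample and aggregate output of one ensemble experiment."""

    feature_ids: list[str]
    plan_id: str
    metric_name: str
    metric_pre: np.ndarray
    metric_post: np.ndarray
    costs_pre: np.ndarray
    costs_post: np.ndarray
    selected: np.ndarray  # (n_resamples, n_features) bool
    weights: np.ndarray  # post-RFE weights, zero where not selected
    test_scores: list[pd.Series] = field(repr=False, default_factory=list)

    @property
    def n_resamples(self) -> int:
        return len(self.metric_pre)

    @property
    def selection_frequency(self) -> pd.Series:
        return pd.Series(
            self.selected.mean(axis=0), index=self.feature_ids
        ).sort_values(ascending=False)

    @property
    def mean_weight(self) -> pd.Series:
        return pd.Series(self.weights.mean(axis=0), index=self.feature_ids)

    # backwards-friendly aliases for the classification case
    @property
    def auc_pre(self) -> np.ndarray:
        return self.metric_pre

    @property
    def auc_post(self) -> np.ndarray:
        return self.metric_post

    def summary(self) -> dict:
        return {
            "metric": self.metric_name,
            "mean_pre": float(np.mean(self.metric_pre)),
            "mean_post": float(np.mean(self.metric_post)),
            "sd_pre": float(np.std(self.metric_pre)),
            "sd_post": float(np.std(self.metric_post)),
            "n_resamples": self.n_resamples,
        }


def _scale_train_test(Xtr: np.ndarray, Xte: np.ndarray):
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    degenerate = sd == 0
    sd = np.where(degenerate, 1.0, sd)
    str_ = (Xtr - mean) / sd
    ste = (Xte - mean) / sd
    str_[:, degenerate] = 0.0
    ste[:, degenerate] = 0.0
    return str_, ste


def _run_protocol(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: list[str],
    sample_ids: list[str],
    plan: SplitPlan,
    grid,
    classifier: bool,
    seed: int,
    step_fraction: float,
    cv: int,
) -> EnsembleResult:
    g = default_cost_grid() if grid is None else _check_grid(grid)
    n_res = plan.n_resamples
    p = X.shape[1]
    metric_pre = np.zeros(n_res)
    metric_post = np.zeros(n_res)
    costs_pre = np.zeros(n_res)
    costs_post = np.zeros(n_res)
    selected = np.zeros((n_res, p), dtype=bool)
    weights = np.zeros((n_res, p))
    test_scores: list[pd.Series] = []
    for i, (tr, te) in enumerate(plan.splits):
        try:
            sub_seeds = (
                np.random.SeedSequence([seed, plan.seed, i]).generate_state(3)
                % _MAX_SEED
            )
            Xtr, Xte = _scale_train_test(X[tr], X[te])
            ytr, yte = y[tr], y[te]
            cost1 = tune_cost(
                Xtr, ytr, g, cv=cv, seed=int(sub_seeds[0]), classifier=classifier
            )
            model = _fit(Xtr, ytr, cost1, classifier)
            metric_pre[i] = _metric(
                _scores(model, Xte, classifier), yte, classifier
            )
            costs_pre[i] = cost1

            sel = rfe(
                Xtr,
                ytr,
                cost1,
                step_fraction=step_fraction,
                cv=cv,
                seed=int(sub_seeds[1]),
                classifier=classifier,
            ).selected
            cost2 = tune_cost(
                Xtr[:, sel],
                ytr,
                g,
                cv=cv,
                seed=int(sub_seeds[2]),
                classifier=classifier,
            )
            final = _fit(Xtr[:, sel], ytr, cost2, classifier)
            s_te = _scores(final, Xte[:, sel], classifier)
            metric_post[i] = _metric(s_te, yte, classifier)
            costs_post[i] = cost2
            selected[i, sel] = True
            weights[i, sel] = final.coef_.ravel()
            test_scores.append(
                pd.Series(s_te, index=[sample_ids[j] for j in te], name=i)
            )
        except ValueError as err:
            raise ValueError(f"resample {i}: {err}") from err
    return EnsembleResult(
        feature_ids=feature_ids,
        plan_id=plan.plan_id,
        metric_name="auc" if classifier else "pearson_r",
        metric_pre=metric_pre,
        metric_post=metric_post,
        costs_pre=costs_pre,
        costs_post=costs_post,
        selected=selected,
        weights=weights,
        test_scores=test_scores,
    )


def run_ensemble(
    table: FeatureTable,
    labels: pd.Series,
    plan: SplitPlan,
    grid=None,
    seed: int = 0,
    step_fraction: float = 0.1,
    cv: int = 5,
) -> EnsembleResult:
    """Run the full classification protocol over a tracked split plan."""
    if isinstance(table, FeatureTable):
        if table.sample_ids != plan.sample_ids:
            raise ValueError("table samples differ from split-plan samples")
        X = table.values
        feature_ids = table.feature_ids
        sample_ids = table.sample_ids
    else:
        X = np.asarray(table, dtype=float)
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
        sample_ids = plan.sample_ids
    y = labels.reindex(plan.sample_ids).to_numpy() if isinstance(
        labels, pd.Series
    ) else np.asarray(labels)
    return _run_protocol(
        X,
        y,
        feature_ids,
        sample_ids,
        plan,
        grid,
        classifier=True,
        seed=seed,
        step_fraction=step_fraction,
        cv=cv,
    )


def compare_aucs(
    result_a,
    result_b,
    paired: bool = True,
    n_comparisons: int = 1,
    which: str = "post",
) -> tuple[float, float, float]:
    """Paired Wilcoxon signed-rank comparison of per-resample AUCs.

    Returns ``(statistic, raw_p, adjusted_p)`` with Bonferroni family-wise
    adjustment ``min(1, raw * n_comparisons)``.  Zero differences are
    dropped (Wilcoxon convention); all-zero differences give p = 1.
    EnsembleResults must share the same split plan.
    """
    def _arr(r):
        if isinstance(r, EnsembleResult):
            return r.metric_post if which == "post" else r.metric_pre
        return np.asarray(r, dtype=float)

    if isinstance(result_a, EnsembleResult) and isinstance(
        result_b, EnsembleResult
    ):
        if result_a.plan_id != result_b.plan_id:
            raise ValueError(
                "results come from different split plans; tracked-split "
                "comparison requires plan identity"
            )
    x, y = _arr(result_a), _arr(result_b)
    if len(x) != len(y):
        raise ValueError("resample counts differ")
    if not paired:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return float(stat), float(p), float(min(1.0, p * n_comparisons))
    if not np.any(x != y):
        return 0.0, 1.0, 1.0  # all differences zero: no evidence
    try:
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=True, method="approx"
        )
        stat, p = float(res.statistic), float(res.pvalue)
    except ValueError:
        stat, p = 0.0, 1.0
    if np.isnan(p):
        stat, p = 0.0, 1.0
    return stat, p, float(min(1.0, p * n_comparisons))


@dataclass
class RankScanResult:
    """Per-taxonomic-rank ensembles with paired pre/post-RFE comparisons."""

    results: dict[str, EnsembleResult]
    comparisons: dict[str, tuple[float, float, float]]

    def auc_table(self) -> pd.DataFrame:
        rows = []
        for rank, res in self.results.items():
            rows.append(
                {
                    "rank": rank,
                    "mean_auc_pre": float(np.mean(res.metric_pre)),
                    "mean_auc_post": float(np.mean(res.metric_post)),
                    "p_adj_pre_vs_post": self.comparisons[rank][2],
                }
            )
        return pd.DataFrame(rows).set_index("rank")


def rank_scan(
    species_table: FeatureTable,
    lineage: TaxonLineage,
    labels: pd.Series,
    plan: SplitPlan,
    grid=None,
    seed: int = 0,
    ranks=RANKS,
    **kwargs,
) -> RankScanResult:
    """Aggregate to every taxonomic rank and run the shared-plan ensemble.

    The paired pre-vs-post-RFE Wilcoxon comparison is Bonferroni-adjusted
    across the scanned ranks.
    """
    results: dict[str, EnsembleResult] = {}
    comparisons: dict[str, tuple[float, float, float]] = {}
    ranks = list(ranks)
    for rank in ranks:
        agg = aggregate_to_rank(species_table, lineage, rank)
        res = run_ensemble(agg, labels, plan, grid=grid, seed=seed, **kwargs)
        results[rank] = res
        comparisons[rank] = compare_aucs(
            res.metric_pre, res.metric_post, n_comparisons=len(ranks)
        )
    return RankScanResult(results, comparisons)


def associate_phenotype(
    table: FeatureTable,
    phenotype_values: pd.Series,
    phenotype_type: str,
    n_resamples: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    grid=None,
    step_fraction: float = 0.1,
    cv: int = 5,
) -> EnsembleResult:
    """Ensemble association of features with one phenotype variable.

    Binary phenotypes run the classification protocol; continuous
    phenotypes run the epsilon-insensitive linear regression protocol with
    Pearson r as the test metric.  Samples with missing phenotype are
    dropped *before* splitting.
    """
    if phenotype_type not in ("binary", "continuous"):
        raise ValueError("phenotype_type must be 'binary' or 'continuous'")
    values = phenotype_values.reindex(table.sample_ids)
    keep = values.notna()
    n_used = int(keep.sum())
    if n_used < 20:
        raise ValueError(
            f"only {n_used} non-missing samples; need >= 20 for 80:20 "
            "splitting with 5-fold CV"
        )
    data = table.data.loc[keep]
    y = values[keep]
    if phenotype_type == "binary":
        levels = sorted(y.unique())
        if len(levels) != 2:
            raise ValueError(f"binary phenotype has levels {levels}")
        y = y.map({levels[0]: 0, levels[1]: 1}).astype(int)
        plan = make_splits(
            y, n_resamples=n_resamples, test_fraction=test_fraction, seed=seed
        )
        classifier = True
    else:
        y = y.astype(float)
        plan = make_splits(
            y,
            n_resamples=n_resamples,
            test_fraction=test_fraction,
            seed=seed,
            stratify=False,
        )
        classifier = False
    return _run_protocol(
        data.to_numpy(dtype=float),
        y.to_numpy(),
        list(data.columns),
        list(data.index),
        plan,
        grid,
        classifier=classifier,
        seed=seed,
        step_fraction=step_fraction,
        cv=cv,
    )
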