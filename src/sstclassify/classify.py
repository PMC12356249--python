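"""Clustering-informed heuristic classification of SST subtypes.

The method is unsupervised at its core: z-score the top class-separating
features, embed them in 2-D with UMAP, grid-search clustering
hyperparameters (k-means, spectral, DBSCAN), rank solutions by silhouette
score in embedding space, and designate the cluster with the strongest
stimulus responses (highest mean response probability and evoked peak, by
rank sum) as putative SST-Calb2. Evaluation compares these putative labels
with genetic (mCherry/Calb2) labels via a confusion matrix.

Exposed both as functions and as sklearn-style estimators
(:class:`TopFeatureSelector`, :class:`SubtypeClusterPipeline`).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import DBSCAN, KMeans, SpectralClustering
from sklearn.metrics import silhouette_score

from . import features as feat

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "SST-Calb2"
NEGATIVE_LABEL = "SST-O"
PRED_POSITIVE = "putative-Calb2"
PRED_NEGATIVE = "putative-O"
NOISE_ID = -1


def zscore(matrix):
    """Column-wise z-scoring (population SD); zero-variance columns dropped.

    Accepts an array or DataFrame; returns the same type plus the boolean
    mask of retained columns.
    """
    X = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ValueError("z-scoring needs >= 2 cells")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d zero-variance column(s)", (~keep).sum())
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(Z, index=matrix.index,
                            columns=matrix.columns[keep]), keep
    return Z, keep


@dataclass(frozen=True)
class EmbeddingConfig:
    """UMAP hyperparameters for one embedding in the grid."""

    n_neighbors: int
    min_dist: float
    n_components: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors >= 2 required")
        if not (0 <= self.min_dist < 1):
            raise ValueError("0 <= min_dist < 1 required")


def embed(matrix, config: EmbeddingConfig) -> np.ndarray:
    """2-D UMAP embedding, deterministic given ``config.seed``."""
    import umap

    X = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if X.shape[0] <= config.n_neighbors:
        raise ValueError(
            f"{X.shape[0]} cells <= n_neighbors={config.n_neighbors}"
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        reducer = umap.UMAP(
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            n_components=config.n_components,
            random_state=config.seed,
        )
        return reducer.fit_transform(X)


@dataclass
class ClusterSolution:
    """One point of the clustering grid, scored by silhouette."""

    embed_config: EmbeddingConfig
    embedding: np.ndarray
    method: str  # kmeans | spectral | density
    params: dict
    labels: np.ndarray  # NOISE_ID allowed for the density method
    silhouette: float
    n_clusters: int
    inertia: float | None = None


def default_embedding_grid(seed: int = 0):
    return [
        EmbeddingConfig(n_neighbors=nn, min_dist=md, seed=seed)
        for nn, md in itertools.product((5, 10, 15, 30),
                                        (0.0, 0.1, 0.25, 0.5))
    ]


def default_cluster_grid():
    return {
        "kmeans": list(range(2, 9)),
        "spectral": list(range(2, 9)),
        "density": list(np.logspace(-1.0, 0.7, 10)),
    }


def small_embedding_grid(seed: int = 0):
    """Scaled-down grid used by the test suite and worked examples."""
    return [
        EmbeddingConfig(n_neighbors=nn, min_dist=0.1, seed=seed)
        for nn in (8, 15)
    ]


def small_cluster_grid():
    return {
        "kmeans": list(range(2, 7)),
        "spectral": list(range(2, 7)),
        "density": list(np.logspace(-0.7, 0.5, 4)),
    }


def full_embedding_grid(seed: int = 0):
    """Large search (~5000 embedding x clustering combinations)."""
    return [
        EmbeddingConfig(n_neighbors=nn, min_dist=md, seed=seed)
        for nn, md in itertools.product(
            (5, 8, 10, 12, 15, 20, 25, 30, 40, 50),
            (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
        )
    ]


def full_cluster_grid():
    return {
        "kmeans": list(range(2, 21)),
        "spectral": list(range(2, 21)),
        "density": list(np.logspace(-1.5, 1.0, 30)),
    }


def _cluster_once(emb, method, param, seed):
    if method == "kmeans":
        km = KMeans(n_clusters=int(param), n_init=10, random_state=seed)
        labels = km.fit_predict(emb)
        return labels, float(km.inertia_)
    if method == "spectral":
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", module="sklearn")
            sc = SpectralClustering(
                n_clusters=int(param), random_state=seed,
                assign_labels="kmeans", affinity="nearest_neighbors",
                n_neighbors=min(10, emb.shape[0] - 1),
            )
            return sc.fit_predict(emb), None
    if method == "density":
        return DBSCAN(eps=float(param), min_samples=3).fit_predict(emb), None
    raise ValueError(f"unknown clustering method {method!r}")


def _score_solution(emb, labels):
    """Silhouette on embedding coordinates, noise points excluded.

    Returns (silhouette, n_clusters) or (None, n) for degenerate solutions
    (single cluster, empty clusters, or silhouette undefined).
    """
    core = labels != NOISE_ID
    uniq = np.unique(labels[core])
    n_clusters = len(uniq)
    if n_clusters < 2 or core.sum() <= n_clusters:
        return None, n_clusters
    try:
        s = silhouette_score(emb[core], labels[core])
    except ValueError:
        return None, n_clusters
    return float(s), n_clusters


def grid_search(matrix, embed_grid=None, cluster_grid=None, seed: int = 0):
    """Evaluate every embedding x clustering combination.

    ``matrix`` is the z-scored top-feature matrix. Degenerate solutions are
    discarded; the rest are ranked by silhouette (descending, stable order).
    Returns ``(solutions, best)``.
    """
    if embed_grid is None:
        embed_grid = default_embedding_grid(seed)
    if cluster_grid is None:
        cluster_grid = default_cluster_grid()
    X = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    solutions = []
    for cfg in embed_grid:
        emb = embed(X, cfg)
        for method, params in cluster_grid.items():
            for param in params:
                labels, inertia = _cluster_once(emb, method, param, seed)
                sil, ncl = _score_solution(emb, labels)
                if sil is None:
                    continue
                key = "eps" if method == "density" else "n_clusters"
                solutions.append(
                    ClusterSolution(
                        embed_config=cfg, embedding=emb, method=method,
                        params={key: param}, labels=labels,
                        silhouette=sil, n_clusters=ncl, inertia=inertia,
                    )
                )
    solutions.sort(key=lambda s: -s.silhouette)
    if not solutions:
        raise ValueError("every grid point degenerate; nothing to rank")
    return solutions, solutions[0]


def selection_report(solutions) -> pd.DataFrame:
    """Model-selection summary: best silhouette and k-means inertia per
    cluster count, supporting the choice of cluster number."""
    rows = []
    for ncl in sorted({s.n_clusters for s in solutions}):
        sub = [s for s in solutions if s.n_clusters == ncl]
        best = max(sub, key=lambda s: s.silhouette)
        inertias = [s.inertia for s in sub if s.inertia is not None]
        rows.append(
            {
                "n_clusters": ncl,
                "n_solutions": len(sub),
                "best_silhouette": best.silhouette,
                "best_method": best.method,
                "min_inertia": min(inertias) if inertias else np.nan,
            }
        )
    return pd.DataFrame(rows)


def laplacian_eigenvalues(embedding, n_neighbors: int = 10, n_values: int = 10):
    """Smallest eigenvalues of the symmetric normalized Laplacian of the
    kNN graph on the embedding (eigengap heuristic for cluster count)."""
    from scipy.sparse.csgraph import laplacian
    from sklearn.neighbors import kneighbors_graph

    n = embedding.shape[0]
    g = kneighbors_graph(embedding, min(n_neighbors, n - 1), mode="connectivity")
    g = 0.5 * (g + g.T)
    lap = laplacian(g, normed=True)
    vals = np.linalg.eigvalsh(lap.toarray())
    return vals[:n_values]


@dataclass
class ClassificationResult:
    """Putative-subtype assignment and (optionally) its evaluation."""

    putative_calb2_cluster: int | None
    predicted: pd.Series  # cell_id -> putative-Calb2 / putative-O
    cluster_labels: pd.Series | None = None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    metrics: dict = field(default_factory=dict)


def _heuristic_scores(feature_matrix: pd.DataFrame):
    """Per-cell stimulus response probability and evoked peak, from the raw
    (unscaled) feature matrix."""
    rp_cols = [
        c for c in feature_matrix.columns
        if c.startswith("rp|stimulus|")
    ]
    peak_col = "trial|stimulus|response|peak"
    if not rp_cols or peak_col not in feature_matrix.columns:
        raise ValueError(
            "feature matrix lacks stimulus response-probability/peak columns"
        )
    return (feature_matrix[rp_cols].mean(axis=1),
            feature_matrix[peak_col])


def assign_putative_subtype(solution: ClusterSolution,
                            feature_matrix: pd.DataFrame,
                            manual_cluster: int | None = None) -> ClassificationResult:
    """Designate the putative SST-Calb2 cluster.

    The cluster whose cells have the highest mean stimulus response
    probability and evoked peak (rank sum over the two criteria) becomes
    putative SST-Calb2; all other clusters, and density-method noise
    points, become putative SST-O. Ties break to the lower cluster id with
    a warning. ``manual_cluster`` overrides the heuristic.
    """
    labels = np.asarray(solution.labels)
    ids = [int(c) for c in np.unique(labels) if c != NOISE_ID]
    if len(ids) < 2:
        raise ValueError("assignment undefined for single-cluster solutions")
    if len(labels) != len(feature_matrix):
        raise ValueError("labels and feature matrix misaligned")
    if manual_cluster is not None:
        if manual_cluster not in ids:
            raise ValueError(f"cluster {manual_cluster} not in solution")
        winner = int(manual_cluster)
    else:
        rp, peak = _heuristic_scores(feature_matrix)
        means = pd.DataFrame(
            {
                "rp": [rp.values[labels == c].mean() for c in ids],
                "peak": [peak.values[labels == c].mean() for c in ids],
            },
            index=ids,
        )
        # rank 0 = highest; rank sum over the two criteria
        ranksum = ((-means["rp"]).rank(method="min")
                   + (-means["peak"]).rank(method="min"))
        best = ranksum.min()
        tied = sorted(ranksum.index[ranksum == best])
        if len(tied) > 1:
            warnings.warn(
                f"heuristic tie between clusters {tied}; choosing {tied[0]}"
            )
        winner = int(tied[0])
    predicted = pd.Series(
        np.where(labels == winner, PRED_POSITIVE, PRED_NEGATIVE),
        index=feature_matrix.index, name="predicted",
    )
    return ClassificationResult(
        putative_calb2_cluster=winner,
        predicted=predicted,
        cluster_labels=pd.Series(labels, index=feature_matrix.index,
                                 name="cluster"),
    )


def evaluate(predicted: pd.Series, true_labels: pd.Series) -> ClassificationResult:
    """Confusion-matrix metrics with SST-Calb2 as the positive class.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R),
    accuracy = (TP+TN)/total; the negative class gets its own
    precision/recall analogously. Cells with unknown true labels are
    excluded; an empty class leaves its metrics NaN (flagged).
    """
    predicted = pd.Series(predicted)
    true_labels = pd.Series(true_labels).reindex(predicted.index)
    known = true_labels.isin([POSITIVE_LABEL, NEGATIVE_LABEL])
    pred_pos = predicted[known].isin([PRED_POSITIVE, POSITIVE_LABEL]).values
    true_pos = (true_labels[known] == POSITIVE_LABEL).values
    tp = int(np.sum(pred_pos & true_pos))
    fp = int(np.sum(pred_pos & ~true_pos))
    tn = int(np.sum(~pred_pos & ~true_pos))
    fn = int(np.sum(~pred_pos & true_pos))
    return ClassificationResult(
        putative_calb2_cluster=None, predicted=predicted,
        tp=tp, fp=fp, tn=tn, fn=fn,
        metrics=metrics_from_counts(tp, fp, tn, fn),
    )


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Closed-form confusion-matrix metrics from the four counts."""
    def _div(a, b):
        return a / b if b else float("nan")

    precision = _div(tp, tp + fp)
    recall = _div(tp, tp + fn)
    denom = precision + recall
    f1 = 2 * precision * recall / denom if denom and np.isfinite(denom) else float("nan")
    if (tp + fn) == 0 or (tn + fp) == 0:
        logger.warning("empty class; some metrics undefined")
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": _div(tp + tn, tp + fp + tn + fn),
        "precision_negative": _div(tn, tn + fn),
        "recall_negative": _div(tn, tn + fp),
    }


class TopFeatureSelector(BaseEstimator, TransformerMixin):
    """Select the top class-separating features by unpaired t-test.

    sklearn-style transformer: ``fit(X, y)`` ranks columns by p-value of a
    two-sample t-test between the two classes in ``y``; ``transform``
    keeps the best ``n_features``.
    """

    def __init__(self, n_features: int = 30, positive: str = POSITIVE_LABEL):
        self.n_features = n_features
        self.positive = positive

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.ranking_ = feat.rank_features(
            X, pd.Series(np.asarray(y), index=X.index), positive=self.positive
        )
        self.selected_features_ = feat.top_features(self.ranking_,
                                                    self.n_features)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X[self.selected_features_]


class SubtypeClusterPipeline(BaseEstimator):
    """End-to-end clustering-informed subtype classifier.

    ``fit(X, y=None)`` takes the raw feature matrix (cells x named
    features). If ``y`` (genetic labels) is given, the top ``n_top``
    t-test-ranked features are used, as in the labeled dataset; otherwise
    ``selected_features`` (e.g. carried over from a labeled dataset) or all
    columns. The matrix is z-scored, embedded and grid-searched; the best
    solution by silhouette — restricted to ``n_clusters`` when an int — is
    kept, and the strongest-responding cluster becomes putative SST-Calb2.

    Fitted attributes: ``ranking_``, ``selected_features_``, ``solutions_``,
    ``solution_``, ``embedding_``, ``labels_``, ``predicted_``, ``result_``.
    """

    def __init__(self, n_top: int = 30, n_clusters="auto",
                 embed_grid=None, cluster_grid=None, random_state: int = 0,
                 assign="auto", selected_features=None):
        self.n_top = n_top
        self.n_clusters = n_clusters
        self.embed_grid = embed_grid
        self.cluster_grid = cluster_grid
        self.random_state = random_state
        self.assign = assign
        self.selected_features = selected_features

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if y is not None:
            sel = TopFeatureSelector(n_features=self.n_top).fit(X, y)
            self.ranking_ = sel.ranking_
            self.selected_features_ = sel.selected_features_
        elif self.selected_features is not None:
            self.ranking_ = None
            self.selected_features_ = [c for c in self.selected_features
                                       if c in X.columns]
        else:
            self.ranking_ = None
            self.selected_features_ = list(X.columns)
        Z, _ = zscore(X[self.selected_features_])
        embed_grid = self.embed_grid
        if embed_grid is None:
            embed_grid = default_embedding_grid(self.random_state)
        solutions, best = grid_search(
            Z, embed_grid=embed_grid, cluster_grid=self.cluster_grid,
            seed=self.random_state,
        )
        if self.n_clusters != "auto":
            matching = [s for s in solutions
                        if s.n_clusters == int(self.n_clusters)]
            if not matching:
                raise ValueError(
                    f"no non-degenerate solution with {self.n_clusters} clusters"
                )
            best = matching[0]
        self.solutions_ = solutions
        self.solution_ = best
        self.embedding_ = best.embedding
        manual = None if self.assign == "auto" else int(self.assign)
        result = assign_putative_subtype(best, X, manual_cluster=manual)
        self.result_ = result
        self.labels_ = result.cluster_labels.values
        self.predicted_ = result.predicted
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).predicted_

    def score(self, X, y):
        """Accuracy of the fitted assignment against genetic labels."""
        res = evaluate(self.predicted_, pd.Series(y, index=self.predicted_.index))
        return res.metrics["accuracy"]
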