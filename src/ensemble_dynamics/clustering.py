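"""Stability-selected spectral clustering of firing-rate features.

The affinity is a symmetrized k-nearest-neighbor connectivity graph under the
cosine metric. Clustering embeds the graph via the eigenvectors of the
symmetric normalized Laplacian (row-normalized) and partitions the embedding
with k-means. Parameter selection scans (k, knn) combinations, scoring each
by the stability of bootstrap subsample clusterings against the full-data
reference, measured with ARI and AMI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score, silhouette_samples
from sklearn.neighbors import kneighbors_graph

from .datatypes import ValidationError
from .io import derive_rng, derive_seed

log = logging.getLogger("ensemble_dynamics")

#: Regularization added to disconnected affinity graphs instead of failing.
GRAPH_REG = 1e-8


@dataclass
class ClusterSolution:
    labels: np.ndarray
    k: int
    knn: int
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValidationError("labels out of range [0, k)")


@dataclass
class StabilityReport:
    grid: dict  # (k, knn) -> {ari_mean, ari_sd, ami_mean, ami_sd, n_boot}
    selected: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "grid": {f"{k},{knn}": v for (k, knn), v in sorted(self.grid.items())},
            "selected": self.selected,
        }


def knn_cosine_graph(features: np.ndarray, knn: int) -> np.ndarray:
    """Symmetric binary affinity: edge i-j iff j in i's knn by cosine, or vice versa."""
    X = np.asarray(features, dtype=float)
    if knn >= X.shape[0]:
        raise ValidationError(f"knn={knn} must be < n_cells={X.shape[0]}")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValidationError("zero feature vector: cosine distance undefined")
    G = kneighbors_graph(X, n_neighbors=knn, metric="cosine", mode="connectivity")
    A = G.toarray()
    A = np.maximum(A, A.T)  # OR-symmetrization
    np.fill_diagonal(A, 0.0)
    return A


def _spectral_embedding(affinity: np.ndarray, k: int) -> np.ndarray:
    A = np.asarray(affinity, dtype=float)
    n = A.shape[0]
    n_comp, _ = connected_components(A > 0, directed=False)
    if n_comp > k:
        log.info(
            "affinity graph has %d components; adding %.0e regularization", n_comp, GRAPH_REG
        )
        A = A + GRAPH_REG * (1 - np.eye(n))
    d = A.sum(axis=1)
    d[d == 0] = GRAPH_REG
    dm12 = 1.0 / np.sqrt(d)
    M = A * dm12[:, None] * dm12[None, :]
    # top-k eigenvectors of D^-1/2 A D^-1/2 == bottom-k of the normalized Laplacian
    w, v = scipy.linalg.eigh(M, subset_by_index=[n - k, n - 1])
    emb = v
    row_norm = np.linalg.norm(emb, axis=1, keepdims=True)
    row_norm[row_norm == 0] = 1.0
    return emb / row_norm


def spectral_cluster(affinity: np.ndarray, k: int, seed: int) -> "ClusterSolution":
    """Normalized-Laplacian embedding + seeded k-means (10 restarts)."""
    n = affinity.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds n_cells={n}")
    if k == 1:
        return ClusterSolution(labels=np.zeros(n, dtype=int), k=1, knn=0, seed=seed)
    emb = _spectral_embedding(affinity, k)
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    labels = km.fit_predict(emb)
    return ClusterSolution(labels=labels, k=k, knn=0, seed=seed)


def cluster_features(features: np.ndarray, k: int, knn: int, seed: int) -> ClusterSolution:
    sol = spectral_cluster(knn_cosine_graph(features, knn), k, seed)
    sol.knn = knn
    return sol


def partition_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Chance-corrected agreement between two partitions of the same cells."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError("labelings must cover the same cells")
    return {
        "ari": float(adjusted_rand_score(a, b)),
        "ami": float(adjusted_mutual_info_score(a, b)),
    }


def stability_scan(
    features: np.ndarray,
    k_range,
    knn_range,
    n_boot: int = 100,
    frac: float = 0.9,
    seed: int = 0,
) -> StabilityReport:
    """Bootstrap-stability scan over the (k, knn) grid.

    For each grid cell the full data is clustered once (the reference); each
    bootstrap clusters a random ``frac`` subsample (without replacement) and
    its ARI/AMI against the reference restricted to the subsample is recorded.
    """
    X = np.asarray(features, dtype=float)
    n = X.shape[0]
    k_range = list(k_range)
    knn_range = list(knn_range)
    if not k_range or not knn_range:
        raise ValidationError("empty parameter range")
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2 for an SD")
    n_sub = int(round(frac * n))
    if n_sub < max(k_range):
        raise ValidationError("subsample smaller than the largest k")
    rng = derive_rng(seed, "stability", "subsamples")
    subsamples = [rng.choice(n, size=n_sub, replace=False) for _ in range(n_boot)]
    grid = {}
    for knn in knn_range:
        for k in k_range:
            ref = cluster_features(X, k, knn, derive_seed(seed, "ref", k, knn))
            ari = np.empty(n_boot)
            ami = np.empty(n_boot)
            for i, idx in enumerate(subsamples):
                sub = cluster_features(X[idx], k, knn, derive_seed(seed, "boot", k, knn, i))
                agree = partition_agreement(ref.labels[idx], sub.labels)
                ari[i] = agree["ari"]
                ami[i] = agree["ami"]
            grid[(k, knn)] = {
                "ari_mean": float(ari.mean()),
                "ari_sd": float(ari.std(ddof=1)),
                "ami_mean": float(ami.mean()),
                "ami_sd": float(ami.std(ddof=1)),
                "n_boot": n_boot,
            }
    report = StabilityReport(grid=grid)
    report.selected = select_parameters(report)
    return report


def select_parameters(report: StabilityReport) -> dict:
    """Two selection criteria over the stability grid.

    (i) by_mean: argmax of the mean of {ARI mean, AMI mean};
    (ii) by_mean_over_sd: argmax of the mean of {ARI mean/SD, AMI mean/SD}
    (variance-adjusted). Ties break toward smaller k, then smaller knn. A
    grid cell whose bootstrap agreement is perfectly reproducible (positive
    mean, zero SD) is maximally stable: its ratio is treated as +inf. Cells
    with zero SD and non-positive mean are skipped with a warning.
    """
    if not report.grid:
        raise ValidationError("stability report is empty")
    by_mean, by_ratio = None, None
    best_mean, best_ratio = -np.inf, -np.inf
    for (k, knn) in sorted(report.grid):
        cell = report.grid[(k, knn)]
        mean_score = 0.5 * (cell["ari_mean"] + cell["ami_mean"])
        if mean_score > best_mean:
            best_mean, by_mean = mean_score, (k, knn)
        if cell["ari_sd"] == 0 or cell["ami_sd"] == 0:
            if min(cell["ari_mean"], cell["ami_mean"]) > 0:
                ratio_score = np.inf
            else:
                log.warning(
                    "grid cell (k=%d, knn=%d): zero SD with non-positive mean; "
                    "skipped from ratio criterion", k, knn)
                continue
        else:
            ratio_score = 0.5 * (cell["ari_mean"] / cell["ari_sd"]
                                 + cell["ami_mean"] / cell["ami_sd"])
        if ratio_score > best_ratio:
            best_ratio, by_ratio = ratio_score, (k, knn)
    return {"by_mean": by_mean, "by_mean_over_sd": by_ratio}


def cluster_quality(first5_pcs: np.ndarray, labels: np.ndarray) -> dict:
    """Mean within- vs between-cluster Pearson correlation of the first PCs."""
    X = np.asarray(first5_pcs, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 clusters")
    sizes = {u: int(np.sum(labels == u)) for u in uniq}
    for u, sz in sizes.items():
        if sz < 2:
            log.warning("cluster %s has a single cell; excluded from intra correlations", u)
    R = np.corrcoef(X)
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    intra = float(np.mean(R[iu[same], ju[same]])) if same.any() else np.nan
    inter = float(np.mean(R[iu[~same], ju[~same]])) if (~same).any() else np.nan
    return {"intra": intra, "inter": inter, "ratio": intra / inter if inter else np.nan}


def silhouette_filter(
    features: np.ndarray,
    k: int,
    knn: int,
    n_iter: int = 100,
    min_pass: int = 95,
    seed: int = 0,
) -> dict:
    """Retain cells with positive cosine silhouette in >= min_pass of n_iter runs.

    The graph and embedding are deterministic given (features, k, knn); the
    iterations vary the k-means seed only.
    """
    if min_pass > n_iter:
        raise ValidationError("min_pass exceeds n_iter")
    X = np.asarray(features, dtype=float)
    emb = _spectral_embedding(knn_cosine_graph(X, knn), k)
    pass_counts = np.zeros(X.shape[0], dtype=int)
    for i in range(n_iter):
        km = KMeans(n_clusters=k, n_init=10, random_state=derive_seed(seed, "silhouette", i))
        labels = km.fit_predict(emb)
        s = silhouette_samples(X, labels, metric="cosine")
        pass_counts += (s > 0).astype(int)
    return {"retained": pass_counts >= min_pass, "pass_counts": pass_counts}
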