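"""From-scratch cluster analysis for isotope-phenotype discovery.

Implements the ten algorithms compared in the method — seven agglomerative
linkages via the Lance–Williams recurrence, partitioning around medoids
(PAM), k-means and fuzzy c-means — together with the Calinski–Harabasz (CH)
validity index, silhouette widths, and a (method × k) validation scan used
to choose the clustering method and the number of isotope phenotypes.

Conventions
-----------
* Hard labels are 1-based (1..k), matching how phenotype clusters are
  usually reported.
* All ties break toward the lowest index; randomness enters only through an
  explicit seed.
* Feature matrices are z-scored per column by default; the scaling is
  recorded so centers can be reported back in raw ratio space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HIERARCHICAL_METHODS = ("single", "median", "average", "complete",
                        "centroid", "ward", "mcquitty")
PARTITIONAL_METHODS = ("pam", "kmeans", "fuzzy_cmeans")
ALL_METHODS = HIERARCHICAL_METHODS + PARTITIONAL_METHODS


# ---------------------------------------------------------------------------
# feature matrix

@dataclass
class FeatureMatrix:
    """Numeric matrix of ROIs × selected ratio columns, optionally z-scored.

    ``means``/``sds`` record the per-column scaling so that centers found in
    standardized space can be back-transformed to raw ratio space.
    """

    data: np.ndarray
    columns: list[str]
    index: pd.Index
    scaling: str = "none"          # "zscore" or "none"
    means: np.ndarray | None = None
    sds: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def to_raw(self, points: np.ndarray) -> np.ndarray:
        """Back-transform points (e.g. cluster centers) to raw ratio space."""
        if self.scaling == "none":
            return np.asarray(points, dtype=float)
        return np.asarray(points, dtype=float) * self.sds + self.means

    def to_scaled(self, points: np.ndarray) -> np.ndarray:
        """Map raw-space points into this matrix's (possibly scaled) space."""
        if self.scaling == "none":
            return np.asarray(points, dtype=float)
        return (np.asarray(points, dtype=float) - self.means) / self.sds


def build_features(ratios: pd.DataFrame, columns: list[str] | None = None,
                   scaling: str = "zscore") -> FeatureMatrix:
    """Assemble the clustering feature matrix from a ratio table.

    Columns with zero variance are dropped with a warning (they carry no
    clustering information and break z-scoring).
    """
    if columns is None:
        columns = [c for c in ("r13C", "r15N", "r33S", "rC_CN", "rS_CN")
                   if c in ratios.columns]
    X = ratios[list(columns)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    keep, dropped = [], []
    sds = X.std(axis=0, ddof=1)
    for j, c in enumerate(columns):
        (keep if sds[j] > 0 else dropped).append(j)
    if dropped:
        log.warning("dropping constant columns: %s", [columns[j] for j in dropped])
    if not keep:
        raise ValueError("all feature columns are constant")
    cols = [columns[j] for j in keep]
    X = X[:, keep]
    if scaling == "zscore":
        means = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        return FeatureMatrix((X - means) / sd, cols, ratios.index, "zscore", means, sd)
    elif scaling == "none":
        return FeatureMatrix(X, cols, ratios.index, "none")
    raise ValueError(f"unknown scaling {scaling!r}")


standardize = build_features


# ---------------------------------------------------------------------------
# solutions

@dataclass
class ClusterSolution:
    """A hard (optionally fuzzy) partition of the feature matrix."""

    method: str
    k: int
    labels: np.ndarray                    # 1..k, shape (n,)
    centers: np.ndarray | None = None     # (k, d) in feature space
    membership: np.ndarray | None = None  # (n, k), fuzzy only
    medoid_ids: np.ndarray | None = None  # row indices, pam only
    objective: float | None = None
    seed: int | None = None
    restarts: int | None = None
    objective_history: list | None = field(default=None, repr=False)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.min() < 1 or lab.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if len(np.unique(lab)) != self.k:
            raise ValueError("every cluster must be nonempty")
        if self.membership is not None:
            s = self.membership.sum(axis=1)
            if np.abs(s - 1).max() > 1e-9:
                raise ValueError("membership rows must sum to 1")


def cluster_means(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Per-cluster mean points (used as centers for non-center methods)."""
    return np.vstack([X[labels == j + 1].mean(axis=0) for j in range(k)])


# ---------------------------------------------------------------------------
# k-means

def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def kmeans(X: np.ndarray, k: int, seed: int = 0, restarts: int = 20,
           max_iter: int = 300) -> ClusterSolution:
    """Lloyd's k-means with k-means++ seeding, best of ``restarts`` by WSS.

    Empty clusters are repaired by reassigning the point farthest from its
    center.  The within-cluster sum of squares is non-increasing across
    iterations; the best run (lowest WSS) is returned.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        centers = _kmeanspp_init(X, k, rng)
        history = []
        for _ in range(max_iter):
            d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            lab = d2.argmin(axis=1)
            # repair empty clusters with the globally farthest points
            for j in range(k):
                if not (lab == j).any():
                    far = d2[np.arange(n), lab].argmax()
                    lab[far] = j
                    d2[far, :] = np.inf
                    d2[far, j] = 0.0
            wss = d2[np.arange(n), lab].sum()
            history.append(wss)
            new_centers = np.vstack([X[lab == j].mean(axis=0) for j in range(k)])
            if np.allclose(new_centers, centers):
                centers = new_centers
                break
            centers = new_centers
        d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        lab = d2.argmin(axis=1)
        wss = d2[np.arange(n), lab].sum()
        if len(np.unique(lab)) < k:
            continue
        if best is None or wss < best[0]:
            best = (wss, lab, centers, history)
    if best is None:
        raise RuntimeError("k-means failed to produce a valid partition")
    wss, lab, centers, history = best
    return ClusterSolution("kmeans", k, lab + 1, centers=centers, objective=wss,
                           seed=seed, restarts=restarts, objective_history=history)


# ---------------------------------------------------------------------------
# fuzzy c-means

def fuzzy_cmeans(X: np.ndarray, k: int, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 500, seed: int = 0, restarts: int = 20
                 ) -> ClusterSolution:
    """Bezdek fuzzy c-means minimizing J = Σ_i Σ_j u_ij^m ||x_i − c_j||².

    Alternates the center update c_j = Σ_i u_ij^m x_i / Σ_i u_ij^m with the
    membership update u_ij ∝ (1/d_ij²)^{1/(m−1)}; a point coincident with a
    center receives membership 1 there.  Convergence when max|Δu| < tol.
    Hard labels are the argmax memberships (ties to the lowest cluster).
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    expo = 1.0 / (m - 1.0)
    best = None
    for _ in range(restarts):
        U = rng.random((n, k))
        U /= U.sum(axis=1, keepdims=True)
        history = []
        for _ in range(max_iter):
            Um = U ** m
            centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
            D = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
            history.append(float((Um * D).sum()))
            zero = D <= 0
            if zero.any():
                Unew = np.zeros_like(D)
                rows = zero.any(axis=1)
                Unew[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
                inv = (1.0 / D[~rows]) ** expo
                Unew[~rows] = inv / inv.sum(axis=1, keepdims=True)
            else:
                inv = (1.0 / D) ** expo
                Unew = inv / inv.sum(axis=1, keepdims=True)
            delta = np.abs(Unew - U).max()
            U = Unew
            if delta < tol:
                break
        Um = U ** m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        D = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        J = float((Um * D).sum())
        if best is None or J < best[0]:
            best = (J, U, centers, history)
    J, U, centers, history = best
    lab = U.argmax(axis=1) + 1
    if len(np.unique(lab)) < k:
        # degenerate hardening; callers (e.g. the scan) treat this as invalid
        log.warning("fuzzy c-means hardening produced an empty cluster (k=%d)", k)
        raise DegeneratePartition(k, U, centers, J)
    return ClusterSolution("fuzzy_cmeans", k, lab, centers=centers, membership=U,
                           objective=J, seed=seed, restarts=restarts,
                           objective_history=history)


class DegeneratePartition(Exception):
    """Raised when hardening a fuzzy solution empties a cluster."""

    def __init__(self, k, membership, centers, objective):
        super().__init__(f"empty cluster after hardening (k={k})")
        self.k, self.membership, self.centers, self.objective = k, membership, centers, objective


# ---------------------------------------------------------------------------
# PAM

def _pairwise_distances(X: np.ndarray) -> np.ndarray:
    sq = ((X[:, None, :] - X[None]) ** 2).sum(axis=2)
    np.fill_diagonal(sq, 0.0)
    return np.sqrt(np.maximum(sq, 0.0))


def pam(X: np.ndarray, k: int, seed: int = 0) -> ClusterSolution:
    """Partitioning around medoids: greedy BUILD then exhaustive SWAP.

    BUILD selects medoids one at a time, each maximizing the decrease in
    total dissimilarity; SWAP repeatedly applies the best (medoid,
    non-medoid) exchange that lowers the cost until no improving swap
    exists.  Deterministic given the data order; ``seed`` is recorded only.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    D = _pairwise_distances(X)
    # BUILD
    medoids = [int(D.sum(axis=1).argmin())]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        m_new = int(gains.argmax())
        medoids.append(m_new)
        nearest = np.minimum(nearest, D[m_new])
    medoids = sorted(medoids)
    # SWAP
    while True:
        med = np.array(medoids)
        dm = D[:, med]                       # (n, k)
        order = dm.argsort(axis=1)
        d1 = dm[np.arange(n), order[:, 0]]   # nearest medoid distance
        d2 = dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        near_idx = order[:, 0]
        best_delta, best_swap = -1e-12, None
        nonmed = [h for h in range(n) if h not in medoids]
        if not nonmed:
            break
        for i_pos in range(k):
            is_near = near_idx == i_pos
            Dh = D[:, nonmed]                # (n, |nonmed|)
            # points whose nearest medoid is being removed
            contrib_near = np.minimum(Dh[is_near], d2[is_near, None]) - d1[is_near, None]
            # remaining points may switch to h
            contrib_other = np.minimum(Dh[~is_near] - d1[~is_near, None], 0.0)
            deltas = contrib_near.sum(axis=0) + contrib_other.sum(axis=0)
            j = int(deltas.argmin())
            if deltas[j] < best_delta:
                best_delta, best_swap = deltas[j], (i_pos, nonmed[j])
        if best_swap is None:
            break
        i_pos, h = best_swap
        medoids[i_pos] = h
        medoids = sorted(medoids)
    med = np.array(medoids)
    lab = D[:, med].argmin(axis=1)
    cost = D[np.arange(n), med[lab]].sum()
    return ClusterSolution("pam", k, lab + 1, centers=X[med], medoid_ids=med,
                           objective=float(cost), seed=seed)


# ---------------------------------------------------------------------------
# hierarchical clustering (Lance–Williams)

@dataclass
class Dendrogram:
    """Agglomerative merge history: (n−1) merges of cluster ids.

    Cluster ids 0..n−1 are leaves; merge t creates id n+t.  ``heights`` are
    linkage distances (for centroid/median/ward linkages they are in
    squared-distance units, which does not affect cutting by merge order).
    """

    merges: np.ndarray   # (n-1, 2)
    heights: np.ndarray  # (n-1,)
    n: int
    linkage: str


_LW_SQUARED = {"centroid", "median", "ward"}


def _lw_update(linkage, di, dj, dij, ni, nj, nk):
    if linkage == "single":
        return 0.5 * di + 0.5 * dj - 0.5 * np.abs(di - dj)
    if linkage == "complete":
        return 0.5 * di + 0.5 * dj + 0.5 * np.abs(di - dj)
    if linkage == "average":
        return (ni * di + nj * dj) / (ni + nj)
    if linkage == "mcquitty":
        return 0.5 * di + 0.5 * dj
    if linkage == "centroid":
        s = ni + nj
        return (ni * di + nj * dj) / s - (ni * nj * dij) / (s * s)
    if linkage == "median":
        return 0.5 * di + 0.5 * dj - 0.25 * dij
    if linkage == "ward":
        s = ni + nj + nk
        return ((ni + nk) * di + (nj + nk) * dj - nk * dij) / s
    raise ValueError(f"unknown linkage {linkage!r}")


def hclust_lance_williams(X: np.ndarray, linkage: str) -> Dendrogram:
    """Agglomerative clustering via the Lance–Williams recurrence.

    Single/complete/average/McQuitty operate on Euclidean distances;
    centroid (UPGMC), median (WPGMC) and Ward operate on squared Euclidean
    distances.  Merge ties break toward the lowest (i, j) pair index.
    """
    if linkage not in HIERARCHICAL_METHODS:
        raise ValueError(f"unknown linkage {linkage!r}")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    D = _pairwise_distances(X)
    if linkage in _LW_SQUARED:
        D = D ** 2
    big = np.inf
    D = D.copy()
    np.fill_diagonal(D, big)
    active = list(range(n))                 # maps matrix slot -> cluster id
    sizes = np.ones(n)
    merges = np.empty((n - 1, 2), dtype=int)
    heights = np.empty(n - 1)
    slot_of = {i: i for i in range(n)}
    alive = np.ones(n, dtype=bool)
    ids = np.arange(n)
    for t in range(n - 1):
        sub = np.where(alive)[0]
        Dsub = D[np.ix_(sub, sub)]
        flat = np.argmin(Dsub)
        a, b = divmod(flat, len(sub))
        if a > b:
            a, b = b, a
        si, sj = sub[a], sub[b]             # matrix slots, si < sj
        dij = D[si, sj]
        ci, cj = ids[si], ids[sj]
        merges[t] = (min(ci, cj), max(ci, cj))
        heights[t] = dij
        ni, nj = sizes[si], sizes[sj]
        others = sub[(sub != si) & (sub != sj)]
        if len(others):
            nk = sizes[others]
            D[si, others] = D[others, si] = _lw_update(
                linkage, D[si, others], D[sj, others], dij, ni, nj, nk)
        sizes[si] = ni + nj
        ids[si] = n + t
        alive[sj] = False
        D[sj, :] = big
        D[:, sj] = big
    return Dendrogram(merges, heights, n, linkage)


def cut_dendrogram(dend: Dendrogram, k: int) -> np.ndarray:
    """Labels (1..k) of the k-cluster partition: undo the last k−1 merges.

    Clusters are numbered by the smallest leaf index they contain, in
    ascending order.
    """
    n = dend.n
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    parent = np.arange(2 * n - 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b = dend.merges[t]
        ra, rb = find(a), find(b)
        parent[ra] = parent[rb] = n + t
    roots = np.array([find(i) for i in range(n)])
    labels = np.empty(n, dtype=int)
    # order clusters by their smallest member
    seen = {}
    for i in range(n):
        if roots[i] not in seen:
            seen[roots[i]] = len(seen) + 1
        labels[i] = seen[roots[i]]
    return labels


def hclust(X: np.ndarray, linkage: str, k: int) -> ClusterSolution:
    """Convenience wrapper: build the dendrogram and cut at k clusters."""
    dend = hclust_lance_williams(X, linkage)
    lab = cut_dendrogram(dend, k)
    X = np.asarray(X, dtype=float)
    centers = cluster_means(X, lab, k)
    return ClusterSolution(linkage, k, lab, centers=centers)


# ---------------------------------------------------------------------------
# validity indices

def ch_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz index: [B/(k−1)] / [W/(n−k)].

    B is the size-weighted dispersion of cluster centroids about the grand
    mean, W the pooled within-cluster dispersion.  Larger values indicate
    tighter, better-separated clusters.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2 or k >= n:
        raise ValueError("CH index requires 2 <= k <= n-1")
    grand = X.mean(axis=0)
    B = W = 0.0
    for u in uniq:
        Xj = X[labels == u]
        c = Xj.mean(axis=0)
        B += len(Xj) * ((c - grand) ** 2).sum()
        W += ((Xj - c) ** 2).sum()
    return float((B / (k - 1)) / (W / (n - k)))


@dataclass
class SilhouetteResult:
    widths: np.ndarray            # s(i) per row
    cluster_means: dict           # label -> mean width
    overall_mean: float


def silhouette_widths(X: np.ndarray, labels: np.ndarray) -> SilhouetteResult:
    """Silhouette widths s(i) = (b−a)/max(a,b); singletons get s = 0.

    a(i) is the mean distance to the point's own cluster (excluding
    itself); b(i) the smallest mean distance to any other cluster.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = _pairwise_distances(X)
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == u].mean() for u in uniq if u != labels[i])
        s[i] = (b - a) / max(a, b)
    cl_means = {int(u): float(s[labels == u].mean()) for u in uniq}
    return SilhouetteResult(s, cl_means, float(s.mean()))


# ---------------------------------------------------------------------------
# method × k scan

@dataclass
class MethodScan:
    """CH values over a (method × k) grid, with the best cell and solutions."""

    grid: pd.DataFrame            # columns: method, k, ch, valid
    solutions: dict               # (method, k) -> ClusterSolution
    best: tuple                   # (method, k)

    def best_solution(self) -> ClusterSolution:
        return self.solutions[self.best]


def _fit_method(X, method, k, seed, restarts, dendros):
    if method == "kmeans":
        return kmeans(X, k, seed=seed, restarts=restarts)
    if method == "fuzzy_cmeans":
        return fuzzy_cmeans(X, k, seed=seed, restarts=restarts)
    if method == "pam":
        return pam(X, k, seed=seed)
    if method in HIERARCHICAL_METHODS:
        if method not in dendros:
            dendros[method] = hclust_lance_williams(X, method)
        lab = cut_dendrogram(dendros[method], k)
        return ClusterSolution(method, k, lab, centers=cluster_means(np.asarray(X, float), lab, k))
    raise ValueError(f"unknown method {method!r}")


def scan_methods(features: FeatureMatrix | np.ndarray,
                 methods: list[str] | None = None,
                 k_range: range = range(2, 11),
                 seed: int = 0, restarts: int = 20) -> MethodScan:
    """Evaluate every (method, k) cell with the CH index on hard partitions.

    Fuzzy solutions are hardened by argmax membership before computing CH.
    Cells whose hardening empties a cluster are recorded as invalid and
    excluded from the argmax.  Ties break toward smaller k, then method
    name order.
    """
    X = features.data if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if methods is None:
        methods = list(ALL_METHODS)
    if not methods:
        raise ValueError("methods must be nonempty")
    rows, solutions, dendros = [], {}, {}
    for method in methods:
        for k in k_range:
            try:
                sol = _fit_method(X, method, k, seed, restarts, dendros)
                chv = ch_index(X, sol.labels)
                rows.append((method, k, chv, True))
                solutions[(method, k)] = sol
            except DegeneratePartition:
                log.warning("scan cell (%s, k=%d) degenerate; excluded", method, k)
                rows.append((method, k, np.nan, False))
    grid = pd.DataFrame(rows, columns=["method", "k", "ch", "valid"])
    valid = grid[grid["valid"]]
    if valid.empty:
        raise RuntimeError("no valid cells in method scan")
    # argmax CH; ties -> smaller k, then method name
    best_row = valid.sort_values(["ch", "k", "method"],
                                 ascending=[False, True, True]).iloc[0]
    best = (best_row["method"], int(best_row["k"]))
    return MethodScan(grid, solutions, best)
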