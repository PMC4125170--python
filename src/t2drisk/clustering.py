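"""Cohort partitioning: standardization, k-means, CCC, and choice of k.

The cohort is standardized on the nine risk variables (sample SD, n-1
denominator) and partitioned by Lloyd's algorithm run to an assignment
fixed point, seeded by k-means++ (several restarts, best within-cluster sum
of squares kept) or, optionally, by nested refinement of the (k-1)-cluster
solution, which makes R^2 provably non-decreasing in k.  Candidate cluster
counts are scored by R^2 = 1 - SS_within/SS_total and by Sarle's cubic
clustering criterion; the selection rule keeps the smallest k with CCC >= 10
whose R^2 increment over k-1 is maximal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus

logger = logging.getLogger(__name__)

CCC_THRESHOLD = 10.0
DEFAULT_K_RANGE = range(2, 8)
#: Cluster count of the shipped model when selection is skipped.
DEFAULT_K = 3


@dataclass
class StandardizationParams:
    """Per-variable location/scale retained for projecting new subjects."""

    variables: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.variables].to_numpy(dtype=float)
        return (x - self.mean) / self.sd

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.sd + self.mean


def standardize(cohort: pd.DataFrame, variables: list[str]):
    """Column-wise z-scoring with the n-1 SD convention.

    Returns ``(matrix, params)``; raises on any zero-variance column,
    naming the offending variable.
    """
    x = cohort[list(variables)].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    for v, s in zip(variables, sd):
        if not np.isfinite(s) or s <= 0:
            raise ValueError(f"variable {v!r} has zero variance; cannot standardize")
    params = StandardizationParams(list(variables), mean, sd)
    return (x - mean) / sd, params


def _lloyd(x: np.ndarray, centroids: np.ndarray, max_iter: int = 1000):
    """Lloyd iteration to an assignment fixed point.

    Empty clusters are re-seeded from the point farthest from its centroid.
    Returns ``(labels, centroids, sse)``.
    """
    k = len(centroids)
    labels = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = x[labels == c]
            if len(members) == 0:
                far = int(d2[np.arange(len(x)), labels].argmax())
                logger.info("empty cluster %d re-seeded from farthest point", c)
                centroids[c] = x[far]
                labels[far] = c
                members = x[labels == c]
            centroids[c] = members.mean(axis=0)
    sse = float(((x - centroids[labels]) ** 2).sum())
    return labels, centroids.copy(), sse


def kmeans_partition(x: np.ndarray, k: int, seed: int = 0, *,
                     init: str | np.ndarray = "k-means++", n_init: int = 5):
    """Partition ``x`` into ``k`` clusters; returns (labels, centroids, R^2).

    ``init`` may be ``"k-means++"`` (``n_init`` seeded restarts, best SSE
    kept) or an explicit (k, p) centroid array (single run — used by the
    nested-refinement mode).  Deterministic given ``seed``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(x, axis=0)) < k:
        raise ValueError(f"need at least {k} distinct points for k={k}")
    ss_total = float(((x - x.mean(axis=0)) ** 2).sum())
    best = None
    if isinstance(init, np.ndarray):
        starts = [np.array(init, dtype=float)]
    else:
        starts = [
            kmeans_plusplus(x, n_clusters=k,
                            random_state=(int(seed) % (2**31 - 1)) + r)[0]
            for r in range(n_init)
        ]
    for start in starts:
        labels, centroids, sse = _lloyd(x, start)
        if best is None or sse < best[2] - 1e-12:
            best = (labels, centroids, sse)
    labels, centroids, sse = best
    r2 = 1.0 - sse / ss_total if ss_total > 0 else 1.0
    return labels, centroids, r2


def nested_kmeans(x: np.ndarray, k_max: int, seed: int = 0):
    """Solutions for k = 2..k_max where each k is initialized from the k-1
    centroids plus the worst-fit point; R^2 is non-decreasing in k."""
    x = np.asarray(x, dtype=float)
    results = {}
    prev_centroids = None
    for k in range(2, k_max + 1):
        if prev_centroids is None:
            labels, centroids, r2 = kmeans_partition(x, k, seed)
        else:
            d2 = ((x[:, None, :] - prev_centroids[None, :, :]) ** 2).sum(axis=2)
            worst = int(d2.min(axis=1).argmax())
            init = np.vstack([prev_centroids, x[worst]])
            labels, centroids, r2 = kmeans_partition(x, k, seed, init=init)
        results[k] = (labels, centroids, r2)
        prev_centroids = centroids
    return results


def cubic_clustering_criterion(x: np.ndarray, labels: np.ndarray) -> float:
    """Sarle's cubic clustering criterion for one partition.

    Observed R^2 is compared with its expectation under a uniform null over
    the data's principal hyperbox, following the SAS Technical Report A-108
    formulation with its published approximation: eigenvalue scale factors
    ``u_j = s_j / c`` with ``c = (prod s_j / q)^(1/p)``, effective dimension
    ``p* = min(#{u_j >= 1}, q - 1)``, and

        CCC = ln[(1 - E(R^2)) / (1 - R^2)] * sqrt(n p*/2) / (0.001 + E(R^2))^1.2
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    q = len(clusters)
    if q < 2:
        raise ValueError("CCC is undefined for a single cluster")
    n, p = x.shape
    xc = x - x.mean(axis=0)
    ss_total = float((xc ** 2).sum())
    ss_within = 0.0
    for c in clusters:
        m = xc[labels == c]
        ss_within += float(((m - m.mean(axis=0)) ** 2).sum())
    r2 = 1.0 - ss_within / ss_total

    if x.shape[1] == 1:
        eig = np.array([float(np.var(xc, ddof=1))])
    else:
        eig = np.sort(np.linalg.eigvalsh(np.cov(xc, rowvar=False)))[::-1]
    s = np.sqrt(np.clip(eig, 0.0, None))
    s = s[s > 1e-12]
    if len(s) == 0:
        raise ValueError("data has no variance")
    # p* is the largest dimension count whose scaled eigenvalue still
    # exceeds the cell edge c = (prod_{j<=p*} s_j / q)^(1/p*); c and p*
    # are interdependent, so p* is found by scanning candidates
    p_star, c_scale = 1, s[0] / q
    for cand in range(1, len(s) + 1):
        c_cand = (float(np.prod(s[:cand])) / q) ** (1.0 / cand)
        if s[cand - 1] >= c_cand:
            p_star, c_scale = cand, c_cand
    u = s / c_scale
    a = float((1.0 / (n + u[:p_star])).sum())
    b = float((u[p_star:] ** 2 / (n + u[p_star:])).sum())
    e_r2 = 1.0 - ((a + b) / float((u ** 2).sum())) * ((n - q) ** 2 / n) * (1 + 4.0 / n)
    e_r2 = min(max(e_r2, 1e-12), 1 - 1e-12)
    r2 = min(r2, 1 - 1e-12)
    return float(np.log((1 - e_r2) / (1 - r2)) * np.sqrt(n * p_star / 2.0)
                 / (0.001 + e_r2) ** 1.2)


@dataclass
class ClusterDiagnostics:
    k: int
    r_squared: float
    ccc: float


def choose_k(diagnostics: list[ClusterDiagnostics]) -> int:
    """Smallest k with CCC >= 10 whose R^2 increment over k-1 is maximal.

    The increment for the smallest candidate k is taken over the trivial
    one-cluster solution (R^2 = 0).  When no k passes the CCC threshold the
    k with maximal CCC is returned with a warning.
    """
    if not diagnostics:
        raise ValueError("no diagnostics supplied")
    by_k = {d.k: d for d in sorted(diagnostics, key=lambda d: d.k)}
    ks = sorted(by_k)
    incr = {}
    for k in ks:
        prev = by_k[k - 1].r_squared if (k - 1) in by_k else 0.0
        incr[k] = by_k[k].r_squared - prev
    passing = [k for k in ks if by_k[k].ccc >= CCC_THRESHOLD]
    if not passing:
        best = max(ks, key=lambda k: by_k[k].ccc)
        logger.warning("no candidate k reaches CCC >= %.0f; falling back to "
                       "k=%d (max CCC %.2f)", CCC_THRESHOLD, best, by_k[best].ccc)
        return best
    best_incr = max(incr[k] for k in passing)
    return min(k for k in passing if incr[k] >= best_incr - 1e-12)


@dataclass
class ClusterModel:
    """A fitted partition: standardization, centroids, assignments, diagnostics."""

    params: StandardizationParams
    k: int
    centroids: np.ndarray
    assignments: pd.Series  # indexed by subject id
    diagnostics: list[ClusterDiagnostics] = field(default_factory=list)

    def assign(self, cohort: pd.DataFrame) -> np.ndarray:
        """Nearest-centroid cluster index for new subjects (standardized
        Euclidean distance)."""
        z = self.params.transform(cohort)
        d2 = ((z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def to_dict(self) -> dict:
        return {
            "variables": self.params.variables,
            "mean": self.params.mean.tolist(),
            "sd": self.params.sd.tolist(),
            "k": int(self.k),
            "centroids": self.centroids.tolist(),
            "assignments": {str(i): int(c) for i, c in self.assignments.items()},
            "diagnostics": [
                {"k": d.k, "r_squared": d.r_squared, "ccc": d.ccc}
                for d in self.diagnostics
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterModel":
        return cls(
            params=StandardizationParams(
                list(d["variables"]), np.array(d["mean"]), np.array(d["sd"])),
            k=int(d["k"]),
            centroids=np.array(d["centroids"]),
            assignments=pd.Series({int(i): c for i, c in d["assignments"].items()},
                                  dtype=int).sort_index(),
            diagnostics=[ClusterDiagnostics(**x) for x in d["diagnostics"]],
        )

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def fit_cluster_model(cohort: pd.DataFrame, variables: list[str], *,
                      seed: int = 0, k_range=DEFAULT_K_RANGE,
                      k_fixed: int | None = None) -> ClusterModel:
    """Standardize, scan candidate k (unless ``k_fixed``), keep the chosen
    partition as a :class:`ClusterModel` indexed by the cohort's ``id``."""
    z, params = standardize(cohort, variables)
    diagnostics = []
    solutions = {}
    ks = [k_fixed] if k_fixed is not None else list(k_range)
    for k in ks:
        labels, centroids, r2 = kmeans_partition(z, k, seed)
        ccc = cubic_clustering_criterion(z, labels)
        diagnostics.append(ClusterDiagnostics(k=k, r_squared=r2, ccc=ccc))
        solutions[k] = (labels, centroids)
    k = k_fixed if k_fixed is not None else choose_k(diagnostics)
    labels, centroids = solutions[k]
    return ClusterModel(
        params=params, k=k, centroids=centroids,
        assignments=pd.Series(labels, index=cohort["id"].to_numpy()),
        diagnostics=diagnostics,
    )
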