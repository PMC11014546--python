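"""Comparator multivariate two-sample methods for the benchmark.

Three established alternatives to retrieval-based assessment, each taking two
groups of profiles and returning a detection decision:

* **mp-value** — Mahalanobis distance between group centroids in a
  variance-weighted PCA space with a label-permutation null;
* **MMD** — unbiased maximum mean discrepancy with an RBF kernel at the
  median-heuristic bandwidth, label-permutation p-value;
* **k-means** — k=2 clustering of the pooled profiles; detection means the
  best-inertia partition reproduces the group labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

DEFAULT_N_PERM = 1_000

#: ridge factor for the pooled covariance (times mean diagonal variance)
RIDGE = 1e-6


@dataclass(frozen=True)
class TwoGroupResult:
    """Outcome of one two-group comparison."""

    method: str
    statistic: float
    p_value: float | None
    detected: bool


def _check_groups(a: np.ndarray, b: np.ndarray, min_each: int, min_total: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share feature dimension")
    if min(len(a), len(b)) < min_each:
        raise ValueError(f"each group needs at least {min_each} profiles")
    if len(a) + len(b) < min_total:
        raise ValueError(f"combined sample size must be at least {min_total}")
    return a, b


def _smoothed_p(perm_stats: np.ndarray, observed: float) -> float:
    b = int((perm_stats >= observed - 1e-12).sum())
    return (1 + b) / (1 + len(perm_stats))


# ---------------------------------------------------------------------------
# mp-value
# ---------------------------------------------------------------------------


def _weighted_scores(X: np.ndarray) -> np.ndarray:
    """PCA scores of the pooled sample, weighted by explained-variance share.

    All components up to the pooled-sample rank are retained (components with
    numerically zero variance are dropped). The pooled sample is invariant
    under label permutation, so the projection is computed once.
    """
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    keep = evr > 1e-12
    return scores[:, keep] * evr[keep]


def _mahalanobis_stat(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mahalanobis distance between centroids under pooled within-group
    covariance (ridge-regularized for rank deficiency)."""
    ga = scores[labels]
    gb = scores[~labels]
    diff = ga.mean(axis=0) - gb.mean(axis=0)
    k = scores.shape[1]
    S = np.zeros((k, k))
    dof = 0
    for g in (ga, gb):
        if len(g) >= 2:
            S += (len(g) - 1) * np.cov(g, rowvar=False)
            dof += len(g) - 1
    if dof > 0:
        S /= dof
    lam = RIDGE * max(np.trace(S) / k, np.finfo(float).tiny)
    S = S + lam * np.eye(k)
    try:
        d2 = float(diff @ np.linalg.solve(S, diff))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "degenerate pooled covariance after regularization"
        ) from exc
    return float(np.sqrt(max(d2, 0.0)))


def mp_value(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = 0.05,
) -> TwoGroupResult:
    """Multidimensional perturbation value: PCA + Mahalanobis + permutations."""
    a, b = _check_groups(group_a, group_b, min_each=1, min_total=3)
    X = np.vstack([a, b])
    labels = np.zeros(len(X), dtype=bool)
    labels[: len(a)] = True
    scores = _weighted_scores(X)
    observed = _mahalanobis_stat(scores, labels)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = _mahalanobis_stat(scores, rng.permutation(labels))
    p = _smoothed_p(perm, observed)
    return TwoGroupResult("mp_value", observed, p, p < alpha)


# ---------------------------------------------------------------------------
# MMD
# ---------------------------------------------------------------------------


def _rbf_kernel(X: np.ndarray) -> np.ndarray:
    """RBF kernel exp(-||x-y||^2 / (2 sigma^2)), sigma = median pairwise
    Euclidean distance of the pooled sample."""
    d = pdist(X, metric="euclidean")
    sigma = float(np.median(d))
    if sigma == 0:
        raise ValueError("zero kernel bandwidth: all pooled points identical")
    sq = squareform(d) ** 2
    return np.exp(-sq / (2.0 * sigma**2))


def _mmd2_unbiased(K: np.ndarray, labels: np.ndarray) -> float:
    ia = np.flatnonzero(labels)
    ib = np.flatnonzero(~labels)
    m, n = len(ia), len(ib)
    Kaa = K[np.ix_(ia, ia)]
    Kbb = K[np.ix_(ib, ib)]
    Kab = K[np.ix_(ia, ib)]
    term_a = (Kaa.sum() - np.trace(Kaa)) / (m * (m - 1))
    term_b = (Kbb.sum() - np.trace(Kbb)) / (n * (n - 1))
    return float(term_a + term_b - 2.0 * Kab.mean())


def mmd_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = 0.05,
) -> TwoGroupResult:
    """Unbiased MMD^2 two-sample test with label-permutation p-value."""
    a, b = _check_groups(group_a, group_b, min_each=2, min_total=4)
    X = np.vstack([a, b])
    labels = np.zeros(len(X), dtype=bool)
    labels[: len(a)] = True
    K = _rbf_kernel(X)
    observed = _mmd2_unbiased(K, labels)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for i in range(n_perm):
        perm[i] = _mmd2_unbiased(K, rng.permutation(labels))
    p = _smoothed_p(perm, observed)
    return TwoGroupResult("mmd", observed, p, p < alpha)


# ---------------------------------------------------------------------------
# k-means separation
# ---------------------------------------------------------------------------


def kmeans_separation(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_restarts: int = 10,
    seed: int | None = None,
) -> TwoGroupResult:
    """k=2 clustering; detected iff the best-inertia partition equals the
    group partition up to cluster-label swap."""
    a, b = _check_groups(group_a, group_b, min_each=1, min_total=2)
    X = np.vstack([a, b])
    labels = np.zeros(len(X), dtype=int)
    labels[: len(a)] = 1
    km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed)
    assign = km.fit_predict(X)
    match = bool(np.array_equal(assign, labels) or np.array_equal(1 - assign, labels))
    return TwoGroupResult("kmeans", float(match), None, match)
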