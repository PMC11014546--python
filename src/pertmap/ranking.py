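"""Distances, binary rank lists, and (mean) average precision.

Average precision here is the conventional non-interpolated form: the mean of
precision@k over the ranks k that hold a correct match, equivalently the sum
of precision weighted by the increment in recall. It equals the area under
the (non-interpolated) precision-recall curve and is normalized by the number
of positives, so a perfect ranking scores 1 regardless of list length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .grouping import RetrievalInstance
from .profiles import ProfileTable

_METRIC_ALIASES = {
    "cosine": "cosine",
    "euclidean": "euclidean",
    "correlation": "correlation",
    "pearson": "correlation",
    "pearson_correlation_distance": "correlation",
}

TIE_BREAKS = ("index", "random")


@dataclass(frozen=True)
class DistanceSpec:
    """Dissimilarity metric and tie-breaking rule for rank lists.

    Cosine distance is ``1 - cosine similarity`` (range [0, 2]); correlation
    distance is ``1 - Pearson r``; Euclidean is the usual L2 norm. Ties are
    broken by original row index (deterministic, the default) or by a seeded
    random permutation for tie-heavy data.
    """

    metric: str = "cosine"
    tie_break: str = "index"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.metric not in _METRIC_ALIASES:
            raise ValueError(
                f"unknown metric {self.metric!r}; expected one of "
                f"{sorted(set(_METRIC_ALIASES))}"
            )
        if self.tie_break not in TIE_BREAKS:
            raise ValueError(f"unknown tie_break {self.tie_break!r}")

    @property
    def scipy_metric(self) -> str:
        return _METRIC_ALIASES[self.metric]


def _check_vectors(X: np.ndarray, metric: str, what: str) -> None:
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if np.any(norms == 0):
            raise ValueError(f"zero vector not allowed under cosine distance ({what})")
    elif metric == "correlation":
        if np.any(X.std(axis=1) == 0):
            raise ValueError(
                f"constant vector not allowed under correlation distance ({what})"
            )


def distance(x: Sequence[float], y: Sequence[float], spec: DistanceSpec | str = "cosine") -> float:
    """Dissimilarity between two profile vectors."""
    if isinstance(spec, str):
        spec = DistanceSpec(metric=spec)
    xa = np.atleast_2d(np.asarray(x, dtype=float))
    ya = np.atleast_2d(np.asarray(y, dtype=float))
    if xa.shape[1] != ya.shape[1]:
        raise ValueError(f"dimension mismatch: {xa.shape[1]} vs {ya.shape[1]}")
    m = spec.scipy_metric
    _check_vectors(np.vstack([xa, ya]), m, "pair")
    return float(cdist(xa, ya, metric=m)[0, 0])


def query_distances(
    X: np.ndarray, query_index: int, candidate_indices: np.ndarray, spec: DistanceSpec
) -> np.ndarray:
    """Distances from one query row of ``X`` to the candidate rows."""
    m = spec.scipy_metric
    q = X[query_index][None, :]
    C = X[candidate_indices]
    _check_vectors(q, m, "query")
    _check_vectors(C, m, "candidates")
    return cdist(q, C, metric=m)[0]


@dataclass
class BinaryRankList:
    """0/1 relevance sequence ordered by increasing distance to the query."""

    relevance: np.ndarray
    query_id: Any = None
    group_id: Any = None

    def __post_init__(self) -> None:
        self.relevance = np.asarray(self.relevance, dtype=int)
        if not np.isin(self.relevance, (0, 1)).all():
            raise ValueError("relevance must be binary")

    @property
    def n_pos(self) -> int:
        return int(self.relevance.sum())

    @property
    def n_total(self) -> int:
        return len(self.relevance)


def relevance_from_distances(
    distances: np.ndarray,
    is_positive: np.ndarray,
    tie_order: np.ndarray | None = None,
) -> np.ndarray:
    """Sort candidates by increasing distance; return the binary relevance.

    ``tie_order`` supplies the secondary sort key (original row index by
    default); any strictly monotone transform of the distances yields the
    same relevance sequence.
    """
    distances = np.asarray(distances, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if tie_order is None:
        tie_order = np.arange(len(distances))
    order = np.lexsort((tie_order, distances))
    return is_positive[order].astype(int)


def rank_list(
    instance: RetrievalInstance, table: ProfileTable, spec: DistanceSpec
) -> BinaryRankList:
    """Build the query's binary rank list over positives + references."""
    cand = np.concatenate([instance.positive_indices, instance.reference_indices])
    is_pos = np.zeros(len(cand), dtype=bool)
    is_pos[: len(instance.positive_indices)] = True
    try:
        d = query_distances(table.values, instance.query_index, cand, spec)
    except ValueError as exc:
        raise ValueError(
            f"distance error for query {instance.query_index} "
            f"in group {instance.group_id!r}: {exc}"
        ) from exc
    if spec.tie_break == "random":
        rng = np.random.default_rng(spec.seed)
        tie_order = rng.permutation(len(cand))
    else:
        tie_order = cand  # original table row index
    rel = relevance_from_distances(d, is_pos, tie_order)
    return BinaryRankList(rel, query_id=instance.query_index, group_id=instance.group_id)


@dataclass(frozen=True)
class APScore:
    """Average precision for one query."""

    value: float
    n_pos: int
    n_total: int
    query_id: Any = None


@dataclass
class MAPScore:
    """Group-level mean of per-query AP scores (members retained)."""

    value: float
    group_id: Any = None
    ap_scores: list[APScore] = field(default_factory=list)

    @property
    def n_queries(self) -> int:
        return len(self.ap_scores)


def average_precision_from_positions(
    positions: np.ndarray, n_pos: int | None = None
) -> float:
    """AP from 0-based sorted rank positions of the positives."""
    positions = np.asarray(positions)
    k = np.arange(1, len(positions) + 1)
    return float(np.mean(k / (positions + 1.0)))


def average_precision(rank: BinaryRankList | Sequence[int]) -> APScore:
    """Non-interpolated average precision of a binary rank list.

    Computed as the precision at each positive rank, averaged over the
    positives (the recall-increment weighting of precision@k).
    """
    if not isinstance(rank, BinaryRankList):
        rank = BinaryRankList(np.asarray(rank))
    rel = rank.relevance
    n_pos = int(rel.sum())
    if n_pos == 0:
        raise ValueError("rank list has zero positives")
    tp = np.cumsum(rel)
    k = np.arange(1, len(rel) + 1)
    precision = tp / k
    value = float(precision[rel.astype(bool)].mean())
    return APScore(value=value, n_pos=n_pos, n_total=len(rel), query_id=rank.query_id)


def mean_average_precision(
    scores: Sequence[APScore], group_id: Any = None
) -> MAPScore:
    """Arithmetic mean of a group's AP scores."""
    scores = list(scores)
    if not scores:
        raise ValueError("empty group")
    value = float(np.mean([s.value for s in scores]))
    return MAPScore(value=value, group_id=group_id, ap_scores=scores)
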