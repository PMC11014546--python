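"""Translate a declarative metadata block design into retrieval instances.

The block design states which metadata columns must match (``pos_same``) or
differ (``pos_diff``) between a query and another profile for that profile to
count as a correct match, and analogous constraints (``ref_same`` /
``ref_diff``) restricting which reference profiles enter the query's rank
list. This is how well-position and plate effects are probed: e.g. retrieving
replicates "from the same well position but a different plate" is
``pos_same=[pert, well], pos_diff=[plate]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import ProfileTable

logger = logging.getLogger(__name__)


class GroupingError(ValueError):
    """Raised when a grouping spec is inconsistent with the table."""


class Filter:
    """Conjunction of ``column == value`` / ``column in set`` clauses.

    ``~filter`` yields the complement (used e.g. to select non-control rows
    from a control predicate).
    """

    def __init__(self, clauses: Mapping[str, Any] | None = None, **kw: Any):
        merged: dict[str, Any] = dict(clauses or {})
        merged.update(kw)
        self.clauses = {
            col: (set(v) if isinstance(v, (list, tuple, set, frozenset)) else {v})
            for col, v in merged.items()
        }

    def columns(self) -> list[str]:
        return list(self.clauses)

    def mask(self, metadata: pd.DataFrame) -> np.ndarray:
        m = np.ones(len(metadata), dtype=bool)
        for col, values in self.clauses.items():
            if col not in metadata.columns:
                raise GroupingError(f"filter references missing metadata column: {col!r}")
            m &= metadata[col].isin(values).to_numpy()
        return m

    def __invert__(self) -> "_NegatedFilter":
        return _NegatedFilter(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Filter({self.clauses!r})"


class _NegatedFilter:
    def __init__(self, inner: Filter):
        self.inner = inner

    def columns(self) -> list[str]:
        return self.inner.columns()

    def mask(self, metadata: pd.DataFrame) -> np.ndarray:
        return ~self.inner.mask(metadata)

    def __invert__(self) -> Filter:
        return self.inner


FilterLike = "Filter | _NegatedFilter | np.ndarray | None"


def _resolve_mask(flt, metadata: pd.DataFrame) -> np.ndarray:
    if flt is None:
        return np.ones(len(metadata), dtype=bool)
    if isinstance(flt, np.ndarray):
        if flt.dtype != bool or len(flt) != len(metadata):
            raise GroupingError("mask filter must be a boolean array of table length")
        return flt
    return flt.mask(metadata)


@dataclass
class GroupingSpec:
    """Declarative block design over metadata.

    ``group_by`` partitions the query-filtered profiles into query groups;
    within a group, each member serves as query once. ``pos_same``/``pos_diff``
    constrain which other group members are correct matches for a given query;
    ``ref_same``/``ref_diff`` constrain which reference-filtered profiles enter
    the query's rank list.
    """

    group_by: Sequence[str]
    query_filter: Any = None
    reference_filter: Any = None
    pos_same: Sequence[str] = field(default_factory=list)
    pos_diff: Sequence[str] = field(default_factory=list)
    ref_same: Sequence[str] = field(default_factory=list)
    ref_diff: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.group_by = list(self.group_by)
        self.pos_same = list(self.pos_same)
        self.pos_diff = list(self.pos_diff)
        self.ref_same = list(self.ref_same)
        self.ref_diff = list(self.ref_diff)
        if not self.group_by:
            raise GroupingError("group_by must be nonempty")
        if set(self.pos_same) & set(self.pos_diff):
            raise GroupingError("pos_same and pos_diff overlap")
        if set(self.ref_same) & set(self.ref_diff):
            raise GroupingError("ref_same and ref_diff overlap")

    def named_columns(self) -> list[str]:
        cols = list(self.group_by) + self.pos_same + self.pos_diff
        cols += self.ref_same + self.ref_diff
        for flt in (self.query_filter, self.reference_filter):
            if flt is not None and hasattr(flt, "columns"):
                cols += flt.columns()
        return cols

    def validate(self, table: ProfileTable) -> None:
        missing = set(self.named_columns()) - set(table.metadata_columns)
        if missing:
            raise GroupingError(
                f"grouping spec references missing metadata columns: {sorted(missing)}"
            )


@dataclass
class RetrievalInstance:
    """One query profile with its correct matches and admitted references."""

    group_id: Any
    query_index: int
    positive_indices: np.ndarray  # count M-1
    reference_indices: np.ndarray  # count N

    @property
    def n_pos(self) -> int:
        return len(self.positive_indices)

    @property
    def n_total(self) -> int:
        return len(self.positive_indices) + len(self.reference_indices)


@dataclass
class SkippedGroup:
    """Machine-readable record of a group or query excluded from retrieval."""

    group_id: Any
    reason: str  # one of: group_too_small, no_positives, no_references
    query_index: int | None = None


def _pairwise_ok(
    meta: pd.DataFrame,
    query: int,
    candidates: np.ndarray,
    same: Sequence[str],
    diff: Sequence[str],
) -> np.ndarray:
    ok = np.ones(len(candidates), dtype=bool)
    for col in same:
        ok &= (meta[col].to_numpy()[candidates] == meta[col].iat[query]) | (
            pd.isna(meta[col].to_numpy()[candidates]) & pd.isna(meta[col].iat[query])
        )
    for col in diff:
        ok &= meta[col].to_numpy()[candidates] != meta[col].iat[query]
    return ok


def build_instances(
    table: ProfileTable,
    spec: GroupingSpec,
    return_skipped: bool = False,
) -> list[RetrievalInstance] | tuple[list[RetrievalInstance], list[SkippedGroup]]:
    """Enumerate one :class:`RetrievalInstance` per (group, query member).

    Groups with fewer than two members, and queries left with no positives or
    no references after the same/diff constraints, are skipped with a logged
    :class:`SkippedGroup` record rather than aborting the run.
    """
    spec.validate(table)
    meta = table.metadata
    qmask = _resolve_mask(spec.query_filter, meta)
    rmask = _resolve_mask(spec.reference_filter, meta)
    qidx = np.flatnonzero(qmask)
    ridx = np.flatnonzero(rmask)

    instances: list[RetrievalInstance] = []
    skipped: list[SkippedGroup] = []
    if len(qidx) == 0:
        raise GroupingError("query filter selects no profiles")
    if len(ridx) == 0:
        raise GroupingError("reference filter selects no profiles")

    keys = meta.iloc[qidx][spec.group_by]
    # deterministic iteration in table row order
    grouped: dict[Any, list[int]] = {}
    for row, key in zip(qidx, keys.itertuples(index=False, name=None)):
        gid = key[0] if len(spec.group_by) == 1 else key
        grouped.setdefault(gid, []).append(row)

    for gid, members in grouped.items():
        members_arr = np.asarray(members)
        if len(members_arr) < 2:
            skipped.append(SkippedGroup(gid, "group_too_small"))
            logger.info("skipping group %r: fewer than 2 members", gid)
            continue
        for q in members_arr:
            others = members_arr[members_arr != q]
            pos = others[_pairwise_ok(meta, q, others, spec.pos_same, spec.pos_diff)]
            refs = ridx[_pairwise_ok(meta, q, ridx, spec.ref_same, spec.ref_diff)]
            # keep the rank list disjoint: drop the query itself and any
            # profile already counted as a positive from the reference side
            refs = refs[(refs != q) & ~np.isin(refs, pos)]
            if len(pos) < 1:
                skipped.append(SkippedGroup(gid, "no_positives", query_index=int(q)))
                logger.info("skipping query %d in group %r: no positives", q, gid)
                continue
            if len(refs) < 1:
                skipped.append(SkippedGroup(gid, "no_references", query_index=int(q)))
                logger.info("skipping query %d in group %r: no references", q, gid)
                continue
            instances.append(RetrievalInstance(gid, int(q), pos, refs))

    if return_skipped:
        return instances, skipped
    return instances
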