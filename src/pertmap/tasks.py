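"""End-to-end retrieval assessments built on the ranking/significance core.

Three assessments share one engine:

* **phenotypic activity** — retrieve a perturbation's replicates against
  control profiles (replicate retrievability);
* **phenotypic consistency** — retrieve consensus profiles sharing a
  biological annotation against differently annotated perturbations;
* **phenotypic distinctiveness** — retrieve a perturbation's replicates
  against the replicates of all other perturbations.

Each is exposed as a scikit-learn style estimator (``fit`` on a profile
table, results in trailing-underscore attributes) plus a thin function
wrapper. The multi-label extension computes a sparse perturbation-by-label
AP matrix for perturbations carrying several annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .grouping import (
    Filter,
    GroupingError,
    GroupingSpec,
    RetrievalInstance,
    SkippedGroup,
    _resolve_mask,
    build_instances,
)
from .profiles import ProfileTable
from .ranking import (
    APScore,
    DistanceSpec,
    MAPScore,
    average_precision,
    mean_average_precision,
    rank_list,
)
from .significance import (
    DEFAULT_MAX_EXACT,
    DEFAULT_N_PERM,
    SignificanceResult,
    correct_results,
    map_p_value,
    percent_retrieved,
)

logger = logging.getLogger(__name__)


def _as_distance_spec(distance) -> DistanceSpec:
    return distance if isinstance(distance, DistanceSpec) else DistanceSpec(metric=distance)


def score_instances(
    table: ProfileTable,
    instances: Sequence[RetrievalInstance],
    distance: DistanceSpec,
) -> dict[Any, MAPScore]:
    """AP per instance, aggregated to one MAPScore per group (in input order)."""
    by_group: dict[Any, list[APScore]] = {}
    for inst in instances:
        ap = average_precision(rank_list(inst, table, distance))
        by_group.setdefault(inst.group_id, []).append(ap)
    return {
        gid: mean_average_precision(aps, group_id=gid) for gid, aps in by_group.items()
    }


def significance_of_groups(
    map_scores: Mapping[Any, MAPScore],
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = 0.05,
    seed: int | None = None,
    max_exact: int = DEFAULT_MAX_EXACT,
) -> list[SignificanceResult]:
    """Permutation p-value per group, BH-corrected across groups."""
    results = [
        SignificanceResult(
            group_id=gid,
            map_score=ms,
            p_value=map_p_value(ms, n_perm=n_perm, seed=seed, max_exact=max_exact),
        )
        for gid, ms in map_scores.items()
    ]
    return correct_results(results, alpha=alpha)


def results_to_frame(results: Sequence[SignificanceResult]) -> pd.DataFrame:
    """One row per group: mAP, raw/corrected p-values, retrieval flag."""
    return pd.DataFrame(
        {
            "group_id": [r.group_id for r in results],
            "mAP": [r.map for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.corrected_p for r in results],
            "retrieved": [r.retrieved for r in results],
            "n_pos": [r.n_pos for r in results],
            "n_total": [r.n_total for r in results],
            "n_queries": [r.n_queries for r in results],
        }
    )


def ap_to_frame(map_scores: Mapping[Any, MAPScore]) -> pd.DataFrame:
    """One row per (group, query): the per-query AP table."""
    rows = []
    for gid, ms in map_scores.items():
        for s in ms.ap_scores:
            rows.append(
                {
                    "group_id": gid,
                    "query_id": s.query_id,
                    "AP": s.value,
                    "n_pos": s.n_pos,
                    "n_total": s.n_total,
                }
            )
    return pd.DataFrame(rows)


class _RetrievalAssessment(BaseEstimator):
    """Shared fit machinery for the three assessments."""

    # subclasses define _grouping_spec(table) -> GroupingSpec

    def __init__(
        self,
        distance: str | DistanceSpec = "cosine",
        n_perm: int = DEFAULT_N_PERM,
        alpha: float = 0.05,
        max_exact: int = DEFAULT_MAX_EXACT,
        random_state: int | None = 0,
    ):
        self.distance = distance
        self.n_perm = n_perm
        self.alpha = alpha
        self.max_exact = max_exact
        self.random_state = random_state

    def fit(self, table: ProfileTable, y=None):
        table.validate(min_profiles=2)
        spec = self._grouping_spec(table)
        instances, skipped = build_instances(table, spec, return_skipped=True)
        if not instances:
            raise GroupingError("no retrieval instances after filtering")
        dspec = _as_distance_spec(self.distance)
        self.map_scores_ = score_instances(table, instances, dspec)
        self.results_ = significance_of_groups(
            self.map_scores_,
            n_perm=self.n_perm,
            alpha=self.alpha,
            seed=self.random_state,
            max_exact=self.max_exact,
        )
        self.skipped_ = skipped
        self.ap_frame_ = ap_to_frame(self.map_scores_)
        self.results_frame_ = results_to_frame(self.results_)
        self.percent_retrieved_ = percent_retrieved(self.results_, alpha=self.alpha)
        return self


class PhenotypicActivity(_RetrievalAssessment):
    """Replicate retrievability of each perturbation against controls.

    Queries are the non-control profiles grouped by ``pert_column``; each
    query's positives are its sibling replicates and the references are the
    control profiles selected by ``control_filter``. Perturbations with fewer
    than two replicates are skipped and reported.
    """

    def __init__(
        self,
        pert_column: str = "Metadata_pert",
        control_filter: Filter | None = None,
        pos_same: Sequence[str] = (),
        pos_diff: Sequence[str] = (),
        ref_same: Sequence[str] = (),
        ref_diff: Sequence[str] = (),
        distance: str | DistanceSpec = "cosine",
        n_perm: int = DEFAULT_N_PERM,
        alpha: float = 0.05,
        max_exact: int = DEFAULT_MAX_EXACT,
        random_state: int | None = 0,
    ):
        super().__init__(distance, n_perm, alpha, max_exact, random_state)
        self.pert_column = pert_column
        self.control_filter = control_filter
        self.pos_same = pos_same
        self.pos_diff = pos_diff
        self.ref_same = ref_same
        self.ref_diff = ref_diff

    def _grouping_spec(self, table: ProfileTable) -> GroupingSpec:
        if self.control_filter is None:
            raise GroupingError("control_filter is required for phenotypic activity")
        cmask = _resolve_mask(self.control_filter, table.metadata)
        if not cmask.any():
            raise GroupingError("no controls match the control filter")
        return GroupingSpec(
            group_by=[self.pert_column],
            query_filter=~cmask if isinstance(cmask, np.ndarray) else None,
            reference_filter=cmask,
            pos_same=[self.pert_column, *self.pos_same],
            pos_diff=list(self.pos_diff),
            ref_same=list(self.ref_same),
            ref_diff=list(self.ref_diff),
        )


class PhenotypicConsistency(_RetrievalAssessment):
    """Retrieval of same-annotation consensus profiles against the rest.

    Expects one consensus profile per perturbation. Groups are the distinct
    values of ``label_column``; references for a query are all profiles whose
    label differs. Labels with a single member are skipped and reported.
    """

    def __init__(
        self,
        label_column: str = "Metadata_label",
        distance: str | DistanceSpec = "cosine",
        n_perm: int = DEFAULT_N_PERM,
        alpha: float = 0.05,
        max_exact: int = DEFAULT_MAX_EXACT,
        random_state: int | None = 0,
    ):
        super().__init__(distance, n_perm, alpha, max_exact, random_state)
        self.label_column = label_column

    def _grouping_spec(self, table: ProfileTable) -> GroupingSpec:
        return GroupingSpec(
            group_by=[self.label_column],
            pos_same=[self.label_column],
            ref_diff=[self.label_column],
        )


class PhenotypicDistinctiveness(_RetrievalAssessment):
    """Retrieval of each perturbation's replicates against all other
    perturbations' replicates (controls excluded unless requested)."""

    def __init__(
        self,
        pert_column: str = "Metadata_pert",
        control_filter: Filter | None = None,
        include_controls: bool = False,
        distance: str | DistanceSpec = "cosine",
        n_perm: int = DEFAULT_N_PERM,
        alpha: float = 0.05,
        max_exact: int = DEFAULT_MAX_EXACT,
        random_state: int | None = 0,
    ):
        super().__init__(distance, n_perm, alpha, max_exact, random_state)
        self.pert_column = pert_column
        self.control_filter = control_filter
        self.include_controls = include_controls

    def _grouping_spec(self, table: ProfileTable) -> GroupingSpec:
        n = table.n_profiles
        if self.control_filter is not None:
            cmask = _resolve_mask(self.control_filter, table.metadata)
        else:
            cmask = np.zeros(n, dtype=bool)
        qmask = ~cmask
        rmask = np.ones(n, dtype=bool) if self.include_controls else ~cmask
        if table.metadata.loc[qmask, self.pert_column].nunique() < 2:
            raise GroupingError("fewer than 2 perturbations")
        return GroupingSpec(
            group_by=[self.pert_column],
            query_filter=qmask,
            reference_filter=rmask,
            pos_same=[self.pert_column],
            ref_diff=[self.pert_column],
        )


# -- thin function wrappers -------------------------------------------------


def phenotypic_activity(
    table: ProfileTable,
    pert_column: str,
    control_filter: Filter,
    distance: str | DistanceSpec = "cosine",
    **kw,
) -> list[SignificanceResult]:
    est = PhenotypicActivity(
        pert_column=pert_column, control_filter=control_filter, distance=distance, **kw
    ).fit(table)
    return est.results_


def phenotypic_consistency(
    consensus: ProfileTable,
    label_column: str,
    distance: str | DistanceSpec = "cosine",
    **kw,
) -> list[SignificanceResult]:
    est = PhenotypicConsistency(
        label_column=label_column, distance=distance, **kw
    ).fit(consensus)
    return est.results_


def phenotypic_distinctiveness(
    table: ProfileTable,
    pert_column: str,
    control_filter: Filter | None = None,
    distance: str | DistanceSpec = "cosine",
    **kw,
) -> list[SignificanceResult]:
    est = PhenotypicDistinctiveness(
        pert_column=pert_column, control_filter=control_filter, distance=distance, **kw
    ).fit(table)
    return est.results_


# ---------------------------------------------------------------------------
# Multi-label extension
# ---------------------------------------------------------------------------


@dataclass
class MultiLabelAPMatrix:
    """Sparse perturbation-by-label AP matrix.

    An entry exists only where the perturbation carries the label; absent
    entries are *missing*, not zeros, and are excluded from aggregation means.
    """

    entries: dict[tuple[Any, Any], float] = field(default_factory=dict)
    perturbations: list[Any] = field(default_factory=list)
    labels: list[Any] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame with NaN where (perturbation, label) is absent."""
        df = pd.DataFrame(np.nan, index=self.perturbations, columns=self.labels)
        for (p, t), v in self.entries.items():
            df.loc[p, t] = v
        return df

    def aggregate(self, axis: str = "per_label") -> pd.Series:
        """Mean AP over present entries only, per label or per perturbation."""
        if not self.entries:
            raise ValueError("empty AP matrix")
        df = self.to_frame()
        if axis == "per_label":
            return df.mean(axis=0, skipna=True).dropna()
        if axis == "per_perturbation":
            return df.mean(axis=1, skipna=True).dropna()
        raise ValueError(f"unknown axis {axis!r}; use per_label or per_perturbation")


def _annotations_to_map(annotations) -> dict[Any, set]:
    """Accept a pert -> labels mapping or a long-format two-column frame."""
    if isinstance(annotations, pd.DataFrame):
        if annotations.shape[1] < 2:
            raise ValueError("annotation frame needs (perturbation, label) columns")
        pcol, tcol = annotations.columns[:2]
        out: dict[Any, set] = {}
        for p, t in zip(annotations[pcol], annotations[tcol]):
            out.setdefault(p, set()).add(t)
        return out
    return {p: set(ts) for p, ts in annotations.items()}


class MultiLabelRetrieval(BaseEstimator):
    """AP per (perturbation, label) pair, one annotation label at a time.

    For each label t, each annotated consensus profile serves as query;
    positives are the other members of t and references are all remaining
    perturbations (including those sharing a *different* label with the
    query). Labels with fewer than two members are omitted and logged.
    """

    def __init__(
        self,
        pert_column: str = "Metadata_pert",
        distance: str | DistanceSpec = "cosine",
    ):
        self.pert_column = pert_column
        self.distance = distance

    def fit(self, consensus: ProfileTable, annotations) -> "MultiLabelRetrieval":
        ann = _annotations_to_map(annotations)
        perts = consensus.metadata[self.pert_column]
        if perts.duplicated().any():
            raise ValueError("consensus table must have one profile per perturbation")
        row_of = {p: i for i, p in enumerate(perts)}
        missing = [p for p in ann if p not in row_of]
        if missing:
            raise ValueError(f"annotated perturbations without profiles: {missing}")
        labels = sorted({t for ts in ann.values() for t in ts}, key=str)
        dspec = _as_distance_spec(self.distance)
        matrix = MultiLabelAPMatrix(perturbations=list(perts), labels=labels)
        skipped: list[SkippedGroup] = []
        all_rows = np.arange(consensus.n_profiles)
        for t in labels:
            members = [p for p, ts in ann.items() if t in ts]
            if len(members) < 2:
                skipped.append(SkippedGroup(t, "group_too_small"))
                logger.info("multilabel: label %r has a single member; omitted", t)
                continue
            member_rows = np.array([row_of[p] for p in members])
            for p in members:
                q = row_of[p]
                pos = member_rows[member_rows != q]
                refs = all_rows[~np.isin(all_rows, member_rows)]
                if len(refs) == 0:
                    skipped.append(SkippedGroup(t, "no_references", query_index=q))
                    continue
                inst = RetrievalInstance(t, int(q), pos, refs)
                ap = average_precision(rank_list(inst, consensus, dspec))
                matrix.entries[(p, t)] = ap.value
        self.matrix_ = matrix
        self.skipped_ = skipped
        self.per_label_map_ = matrix.aggregate("per_label")
        self.per_perturbation_map_ = matrix.aggregate("per_perturbation")
        return self


def multilabel_map(
    consensus: ProfileTable,
    annotations,
    distance: str | DistanceSpec = "cosine",
    pert_column: str = "Metadata_pert",
) -> MultiLabelAPMatrix:
    est = MultiLabelRetrieval(pert_column=pert_column, distance=distance).fit(
        consensus, annotations
    )
    return est.matrix_


def aggregate_multilabel(matrix: MultiLabelAPMatrix, axis: str = "per_label") -> pd.Series:
    return matrix.aggregate(axis)
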