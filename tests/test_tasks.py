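import numpy as np
import pandas as pd
import pytest

from pertmap import (
    Filter,
    GroupingError,
    MultiLabelRetrieval,
    PhenotypicActivity,
    PhenotypicConsistency,
    PhenotypicDistinctiveness,
    aggregate_multilabel,
    from_dataframe,
    multilabel_map,
    multilabel_toy,
    phenotypic_consistency,
    toy_screen,
)
from pertmap.tasks import MultiLabelAPMatrix


def _table(meta: dict, X: np.ndarray):
    df = pd.concat(
        [pd.DataFrame(meta), pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])],
        axis=1,
    )
    return from_dataframe(df)


class TestPhenotypicActivity:
    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        reps = np.tile([10.0, 0.0, 0.0], (2, 1))
        ctrls = np.abs(rng.normal(size=(12, 3)))
        ctrls[:, 0] = 0.0  # orthogonal to the replicate signature
        X = np.vstack([reps, ctrls])
        t = _table(
            {
                "Metadata_pert": ["a"] * 2 + ["ctrl"] * 12,
                "Metadata_control": [False] * 2 + [True] * 12,
            },
            X,
        )
        est = PhenotypicActivity(
            control_filter=Filter(Metadata_control=True), random_state=0
        ).fit(t)
        assert est.results_[0].map == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_toy_screen_separates_active_from_null(self, seed):
        """All truly active perturbations (2 SD shift in every feature) are
        retrieved with mAP ~ 1; inactive ones score near the chance level and
        at most a stray one clears the threshold (the group-level permutation
        null runs mildly anti-conservative, see docs)."""
        t = toy_screen(seed=seed)
        est = PhenotypicActivity(
            control_filter=Filter(Metadata_control=True), random_state=0
        ).fit(t)
        truth = dict(
            t.data.drop_duplicates("Metadata_pert")[
                ["Metadata_pert", "Metadata_active"]
            ].values
        )
        active = [r for r in est.results_ if truth[r.group_id]]
        inactive = [r for r in est.results_ if not truth[r.group_id]]
        assert all(r.retrieved for r in active)
        assert all(r.map == pytest.approx(1.0) for r in active)
        assert sum(r.retrieved for r in inactive) <= 2  # a stray minority
        # inactive groups average near the chance level, far from saturation
        assert np.mean([r.map for r in inactive]) < 0.5

    def test_small_replicate_groups_skipped(self):
        rng = np.random.default_rng(1)
        t = _table(
            {
                "Metadata_pert": ["a", "a", "b"] + ["ctrl"] * 4,
                "Metadata_control": [False] * 3 + [True] * 4,
            },
            rng.normal(size=(7, 5)),
        )
        est = PhenotypicActivity(
            control_filter=Filter(Metadata_control=True), random_state=0
        ).fit(t)
        assert [r.group_id for r in est.results_] == ["a"]
        assert any(s.group_id == "b" for s in est.skipped_)

    def test_no_matching_controls_errors(self):
        rng = np.random.default_rng(1)
        t = _table(
            {"Metadata_pert": list("aabb"), "Metadata_control": [False] * 4},
            rng.normal(size=(4, 3)),
        )
        with pytest.raises(GroupingError, match="controls"):
            PhenotypicActivity(control_filter=Filter(Metadata_control=True)).fit(t)

    def test_sklearn_params_roundtrip(self):
        est = PhenotypicActivity(n_perm=123, alpha=0.1)
        est2 = est.set_params(**est.get_params())
        assert est2.get_params()["n_perm"] == 123


class TestPhenotypicConsistency:
    def test_orthogonal_label_blocks(self):
        X = np.array(
            [[5.0, 0.1, 0.0], [4.0, 0.0, 0.1], [0.1, 6.0, 0.0], [0.0, 5.0, 0.1]]
        )
        t = _table({"Metadata_label": ["A", "A", "B", "B"]}, X)
        results = phenotypic_consistency(t, "Metadata_label", random_state=0)
        assert {r.group_id: r.map for r in results} == pytest.approx(
            {"A": 1.0, "B": 1.0}
        )

    def test_guide_vs_other_genes_shape(self):
        # 60 genes x 2 consensus guides: each query retrieves its 1 sibling
        # against the 118 guides of other genes
        rng = np.random.default_rng(2)
        genes = np.repeat([f"gene{i}" for i in range(60)], 2)
        t = _table({"Metadata_label": genes}, rng.normal(size=(120, 10)))
        est = PhenotypicConsistency(
            label_column="Metadata_label", n_perm=200, random_state=0
        ).fit(t)
        assert all(r.n_pos == 1 and r.n_total == 119 for r in est.results_)
        assert len(est.results_) == 60

    def test_single_member_label_skipped(self):
        rng = np.random.default_rng(3)
        t = _table({"Metadata_label": ["A", "A", "B", "C", "C"]}, rng.normal(size=(5, 4)))
        est = PhenotypicConsistency(label_column="Metadata_label", random_state=0).fit(t)
        assert "B" not in {r.group_id for r in est.results_}
        assert any(s.group_id == "B" for s in est.skipped_)

    def test_invariant_to_renaming_other_labels(self):
        """References are defined by label inequality, so splitting the
        non-member labels into differently named groups changes nothing."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 6))
        t1 = _table({"Metadata_label": ["A"] * 3 + ["B"] * 5}, X)
        t2 = _table({"Metadata_label": ["A"] * 3 + ["B", "B", "C", "C", "D"]}, X)
        r1 = {r.group_id: r.map for r in phenotypic_consistency(t1, "Metadata_label", random_state=0)}
        r2 = {r.group_id: r.map for r in phenotypic_consistency(t2, "Metadata_label", random_state=0)}
        assert r2["A"] == pytest.approx(r1["A"])


class TestPhenotypicDistinctiveness:
    def test_orthogonal_perturbations_perfect(self):
        X = np.array([[5.0, 0.0], [4.0, 0.0], [0.0, 5.0], [0.0, 4.0]])
        t = _table({"Metadata_pert": ["a", "a", "b", "b"]}, X)
        est = PhenotypicDistinctiveness(random_state=0).fit(t)
        assert all(r.map == pytest.approx(1.0) for r in est.results_)

    def test_identically_distributed_perturbations_interleave(self):
        """Two perturbations drawn from one tight cluster cannot each fully
        retrieve themselves; an orthogonal third can."""
        rng = np.random.default_rng(5)
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        A = u + rng.normal(scale=0.01, size=(4, 3))
        B = u + rng.normal(scale=0.01, size=(4, 3))
        C = 5 * v + rng.normal(scale=0.01, size=(4, 3))
        t = _table(
            {"Metadata_pert": ["a"] * 4 + ["b"] * 4 + ["c"] * 4},
            np.vstack([A, B, C]),
        )
        est = PhenotypicDistinctiveness(random_state=0).fit(t)
        maps = {r.group_id: r.map for r in est.results_}
        assert maps["a"] < 1.0 and maps["b"] < 1.0
        assert maps["c"] == pytest.approx(1.0)

    def test_controls_excluded_by_default(self):
        rng = np.random.default_rng(6)
        t = _table(
            {
                "Metadata_pert": ["a"] * 2 + ["b"] * 2 + ["ctrl"] * 3,
                "Metadata_control": [False] * 4 + [True] * 3,
            },
            rng.normal(size=(7, 4)),
        )
        est = PhenotypicDistinctiveness(
            control_filter=Filter(Metadata_control=True), random_state=0
        ).fit(t)
        for gid, ms in est.map_scores_.items():
            assert all(s.n_total == 3 for s in ms.ap_scores)  # 1 pos + 2 refs
        est_inc = PhenotypicDistinctiveness(
            control_filter=Filter(Metadata_control=True),
            include_controls=True,
            random_state=0,
        ).fit(t)
        for gid, ms in est_inc.map_scores_.items():
            assert all(s.n_total == 6 for s in ms.ap_scores)

    def test_fewer_than_two_perturbations_errors(self):
        rng = np.random.default_rng(7)
        t = _table({"Metadata_pert": ["a"] * 3}, rng.normal(size=(3, 4)))
        with pytest.raises(GroupingError, match="fewer than 2"):
            PhenotypicDistinctiveness(random_state=0).fit(t)


class TestMultiLabel:
    def test_sparsity_matches_annotations(self):
        table, ann = multilabel_toy(seed=0)
        mat = multilabel_map(table, ann)
        # pert_7 carries two labels -> exactly two entries
        assert sum(1 for (p, _) in mat.entries if p == "pert_7") == 2
        incidence = set(map(tuple, ann.values))
        assert set(mat.entries) == incidence

    def test_orthogonal_signatures_all_perfect_except_shared(self):
        table, ann = multilabel_toy(seed=0)
        mat = multilabel_map(table, ann)
        # single-label members of disjoint blocks retrieve each other first
        assert mat.entries[("pert_3", "B")] == pytest.approx(1.0)
        assert mat.entries[("pert_4", "B")] == pytest.approx(1.0)

    def test_column_means_match_consistency_for_single_labels(self):
        rng = np.random.default_rng(8)
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 2
        perts = [f"p{i}" for i in range(8)]
        X = rng.normal(size=(8, 12))
        t = _table({"Metadata_pert": perts, "Metadata_label": labels}, X)
        ann = pd.DataFrame({"perturbation_id": perts, "label": labels})
        mat = multilabel_map(t, ann)
        per_label = aggregate_multilabel(mat, "per_label")
        cons = {
            r.group_id: r.map
            for r in phenotypic_consistency(t, "Metadata_label", random_state=0)
        }
        for lbl, v in per_label.items():
            assert v == pytest.approx(cons[lbl])

    def test_aggregation_treats_absent_as_missing(self):
        mat = MultiLabelAPMatrix(
            entries={("p1", "A"): 1.0, ("p2", "A"): 0.5, ("p1", "B"): 0.8},
            perturbations=["p1", "p2"],
            labels=["A", "B"],
        )
        per_label = aggregate_multilabel(mat, "per_label")
        assert per_label["A"] == pytest.approx(0.75)
        assert per_label["B"] == pytest.approx(0.8)  # not dragged down by absence
        per_pert = aggregate_multilabel(mat, "per_perturbation")
        assert per_pert["p2"] == pytest.approx(0.5)

    def test_single_member_label_omitted(self):
        table, ann = multilabel_toy(seed=0)
        ann = pd.concat(
            [ann, pd.DataFrame({"perturbation_id": ["pert_8"], "label": ["D"]})]
        )
        est = MultiLabelRetrieval().fit(table, ann)
        assert all(t != "D" for (_, t) in est.matrix_.entries)
        assert any(s.group_id == "D" for s in est.skipped_)

    def test_empty_matrix_aggregation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MultiLabelAPMatrix().aggregate("per_label")


def test_activity_then_consistency_filter_composition():
    """Filtering to phenotypically active perturbations before consistency
    never introduces label groups absent from the input."""
    t = toy_screen(seed=3)
    est = PhenotypicActivity(
        control_filter=Filter(Metadata_control=True), random_state=0
    ).fit(t)
    active = {r.group_id for r in est.results_ if r.retrieved}
    sub = t.data[t.data["Metadata_pert"].isin(active)]
    assert set(sub["Metadata_pert"]) <= set(t.data["Metadata_pert"])
    assert active  # the toy screen has true actives
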