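"""Node splitting, eligibility criteria, lesion-overlap rule and the
node-level symptom tests."""

import numpy as np
import pandas as pd
import pytest

from tddkit.lesion_mapping import (LabelVolume, LesionMask, NodeCriteria,
                                   annotation_mentions_target, build_matrix,
                                   eligible_nodes, lesion_in_node,
                                   node_symptom_test, side_composite_scores,
                                   split_into_contiguous_nodes,
                                   target_area_association)
from tddkit.synthetic import (NodeShape, PhantomSpec,
                              make_phantom_parcellation,
                              simulate_patient_cohort)

EYE = np.eye(4)


def volume(data):
    return LabelVolume(np.asarray(data, np.int32), EYE)


class TestSplitIntoNodes:
    def test_single_cuboid_is_one_node(self):
        data = np.zeros((10, 10, 10), np.int32)
        data[2:6, 2:6, 2:6] = 3
        nodes, table = split_into_contiguous_nodes(volume(data))
        assert len(table) == 1
        assert table.iloc[0]["n_voxels"] == 64
        assert table.iloc[0]["parent_label"] == 3

    def test_two_disjoint_cubes_sharing_a_label(self):
        data = np.zeros((12, 12, 12), np.int32)
        data[0:3, 0:3, 0:3] = 1
        data[8:12, 8:12, 8:12] = 1
        nodes, table = split_into_contiguous_nodes(volume(data))
        assert len(table) == 2
        # size-descending ordering within the parent label
        assert table["n_voxels"].tolist() == [64, 27]

    def test_phantom_component_structure(self, small_phantom):
        parc = make_phantom_parcellation(small_phantom)
        nodes, table = split_into_contiguous_nodes(parc)
        assert table["n_voxels"].tolist() == [512, 125, 125, 64]
        assert table["parent_label"].tolist() == [1, 1, 2, 2]
        assert table["node_id"].tolist() == [1, 2, 3, 4]

    def test_voxel_counts_sum_to_nonzero_voxels(self, small_phantom):
        parc = make_phantom_parcellation(small_phantom)
        _, table = split_into_contiguous_nodes(parc)
        assert table["n_voxels"].sum() == int((parc.data > 0).sum())

    def test_face_connectivity_separates_corner_touching_cubes(self):
        data = np.zeros((8, 8, 8), np.int32)
        data[0:2, 0:2, 0:2] = 1
        data[2:4, 2:4, 2:4] = 1  # touches only at a corner
        _, t6 = split_into_contiguous_nodes(volume(data), connectivity=6)
        _, t26 = split_into_contiguous_nodes(volume(data), connectivity=26)
        assert len(t6) == 2
        assert len(t26) == 1

    def test_different_labels_never_merge(self):
        data = np.zeros((6, 6, 6), np.int32)
        data[0:3] = 1
        data[3:6] = 2  # face-adjacent but different parents
        _, table = split_into_contiguous_nodes(volume(data))
        assert len(table) == 2

    def test_empty_parcellation(self):
        _, table = split_into_contiguous_nodes(volume(np.zeros((4, 4, 4))))
        assert table.empty


class TestEligibility:
    def test_boundary_is_strict(self):
        table = pd.DataFrame({"node_id": [1, 2], "parent_label": [1, 1],
                              "n_voxels": [100, 101]})
        kept = eligible_nodes(table, NodeCriteria())
        assert kept["node_id"].tolist() == [2]


class TestLesionInNode:
    @staticmethod
    def _node_and_lesion(node_voxels, overlap_voxels):
        side = 32
        data = np.zeros((side, side, side), np.int32)
        flat = data.reshape(-1)
        flat[:node_voxels] = 1
        nodes = LabelVolume(data, EYE)
        lesion = np.zeros(side**3, np.uint8)
        lesion[:overlap_voxels] = 1
        return nodes, LesionMask(lesion.reshape(data.shape), EYE)

    @pytest.mark.parametrize("node_size, overlap, expected", [
        (2000, 99, False),   # required = min(100, ceil(200)) = 100
        (2000, 100, True),
        (500, 50, True),     # required = min(100, ceil(50)) = 50
        (500, 49, False),
        (500, 0, False),
    ])
    def test_overlap_rule(self, node_size, overlap, expected):
        nodes, lesion = self._node_and_lesion(node_size, overlap)
        assert lesion_in_node(lesion, nodes, 1) is expected

    def test_geometry_mismatch_rejected(self):
        nodes, lesion = self._node_and_lesion(500, 50)
        shifted = LesionMask(lesion.data.astype(np.uint8), np.diag([2., 1, 1, 1]))
        with pytest.raises(ValueError, match="geometr"):
            lesion_in_node(shifted, nodes, 1)

    def test_monotone_in_lesion_size(self):
        nodes, _ = self._node_and_lesion(500, 0)
        previous = False
        for overlap in range(0, 120, 10):
            _, lesion = self._node_and_lesion(500, overlap)
            hit = lesion_in_node(lesion, nodes, 1)
            assert hit or not previous  # adding voxels never flips True->False
            previous = hit or previous


class TestBuildMatrix:
    def test_three_patients_not_analyzable(self, small_phantom):
        sim = simulate_patient_cohort(n_deficit_lesioned=3,
                                      phantom=small_phantom, seed=0)
        nodes, table = split_into_contiguous_nodes(sim.parcellation)
        mat = build_matrix(sim.lesions, nodes, table)
        assert mat.analyzable == []

    def test_exactly_one_analyzable_node(self, small_phantom):
        sim = simulate_patient_cohort(phantom=small_phantom, seed=1)
        nodes, table = split_into_contiguous_nodes(sim.parcellation)
        mat = build_matrix(sim.lesions, nodes, table)
        assert mat.analyzable == [1]
        lesioned = sorted(mat.matrix.index[mat.matrix[1]])
        assert lesioned == sim.truth["deficit_patients"]
        # the 64-voxel fragment never enters the matrix
        assert 4 not in mat.matrix.columns


class TestNodeSymptomTest:
    def test_equal_group_means_give_half_p(self, small_phantom):
        sim = simulate_patient_cohort(phantom=small_phantom, seed=2, effect_sd=0.0)
        nodes, table = split_into_contiguous_nodes(sim.parcellation)
        mat = build_matrix(sim.lesions, nodes, table)
        lesioned = mat.matrix.index[mat.matrix[1]]
        rest = mat.matrix.index[~mat.matrix[1]]
        scores = side_composite_scores(sim.cohort)
        # both groups centred at zero on both sides: t = 0, one-tailed p = 0.5
        for side in ("left", "right"):
            scores.loc[lesioned, side] = np.linspace(-1, 1, len(lesioned))
            scores.loc[rest, side] = np.linspace(-1, 1, len(rest))
        res = node_symptom_test(mat, scores)
        assert res["t"].abs().max() == pytest.approx(0.0, abs=1e-12)
        assert res["p"].tolist() == pytest.approx([0.5, 0.5])

    def test_two_tests_holm_criticals(self, small_phantom):
        sim = simulate_patient_cohort(phantom=small_phantom, seed=3)
        nodes, table = split_into_contiguous_nodes(sim.parcellation)
        mat = build_matrix(sim.lesions, nodes, table)
        res = node_symptom_test(mat, side_composite_scores(sim.cohort))
        assert len(res) == 2  # one node, two sides
        assert sorted(res["critical_alpha"]) == pytest.approx([0.025, 0.05])

    def test_power_at_documented_effect(self, small_phantom):
        # left-sided deficit of 1.5 baseline SDs in 9 of 28 patients,
        # one analyzable node: Holm-corrected detection in >=80% of runs
        detections = 0
        reps = 500
        for rep in range(reps):
            sim = simulate_patient_cohort(phantom=small_phantom, seed=rep,
                                          effect_sd=1.5)
            nodes, table = split_into_contiguous_nodes(sim.parcellation)
            mat = build_matrix(sim.lesions, nodes, table)
            res = node_symptom_test(mat, side_composite_scores(sim.cohort))
            hit = res[(res["node_id"] == 1) & (res["side"] == "left")]
            detections += bool(hit["reject"].iloc[0])
        assert detections / reps >= 0.80

    def test_familywise_error_under_null(self, small_phantom):
        # no injected deficit: any rejection anywhere is a family-wise error
        errors = 0
        reps = 500
        for rep in range(reps):
            sim = simulate_patient_cohort(phantom=small_phantom,
                                          seed=10_000 + rep, effect_sd=0.0)
            nodes, table = split_into_contiguous_nodes(sim.parcellation)
            mat = build_matrix(sim.lesions, nodes, table)
            res = node_symptom_test(mat, side_composite_scores(sim.cohort))
            errors += bool(res["reject"].any())
        # alpha plus ~3 binomial SEs of simulation error
        assert errors / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestTargetAreaAssociation:
    def test_patient_table_counts(self, cohort):
        res = target_area_association(cohort, "m3")
        assert (res.table.a, res.table.b) == (9, 0)
        assert (res.table.c, res.table.d) == (12, 7)
        assert res.p == pytest.approx(0.042556, abs=5e-6)
        assert res.or_ci[0] == pytest.approx(1.08, abs=5e-3)
        assert np.isinf(res.or_ci[1])

    def test_no_target_annotations_degenerate(self, cohort):
        df = cohort.copy()
        df["lesion"] = "Right WM"
        res = target_area_association(df, "m3")
        assert res.table.a + res.table.b == 0
        assert res.p == 1.0

    def test_missing_annotation_excluded_with_warning(self, cohort):
        df = cohort.copy()
        df.loc[df.index[:2], "lesion"] = ""
        with pytest.warns(UserWarning, match="excluding 2"):
            res = target_area_association(df, "m3")
        assert sum(res.table) == 26

    @pytest.mark.parametrize("annotation, expected", [
        ("Right IC, LN, internal capsule", True),
        ("Left S2 OP1, cerebellum", True),
        ("Right IC, DLPFC", True),
        ("Left LN, CN, right putamen, internal capsule", False),
        ("Bilateral WM, BS, cerebellum", False),
        ("", False),
    ])
    def test_target_annotation_parsing(self, annotation, expected):
        assert annotation_mentions_target(annotation) is expected
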