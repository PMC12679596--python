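"""Quad clustering, cherry detection and scenario mapping."""

import numpy as np
import pandas as pd
import pytest

from dupdiverge.evaluation import FIXED_D4, lance_williams_ward_heights, ward_height_agreement
from dupdiverge.io import FamilyTree
from dupdiverge.trajectory import (
    ClusterResult,
    call_trajectory,
    cluster_genes,
    infer_trajectory,
    recent_pair_partition,
    specificity_matrix,
)

GENES = ["gA", "gB", "gC", "gD"]


def _flags(rows, genes=GENES, n_ct=12):
    return pd.DataFrame(np.array(rows), index=genes, columns=[f"ct{i:02d}" for i in range(n_ct)])


def _block(idx, n_ct=12):
    v = np.zeros(n_ct, int)
    v[list(idx)] = 1
    return v


B1, B2, B3 = _block(range(4)), _block(range(4, 8)), _block(range(8, 12))


class TestRecentPairs:
    def test_balanced_topology(self):
        t = FamilyTree.from_newick("((gA,gB),(gC,gD));")
        assert set(recent_pair_partition(t, GENES)) == {
            frozenset({"gA", "gB"}), frozenset({"gC", "gD"})
        }

    def test_relabelled_topology(self):
        t = FamilyTree.from_newick("((gA,gC),(gB,gD));")
        assert set(recent_pair_partition(t, GENES)) == {
            frozenset({"gA", "gC"}), frozenset({"gB", "gD"})
        }

    def test_caterpillar_is_unresolved(self):
        t = FamilyTree.from_newick("(((gA,gB),gC),gD);")
        # one cherry only -> cannot partition into two recent pairs
        assert recent_pair_partition(t, GENES) is None


class TestSpecificityMatrix:
    def test_zero_rows_removed(self):
        flags = _flags([B1, B1, B1, np.zeros(12, int)])
        mat, zero = specificity_matrix(flags, GENES)
        assert list(mat.index) == ["gA", "gB", "gC"]
        assert zero == ["gD"]

    def test_jaccard_of_mixed_rows(self):
        from scipy.spatial.distance import pdist

        rows = np.array([[1, 1, 0], [1, 0, 1]], dtype=bool)
        assert pdist(rows, metric="jaccard")[0] == pytest.approx(2 / 3)


class TestWard:
    def test_heights_match_hand_lance_williams(self):
        assert ward_height_agreement(FIXED_D4) < 1e-10

    def test_hand_recurrence_first_merges_are_raw_distances(self):
        h = lance_williams_ward_heights(FIXED_D4)
        assert h[0] == pytest.approx(0.2) and h[1] == pytest.approx(0.3)


class TestClusterGenes:
    def test_identical_rows_single_cluster(self):
        res = cluster_genes(_flags([B1] * 4))
        assert res.k == 1 and res.partition == [GENES]

    def test_two_separated_pairs(self):
        res = cluster_genes(_flags([B1, B1, B2, B2]))
        assert res.k == 2
        assert sorted(map(sorted, res.partition)) == [["gA", "gB"], ["gC", "gD"]]
        assert res.silhouettes[2] == pytest.approx(1.0)

    def test_all_distinct_rows(self):
        rows = [_block(range(3)), _block(range(3, 6)), _block(range(6, 9)), _block(range(9, 12))]
        res = cluster_genes(_flags(rows))
        assert res.k == 4


class TestScenarioMapping:
    @pytest.mark.parametrize(
        "rows,scenario",
        [
            ([B1, B1, B1, B1], 1),
            ([B1, B1, B2, B2], 2),
            ([B1, B1, B1, B2], 3),
            ([B1, B1, B2, B3], 4),
            (
                [_block(range(3)), _block(range(3, 6)), _block(range(6, 9)), _block(range(9, 12))],
                5,
            ),
        ],
    )
    def test_planted_structures(self, rows, scenario):
        tree = FamilyTree.from_newick("((gA,gB),(gC,gD));")
        call = infer_trajectory("s", _flags(rows), GENES, tree=tree)
        assert call.scenario == scenario

    def test_strict_mode_rejects_mismatched_split(self):
        tree = FamilyTree.from_newick("((gA,gC),(gB,gD));")  # recent pairs cross
        flags = _flags([B1, B1, B2, B2])  # split pairs gA+gB / gC+gD
        strict = infer_trajectory("s", flags, GENES, tree=tree, strict_recent_split=True)
        lax = infer_trajectory("s", flags, GENES, tree=tree, strict_recent_split=False)
        assert strict.scenario == 0 and strict.recent_match is False
        assert lax.scenario == 2

    def test_zero_row_counts_as_own_group(self):
        flags = _flags([B1, B1, B1, np.zeros(12, int)])
        call = infer_trajectory("s", flags, GENES)
        assert call.sizes == [1, 3] and call.scenario == 3

    def test_relabeling_invariance(self):
        flags = _flags([B1, B2, B1, B2], genes=["gB", "gC", "gA", "gD"])
        tree = FamilyTree.from_newick("((gB,gA),(gC,gD));")
        call = infer_trajectory("s", flags, ["gB", "gC", "gA", "gD"], tree=tree)
        flags2 = _flags([B1, B1, B2, B2], genes=["gA", "gB", "gC", "gD"])
        call2 = infer_trajectory("s", flags2, GENES, tree=FamilyTree.from_newick("((gA,gB),(gC,gD));"))
        assert call.scenario == call2.scenario == 2

    def test_unresolved_tree_excludes_quad(self):
        tree = FamilyTree.from_newick("(((gA,gB),gC),gD);")
        call = infer_trajectory("s", _flags([B1, B1, B2, B2]), GENES, tree=tree)
        assert call.scenario == 0 and call.scenario_name == "unresolved"
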