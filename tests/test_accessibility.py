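"""Accessibility-profile Jaccard distances and ctACR matching."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupdiverge.accessibility import jaccard_distance, match_ctacrs
from dupdiverge.evaluation import jaccard_vs_bruteforce
from dupdiverge.io import AcrInterval


def _prof(rows, conds=None):
    mat = np.array(rows)
    conds = conds or [f"c{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(mat, columns=conds)


class TestJaccard:
    def test_identical_presence_sets_zero(self):
        assert jaccard_distance(_prof([[1, 1, 1, 1], [1, 1, 1, 1], [0, 0, 0, 0]])) == 0.0

    def test_pairwise_disjoint_sets_one(self):
        eye = np.eye(4, dtype=int)
        assert jaccard_distance(_prof(eye)) == 1.0

    def test_two_condition_worked_example(self):
        # A = {a, b, c}, B = {a, b, d}: 1 - 2/4
        prof = _prof([[1, 1], [1, 1], [1, 0], [0, 1]])
        assert jaccard_distance(prof) == pytest.approx(0.5)

    def test_empty_everywhere_is_na(self):
        assert math.isnan(jaccard_distance(_prof([[0, 0], [0, 0]])))

    def test_single_condition_raises(self):
        with pytest.raises(ValueError):
            jaccard_distance(_prof([[1]]))

    def test_pooled_variant(self):
        prof = _prof([[1, 1], [1, 0], [0, 1]])
        assert jaccard_distance(prof, pooled=True) == pytest.approx(1 - 1 / 3)

    def test_matches_bruteforce_on_random_profiles(self):
        assert jaccard_vs_bruteforce(300, seed=5) < 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_permutation_and_absent_acr_invariance(self, seed):
        rng = np.random.default_rng(seed)
        mat = (rng.random((6, 4)) < 0.5).astype(int)
        if not mat.any():
            mat[0, 0] = 1
        prof = _prof(mat)
        perm = prof[list(rng.permutation(prof.columns))]
        assert jaccard_distance(perm) == pytest.approx(jaccard_distance(prof))
        padded = pd.concat(
            [prof, pd.DataFrame([[0] * 4], columns=prof.columns)], ignore_index=True
        )
        assert jaccard_distance(padded) == pytest.approx(jaccard_distance(prof))


class TestMatchCtacrs:
    SPEC = pd.DataFrame(
        [[1, 0], [0, 0]], index=["gene1", "gene2"], columns=["epidermis", "endothelium"]
    )

    def test_match_emitted_when_labels_agree(self):
        acr = AcrInterval("a1", "c", 0, 10, ct_label="epidermis")
        out = match_ctacrs(self.SPEC, [acr], {"a1": "gene1"})
        assert out.to_dict("records") == [
            {"gene": "gene1", "acr_id": "a1", "cell_type": "epidermis"}
        ]

    def test_no_match_when_gene_not_specific_there(self):
        acr = AcrInterval("a1", "c", 0, 10, ct_label="endothelium")
        assert match_ctacrs(self.SPEC, [acr], {"a1": "gene1"}).empty

    def test_gene_without_acr_gives_no_triples(self):
        acr = AcrInterval("a1", "c", 0, 10, ct_label="epidermis")
        assert match_ctacrs(self.SPEC, [acr], {}).empty

    def test_unknown_cell_type_lists_vocabulary(self):
        acr = AcrInterval("a1", "c", 0, 10, ct_label="mesophyll")
        with pytest.raises(ValueError, match="endothelium"):
            match_ctacrs(self.SPEC, [acr], {"a1": "gene1"})
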