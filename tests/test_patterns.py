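"""Pattern statistics, category rules, QC, normalization, consolidation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupdiverge.io import CountsTable
from dupdiverge.patterns import (
    PairStats,
    celltype_mean_cpm,
    classify_pair,
    cpm_normalize,
    filter_low_expression,
    pair_stats,
    qc_cell_types,
    shared_categories,
)


def _table(mat, cts=("ct1", "ct2"), reps=2, genes=None):
    cols = [f"{ct}.r{k + 1}" for ct in cts for k in range(reps)]
    genes = genes or [f"g{i}" for i in range(len(mat))]
    return CountsTable(pd.DataFrame(mat, index=genes, columns=cols))


class TestClassifier:
    @pytest.mark.parametrize(
        "r,m,s,expect",
        [
            (0.95, 0.5, 0.3, "dosage_balanced"),
            (0.95, 2.0, 0.5, "paralogue_dominance"),
            (0.95, 2.0, 1.5, "specialization"),
            (0.3, 2.0, 1.5, "divergence"),
            (0.7, 2.0, 0.5, "others"),
            (0.95, 0.5, 1.2, "others"),  # no rule covers r>0.9, m<1, s>=1
            (0.3, 0.5, 1.5, "others"),
            (0.91, 1.0, 0.99, "paralogue_dominance"),  # m boundary inclusive
        ],
    )
    def test_rule_table(self, r, m, s, expect):
        st_ = PairStats(r=r, m=m, s=s, expressed1=True, expressed2=True)
        assert classify_pair(st_).pattern == expect

    def test_expression_gates(self):
        non = PairStats(float("nan"), 0, 0, False, False)
        mono = PairStats(float("nan"), 2, 1, True, False)
        assert classify_pair(non).pattern == "non_expressed"
        assert classify_pair(mono).pattern == "mono_expressed"
        assert classify_pair(mono).simplified == "mono"

    def test_simplified_is_pure_function_of_pattern(self):
        assert classify_pair(PairStats(0.95, 0.5, 0.3, True, True)).simplified == "correlated"
        assert classify_pair(PairStats(0.3, 2, 1.5, True, True)).simplified == "uncorrelated"


class TestQc:
    def test_identical_replicates_kept(self):
        tab = _table(np.arange(40).reshape(10, 4))
        kept, report = qc_cell_types(tab)
        assert set(kept.cell_types) == {"ct1", "ct2"}
        assert (report["rho"] > 0.99).all()

    def test_anticorrelated_and_boundary_removed(self):
        base = np.arange(1, 11)
        mat = np.c_[base, base[::-1], base, base]  # ct1 replicates reversed
        tab = _table(mat)
        kept, report = qc_cell_types(tab)
        assert kept.cell_types == ["ct2"]
        rho1 = report.set_index("cell_type").loc["ct1", "rho"]
        assert rho1 == pytest.approx(-1.0)

    def test_boundary_rho_fails(self, rng):
        # a replicate pair whose exact Spearman rho is used as the threshold
        # must be removed: the boundary counts as failing QC
        a = rng.integers(1, 1000, 30)
        b = rng.permutation(a)
        good = np.arange(1, 31)
        mat = np.c_[a, b, good, good]
        tab = _table(mat)
        _, report = qc_cell_types(tab, rho_min=-1.0)
        rho1 = float(report.set_index("cell_type").loc["ct1", "rho"])
        kept, _ = qc_cell_types(tab, rho_min=rho1)
        assert kept.cell_types == ["ct2"]

    def test_all_removed_raises(self):
        base = np.arange(1, 11)
        mat = np.c_[base, base[::-1], base, base[::-1]]
        with pytest.raises(ValueError, match="no cell types pass QC"):
            qc_cell_types(_table(mat))


class TestCpm:
    def test_definition(self):
        tab = _table([[10, 10, 0, 0], [90, 90, 5, 5]])
        cpm = cpm_normalize(tab)
        assert cpm.iloc[0, 0] == pytest.approx(1e5)
        assert cpm.iloc[1, 0] == pytest.approx(9e5)

    def test_column_sums_are_1e6(self, rng):
        tab = _table(rng.integers(0, 500, size=(50, 4)) + 1)
        cpm = cpm_normalize(tab)
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_library_names_sample(self):
        with pytest.raises(ValueError, match="ct2.r1"):
            cpm_normalize(_table([[1, 1, 0, 1]]))


def test_filter_low_expression_rules():
    cpm = pd.DataFrame(
        {
            "s1": [5.0, 5.0, 0.0],
            "s2": [5.0, 0.4, 0.0],
            "s3": [5.0, 0.4, 0.0],
        },
        index=["kept", "dropped", "zero"],
    )
    retained, non = filter_low_expression(cpm)
    assert list(retained) == ["kept"]
    assert list(non) == ["zero"]


class TestPairStats:
    def test_identical_profiles(self):
        prof = pd.DataFrame({"gA": [10, 100, 1000], "gB": [10, 100, 1000]}).T
        st_ = pair_stats(prof, "gA", "gB", {"gA", "gB"})
        assert st_.r == pytest.approx(1.0)
        assert st_.m == pytest.approx(0.0)
        assert st_.s == pytest.approx(0.0)

    def test_constant_fourfold_offset_high_counts(self):
        base = np.array([1e4, 4e4, 1.6e5])
        prof = pd.DataFrame({"gA": base * 4, "gB": base}).T
        st_ = pair_stats(prof, "gA", "gB", {"gA", "gB"})
        assert st_.r == pytest.approx(1.0, abs=1e-6)
        assert st_.m == pytest.approx(2.0, abs=1e-3)  # log2(4), pseudocount negligible
        assert st_.s == pytest.approx(0.0, abs=1e-3)

    def test_non_expressed_partner_gives_na_r(self):
        prof = pd.DataFrame({"gA": [10, 100, 1000], "gB": [0, 0, 0]}).T
        st_ = pair_stats(prof, "gA", "gB", {"gA"})
        assert math.isnan(st_.r)
        assert classify_pair(st_).pattern == "mono_expressed"

    def test_requires_three_cell_types(self):
        prof = pd.DataFrame({"gA": [1, 2], "gB": [1, 2]}).T
        with pytest.raises(ValueError):
            pair_stats(prof, "gA", "gB", {"gA", "gB"})


class TestSharedCategories:
    @pytest.mark.parametrize(
        "calls,expect",
        [
            (["correlated"] * 4, 1),
            (["non", "non", "correlated", "correlated"], 1),
            (["mono", "correlated", "uncorrelated", "non"], 3),
            (["non"] * 4, 1),
            (["non", "non", "non", "mono"], 1),
        ],
    )
    def test_examples(self, calls, expect):
        assert shared_categories(calls) == expect

    @given(st.permutations(["non", "mono", "correlated", "uncorrelated"]))
    @settings(max_examples=24, deadline=None)
    def test_permutation_invariance(self, calls):
        assert shared_categories(calls) == shared_categories(sorted(calls))

    def test_missing_condition_raises(self):
        with pytest.raises(ValueError):
            shared_categories(["correlated", float("nan"), "non", "non"])
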