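"""ACR association, reference regions and conservation metrics."""

import math

import numpy as np
import pytest

from dupdiverge.align import Hsp
from dupdiverge.conservation import (
    associate_acrs,
    conservation_metrics,
    interval_gap,
    pair_acr_summary,
    reference_region,
)
from dupdiverge.io import AcrInterval, GeneModel


def _hsp(q0, q1, r0, r1, mm=0, score=None):
    ln = max(q1 - q0, r1 - r0)
    return Hsp(q0, q1, r0, r1, aln_len=ln, matches=ln - mm, mismatches=mm,
               gap_opens=0, score=score if score is not None else ln - 2 * mm,
               evalue=1e-9)


class TestAssociation:
    GENES = [
        GeneModel("geneA", "chr1", 1000, 2000),
        GeneModel("geneB", "chr1", 5000, 6000),
    ]

    def test_nearest_gene_wins(self):
        acr = AcrInterval("a", "chr1", 2100, 2200)  # 100 bp from A, 2800 from B
        assert associate_acrs([acr], self.GENES)["a"] == "geneA"

    def test_overlap_distance_zero(self):
        acr = AcrInterval("a", "chr1", 1500, 1600)
        assert associate_acrs([acr], self.GENES)["a"] == "geneA"

    def test_tie_breaks_lexicographically_vs_bruteforce(self):
        acr = AcrInterval("a", "chr1", 3000, 4000)  # 1000 bp from both
        got = associate_acrs([acr], self.GENES)["a"]
        dists = {
            g.gene_id: interval_gap(acr.start, acr.end, g.start, g.end)
            for g in self.GENES
        }
        best = min(dists.values())
        assert got == min(g for g, d in dists.items() if d == best)
        assert got == "geneA"

    def test_chromosome_without_genes_warns_and_skips(self):
        acr = AcrInterval("a", "chrX", 0, 100)
        with pytest.warns(UserWarning):
            assert associate_acrs([acr], self.GENES) == {}


class TestReferenceRegion:
    GENES = [
        GeneModel("gA", "chr1", 0, 100),
        GeneModel("gB", "chr1", 400, 500),
        GeneModel("gC", "chr1", 900, 1000),
    ]

    def test_spans_upstream_to_downstream_neighbour(self):
        assert reference_region(self.GENES[1], self.GENES, 1200) == ("chr1", 0, 1000)

    def test_terminal_gene_clipped_to_chromosome(self):
        assert reference_region(self.GENES[0], self.GENES, 1200) == ("chr1", 0, 500)
        assert reference_region(self.GENES[2], self.GENES, 1200) == ("chr1", 400, 1200)

    def test_tandem_pair_regions_may_overlap(self):
        r1 = reference_region(self.GENES[0], self.GENES, 1200)
        r2 = reference_region(self.GENES[1], self.GENES, 1200)
        assert max(r1[1], r2[1]) < min(r1[2], r2[2])


class TestMetrics:
    def test_definition_arithmetic(self):
        B, M, cons = conservation_metrics([_hsp(0, 250, 100, 350, mm=10)], 500)
        assert (B, M, cons) == (0.5, 10 / 250, True)

    def test_boundary_just_below_threshold_not_conserved(self):
        B, M, cons = conservation_metrics([_hsp(0, 49, 0, 49)], 500)
        assert B == pytest.approx(0.098)
        assert not cons

    def test_identical_copy(self):
        B, M, cons = conservation_metrics([_hsp(0, 500, 0, 500)], 500)
        assert (B, M, cons) == (1.0, 0.0, True)

    def test_empty_table_is_unblasted(self):
        B, M, cons = conservation_metrics([], 500)
        assert B == 0.0 and math.isnan(M) and not cons

    def test_overlapping_hsps_reduced_greedily_by_score(self):
        big = _hsp(0, 300, 0, 300, mm=0, score=300)
        overlapping = _hsp(100, 400, 600, 900, mm=0, score=200)  # overlaps big
        disjoint = _hsp(350, 450, 950, 1050, mm=10, score=80)
        B, M, _ = conservation_metrics([overlapping, big, disjoint], 500)
        assert B == pytest.approx((300 + 100) / 500)
        assert M == pytest.approx(10 / 400)

    def test_stricter_thresholds(self):
        B, _, cons = conservation_metrics([_hsp(0, 150, 0, 150)], 500, conserved_b=0.4)
        assert B == pytest.approx(0.3) and not cons


def test_pair_summary_on_synthetic_pair(small_synth):
    cfg, synth = small_synth
    assoc = associate_acrs(synth.acrs, synth.genes)
    by_gene = {}
    for a in synth.acrs:
        gid = assoc.get(a.acr_id)
        if gid:
            by_gene.setdefault(gid, []).append(a)
    row = synth.pairs.iloc[0]
    rec = pair_acr_summary(
        (row.gene1, row.gene2), by_gene, synth.genome, synth.genes,
        synth.chrom_lengths,
    )
    assert rec["n_acrs"] == rec["large_count"] + rec["small_count"]
    assert rec["large_count"] >= rec["small_count"]
    if rec["n_acrs"]:
        assert 0 <= rec["frac_conserved"] <= 1
        assert 0 <= rec["frac_unblasted"] <= 1


def test_pair_with_no_acrs_gives_na_fields():
    genes = [GeneModel("g1", "c1", 100, 200), GeneModel("g2", "c2", 100, 200)]
    rec = pair_acr_summary(("g1", "g2"), {}, {"c1": "A" * 300, "c2": "A" * 300}, genes)
    assert rec["n_acrs"] == 0 and math.isnan(rec["frac_conserved"])
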