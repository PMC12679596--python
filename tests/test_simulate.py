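"""Synthetic generator: determinism, planted limits, margin certification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from dupdiverge.patterns import classify_pair, PairStats
from dupdiverge.simulate import (
    SynthConfig,
    _draw_latents,
    _latent_stats,
    _scenario_vectors,
    gen_accessibility,
    gen_duplicated_genome,
    gen_expression,
    gen_trajectories,
    mutate_seq,
    random_seq,
)


def test_identical_seeds_give_identical_outputs():
    a = gen_duplicated_genome(SynthConfig(seed=5, n_pairs=4, n_quads=1))
    b = gen_duplicated_genome(SynthConfig(seed=5, n_pairs=4, n_quads=1))
    assert a.genome == b.genome
    assert a.pairs.equals(b.pairs)
    assert a.acr_truth.equals(b.acr_truth)
    c = gen_duplicated_genome(SynthConfig(seed=6, n_pairs=4, n_quads=1))
    assert a.genome != c.genome


def test_no_mutation_limit_partner_acr_identical():
    cfg = SynthConfig(seed=2, n_pairs=5, n_quads=0, sub_rate=0.0, del_frac=0.0,
                      p_acr_loss=0.0, p_de_novo=0.0)
    s = gen_duplicated_genome(cfg)
    acr_by_id = {a.acr_id: a for a in s.acrs}
    for row in s.acr_truth.itertuples(index=False):
        src = acr_by_id[row.acr_id]
        cp = acr_by_id[row.acr_id + "_copy"]
        assert s.genome[src.chrom][src.start:src.end] == s.genome[cp.chrom][cp.start:cp.end]


def test_total_loss_limit_marks_all_unconserved():
    cfg = SynthConfig(seed=3, n_pairs=5, n_quads=0, p_acr_loss=1.0, p_de_novo=0.0)
    s = gen_duplicated_genome(cfg)
    assert s.acr_truth["lost"].all()
    assert not s.acr_truth["expected_conserved"].any()
    assert not any(a.acr_id.endswith("_copy") for a in s.acrs)


def test_substitution_rate_within_binomial_interval(rng):
    mu, n = 0.05, 10_000
    seq = random_seq(rng, n)
    mut = mutate_seq(seq, mu, rng)
    subs = sum(a != b for a, b in zip(seq, mut))
    lo, hi = binom.ppf([0.005, 0.995], n, mu)
    assert lo <= subs <= hi


def test_mono_and_non_expressed_latents():
    rng = np.random.default_rng(0)
    c1, c2 = _draw_latents("mono_expressed", 12, rng)
    assert c1.sum() > 0 and c2.sum() == 0
    c1, c2 = _draw_latents("non_expressed", 12, rng)
    assert c1.sum() == 0 and c2.sum() == 0


@pytest.mark.parametrize(
    "label",
    ["dosage_balanced", "paralogue_dominance", "specialization", "divergence", "others"],
)
def test_latents_certified_inside_rule_region(label):
    """Every accepted latent draw classifies to its label with zero noise."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        c1, c2 = _draw_latents(label, 12, rng)
        r, m, s = _latent_stats(c1, c2)
        got = classify_pair(PairStats(r=r, m=m, s=s, expressed1=True, expressed2=True))
        assert got.pattern == label


def test_gen_expression_plants_labels_and_counts_match_layout():
    cfg = SynthConfig(seed=4, n_pairs=6, n_quads=0, tissues=("root",))
    pairs = pd.DataFrame(
        {"pair_id": [f"p{i}" for i in range(6)],
         "gene1": [f"p{i}A" for i in range(6)],
         "gene2": [f"p{i}B" for i in range(6)],
         "mechanism": ["WGD"] * 6}
    )
    counts, truth = gen_expression(cfg, pairs)
    tab = counts["root"]
    assert tab.df.shape == (12, cfg.cell_types * cfg.replicates)
    assert set(truth["label"]) <= set(cfg.pattern_mix)
    for row in truth[truth["label"] == "non_expressed"].itertuples(index=False):
        assert tab.df.loc[row.gene1].sum() == 0
        assert tab.df.loc[row.gene2].sum() == 0
    for row in truth[truth["label"] == "mono_expressed"].itertuples(index=False):
        zeros = (tab.df.loc[row.gene1].sum() == 0) + (tab.df.loc[row.gene2].sum() == 0)
        assert zeros == 1


def test_too_few_cell_types_rejected():
    with pytest.raises(ValueError):
        SynthConfig(cell_types=2)


class TestScenarioVectors:
    def test_structures(self):
        rng = np.random.default_rng(1)
        m1 = _scenario_vectors(1, 12, rng)
        assert (m1 == m1[0]).all()
        m3 = _scenario_vectors(3, 12, rng)
        assert sum((m3[i] != m3[0]).any() for i in range(4)) == 1
        m5 = _scenario_vectors(5, 12, rng)
        for i in range(4):
            for j in range(i + 1, 4):
                assert (m5[i] != m5[j]).any()

    def test_quad_with_missing_gene_rejected(self):
        cfg = SynthConfig(seed=1, n_pairs=0, n_quads=1)
        quads = pd.DataFrame(
            [{"set_id": "q", "gene1": "a", "gene2": "b", "gene3": "", "gene4": "d"}]
        )
        with pytest.raises(ValueError, match="4 expressed genes"):
            gen_trajectories(cfg, quads)


def test_accessibility_turnover_monotone(rng):
    ids = [f"a{i}" for i in range(400)]
    from dupdiverge.accessibility import jaccard_distance

    d = [
        jaccard_distance(gen_accessibility(ids, ["c1", "c2", "c3", "c4"], rng, turnover=t))
        for t in (0.0, 0.2, 0.5)
    ]
    assert d[0] == 0.0 and d[0] < d[1] < d[2]
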