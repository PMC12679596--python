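"""Local aligner: perfect matches, planted variants, nulls, DP oracle."""

import numpy as np
import pytest

from dupdiverge.align import (
    DEFAULT_SCHEME,
    Hsp,
    evalue,
    karlin_lambda,
    local_align,
    revcomp,
)
from dupdiverge.evaluation import _oracle_sw_score, aligner_oracle
from dupdiverge.simulate import mutate_seq, random_seq


def test_perfect_substring_is_one_full_scoring_hsp(rng):
    ref = random_seq(rng, 1000)
    q = ref[300:400]
    hsps = local_align(q, ref)
    best = hsps[0]
    assert (best.aln_len, best.mismatches, best.score) == (100, 0, 100)
    assert (best.r_start, best.r_end) == (300, 400)


def test_planted_substitutions_are_counted(rng):
    ref = random_seq(rng, 1500)
    q = ref[500:600]
    arr = list(q)
    pos = rng.choice(100, 5, replace=False)
    for p in pos:  # force a different base
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    q5 = "".join(arr)
    hsps = local_align(q5, ref)
    total_mm = sum(h.mismatches for h in hsps)
    assert total_mm == 5  # HSPs may split, but the mismatch total is exact


def test_reverse_strand_hits_are_found(rng):
    ref = random_seq(rng, 800)
    q = revcomp(ref[200:320])
    best = local_align(q, ref)[0]
    assert best.strand == "-"
    assert best.score == 120


def test_random_query_rarely_significant(rng):
    """A null query vs an i.i.d. 5 kb reference almost never yields E<=1e-3."""
    hits = 0
    for _ in range(100):
        ref = random_seq(rng, 5000)
        q = random_seq(rng, 200)
        hits += bool(local_align(q, ref))
    assert hits <= 1  # >=99% of trials empty


def test_empty_inputs_raise():
    with pytest.raises(ValueError):
        local_align("", "ACGT")
    with pytest.raises(ValueError):
        local_align("ACGT", "")


def test_karlin_lambda_matches_closed_form():
    # for +1/-1 with uniform bases the root is exactly ln 3
    assert karlin_lambda(1, -1) == pytest.approx(np.log(3), abs=1e-9)


def test_evalue_decreases_with_score():
    es = [evalue(s, 200, 5000) for s in (15, 20, 30, 60)]
    assert all(a > b for a, b in zip(es, es[1:]))


def test_hsp_invariants_enforced():
    with pytest.raises(ValueError):
        Hsp(0, 10, 0, 10, aln_len=5, matches=0, mismatches=6,
            gap_opens=0, score=1, evalue=1.0)


def test_best_hsp_score_matches_full_dp_oracle():
    """Smaller version of the planted-case DP comparison (full set runs in
    the acceptance suite): equal scores, never higher."""
    res = aligner_oracle(n_cases=40, seed=123)
    assert res["overscores"] == 0
    assert res["agreement"] >= 0.95


def test_deletion_splits_into_hsps_covering_flanks(rng):
    ref = random_seq(rng, 2000)
    q = ref[600:800] + ref[950:1150]  # 150 bp deleted relative to reference
    hsps = local_align(q, ref)
    covered = sum(h.q_end - h.q_start for h in hsps[:2])
    assert covered >= 380  # both flanks recovered
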