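"""Planted-truth evaluation of every pipeline stage on synthetic data.

Each function here generates (or receives) synthetic inputs with known
ground truth, runs the corresponding pipeline stage, and measures recovery
or agreement with an independent oracle:

* the pattern classifier against a stand-alone rule table;
* the seed-and-extend aligner against full dynamic-programming local
  alignment (Bio.Align.PairwiseAligner, an implementation unrelated to ours);
* conservation metrics against the planted substitution rates and states;
* Jaccard distances against naive set arithmetic;
* Ward.D2 against a hand-coded Lance-Williams recurrence and exhaustive
  partition enumeration;
* trajectory calls against planted scenarios;
* the NB exact test against its nominal type-I level and planted effects.

These functions are used both by the test suite and by the repository's
acceptance script.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import accessibility, conservation, de, patterns, trajectory
from .align import DEFAULT_SCHEME, local_align
from .io import CountsTable, FamilyTree
from .patterns import PairStats, classify_pair
from .simulate import (
    SynthConfig,
    gen_accessibility,
    gen_duplicated_genome,
    gen_expression,
    gen_trajectories,
    mutate_seq,
    random_seq,
)


# ---------------------------------------------------------------------------
# pattern classifier vs independent rule table

def reference_pattern_rules(r: float, m: float, s: float, e1: bool, e2: bool) -> str:
    """Stand-alone restatement of the category rules, kept deliberately
    separate from the classifier implementation."""
    if not e1 and not e2:
        return "non_expressed"
    if e1 != e2:
        return "mono_expressed"
    if math.isnan(r):
        return "others"
    if r > 0.9 and s < 1:
        return "dosage_balanced" if m < 1 else "paralogue_dominance"
    if r > 0.9 and s >= 1 and m >= 1:
        return "specialization"
    if r < 0.5 and m >= 1 and s >= 1:
        return "divergence"
    return "others"


def classifier_oracle_disagreements(n: int = 10_000, seed: int = 0) -> int:
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n):
        e1, e2 = rng.random() < 0.9, rng.random() < 0.9
        r = float(rng.uniform(-1, 1)) if (e1 and e2 and rng.random() > 0.05) else float("nan")
        m = float(rng.uniform(0, 3))
        s = float(rng.uniform(0, 3))
        got = classify_pair(PairStats(r=r, m=m, s=s, expressed1=e1, expressed2=e2)).pattern
        want = reference_pattern_rules(r, m, s, e1, e2)
        bad += got != want
    return bad


# ---------------------------------------------------------------------------
# pattern recovery on planted labels

def pattern_recovery(
    n_pairs: int = 500, dispersion: float = 0.05, seed: int = 0,
    tissues: tuple[str, ...] = ("globular", "heart", "cotyledon", "early_maturation"),
) -> float:
    cfg = SynthConfig(
        seed=seed, n_pairs=n_pairs, n_quads=0, nb_dispersion=dispersion, tissues=tissues
    )
    pairs = pd.DataFrame(
        {
            "pair_id": [f"pair{i:04d}" for i in range(n_pairs)],
            "gene1": [f"pair{i:04d}A" for i in range(n_pairs)],
            "gene2": [f"pair{i:04d}B" for i in range(n_pairs)],
            "mechanism": ["WGD"] * n_pairs,
        }
    )
    counts, truth = gen_expression(cfg, pairs)
    hits = tot = 0
    for tissue in cfg.tissues:
        calls = patterns.classify_pairs(counts[tissue], pairs, tissue)
        m = calls.merge(truth[truth["tissue"] == tissue], on=["gene1", "gene2"])
        hits += int((m["pattern"] == m["label"]).sum())
        tot += len(m)
    return hits / tot


# ---------------------------------------------------------------------------
# aligner vs full-DP oracle

def _oracle_sw_score(query: str, reference: str) -> float:
    """Full Smith-Waterman score via Bio.Align (independent implementation).

    Gap costs mirror the BLAST convention 5 + 2g: first gapped base -7,
    each extension -2.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return max(aligner.score(reference, query), aligner.score(reference, _rc(query)))


def _rc(seq: str) -> str:
    from .align import revcomp

    return revcomp(seq)


def aligner_oracle(n_cases: int = 200, seed: int = 0) -> dict:
    """Planted queries (<=200 bp) vs <=2 kb references: best-HSP score
    compared with the full-DP optimum. Returns agreement rate, number of
    heuristic misses (score-lower) and over-scores (must be zero)."""
    rng = np.random.default_rng(seed)
    mus = [0.0, 0.02, 0.05, 0.10, 0.20]
    equal = miss = over = 0
    for i in range(n_cases):
        ref = random_seq(rng, int(rng.integers(800, 2001)))
        qlen = int(rng.integers(60, 201))
        start = int(rng.integers(0, len(ref) - qlen))
        q = ref[start : start + qlen]
        q = mutate_seq(q, mus[i % len(mus)], rng)
        if i % 7 == 0:  # occasional internal deletion
            cut = int(rng.integers(5, max(6, qlen // 4)))
            mid = qlen // 2
            q = q[: mid - cut // 2] + q[mid + cut // 2 :]
        hsps = local_align(q, ref)
        best = hsps[0].score if hsps else 0
        oracle = _oracle_sw_score(q, ref)
        if best == oracle:
            equal += 1
        elif best < oracle:
            miss += 1
        else:
            over += 1
    return {"n": n_cases, "agreement": equal / n_cases, "misses": miss, "overscores": over}


# ---------------------------------------------------------------------------
# conservation metrics and states

def _acrs_by_gene(synth):
    assoc = conservation.associate_acrs(synth.acrs, synth.genes)
    by_gene: dict[str, list] = {}
    for a in synth.acrs:
        gid = assoc.get(a.acr_id)
        if gid is not None:
            by_gene.setdefault(gid, []).append(a)
    return by_gene


def mismatch_rate_vs_planted(
    mu_levels: tuple[float, ...] = (0.02, 0.05, 0.10),
    n_pairs: int = 50,
    seed: int = 0,
) -> dict[float, dict]:
    """Mean B and M of source ACRs vs the partner reference region, per
    planted substitution rate (full-length retained copies)."""
    out = {}
    for mu in mu_levels:
        cfg = SynthConfig(
            seed=seed + int(mu * 1000), n_pairs=n_pairs, n_quads=0,
            sub_rate=mu, del_frac=0.0, p_acr_loss=0.0, p_de_novo=0.0,
            acr_len_range=(500, 500),
        )
        synth = gen_duplicated_genome(cfg)
        by_gene = _acrs_by_gene(synth)
        gene_by_id = {g.gene_id: g for g in synth.genes}
        Bs, Ms = [], []
        for row in synth.acr_truth.itertuples(index=False):
            partner = gene_by_id[row.partner]
            rchrom, r0, r1 = conservation.reference_region(
                partner, synth.genes, synth.chrom_lengths[partner.chrom]
            )
            acr = next(a for a in by_gene[row.gene] if a.acr_id == row.acr_id)
            B, M, cons = conservation.score_acr(acr, synth.genome, rchrom, r0, r1)
            if cons:
                Bs.append(B)
                Ms.append(M)
        out[mu] = {"n_acrs": len(Bs), "mean_B": float(np.mean(Bs)), "mean_M": float(np.mean(Ms))}
    return out


def conservation_state_recovery(mu: float, n_quads: int = 25, seed: int = 0) -> dict:
    """Fraction of planted unique/two_copy/multi_copy states recovered,
    plus mean mismatch rates of multi-copy vs two-copy conserved ACRs."""
    cfg = SynthConfig(seed=seed + 17, n_pairs=0, n_quads=n_quads, sub_rate=mu)
    synth = gen_duplicated_genome(cfg)
    by_gene = _acrs_by_gene(synth)
    agree = tot = 0
    m_by_state: dict[str, list] = {"multi_copy": [], "two_copy": []}
    for q in synth.quads.itertuples(index=False):
        recs = conservation.quad_conservation(
            [q.gene1, q.gene2, q.gene3, q.gene4], by_gene, synth.genome,
            synth.genes, synth.chrom_lengths,
        )
        states = {}
        for r in recs:
            states[r.acr_id] = r.state
            if r.conserved and r.state in m_by_state and not math.isnan(r.mismatch_rate):
                m_by_state[r.state].append(r.mismatch_rate)
        truth = synth.quad_acr_truth[synth.quad_acr_truth["set_id"] == q.set_id]
        for t in truth.itertuples(index=False):
            tot += 1
            agree += states.get(t.acr_id) == t.expected_state
    return {
        "recovery": agree / tot,
        "n_acrs": tot,
        "mean_M_multi": float(np.mean(m_by_state["multi_copy"])) if m_by_state["multi_copy"] else float("nan"),
        "mean_M_two": float(np.mean(m_by_state["two_copy"])) if m_by_state["two_copy"] else float("nan"),
    }


# ---------------------------------------------------------------------------
# accessibility overlap

def jaccard_vs_bruteforce(n_profiles: int = 1000, seed: int = 0) -> float:
    """Max |implementation - naive set recomputation| over random profiles."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_profiles):
        n_acr = int(rng.integers(1, 12))
        n_cond = int(rng.integers(2, 6))
        mat = (rng.random((n_acr, n_cond)) < rng.uniform(0.2, 0.9)).astype(int)
        prof = pd.DataFrame(mat, columns=[f"c{i}" for i in range(n_cond)])
        got = accessibility.jaccard_distance(prof)
        sets = [set(np.flatnonzero(mat[:, j])) for j in range(n_cond)]
        if not any(sets):
            want = float("nan")
        else:
            ds = []
            for a in range(n_cond):
                for b in range(a + 1, n_cond):
                    u = sets[a] | sets[b]
                    ds.append(1 - len(sets[a] & sets[b]) / len(u) if u else 0.0)
            want = sum(ds) / len(ds)
        if math.isnan(got) and math.isnan(want):
            continue
        worst = max(worst, abs(got - want))
    return worst


def jaccard_turnover_curve(
    turnovers: tuple[float, ...] = (0.0, 0.2, 0.5), n_acrs: int = 500, seed: int = 0
) -> list[float]:
    rng = np.random.default_rng(seed)
    out = []
    for t in turnovers:
        prof = gen_accessibility(
            [f"a{i}" for i in range(n_acrs)], ["c1", "c2", "c3", "c4"], rng, turnover=t
        )
        out.append(accessibility.jaccard_distance(prof))
    return out


# ---------------------------------------------------------------------------
# Ward.D2 vs hand recurrence and exhaustive optimum

def lance_williams_ward_heights(D: np.ndarray) -> list[float]:
    """Hand-coded Ward.D2 agglomeration (Lance-Williams recurrence),
    independent of scipy."""
    n = D.shape[0]
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    heights = []
    nxt = n
    while len(active) > 1:
        (i, j), dij = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(dij)
        ni, nj = sizes[i], sizes[j]
        newd = {}
        for k in active - {i, j}:
            nk = sizes[k]
            dki = d[tuple(sorted((k, i)))]
            dkj = d[tuple(sorted((k, j)))]
            newd[k] = math.sqrt(
                ((ni + nk) * dki**2 + (nj + nk) * dkj**2 - nk * dij**2)
                / (ni + nj + nk)
            )
        active -= {i, j}
        d = {kk: vv for kk, vv in d.items() if i not in kk and j not in kk}
        sizes[nxt] = ni + nj
        for k, v in newd.items():
            d[tuple(sorted((k, nxt)))] = v
        active.add(nxt)
        nxt += 1
    return heights


FIXED_D4 = np.array(
    [
        [0.00, 0.20, 0.90, 0.85],
        [0.20, 0.00, 0.80, 0.95],
        [0.90, 0.80, 0.00, 0.30],
        [0.85, 0.95, 0.30, 0.00],
    ]
)


def ward_height_agreement(D: np.ndarray | None = None) -> float:
    """Max |scipy Ward.D2 merge height - hand recurrence| on a 4x4 matrix."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    D = FIXED_D4 if D is None else D
    got = linkage(squareform(D), method="ward")[:, 2]
    want = lance_williams_ward_heights(D)
    return float(np.max(np.abs(got - np.array(want))))


def _bruteforce_ward_partitions(D: np.ndarray) -> dict[int, tuple[float, list]]:
    """Independent exhaustive Ward-objective minimizer per k, plain python."""
    import itertools as it

    def all_partitions(items):
        if len(items) == 1:
            yield [items]
            return
        first = items[0]
        for rest in all_partitions(items[1:]):
            for i in range(len(rest)):
                yield rest[:i] + [[first] + rest[i]] + rest[i + 1 :]
            yield [[first]] + rest

    def obj(p):
        tot = 0.0
        for cl in p:
            if len(cl) > 1:
                tot += sum(D[a][b] ** 2 for a, b in it.combinations(cl, 2)) / len(cl)
        return tot

    best: dict[int, tuple[float, list]] = {}
    for p in all_partitions(list(range(D.shape[0]))):
        k = len(p)
        o = obj(p)
        if k not in best or o < best[k][0]:
            best[k] = (o, p)
    return best


def ward_partition_agreement(n_matrices: int = 100, seed: int = 0) -> float:
    """Fraction of random 4-row binary matrices where the partition returned
    by cluster_genes attains the exhaustive Ward-objective minimum for its
    chosen k (brute force over all 15 partitions of 4 items)."""
    from scipy.spatial.distance import pdist, squareform

    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_matrices):
        while True:
            mat = (rng.random((4, 10)) < 0.4).astype(int)
            if mat.any(axis=1).all():  # no all-zero rows
                break
        df = pd.DataFrame(mat, index=list("abcd"))
        res = trajectory.cluster_genes(df)
        D = squareform(pdist(mat.astype(bool), metric="jaccard"))
        best = _bruteforce_ward_partitions(D)
        idx = {g: i for i, g in enumerate("abcd")}
        got_obj = trajectory.ward_objective(
            D, [[idx[g] for g in cl] for cl in res.partition]
        )
        want_obj = best[res.k][0] if res.k in best else float("nan")
        ok += abs(got_obj - want_obj) < 1e-12
    return ok / n_matrices


# ---------------------------------------------------------------------------
# trajectory scenario recovery

def trajectory_recovery(n_quads: int = 250, flip_rate: float = 0.0, seed: int = 0) -> float:
    cfg = SynthConfig(seed=seed + 5, n_pairs=0, n_quads=n_quads)
    quads = pd.DataFrame(
        {
            "set_id": [f"quad{i:04d}" for i in range(n_quads)],
            **{
                f"gene{j + 1}": [f"quad{i:04d}{'ABCD'[j]}" for i in range(n_quads)]
                for j in range(4)
            },
        }
    )
    rng = np.random.default_rng(seed + 6)
    de_flags, truth, _, _ = gen_trajectories(cfg, quads, rng, flip_rate=flip_rate)
    hits = 0
    for q in quads.itertuples(index=False):
        genes = [q.gene1, q.gene2, q.gene3, q.gene4]
        tree = FamilyTree.from_newick(
            f"(({genes[0]}:1,{genes[1]}:1):2,({genes[2]}:1,{genes[3]}:1):2);"
        )
        call = trajectory.infer_trajectory(q.set_id, de_flags, genes, tree=tree)
        want = int(truth.loc[truth["set_id"] == q.set_id, "scenario"].iloc[0])
        hits += call.scenario == want
    return hits / n_quads


# ---------------------------------------------------------------------------
# DE sanity

def de_null_fraction(
    n_genes: int = 300, n_reps: int = 30, dispersion: float = 0.05, seed: int = 0
) -> float:
    """Fraction of raw p < 0.05 under exchangeable NB counts (2 vs 2)."""
    rng = np.random.default_rng(seed + 9)
    fracs = []
    for _ in range(n_reps):
        mu = rng.lognormal(np.log(300), 1.0, n_genes)
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), (n_genes, 4))
        res = de.nb_exact_test(counts[:, :2], counts[:, 2:])
        fracs.append(float((res["pvalue"] < 0.05).mean()))
    return float(np.mean(fracs))


def de_power_8fold(
    n_genes: int = 200, depth: float = 1e5, dispersion: float = 0.05, seed: int = 0
) -> float:
    """Power to flag genes 8-fold enriched in one cell type as specific,
    at a given per-pseudobulk sequencing depth."""
    rng = np.random.default_rng(seed + 11)
    n_ct, reps = 6, 2
    base = np.full((n_genes, n_ct), 1.0)
    enriched = rng.choice(n_genes, n_genes // 5, replace=False)
    target_cts = rng.integers(0, n_ct, len(enriched))
    for g, ct in zip(enriched, target_cts):
        base[g, ct] = 8.0
    base = base / base.sum(axis=0, keepdims=True) * depth
    cols, data = [], []
    r = 1.0 / dispersion
    for ct in range(n_ct):
        for k in range(reps):
            cols.append(f"ct{ct + 1:02d}.r{k + 1}")
            data.append(rng.negative_binomial(r, r / (r + base[:, ct])))
    df = pd.DataFrame(np.array(data).T, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    flags = patterns.celltype_specific_genes(CountsTable(df), seed=rng)
    hits = sum(
        flags.iloc[g, ct] == 1 for g, ct in zip(enriched, target_cts)
    )
    return hits / len(enriched)
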