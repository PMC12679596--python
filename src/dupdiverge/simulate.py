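"""Synthetic duplicated genomes, expression and trajectories with planted truth.

Every downstream stage of the pipeline is exercised against data generated
here, with the ground truth recorded per entity:

* :func:`gen_duplicated_genome` -- duplicate pairs as two loci (each with
  flanking neighbour genes) whose ACRs are copied to the partner locus and
  then substituted at a controlled per-base rate, truncated by a contiguous
  deletion, dropped, or complemented with de novo ACRs; 4-gene quads built
  by two successive duplication events with per-branch substitutions, so
  recent copies diverge less than ancestral ones, plus the true
  ``((A,B),(C,D))`` topology as Newick.
* :func:`gen_expression` -- per-tissue pseudobulk counts for each pair with
  a planted 7-way pattern label. Latent per-cell-type mean profiles are
  constructed per label and accepted only if the exact pipeline statistics
  (r, m, s) computed on the noise-free latents sit inside the label's rule
  region with margin -- this makes the separability-at-zero-noise guarantee
  constructive. Counts are negative-binomial around the latents.
* :func:`gen_trajectories` -- binary cell-type-specificity vectors per quad
  realizing scenarios 1-5 (all-equal, 2:2 by recent pairs, 1:3, 1:2:1, all
  distinct), optional bit-flip noise, matching cell-type-specific ACRs and
  counts that reproduce the vectors through the DE caller.
* :func:`gen_accessibility` -- per-condition ACR presence with controlled
  turnover.

All randomness flows from one seeded generator; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    AcrInterval,
    CountsTable,
    GeneModel,
    write_bed,
    write_fasta,
    write_gff3,
    write_newick,
    write_pairs,
    write_quads,
)

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

DEFAULT_PATTERN_MIX = {
    "dosage_balanced": 0.20,
    "paralogue_dominance": 0.15,
    "specialization": 0.15,
    "divergence": 0.15,
    "others": 0.15,
    "mono_expressed": 0.10,
    "non_expressed": 0.10,
}

DEFAULT_MECHANISM_MIX = {"WGD": 0.50, "TD": 0.10, "PD": 0.10, "TRD": 0.15, "DSD": 0.15}

# scenario frequencies follow the qualitative report that single-cluster sets
# are rare and multi-cluster sets dominate
DEFAULT_SCENARIO_MIX = {1: 0.08, 2: 0.22, 3: 0.40, 4: 0.20, 5: 0.10}


@dataclass
class SynthConfig:
    seed: int = 0
    n_pairs: int = 200
    n_quads: int = 50
    acr_len_range: tuple[int, int] = (300, 500)
    acrs_per_gene: tuple[int, int] = (1, 3)
    sub_rate: float = 0.02
    recent_rate_factor: float = 0.3  # recent-branch rate = factor * sub_rate
    del_frac: float = 0.0
    p_acr_loss: float = 0.10
    p_de_novo: float = 0.10
    pattern_mix: dict = field(default_factory=lambda: dict(DEFAULT_PATTERN_MIX))
    mechanism_mix: dict = field(default_factory=lambda: dict(DEFAULT_MECHANISM_MIX))
    scenario_mix: dict = field(default_factory=lambda: dict(DEFAULT_SCENARIO_MIX))
    nb_dispersion: float = 0.05
    cell_types: int = 12
    replicates: int = 2
    tissues: tuple[str, ...] = ("globular", "heart", "cotyledon", "early_maturation")
    gene_length: int = 800
    upstream_window: int = 2000  # ACRs placed within this span upstream of the TSS
    # intergenic spacing > upstream_window + max ACR span keeps every ACR in
    # the window strictly nearer its focal gene than the flanking neighbour
    intergenic: int = 4000
    quad_acr_multi: int = 2
    quad_acr_two: int = 1  # per recent pair
    quad_acr_unique: int = 1

    def __post_init__(self):
        for p in (self.sub_rate, self.del_frac, self.p_acr_loss, self.p_de_novo):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        tot = sum(self.pattern_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"pattern_mix sums to {tot}, not 1")
        if self.replicates < 2:
            raise ValueError("need >=2 replicates per cell type")
        if self.cell_types < 3:
            raise ValueError("need >=3 cell types")

    @property
    def cell_type_names(self) -> list[str]:
        return [f"ct{i + 1:02d}" for i in range(self.cell_types)]


@dataclass
class SynthGenome:
    genome: dict[str, str]
    genes: list[GeneModel]
    acrs: list[AcrInterval]
    pairs: pd.DataFrame  # gene1, gene2, mechanism, pair_id
    quads: pd.DataFrame  # set_id, gene1..gene4
    trees: dict[str, str]  # set_id -> newick
    acr_truth: pd.DataFrame
    quad_acr_truth: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def mutate_seq(seq: str, mu: float, rng: np.random.Generator) -> str:
    """Substitute each base with probability mu (always to a different base)."""
    if mu <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    codes = np.searchsorted(BASES, arr)
    hit = rng.random(len(arr)) < mu
    shift = rng.integers(1, 4, size=len(arr))
    codes[hit] = (codes[hit] + shift[hit]) % 4
    return "".join(BASES[codes])


def truncate_seq(seq: str, del_frac: float, rng: np.random.Generator) -> str:
    """Remove one contiguous block covering del_frac of the sequence."""
    if del_frac <= 0:
        return seq
    n = len(seq)
    dlen = int(round(n * del_frac))
    if dlen >= n:
        return ""
    start = int(rng.integers(0, n - dlen + 1))
    return seq[:start] + seq[start + dlen :]


# ---------------------------------------------------------------------------
# genomes


def _locus(
    rng: np.random.Generator,
    cfg: SynthConfig,
    chrom: str,
    gene_prefix: str,
    focal_id: str,
    n_acrs: int,
    slot_lengths: Optional[list[int]] = None,
) -> tuple[str, list[GeneModel], list[AcrInterval], dict[str, tuple[int, int]]]:
    """One locus: [left neighbour] -- ACRs -- [focal gene] -- [right neighbour].

    Returns (sequence, genes, acr slots as empty intervals, layout map).
    ACR sequences are filled in by the caller so copies can share ancestry.
    """
    glen, inter = cfg.gene_length, cfg.intergenic
    margin = 100
    left_start = margin
    focal_start = left_start + glen + inter
    right_start = focal_start + glen + inter
    total = right_start + glen + margin
    seq = random_seq(rng, total)
    genes = [
        GeneModel(f"{gene_prefix}_L", chrom, left_start, left_start + glen, "+"),
        GeneModel(focal_id, chrom, focal_start, focal_start + glen, "+"),
        GeneModel(f"{gene_prefix}_R", chrom, right_start, right_start + glen, "+"),
    ]
    # ACR slots packed upstream of the focal TSS, inside the upstream window;
    # lengths are capped so the configured slot count always fits
    slots = []
    win = min(cfg.upstream_window, inter - 100)
    gap = 40
    budget = (win - 50) // max(n_acrs, 1) - gap
    if budget < cfg.acr_len_range[0]:
        raise ValueError("ACRs do not fit in the configured upstream window")
    pos = focal_start - 50
    for j in range(n_acrs):
        if slot_lengths is not None:
            # mirror a partner locus so pasted copies fit their slots exactly
            length = slot_lengths[j]
        else:
            length = int(rng.integers(cfg.acr_len_range[0], cfg.acr_len_range[1] + 1))
            length = min(length, budget)
        slots.append((pos - length, pos))
        pos -= length + gap
    slots.reverse()
    return seq, genes, slots, {"focal_start": focal_start}


def _paste(seq: str, start: int, piece: str) -> str:
    return seq[:start] + piece + seq[start + len(piece) :]


def gen_duplicated_genome(cfg: SynthConfig) -> SynthGenome:
    rng = np.random.default_rng(cfg.seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    acrs: list[AcrInterval] = []
    pair_rows = []
    truth_rows = []

    mechs = list(cfg.mechanism_mix)
    mech_p = np.array([cfg.mechanism_mix[m] for m in mechs], dtype=float)
    mech_p /= mech_p.sum()

    for i in range(cfg.n_pairs):
        pid = f"pair{i:04d}"
        g1, g2 = f"{pid}A", f"{pid}B"
        n_acr = int(rng.integers(cfg.acrs_per_gene[0], cfg.acrs_per_gene[1] + 1))
        chrom1, chrom2 = f"{pid}a", f"{pid}b"
        seq1, genes1, slots1, lay1 = _locus(rng, cfg, chrom1, f"{pid}a", g1, n_acr)
        lengths = [e - s for s, e in slots1[::-1]]  # iteration order: TSS-proximal first
        seq2, genes2, slots2, lay2 = _locus(
            rng, cfg, chrom2, f"{pid}b", g2, n_acr, slot_lengths=lengths
        )
        # homologous focal gene bodies
        focal_seq = random_seq(rng, cfg.gene_length)
        seq1 = _paste(seq1, genes1[1].start, focal_seq)
        seq2 = _paste(seq2, genes2[1].start, mutate_seq(focal_seq, cfg.sub_rate, rng))
        # source ACRs on gene1's locus; copies (mutated) on gene2's locus
        for j, (s1, e1) in enumerate(slots1):
            acr_seq = random_seq(rng, e1 - s1)
            seq1 = _paste(seq1, s1, acr_seq)
            aid1 = f"{pid}_acr{j}"
            acrs.append(AcrInterval(aid1, chrom1, s1, e1))
            lost = bool(rng.random() < cfg.p_acr_loss)
            retained = 0.0
            if not lost:
                copy = mutate_seq(acr_seq, cfg.sub_rate, rng)
                copy = truncate_seq(copy, cfg.del_frac, rng)
                retained = len(copy) / len(acr_seq)
                s2 = slots2[j][0]
                seq2 = _paste(seq2, s2, copy)
                if copy:
                    acrs.append(AcrInterval(f"{pid}_acr{j}_copy", chrom2, s2, s2 + len(copy)))
            truth_rows.append(
                {
                    "acr_id": aid1,
                    "pair_id": pid,
                    "gene": g1,
                    "partner": g2,
                    "mu": cfg.sub_rate,
                    "lost": lost,
                    "retained_frac": retained,
                    "expected_conserved": (not lost) and retained > 0.1,
                }
            )
        # de novo ACR at the partner locus (no counterpart at the source),
        # placed at the far end of the upstream window, clear of the copies
        if rng.random() < cfg.p_de_novo:
            length = int(rng.integers(cfg.acr_len_range[0], cfg.acr_len_range[1] + 1))
            win2 = min(cfg.upstream_window, cfg.intergenic - 100)
            copies_lo = min((s for s, _ in slots2), default=genes2[1].start - 50)
            start = genes2[1].start - win2 + 5
            if start + length < copies_lo - 40 and start > genes2[0].end:
                dn_seq = random_seq(rng, length)
                seq2 = _paste(seq2, start, dn_seq)
                aid = f"{pid}_denovo"
                acrs.append(AcrInterval(aid, chrom2, start, start + length))
                truth_rows.append(
                    {
                        "acr_id": aid,
                        "pair_id": pid,
                        "gene": g2,
                        "partner": g1,
                        "mu": cfg.sub_rate,
                        "lost": True,  # nothing to find at the partner
                        "retained_frac": 0.0,
                        "expected_conserved": False,
                    }
                )
        genome[chrom1], genome[chrom2] = seq1, seq2
        genes.extend(genes1 + genes2)
        mech = mechs[int(rng.choice(len(mechs), p=mech_p))]
        pair_rows.append({"pair_id": pid, "gene1": g1, "gene2": g2, "mechanism": mech})

    # quads: two successive duplications with per-branch substitution rates
    quad_rows, tree_map, qtruth_rows = [], {}, []
    mu_anc = cfg.sub_rate
    mu_rec = cfg.sub_rate * cfg.recent_rate_factor
    for i in range(cfg.n_quads):
        sid = f"quad{i:04d}"
        leaf_ids = [f"{sid}{x}" for x in "ABCD"]
        n_slots = cfg.quad_acr_multi + 2 * cfg.quad_acr_two + cfg.quad_acr_unique
        loci = {}
        quad_lengths: Optional[list[int]] = None
        for gi, gid in enumerate(leaf_ids):
            chrom = f"{sid}{'abcd'[gi]}"
            seq, gl, slots, _ = _locus(
                rng, cfg, chrom, f"{sid}{'abcd'[gi]}", gid, n_slots,
                slot_lengths=quad_lengths,
            )
            if quad_lengths is None:
                quad_lengths = [e - s for s, e in slots[::-1]]
            loci[gid] = {"chrom": chrom, "seq": seq, "genes": gl, "slots": slots}
        # homologous gene bodies along the tree
        anc_gene = random_seq(rng, cfg.gene_length)
        left_gene = mutate_seq(anc_gene, mu_anc, rng)
        right_gene = mutate_seq(anc_gene, mu_anc, rng)
        for gid, branch_seq in zip(
            leaf_ids, (left_gene, left_gene, right_gene, right_gene)
        ):
            body = mutate_seq(branch_seq, mu_rec, rng)
            L = loci[gid]
            L["seq"] = _paste(L["seq"], L["genes"][1].start, body)
        slot_idx = 0
        def plant(acr_class: str, present: list[str], ancestor_len: int):
            nonlocal slot_idx
            anc = random_seq(rng, ancestor_len)
            if acr_class == "multi":
                left = mutate_seq(anc, mu_anc, rng)
                right = mutate_seq(anc, mu_anc, rng)
                per_leaf = {
                    leaf_ids[0]: mutate_seq(left, mu_rec, rng),
                    leaf_ids[1]: mutate_seq(left, mu_rec, rng),
                    leaf_ids[2]: mutate_seq(right, mu_rec, rng),
                    leaf_ids[3]: mutate_seq(right, mu_rec, rng),
                }
            else:
                per_leaf = {g: mutate_seq(anc, mu_rec, rng) for g in present}
            expected = {"multi": "multi_copy", "two": "two_copy", "unique": "unique"}[
                acr_class
            ]
            for gid in present:
                L = loci[gid]
                s, e = L["slots"][slot_idx]
                piece = per_leaf[gid][: e - s]
                L["seq"] = _paste(L["seq"], s, piece)
                aid = f"{sid}_{gid}_acr{slot_idx}"
                acrs.append(AcrInterval(aid, L["chrom"], s, s + len(piece)))
                qtruth_rows.append(
                    {
                        "acr_id": aid,
                        "set_id": sid,
                        "gene": gid,
                        "acr_class": acr_class,
                        "expected_state": expected,
                    }
                )
            slot_idx += 1

        for _ in range(cfg.quad_acr_multi):
            plant("multi", leaf_ids, int(rng.integers(*cfg.acr_len_range)))
        for _ in range(cfg.quad_acr_two):
            plant("two", leaf_ids[:2], int(rng.integers(*cfg.acr_len_range)))
            plant("two", leaf_ids[2:], int(rng.integers(*cfg.acr_len_range)))
        for _ in range(cfg.quad_acr_unique):
            owner = leaf_ids[int(rng.integers(0, 4))]
            plant("unique", [owner], int(rng.integers(*cfg.acr_len_range)))

        for gid in leaf_ids:
            L = loci[gid]
            genome[L["chrom"]] = L["seq"]
            genes.extend(L["genes"])
        quad_rows.append(
            {"set_id": sid, **{f"gene{j + 1}": g for j, g in enumerate(leaf_ids)}}
        )
        a, b, c, d = leaf_ids
        tree_map[sid] = f"(({a}:1,{b}:1):2,({c}:1,{d}:1):2);"

    return SynthGenome(
        genome=genome,
        genes=sorted(genes, key=lambda g: (g.chrom, g.start)),
        acrs=acrs,
        pairs=pd.DataFrame(pair_rows),
        quads=pd.DataFrame(quad_rows),
        trees=tree_map,
        acr_truth=pd.DataFrame(truth_rows),
        quad_acr_truth=pd.DataFrame(qtruth_rows),
    )


# ---------------------------------------------------------------------------
# expression

_LOG2_MU0 = 7.0  # baseline log2 mean; library scaling keeps CPM near this scale
_LOG2_SD = 2.5


def _latent_stats(c1: np.ndarray, c2: np.ndarray) -> tuple[float, float, float]:
    """(r, m, s) computed exactly as the pattern pipeline computes them."""
    fc = np.log2((c1 + 1.0) / (c2 + 1.0))
    m = abs(float(fc.mean()))
    s = float(fc.std(ddof=1))
    p1, p2 = np.log2(c1 + 1.0), np.log2(c2 + 1.0)
    if p1.std() == 0 or p2.std() == 0:
        return float("nan"), m, s
    r = float(np.corrcoef(p1, p2)[0, 1])
    return r, m, s


def _draw_latents(
    label: str, n_ct: int, rng: np.random.Generator, max_tries: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Latent per-cell-type mean profiles for one pair, certified to satisfy
    the label's rule region with margin on the noise-free statistics."""
    zeros = np.zeros(n_ct)
    for _ in range(max_tries):
        x = rng.normal(_LOG2_MU0, _LOG2_SD, n_ct)
        if label == "non_expressed":
            return zeros, zeros
        if label == "mono_expressed":
            return np.power(2.0, x), zeros
        if label == "dosage_balanced":
            y = x.copy()
            ok = lambda r, m, s: r >= 0.95 and m <= 0.7 and s <= 0.7
        elif label == "paralogue_dominance":
            y = x + 2.0 * (1 if rng.random() < 0.5 else -1)
            ok = lambda r, m, s: r >= 0.95 and m >= 1.3 and s <= 0.7
        elif label == "specialization":
            y = x + 3.5 * (x >= np.median(x))
            ok = lambda r, m, s: r >= 0.95 and m >= 1.3 and s >= 1.3
        elif label == "divergence":
            sign = 1 if rng.random() < 0.5 else -1
            z = rng.normal(0.0, 1.0, n_ct)
            x = _LOG2_MU0 + 1.5 * z
            z2 = rng.normal(0.0, 1.0, n_ct)
            y = (_LOG2_MU0 - 3.0 * sign) + 1.5 * (-0.6 * z + 0.8 * z2)
            ok = lambda r, m, s: r <= 0.40 and m >= 1.3 and s >= 1.3
        elif label == "others":
            # balanced +/- offset: m stays ~0 while s is large, which lands in
            # "others" for every value of r
            delta = np.where(x >= np.median(x), 2.4, -2.4)
            if n_ct % 2 == 1:
                delta[np.argmin(x)] = -2.4
            y = x + delta
            ok = lambda r, m, s: m <= 0.6 and s >= 1.4
        else:
            raise ValueError(f"unknown pattern label {label!r}")
        c1, c2 = np.power(2.0, x), np.power(2.0, y)
        r, m, s = _latent_stats(c1, c2)
        if ok(r, m, s):
            return c1, c2
    raise RuntimeError(f"could not realize label {label!r} within margin")


def gen_expression(
    cfg: SynthConfig, pairs: pd.DataFrame, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, CountsTable], pd.DataFrame]:
    """Per-tissue pseudobulk counts with planted pattern labels per pair."""
    if cfg.cell_types < 3:
        raise ValueError("need >=3 cell types for pattern statistics")
    rng = rng or np.random.default_rng(cfg.seed + 1)
    labels = list(cfg.pattern_mix)
    probs = np.array([cfg.pattern_mix[k] for k in labels], dtype=float)
    probs /= probs.sum()
    cts = cfg.cell_type_names
    samples = [f"{ct}.r{k + 1}" for ct in cts for k in range(cfg.replicates)]
    counts_by_tissue: dict[str, CountsTable] = {}
    truth_rows = []
    gene_order = [g for row in pairs.itertuples(index=False) for g in (row.gene1, row.gene2)]
    for tissue in cfg.tissues:
        lat = np.zeros((len(gene_order), cfg.cell_types))
        for p_idx, row in enumerate(pairs.itertuples(index=False)):
            label = labels[int(rng.choice(len(labels), p=probs))]
            c1, c2 = _draw_latents(label, cfg.cell_types, rng)
            lat[2 * p_idx] = c1
            lat[2 * p_idx + 1] = c2
            truth_rows.append(
                {
                    "pair_id": getattr(row, "pair_id", f"pair{p_idx:04d}"),
                    "gene1": row.gene1,
                    "gene2": row.gene2,
                    "tissue": tissue,
                    "label": label,
                }
            )
        # scale latent means so one pseudobulk library is ~1e6 (CPM ~ latent)
        col_tot = lat.sum(axis=0)
        scale = 1e6 / col_tot.mean() if col_tot.mean() > 0 else 1.0
        lat *= scale
        mat = np.zeros((len(gene_order), len(samples)), dtype=np.int64)
        for ci, ct in enumerate(cts):
            mean = lat[:, ci]
            for k in range(cfg.replicates):
                col = ci * cfg.replicates + k
                mat[:, col] = _nb_draw(mean, cfg.nb_dispersion, rng)
        df = pd.DataFrame(mat, index=gene_order, columns=samples)
        counts_by_tissue[tissue] = CountsTable(df)
    return counts_by_tissue, pd.DataFrame(truth_rows)


def _nb_draw(mean: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(len(mean), dtype=np.int64)
    pos = mean > 0
    if phi <= 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        r = 1.0 / phi
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


# ---------------------------------------------------------------------------
# trajectories

def _scenario_vectors(
    scenario: int, n_ct: int, rng: np.random.Generator
) -> np.ndarray:
    """Planted 4 x n_ct binary specificity vectors for one scenario.

    Groups occupy disjoint cell-type blocks (size 4; size 3 for the
    four-group scenario), drawn on a per-quad random permutation of the cell
    types, so between-group Jaccard distances are maximal by construction.
    """
    if n_ct < 12:
        raise ValueError("trajectory planting needs >=12 cell types")
    perm = rng.permutation(n_ct)
    b4 = [perm[0:4], perm[4:8], perm[8:12]]
    b3 = [perm[0:3], perm[3:6], perm[6:9], perm[9:12]]

    def vec(block):
        v = np.zeros(n_ct, dtype=np.int8)
        v[block] = 1
        return v

    if scenario == 1:
        rows = [vec(b4[0])] * 4
    elif scenario == 2:
        rows = [vec(b4[0])] * 2 + [vec(b4[1])] * 2
    elif scenario == 3:
        rows = [vec(b4[0])] * 3 + [vec(b4[1])]
    elif scenario == 4:
        rows = [vec(b4[0])] * 2 + [vec(b4[1]), vec(b4[2])]
    elif scenario == 5:
        rows = [vec(b) for b in b3]
    else:
        raise ValueError(f"unknown scenario {scenario}")
    return np.array(rows)


def gen_trajectories(
    cfg: SynthConfig,
    quads: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    flip_rate: float = 0.0,
    synth: Optional[SynthGenome] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[AcrInterval], CountsTable]:
    """Planted specificity matrix, truth, ctACRs and realizing counts.

    Returns (de_flags: gene x cell type binary frame with optional bit-flip
    noise, truth frame with the planted scenario per set, matching ctACRs,
    pseudobulk counts whose DE analysis reproduces the noise-free matrix).
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    scen = sorted(cfg.scenario_mix)
    p = np.array([cfg.scenario_mix[s] for s in scen], dtype=float)
    p /= p.sum()
    cts = cfg.cell_type_names
    rows, truth = [], []
    gene_ids: list[str] = []
    for row in quads.itertuples(index=False):
        genes = [row.gene1, row.gene2, row.gene3, row.gene4]
        if any(not g for g in genes):
            raise ValueError(f"set {row.set_id}: needs 4 expressed genes")
        s = int(scen[int(rng.choice(len(scen), p=p))])
        mat = _scenario_vectors(s, cfg.cell_types, rng)
        rows.append(mat)
        gene_ids.extend(genes)
        truth.append({"set_id": row.set_id, "scenario": s})
    clean = np.vstack(rows)
    noisy = clean.copy()
    if flip_rate > 0:
        flips = rng.random(noisy.shape) < flip_rate
        noisy = noisy ^ flips
    de_flags = pd.DataFrame(noisy.astype(np.int8), index=gene_ids, columns=cts)

    # counts realizing the clean matrix: baseline mean, 8x in specific cell types
    base, boost = 50.0, 8.0
    samples = [f"{ct}.r{k + 1}" for ct in cts for k in range(cfg.replicates)]
    mean = base * (1.0 + (boost - 1.0) * clean.astype(float))
    mat = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    for ci in range(len(cts)):
        for k in range(cfg.replicates):
            mat[:, ci * cfg.replicates + k] = _nb_draw(mean[:, ci], cfg.nb_dispersion, rng)
    counts = CountsTable(pd.DataFrame(mat, index=gene_ids, columns=samples))

    ct_acrs: list[AcrInterval] = []
    if synth is not None:
        gene_by_id = {g.gene_id: g for g in synth.genes}
        for gid, vec in zip(gene_ids, clean):
            if gid not in gene_by_id or vec.sum() == 0:
                continue
            g = gene_by_id[gid]
            ct = cts[int(np.flatnonzero(vec)[0])]
            start = max(0, g.start - 120)
            ct_acrs.append(
                AcrInterval(f"{gid}_ctacr", g.chrom, start, g.start - 20, ct_label=ct)
            )
    return de_flags, pd.DataFrame(truth), ct_acrs, counts


# ---------------------------------------------------------------------------
# accessibility

def gen_accessibility(
    acr_ids: Sequence[str],
    conditions: Sequence[str],
    rng: np.random.Generator,
    turnover: float = 0.2,
    p_base: float = 0.9,
) -> pd.DataFrame:
    """Binary ACR x condition presence with controlled cross-condition turnover.

    The first condition's presences are Bernoulli(p_base); each subsequent
    condition flips every presence bit of the first with probability
    ``turnover``. turnover=0 gives identical profiles.
    """
    base = rng.random(len(acr_ids)) < p_base
    cols = {conditions[0]: base.astype(np.int8)}
    for cond in conditions[1:]:
        flips = rng.random(len(acr_ids)) < turnover
        cols[cond] = (base ^ flips).astype(np.int8)
    return pd.DataFrame(cols, index=list(acr_ids))


# ---------------------------------------------------------------------------
# writing a complete synthetic study to disk

def simulate_study(cfg: SynthConfig, outdir) -> dict:
    """Generate and write a full synthetic study; returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    synth = gen_duplicated_genome(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    counts, expr_truth = gen_expression(cfg, synth.pairs, rng)
    rng2 = np.random.default_rng(cfg.seed + 2)
    de_flags, traj_truth, ct_acrs, traj_counts = gen_trajectories(
        cfg, synth.quads, rng2, synth=synth
    )
    rng3 = np.random.default_rng(cfg.seed + 3)
    pair_ids = synth.pairs["pair_id"].tolist()
    acr_ids_by_pair = {
        pid: synth.acr_truth.loc[synth.acr_truth["pair_id"] == pid, "acr_id"].tolist()
        for pid in pair_ids
    }
    access_rows = []
    for pid in pair_ids:
        ids = acr_ids_by_pair[pid]
        if not ids:
            continue
        prof = gen_accessibility(ids, list(cfg.tissues), rng3)
        for aid in prof.index:
            for cond in prof.columns:
                access_rows.append(
                    {"entity": pid, "acr_id": aid, "condition": cond,
                     "present": int(prof.loc[aid, cond])}
                )

    write_fasta(out / "genome.fa", synth.genome)
    write_gff3(out / "genes.gff3", synth.genes)
    write_bed(out / "acrs.bed", synth.acrs)
    write_bed(out / "ct_acrs.bed", ct_acrs)
    write_pairs(out / "pairs.tsv", synth.pairs)
    write_quads(out / "quads.tsv", synth.quads)
    trees_dir = out / "trees"
    trees_dir.mkdir(exist_ok=True)
    for sid, nwk in synth.trees.items():
        write_newick(trees_dir / f"{sid}.nwk", nwk)
    for tissue, tab in counts.items():
        tab.to_tsv(out / f"counts_{tissue}.tsv")
    traj_counts.to_tsv(out / "counts_trajectory.tsv")
    de_flags.to_csv(out / "specificity.tsv", sep="\t")
    pd.DataFrame(access_rows).to_csv(out / "accessibility.tsv", sep="\t", index=False)
    synth.acr_truth.to_csv(out / "truth_acr.tsv", sep="\t", index=False)
    synth.quad_acr_truth.to_csv(out / "truth_quad_acr.tsv", sep="\t", index=False)
    expr_truth.to_csv(out / "truth_expression.tsv", sep="\t", index=False)
    traj_truth.to_csv(out / "truth_trajectory.tsv", sep="\t", index=False)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "n_genes": len(synth.genes),
        "n_acrs": len(synth.acrs),
        "n_pairs": int(len(synth.pairs)),
        "n_quads": int(len(synth.quads)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
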