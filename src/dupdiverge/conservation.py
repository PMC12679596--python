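"""ACR sequence-conservation scoring between duplicated genes.

Each ACR is associated with its nearest gene. For a duplicate pair the ACRs
of one gene are aligned (blastn-short scheme, see :mod:`dupdiverge.align`)
against the partner's *reference region* -- the genomic span from the
partner's nearest upstream neighbour gene to its nearest downstream
neighbour gene. The BLASTed ratio B is the fraction of the query ACR covered
by accepted HSPs (union of non-overlapping query spans, greedy by score);
the mismatch rate M is mismatches over the reference-side aligned length of
the same HSP set. B > 0.1 defines a conserved ACR.

For 4-gene whole-genome-duplication sets each ACR is aligned against the
reference regions of the other 3 genes; the number of alignments with
B > 0.1 is its conservation count (0 -> unique, 1 -> two_copy,
2 or 3 -> multi_copy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import DEFAULT_SCHEME, Hsp, ScoringScheme, local_align
from .io import AcrInterval, GeneModel, get_sequence

CONSERVED_B = 0.1
STATE_BY_COUNT = {0: "unique", 1: "two_copy", 2: "multi_copy", 3: "multi_copy"}


@dataclass
class AcrConservation:
    acr_id: str
    target_gene: str
    blasted_ratio: float
    mismatch_rate: float  # nan when unBLASTed
    conserved: bool
    conservation_count: Optional[int] = None
    state: Optional[str] = None


# ---------------------------------------------------------------------------
# association and reference regions

def associate_acrs(
    acrs: Sequence[AcrInterval], genes: Sequence[GeneModel]
) -> dict[str, str]:
    """Map each ACR to its nearest gene.

    Distance is 0 for overlap, else the gap between closest interval ends.
    Ties break lexicographically by gene_id. ACRs on chromosomes with no
    genes are left unassigned (with a warning).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.gene_id))

    out: dict[str, str] = {}
    for acr in acrs:
        cands = by_chrom.get(acr.chrom)
        if not cands:
            warnings.warn(f"ACR {acr.acr_id}: no genes on {acr.chrom}; unassigned")
            continue
        best_d, best_id = None, None
        for g in cands:  # chromosomes hold few genes; linear scan is exact
            d = interval_gap(acr.start, acr.end, g.start, g.end)
            if best_d is None or d < best_d or (d == best_d and g.gene_id < best_id):
                best_d, best_id = d, g.gene_id
        out[acr.acr_id] = best_id
    return out


def interval_gap(a0: int, a1: int, b0: int, b1: int) -> int:
    """Gap between two half-open intervals; 0 if they overlap or touch."""
    if a1 <= b0:
        return b0 - a1
    if b1 <= a0:
        return a0 - b1
    return 0


def reference_region(
    gene: GeneModel,
    genes: Sequence[GeneModel],
    chrom_length: Optional[int] = None,
) -> tuple[str, int, int]:
    """Span from the nearest upstream neighbour's start to the nearest
    downstream neighbour's end (inclusive of the gene body), clipped to
    chromosome bounds for terminal genes."""
    same = sorted(
        (g for g in genes if g.chrom == gene.chrom), key=lambda g: (g.start, g.gene_id)
    )
    idx = next(i for i, g in enumerate(same) if g.gene_id == gene.gene_id)
    start = same[idx - 1].start if idx > 0 else 0
    if idx + 1 < len(same):
        end = same[idx + 1].end
    else:
        end = chrom_length if chrom_length is not None else gene.end
    return gene.chrom, min(start, gene.start), max(end, gene.end)


# ---------------------------------------------------------------------------
# metrics

def conservation_metrics(
    hsps: Sequence[Hsp], query_len: int, conserved_b: float = CONSERVED_B
) -> tuple[float, float, bool]:
    """(B, M, conserved) from an HSP table.

    HSPs are reduced greedily by score to a set with non-overlapping query
    coverage. B = covered query length / query_len. M = total mismatches /
    total reference-side aligned length over that set (nan if no HSPs).
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    chosen: list[Hsp] = []
    covered: list[tuple[int, int]] = []
    for h in sorted(hsps, key=lambda h: (-h.score, h.q_start)):
        if all(h.q_end <= s or h.q_start >= e for s, e in covered):
            chosen.append(h)
            covered.append((h.q_start, h.q_end))
    if not chosen:
        return 0.0, float("nan"), False
    cov = sum(e - s for s, e in covered)
    ref_len = sum(h.r_end - h.r_start for h in chosen)
    mism = sum(h.mismatches for h in chosen)
    B = cov / query_len
    M = mism / ref_len if ref_len > 0 else float("nan")
    return B, M, B > conserved_b


def score_acr(
    acr: AcrInterval,
    genome,
    ref_chrom: str,
    ref_start: int,
    ref_end: int,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    conserved_b: float = CONSERVED_B,
    mask_self: bool = False,
) -> tuple[float, float, bool]:
    """Align one ACR against a reference region and reduce to (B, M, conserved).

    With ``mask_self`` HSPs whose reference span overlaps the ACR's own
    genomic interval are discarded (tandem self-hit control; the faithful
    default keeps them).
    """
    query = get_sequence(genome, acr.chrom, acr.start, acr.end)
    ref = get_sequence(genome, ref_chrom, ref_start, ref_end)
    hsps = local_align(query, ref, scheme=scheme)
    if mask_self and acr.chrom == ref_chrom:
        hsps = [
            h
            for h in hsps
            if interval_gap(
                acr.start, acr.end, ref_start + h.r_start, ref_start + h.r_end
            )
            > 0
        ]
    return conservation_metrics(hsps, acr.length, conserved_b)


# ---------------------------------------------------------------------------
# pair- and quad-level summaries

def pair_acr_summary(
    pair: tuple[str, str],
    acrs_by_gene: dict[str, list[AcrInterval]],
    genome,
    genes: Sequence[GeneModel],
    chrom_lengths: Optional[dict[str, int]] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    conserved_b: float = CONSERVED_B,
    mask_self: bool = False,
) -> dict:
    """Fig-3C-F style statistics for one duplicate pair.

    Every ACR of gene1 is aligned against gene2's reference region and vice
    versa. Returns fraction conserved, mean B and M over conserved ACRs,
    fraction unBLASTed, and large/small ACR-count groups; NA fields when the
    pair has no associated ACRs.
    """
    g1, g2 = pair
    gene_by_id = {g.gene_id: g for g in genes}
    n1 = len(acrs_by_gene.get(g1, []))
    n2 = len(acrs_by_gene.get(g2, []))
    rec = {
        "gene1": g1,
        "gene2": g2,
        "n_acrs": n1 + n2,
        "large_count": max(n1, n2),
        "small_count": min(n1, n2),
        "frac_conserved": float("nan"),
        "mean_B_conserved": float("nan"),
        "mean_M_conserved": float("nan"),
        "frac_unblasted": float("nan"),
    }
    if n1 + n2 == 0:
        return rec
    Bs, Ms, unb = [], [], 0
    for src, tgt in ((g1, g2), (g2, g1)):
        if tgt not in gene_by_id:
            continue
        tgt_gene = gene_by_id[tgt]
        clen = (chrom_lengths or {}).get(tgt_gene.chrom)
        if clen is None and not isinstance(genome, dict):
            clen = len(genome[tgt_gene.chrom])
        elif clen is None:
            clen = len(genome[tgt_gene.chrom])
        rchrom, r0, r1 = reference_region(tgt_gene, genes, clen)
        for acr in acrs_by_gene.get(src, []):
            B, M, cons = score_acr(
                acr, genome, rchrom, r0, r1, scheme, conserved_b, mask_self
            )
            if B == 0.0:
                unb += 1
            if cons:
                Bs.append(B)
                Ms.append(M)
    total = n1 + n2
    rec["frac_conserved"] = len(Bs) / total
    rec["frac_unblasted"] = unb / total
    if Bs:
        rec["mean_B_conserved"] = float(np.mean(Bs))
        rec["mean_M_conserved"] = float(np.mean(Ms))
    return rec


def quad_conservation(
    quad_genes: Sequence[str],
    acrs_by_gene: dict[str, list[AcrInterval]],
    genome,
    genes: Sequence[GeneModel],
    chrom_lengths: Optional[dict[str, int]] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    conserved_b: float = CONSERVED_B,
) -> list[AcrConservation]:
    """Conservation count and state for every ACR of a 4-gene set.

    Each ACR is aligned against the reference regions of the other 3 genes;
    the per-alignment records carry each target's B/M, and the consolidated
    per-ACR record carries the count and state. Returns one record per
    (ACR, target) plus the consolidated state in every record.
    """
    if len(quad_genes) != 4:
        raise ValueError("quad must have exactly 4 genes")
    gene_by_id = {g.gene_id: g for g in genes}
    regions = {}
    for gid in quad_genes:
        g = gene_by_id[gid]
        clen = (chrom_lengths or {}).get(g.chrom) or len(genome[g.chrom])
        regions[gid] = reference_region(g, genes, clen)
    out: list[AcrConservation] = []
    for gid in quad_genes:
        others = [t for t in quad_genes if t != gid]
        for acr in acrs_by_gene.get(gid, []):
            per_target = []
            for tgt in others:
                rchrom, r0, r1 = regions[tgt]
                B, M, cons = score_acr(acr, genome, rchrom, r0, r1, scheme, conserved_b)
                per_target.append((tgt, B, M, cons))
            count = sum(1 for _, _, _, c in per_target if c)
            state = STATE_BY_COUNT[count]
            for tgt, B, M, cons in per_target:
                out.append(
                    AcrConservation(
                        acr_id=acr.acr_id, target_gene=tgt, blasted_ratio=B,
                        mismatch_rate=M, conserved=cons,
                        conservation_count=count, state=state,
                    )
                )
    return out


def quad_state_summary(records: list[AcrConservation]) -> pd.DataFrame:
    """Per-state mean B and M over conserved alignments, plus ACR counts."""
    df = pd.DataFrame(
        [
            {
                "acr_id": r.acr_id,
                "target_gene": r.target_gene,
                "B": r.blasted_ratio,
                "M": r.mismatch_rate,
                "conserved": r.conserved,
                "count": r.conservation_count,
                "state": r.state,
            }
            for r in records
        ]
    )
    if df.empty:
        return df
    cons = df[df["conserved"]]
    grp = cons.groupby("state")[["B", "M"]].mean().rename(
        columns={"B": "mean_B", "M": "mean_M"}
    )
    n_acrs = df.drop_duplicates("acr_id").groupby("state")["acr_id"].count()
    grp["n_acrs"] = n_acrs
    if "unique" not in grp.index:
        uniq = df[df["state"] == "unique"].drop_duplicates("acr_id")
        if len(uniq):
            grp.loc["unique"] = [float("nan"), float("nan"), len(uniq)]
    return grp.reset_index()
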