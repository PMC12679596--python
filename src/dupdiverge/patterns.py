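"""Per-tissue expression-pattern classification of duplicate pairs.

The per-tissue pipeline: replicate-QC on cell types (Spearman rho > 0.75),
CPM normalization, low-expression filtering, then for each duplicated pair
three statistics over cell types --

* r: Pearson correlation of the two genes' log2(CPM+1) replicate-averaged
  profiles (the coexpression value),
* m: absolute mean of the per-cell-type log2 fold change
  log2((cpm1+1)/(cpm2+1)),
* s: sample standard deviation of those fold changes --

and the 6+1 category rules:

=====================  =========================================
non_expressed          both genes not expressed
mono_expressed         exactly one gene expressed (r is NA)
dosage_balanced        r > 0.9, m < 1, s < 1
paralogue_dominance    r > 0.9, m >= 1, s < 1
specialization         r > 0.9, m >= 1, s >= 1
divergence             r < 0.5, m >= 1, s >= 1
others                 any expressed pair matching no rule
=====================  =========================================

Simplified categories: non, mono, correlated (dosage_balanced,
paralogue_dominance, specialization), uncorrelated (divergence, others).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from . import de
from .io import CountsTable

QC_RHO = 0.75
COEXPR_HIGH = 0.9
COEXPR_LOW = 0.5
FC_THRESHOLD = 1.0
SD_THRESHOLD = 1.0

PATTERNS = (
    "non_expressed",
    "mono_expressed",
    "dosage_balanced",
    "paralogue_dominance",
    "specialization",
    "divergence",
    "others",
)

SIMPLIFIED = {
    "non_expressed": "non",
    "mono_expressed": "mono",
    "dosage_balanced": "correlated",
    "paralogue_dominance": "correlated",
    "specialization": "correlated",
    "divergence": "uncorrelated",
    "others": "uncorrelated",
}


@dataclass
class PairStats:
    r: float  # nan encodes NA
    m: float
    s: float
    expressed1: bool
    expressed2: bool


@dataclass
class PatternCall:
    pattern: str
    simplified: str
    tissue: str = ""


def qc_cell_types(counts: CountsTable, rho_min: float = QC_RHO) -> tuple[CountsTable, pd.DataFrame]:
    """Drop cell types whose replicate Spearman correlation is <= rho_min.

    With more than two replicates the minimum pairwise correlation is used.
    Raises if no cell type survives.
    """
    report = []
    keep = []
    for ct in counts.cell_types:
        reps = counts.replicates_of(ct)
        if len(reps) < 2:
            raise ValueError(f"cell type {ct!r} has fewer than 2 replicates")
        rhos = []
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                rho = spearmanr(counts.df[reps[i]], counts.df[reps[j]]).statistic
                rhos.append(rho)
        rho = float(np.min(rhos))
        passed = rho > rho_min  # boundary value fails
        report.append({"cell_type": ct, "rho": rho, "kept": passed})
        if passed:
            keep.append(ct)
    if not keep:
        raise ValueError("no cell types pass QC")
    return counts.subset_cell_types(keep), pd.DataFrame(report)


def cpm_normalize(counts: CountsTable) -> pd.DataFrame:
    """Counts-per-million per sample; column sums are exactly 1e6."""
    libs = counts.df.sum(axis=0)
    zero = libs[libs <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    return counts.df / libs * 1e6


def filter_low_expression(
    cpm: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2
) -> tuple[pd.Index, pd.Index]:
    """(retained genes, non-expressed genes).

    A gene is retained iff CPM >= min_cpm in >= min_samples samples;
    all-zero genes are the non-expressed set.
    """
    n_ok = (cpm >= min_cpm).sum(axis=1)
    retained = cpm.index[n_ok >= min_samples]
    non_expressed = cpm.index[(cpm == 0).all(axis=1)]
    return retained, non_expressed


def celltype_mean_cpm(counts: CountsTable, cpm: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged CPM per cell type."""
    cols = {}
    for ct in counts.cell_types:
        cols[ct] = cpm[counts.replicates_of(ct)].mean(axis=1)
    return pd.DataFrame(cols)


def pair_stats(
    mean_cpm: pd.DataFrame,
    gene1: str,
    gene2: str,
    expressed: set | pd.Index,
) -> PairStats:
    """Coexpression r, |mean| m and SD s of per-cell-type log2 fold change."""
    if mean_cpm.shape[1] < 3:
        raise ValueError("need >=3 cell types for pair statistics")
    e1, e2 = gene1 in expressed, gene2 in expressed
    c1 = mean_cpm.loc[gene1].to_numpy(dtype=float)
    c2 = mean_cpm.loc[gene2].to_numpy(dtype=float)
    fc = np.log2((c1 + 1.0) / (c2 + 1.0))
    m = abs(float(np.mean(fc)))
    s = float(np.std(fc, ddof=1))
    r = float("nan")
    if e1 and e2:
        p1, p2 = np.log2(c1 + 1.0), np.log2(c2 + 1.0)
        if np.std(p1) > 0 and np.std(p2) > 0:
            r = float(pearsonr(p1, p2).statistic)
    return PairStats(r=r, m=m, s=s, expressed1=e1, expressed2=e2)


def classify_pair(stats: PairStats, tissue: str = "") -> PatternCall:
    """Apply the 6+1 category rules in order; total on all inputs."""
    if not stats.expressed1 and not stats.expressed2:
        p = "non_expressed"
    elif stats.expressed1 != stats.expressed2:
        p = "mono_expressed"
    else:
        r, m, s = stats.r, stats.m, stats.s
        if math.isnan(r):
            p = "others"  # both expressed but degenerate profile
        elif r > COEXPR_HIGH and m < FC_THRESHOLD and s < SD_THRESHOLD:
            p = "dosage_balanced"
        elif r > COEXPR_HIGH and m >= FC_THRESHOLD and s < SD_THRESHOLD:
            p = "paralogue_dominance"
        elif r > COEXPR_HIGH and m >= FC_THRESHOLD and s >= SD_THRESHOLD:
            p = "specialization"
        elif r < COEXPR_LOW and m >= FC_THRESHOLD and s >= SD_THRESHOLD:
            p = "divergence"
        else:
            p = "others"
    return PatternCall(pattern=p, simplified=SIMPLIFIED[p], tissue=tissue)


def classify_pairs(
    counts: CountsTable,
    pairs: pd.DataFrame,
    tissue: str = "",
    rho_min: float = QC_RHO,
) -> pd.DataFrame:
    """QC -> CPM -> filter -> per-pair stats and calls, one tissue.

    Returns a frame with one row per pair: r, m, s, pattern, simplified.
    Pairs whose genes are absent from the counts are treated as
    non-expressed for the missing gene.
    """
    qc_counts, _ = qc_cell_types(counts, rho_min)
    cpm = cpm_normalize(qc_counts)
    retained, _non = filter_low_expression(cpm)
    mean_cpm = celltype_mean_cpm(qc_counts, cpm)
    expressed = set(retained)
    rows = []
    for row in pairs.itertuples(index=False):
        g1, g2 = row.gene1, row.gene2
        missing = [g for g in (g1, g2) if g not in mean_cpm.index]
        if missing:
            sub = mean_cpm.reindex([g1, g2]).fillna(0.0)
            st = pair_stats(sub, g1, g2, expressed - set(missing))
        else:
            st = pair_stats(mean_cpm, g1, g2, expressed)
        call = classify_pair(st, tissue)
        rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "tissue": tissue,
                "r": st.r,
                "m": st.m,
                "s": st.s,
                "pattern": call.pattern,
                "simplified": call.simplified,
            }
        )
    return pd.DataFrame(rows)


def shared_categories(simplified_calls: Sequence[str]) -> int:
    """Number of distinct simplified categories shared across conditions.

    ``non`` is dropped from the multiset when any expressed category is
    present; the count is 1 with category ``non`` only when every condition
    is non-expressed. Permutation-invariant in its conditions.
    """
    calls = list(simplified_calls)
    if any(c is None or (isinstance(c, float) and math.isnan(c)) for c in calls):
        raise ValueError("missing condition call")
    cats = set(calls)
    if cats == {"non"}:
        return 1
    cats.discard("non")
    return len(cats)


def celltype_specific_genes(
    counts: CountsTable,
    seed: int | np.random.Generator = 0,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binary gene x cell-type matrix of cell-type-specific expression.

    Per cell type, the target pseudobulk replicates are tested against an
    equal number of randomly sampled replicates pooled from the other cell
    types (NB exact test, conditional-ML common dispersion, BH across
    genes); an entry is 1 iff log2FC > lfc_min and adjusted p < alpha.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cts = counts.cell_types
    if len(cts) < 2:
        raise ValueError("need at least 2 cell types")
    mat = de.scale_to_common_library(counts.df.to_numpy())
    scaled = pd.DataFrame(mat, index=counts.df.index, columns=counts.df.columns)
    out = pd.DataFrame(0, index=counts.df.index, columns=cts, dtype=np.int8)
    for ct in cts:
        target_cols = counts.replicates_of(ct)
        other_cols = [c for c in counts.df.columns if c not in target_cols]
        pick = rng.choice(len(other_cols), size=len(target_cols), replace=False)
        ctrl_cols = [other_cols[i] for i in sorted(pick)]
        res = de.nb_exact_test(
            scaled[target_cols].to_numpy(), scaled[ctrl_cols].to_numpy()
        )
        hit = (res["log2fc"] > lfc_min) & (res["padj"] < alpha)
        out.loc[hit, ct] = 1
    return out
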