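"""Accessibility-profile overlap across conditions and ctACR matching.

An accessibility profile is a binary ACR x condition matrix: presence means
the ACR was called accessible in that condition (developmental stage or
organ). Turnover is measured as Jaccard distance between the per-condition
present-ACR sets, averaged over the unordered condition pairs (a pooled
variant -- shared = present in all, total = present in any -- is available
behind a flag).
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AcrInterval


def jaccard_distance(profile: pd.DataFrame, pooled: bool = False) -> float:
    """Mean pairwise Jaccard distance of per-condition present-ACR sets.

    ``profile``: binary ACR x condition frame (>=2 conditions). Returns NaN
    for an entity with no ACR present anywhere. ACRs absent everywhere do
    not affect the value.
    """
    if profile.shape[1] < 2:
        raise ValueError("need at least 2 conditions")
    mat = profile.to_numpy(dtype=bool)
    if not mat.any():
        return float("nan")
    if pooled:
        inter = mat.all(axis=1).sum()
        union = mat.any(axis=1).sum()
        return 1.0 - inter / union
    dists = []
    for a, b in itertools.combinations(range(mat.shape[1]), 2):
        union = (mat[:, a] | mat[:, b]).sum()
        if union == 0:
            # neither condition has any ACR: identical (empty) sets
            dists.append(0.0)
        else:
            inter = (mat[:, a] & mat[:, b]).sum()
            dists.append(1.0 - inter / union)
    return float(np.mean(dists))


def profile_from_condition_sets(
    acr_ids: Sequence[str], presence: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Build a binary profile from per-condition lists of present ACR ids."""
    conds = list(presence)
    df = pd.DataFrame(0, index=list(acr_ids), columns=conds, dtype=np.int8)
    for cond, ids in presence.items():
        hit = [i for i in ids if i in df.index]
        df.loc[hit, cond] = 1
    return df


def match_ctacrs(
    gene_specificity: pd.DataFrame,
    ctacrs: Sequence[AcrInterval],
    association: Mapping[str, str],
) -> pd.DataFrame:
    """Match cell-type-specific ACRs to cell-type-specific genes.

    A (gene, ACR, cell type) triple is emitted iff the ACR is associated to
    the gene and its ct_label names a cell type where the gene's specificity
    entry is 1. Unknown cell-type labels raise, listing the vocabulary.
    """
    vocab = set(gene_specificity.columns)
    rows = []
    for acr in ctacrs:
        if acr.ct_label is None:
            continue
        if acr.ct_label not in vocab:
            raise ValueError(
                f"unknown cell type {acr.ct_label!r}; vocabulary: {sorted(vocab)}"
            )
        gene = association.get(acr.acr_id)
        if gene is None or gene not in gene_specificity.index:
            continue
        if gene_specificity.loc[gene, acr.ct_label] == 1:
            rows.append({"gene": gene, "acr_id": acr.acr_id, "cell_type": acr.ct_label})
    return pd.DataFrame(rows, columns=["gene", "acr_id", "cell_type"])
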