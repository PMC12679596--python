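"""Evolutionary-trajectory inference for 4-gene whole-genome-duplication sets.

The four genes of a quad are clustered on their binary cell-type-specificity
vectors (Jaccard distance, Ward.D2 agglomeration); the cluster count and the
cluster-size ratio map to five scenarios of when cell-type-specific
expression arose:

* k=1                -> before the first WGD round            (scenario 1)
* k=2, sizes 2:2     -> before the second WGD round           (scenario 2)
* k=2, sizes 1:3     -> after the second WGD round            (scenario 3)
* k=3, sizes 1:2:1   -> combination of the above              (scenario 4)
* k=4                -> complex integration of the processes  (scenario 5)

Recent pairs come from the gene tree (the two sister-leaf pairs); in strict
mode a 2:2 split must coincide with them, otherwise the set is unresolved.

k selection: candidate partitions per k are the exact Ward-objective
minimizers (n <= 4 makes exhaustive enumeration over the 15 set partitions
cheap, and it coincides with agglomerative Ward except on contrived ties);
a partition is admissible only if no cluster holds two genes farther apart
than ``max_within`` (default 0.7). Among admissible partitions the average
silhouette width decides (singletons contribute 0; ties prefer more
clusters), except that a set whose diameter is at most ``k1_distance``
(default 0.5) is a single cluster outright -- silhouette is undefined at
k=1, and these absolute-distance guards are what distinguish "one noisy
cluster" from genuine splits, which no scale-free score can do.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .io import FamilyTree

SCENARIO_NAMES = {
    1: "before_first_WGD",
    2: "before_second_WGD",
    3: "after_second_WGD",
    4: "combination",
    5: "complex",
    0: "unresolved",
}

K1_DISTANCE = 0.5
MAX_WITHIN = 0.7


@dataclass
class ClusterResult:
    k: int
    partition: list[list[str]]  # gene ids per cluster
    heights: list[float]  # Ward.D2 merge heights (Lance-Williams)
    silhouettes: dict[int, float]
    wss: dict[int, float]  # within-cluster sum of squared distances (elbow)


@dataclass
class TrajectoryCall:
    set_id: str
    k: int
    sizes: list[int]
    scenario: int
    scenario_name: str
    partition: dict[str, int]
    recent_match: Optional[bool] = None


def recent_pair_partition(
    tree: FamilyTree, quad_genes: Sequence[str]
) -> Optional[tuple[frozenset, frozenset]]:
    """The two sister-leaf pairs of the quad, or None if unresolved.

    A caterpillar topology or polytomy over the 4 genes lacks two cherries
    and yields None (the set is excluded with a warning upstream).
    """
    quad = set(quad_genes)
    cherries = [c for c in tree.cherries() if c <= quad]
    if len(cherries) != 2 or (cherries[0] & cherries[1]):
        return None
    if cherries[0] | cherries[1] != quad:
        return None
    return cherries[0], cherries[1]


def specificity_matrix(
    de_flags: pd.DataFrame, quad_genes: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Clustering input: quad rows of the binary matrix, all-zero rows removed.

    Returns (matrix of non-zero rows, list of removed all-zero genes).
    """
    sub = de_flags.loc[list(quad_genes)]
    zero = sub.index[(sub == 0).all(axis=1)]
    return sub.drop(index=zero), list(zero)


def _set_partitions(items: list) -> list[list[list]]:
    if len(items) == 1:
        return [[[items[0]]]]
    first, rest = items[0], items[1:]
    out = []
    for part in _set_partitions(rest):
        for i in range(len(part)):
            out.append(part[:i] + [[first] + part[i]] + part[i + 1 :])
        out.append([[first]] + part)
    return out


def ward_objective(D: np.ndarray, partition: list[list[int]]) -> float:
    """Distance-form Ward criterion: sum_C (1/|C|) sum_{i<j in C} d_ij^2."""
    tot = 0.0
    for cl in partition:
        if len(cl) > 1:
            tot += sum(D[a, b] ** 2 for a, b in itertools.combinations(cl, 2)) / len(cl)
    return tot


def mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width; singleton clusters contribute 0."""
    n = len(labels)
    vals = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            continue
        a = float(np.mean([D[i, j] for j in same]))
        b = min(
            float(np.mean([D[i, j] for j in range(n) if labels[j] == lab]))
            for lab in set(labels)
            if lab != labels[i]
        )
        denom = max(a, b)
        vals[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(vals.mean())


def cluster_genes(
    matrix: pd.DataFrame,
    k1_distance: float = K1_DISTANCE,
    max_within: float = MAX_WITHIN,
) -> ClusterResult:
    """Ward.D2 clustering of binary specificity rows with k selection."""
    genes = list(matrix.index)
    n = len(genes)
    if n < 2:
        raise ValueError("need >=2 rows to cluster")
    X = matrix.to_numpy(dtype=bool)
    cond = pdist(X, metric="jaccard")
    D = squareform(cond)
    heights = linkage(cond, method="ward")[:, 2].tolist()

    # exact Ward-optimal partition per k (n <= 4 in practice)
    best_by_k: dict[int, list[list[int]]] = {}
    for part in _set_partitions(list(range(n))):
        k = len(part)
        if k not in best_by_k or ward_objective(D, part) < ward_objective(
            D, best_by_k[k]
        ):
            best_by_k[k] = part

    wss = {k: ward_objective(D, p) for k, p in best_by_k.items()}

    if D.max() <= k1_distance:
        return ClusterResult(1, [genes], heights, {}, wss)

    cands = {}
    for k, part in best_by_k.items():
        if k == 1:
            continue
        diam = max(
            (D[a, b] for cl in part for a, b in itertools.combinations(cl, 2)),
            default=0.0,
        )
        if diam <= max_within or k == n:
            cands[k] = part
    sils = {}
    for k, part in cands.items():
        labels = np.empty(n, dtype=int)
        for c, cl in enumerate(part):
            labels[cl] = c
        sils[k] = mean_silhouette(D, labels)
    best = max(sils.values())
    k = max(kk for kk, v in sils.items() if v == best)  # ties: more clusters
    partition = [[genes[i] for i in cl] for cl in cands[k]]
    return ClusterResult(k, partition, heights, sils, wss)


def call_trajectory(
    set_id: str,
    cluster: ClusterResult,
    zero_genes: Sequence[str] = (),
    recent_pairs: Optional[tuple[frozenset, frozenset]] = None,
    strict_recent_split: bool = True,
) -> TrajectoryCall:
    """Map cluster structure to a scenario.

    All-zero rows removed before clustering rejoin as one extra
    "no-specificity" group for size accounting, so {specific x3 identical,
    zero x1} yields sizes {3,1} -> scenario 3.
    """
    partition = [list(cl) for cl in cluster.partition]
    if zero_genes:
        partition = partition + [list(zero_genes)]
    k = len(partition)
    sizes = sorted(len(cl) for cl in partition)
    scenario = 0
    recent_match: Optional[bool] = None
    if k == 1:
        scenario = 1
    elif sizes == [2, 2]:
        scenario = 2
        if recent_pairs is not None:
            split = {frozenset(cl) for cl in partition}
            recent_match = split == {frozenset(p) for p in recent_pairs}
            if strict_recent_split and not recent_match:
                scenario = 0
    elif sizes == [1, 3]:
        scenario = 3
    elif sizes == [1, 1, 2]:
        scenario = 4
    elif sizes == [1, 1, 1, 1]:
        scenario = 5
    gene_to_cluster = {g: c for c, cl in enumerate(partition) for g in cl}
    return TrajectoryCall(
        set_id=set_id,
        k=k,
        sizes=sizes,
        scenario=scenario,
        scenario_name=SCENARIO_NAMES[scenario],
        partition=gene_to_cluster,
        recent_match=recent_match,
    )


def infer_trajectory(
    set_id: str,
    de_flags: pd.DataFrame,
    quad_genes: Sequence[str],
    tree: Optional[FamilyTree] = None,
    strict_recent_split: bool = True,
    k1_distance: float = K1_DISTANCE,
    max_within: float = MAX_WITHIN,
) -> TrajectoryCall:
    """End-to-end call for one quad: matrix -> clustering -> scenario."""
    matrix, zero = specificity_matrix(de_flags, quad_genes)
    recent = recent_pair_partition(tree, quad_genes) if tree is not None else None
    if tree is not None and recent is None:
        return TrajectoryCall(
            set_id=set_id, k=0, sizes=[], scenario=0,
            scenario_name=SCENARIO_NAMES[0], partition={}, recent_match=None,
        )
    if len(matrix) < 2:
        # clustering skipped; scenario from row identity only
        cluster = ClusterResult(
            max(1, len(matrix)), [list(matrix.index)] if len(matrix) else [], [], {}, {}
        )
    else:
        cluster = cluster_genes(matrix, k1_distance, max_within)
    return call_trajectory(
        set_id, cluster, zero, recent, strict_recent_split=strict_recent_split
    )
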