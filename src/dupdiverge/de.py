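"""Negative-binomial exact testing for pseudobulk differential expression.

The two-group test conditions on the per-gene sum of group totals: with
replicate counts NB(mu, phi), the group totals are NB with size n/phi, and
under the null of equal means the conditional distribution of one total
given the sum is a Polya (beta-binomial-like) law that depends only on phi.
The two-sided p-value is the double-tail mass of outcomes no more probable
than the observed split. The common dispersion is estimated by maximizing
the within-group conditional likelihood given the group sums, summed over
genes (qCML-style) -- with two replicates per group a moment estimator is
far too noisy.

Counts are assumed to share a common library scale; callers with unequal
library sizes should pre-scale (see :func:`scale_to_common_library`).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.optimize import minimize_scalar
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests


def scale_to_common_library(counts: np.ndarray) -> np.ndarray:
    """Scale columns to their geometric-mean library size and round."""
    libs = counts.sum(axis=0).astype(float)
    if (libs <= 0).any():
        raise ValueError("zero library size")
    target = np.exp(np.log(libs).mean())
    return np.rint(counts * (target / libs)).astype(np.int64)


def common_dispersion(groups: list[np.ndarray]) -> float:
    """Conditional-ML common dispersion over genes.

    ``groups``: list of (genes x replicates) integer arrays, one per
    experimental group. Returns phi >= 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if g.shape[1] >= 2]
    if not groups:
        return 0.0

    def cll(phi: float) -> float:
        r = 1.0 / phi
        tot = 0.0
        for Y in groups:
            n = Y.shape[1]
            s = Y.sum(axis=1)
            tot += (
                gammaln(Y + r).sum(axis=1)
                - n * gammaln(r)
                + gammaln(n * r)
                - gammaln(s + n * r)
            ).sum()
        return tot

    res = minimize_scalar(
        lambda d: -cll(d / (1 - d)), bounds=(1e-6, 0.95), method="bounded"
    )
    d = float(res.x)
    phi = d / (1 - d)
    # boundary -> effectively Poisson
    return 0.0 if phi < 2e-6 else phi


def nb_exact_pvalue(y_a: int, y_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p-value for group totals y_a vs y_b."""
    s = y_a + y_b
    if s == 0:
        return 1.0
    y = np.arange(s + 1)
    if phi <= 0:
        pmf = binom.pmf(y, s, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        lp = (
            gammaln(y + r_a)
            - gammaln(y + 1)
            + gammaln(s - y + r_b)
            - gammaln(s - y + 1)
        )
        lp -= lp.max()
        pmf = np.exp(lp)
        pmf /= pmf.sum()
    return float(min(1.0, pmf[pmf <= pmf[y_a] * (1 + 1e-12)].sum()))


def nb_exact_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    dispersion: float | None = None,
    pseudo: float = 0.5,
) -> dict[str, np.ndarray]:
    """Per-gene exact test of group A vs group B pseudobulk counts.

    Returns dict with ``pvalue``, ``padj`` (Benjamini-Hochberg across
    genes), ``log2fc`` (A over B, on per-replicate means with a pseudo
    count) and the dispersion used.
    """
    A = np.asarray(counts_a, dtype=np.int64)
    B = np.asarray(counts_b, dtype=np.int64)
    if A.shape[0] != B.shape[0]:
        raise ValueError("gene dimensions differ")
    n_a, n_b = A.shape[1], B.shape[1]
    if dispersion is None:
        dispersion = common_dispersion([A, B])
    ya, yb = A.sum(axis=1), B.sum(axis=1)
    pvals = np.array(
        [nb_exact_pvalue(int(a), int(b), n_a, n_b, dispersion) for a, b in zip(ya, yb)]
    )
    padj = multipletests(pvals, method="fdr_bh")[1]
    log2fc = np.log2((ya / n_a + pseudo) / (yb / n_b + pseudo))
    return {
        "pvalue": pvals,
        "padj": padj,
        "log2fc": log2fc,
        "dispersion": dispersion,
    }
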