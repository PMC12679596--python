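"""NB exact test and cell-type-specific gene calling."""

import numpy as np
import pandas as pd
import pytest

from dupdiverge import de
from dupdiverge.io import CountsTable
from dupdiverge.patterns import celltype_specific_genes


def test_exact_pvalue_symmetric_and_bounded():
    p = de.nb_exact_pvalue(30, 30, 2, 2, 0.05)
    assert p == pytest.approx(1.0, abs=1e-9)
    p_hi = de.nb_exact_pvalue(300, 30, 2, 2, 0.05)
    assert 0 < p_hi < 0.05
    assert de.nb_exact_pvalue(30, 300, 2, 2, 0.05) == pytest.approx(p_hi, rel=1e-9)
    assert de.nb_exact_pvalue(0, 0, 2, 2, 0.05) == 1.0


def test_poisson_limit_matches_binomial():
    p = de.nb_exact_pvalue(40, 10, 2, 2, 0.0)
    from scipy.stats import binomtest

    want = binomtest(40, 50, 0.5).pvalue
    assert p == pytest.approx(want, rel=1e-6)


def test_common_dispersion_recovers_truth(rng):
    phi = 0.1
    mu = rng.lognormal(np.log(400), 0.8, 400)
    r = 1 / phi
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), (400, 4))
    est = de.common_dispersion([counts[:, :2], counts[:, 2:]])
    assert est == pytest.approx(phi, rel=0.35)


def test_identical_counts_never_specific(rng):
    mat = np.tile(rng.integers(50, 500, 30)[:, None], (1, 8))
    cols = [f"ct{c}.r{k}" for c in range(1, 5) for k in range(1, 3)]
    flags = celltype_specific_genes(CountsTable(pd.DataFrame(mat, columns=cols)), seed=0)
    assert int(flags.to_numpy().sum()) == 0


def test_strong_enrichment_is_flagged(rng):
    n = 60
    mat = np.full((n, 8), 200)
    mat = rng.poisson(mat).astype(np.int64)
    mat[0, :2] = rng.poisson(200 * 100, 2)  # 100x in ct1
    cols = [f"ct{c}.r{k}" for c in range(1, 5) for k in range(1, 3)]
    flags = celltype_specific_genes(CountsTable(pd.DataFrame(mat, columns=cols)), seed=0)
    assert flags.iloc[0, 0] == 1
    assert flags.iloc[1:, :].to_numpy().sum() == 0


def test_single_cell_type_raises(rng):
    mat = rng.integers(0, 10, (5, 2))
    tab = CountsTable(pd.DataFrame(mat, columns=["ct1.r1", "ct1.r2"]))
    with pytest.raises(ValueError):
        celltype_specific_genes(tab, seed=0)
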