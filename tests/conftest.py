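import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from xenatlas.io import CountMatrix
from xenatlas.simulate import AtlasConfig, generate_atlas

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 barcodes x 3 genes with full metadata."""
    values = np.array(
        [
            [5, 0, 2],
            [0, 3, 1],
            [7, 7, 7],
            [1, 0, 0],
        ]
    )
    meta = pd.DataFrame(
        {
            "batch": ["b1"] * 4,
            "stage": ["NF48", "NF48", "NF59", "NF59"],
            "tissue": ["gut"] * 4,
            "cell_type": ["t1", "t2", "t1", "t2"],
            "lineage": ["l1", "l2", "l1", "l2"],
        },
        index=pd.Index(["bc1", "bc2", "bc3", "bc4"], name="barcode"),
    )
    return CountMatrix(sp.csr_matrix(values), meta.index, pd.Index(["gA", "gB", "gC"]), meta)


@pytest.fixture(scope="session")
def small_atlas():
    """One modest synthetic atlas shared by read-only tests."""
    cfg = AtlasConfig(
        lineages={k: 200 for k in ("epi", "imm", "neu")},
        n_genes=300,
        n_tfs=70,
        planted_tfs_per_lineage=10,
        module_genes_per_archetype=20,
        n_empty_barcodes=800,
        seed=7,
    )
    cm, truth = generate_atlas(cfg)
    return cfg, cm, truth


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def jsd_oracle(p, q) -> float:
    """Direct-summation base-2 JSD, term by term."""
    import math

    total = 0.0
    for pi, qi in zip(p, q):
        mi = 0.5 * (pi + qi)
        if pi > 0:
            total += 0.5 * pi * math.log2(pi / mi)
        if qi > 0:
            total += 0.5 * qi * math.log2(qi / mi)
    return total


def bh_oracle(pvals):
    """Step-up BH with explicit sorting and cumulative minimum."""
    import numpy as np

    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(n)
    out[order] = ranked
    return out


def hypergeom_tail_oracle(k, N, K, n) -> float:
    """P(X >= k) by summing the exact pmf via binomial coefficients."""
    from math import comb

    denom = comb(N, n)
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return num / denom
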