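"""Gene-set over-representation by the one-sided hypergeometric test.

Given a query gene set, a term -> gene-set annotation (plain two-column
table, no ontology graph), and a gene universe, each term's overlap is scored
with the upper-tail hypergeometric probability P(X >= k) and corrected across
terms with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import ValidationError


@dataclass
class EnrichmentResult:
    """Per-term overlap counts, hypergeometric p and BH-adjusted q."""

    table: pd.DataFrame  # term, k, K, n, N, p, q, significant

    def to_frame(self) -> pd.DataFrame:
        return self.table


def hypergeom_pval(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for overlap k, universe N, term size K, query n."""
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"impossible overlap k={k} for K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    query,
    terms: dict,
    universe,
    alpha: float = 0.05,
    flag_on: str = "adjusted",
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation of ``query`` in ``terms``.

    ``query`` must be a subset of ``universe``; term gene sets are intersected
    with the universe first.  Rows are flagged significant when the adjusted
    (default) or raw p falls below ``alpha``.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValidationError(f"query genes outside the universe: {extra}")
    if flag_on not in ("adjusted", "raw"):
        raise ValidationError("flag_on must be 'adjusted' or 'raw'")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in terms.items():
        in_universe = set(genes) & universe
        K = len(in_universe)
        k = len(in_universe & query)
        p = hypergeom_pval(k, N, K, n) if K else 1.0
        rows.append((term, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"]).set_index("term")
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df["significant"] = (df["q"] if flag_on == "adjusted" else df["p"]) < alpha
    return EnrichmentResult(table=df.sort_values(["p", "term"]))


def read_term_table(path) -> dict:
    """Two-column (term, gene) TSV -> term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    return {t: set(g["gene"]) for t, g in df.groupby("term")}
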