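"""Count normalization and pseudocell aggregation.

Two normalizations are used downstream: the log2(CPM/100 + 1) transform
(equivalently log2 counts-per-10k + 1) for clustering-style analyses, and
plain total-count scaling to 100,000 for cross-species comparison inputs.
Pseudocells average groups of ~50 same-cell-type cells on the linear
normalized scale to damp noise and outliers before cross-species work.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, ExpressionMatrix, ValidationError, log


def _check_totals(cm: CountMatrix) -> np.ndarray:
    totals = cm.totals()
    zero = totals == 0
    if zero.any():
        names = cm.barcodes[zero][:5].tolist()
        raise ValidationError(
            f"{int(zero.sum())} barcodes have zero total counts "
            f"(e.g. {names}); filter before normalizing"
        )
    return totals


def lognormalize(cm: CountMatrix) -> ExpressionMatrix:
    """log2((count / total) * 10,000 + 1), i.e. log2(CPM/100 + 1)."""
    totals = _check_totals(cm)
    x = cm.values.astype(float).tocsr()
    scale = 1e4 / totals
    x = sp.diags(scale) @ x
    x.data = np.log2(x.data + 1.0)
    return ExpressionMatrix(x, cm.barcodes, cm.genes, "log2cp10k")


def total_normalize(cm: CountMatrix, target: int = 100_000) -> ExpressionMatrix:
    """Scale every barcode to sum to ``target`` (default 100,000)."""
    totals = _check_totals(cm)
    x = sp.diags(target / totals) @ cm.values.astype(float).tocsr()
    return ExpressionMatrix(x, cm.barcodes, cm.genes, "cp100k")


def subsample_cells(
    cm: CountMatrix, n: int, seed: int = 0
) -> CountMatrix:
    """Randomly keep ``n`` barcodes without replacement (noise/outlier control
    before pseudocell construction); a no-op when ``n`` >= barcode count."""
    if n >= cm.n_barcodes:
        return cm
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(cm.n_barcodes, size=n, replace=False))
    return cm.subset_barcodes(np.isin(np.arange(cm.n_barcodes), idx))


@dataclass
class PseudocellMatrix:
    """Averaged profiles of fixed-size same-cell-type cell groups."""

    values: pd.DataFrame  # pseudocell x gene
    members: dict  # pseudocell id -> list of source barcodes
    group_key: str = "cell_type"

    def __post_init__(self) -> None:
        seen: set = set()
        for pc, mem in self.members.items():
            dup = seen.intersection(mem)
            if dup:
                raise ValidationError(f"barcode(s) {sorted(dup)[:3]} in multiple pseudocells")
            seen.update(mem)

    def to_frame(self) -> pd.DataFrame:
        return self.values


def make_pseudocells(
    em: ExpressionMatrix,
    meta: pd.DataFrame,
    group_size: int = 50,
    min_group: int = 10,
    seed: int = 0,
    group_key: str = "cell_type",
) -> PseudocellMatrix:
    """Average every ``group_size`` cells of the same cell type.

    Within each cell type, barcodes are shuffled (seeded) and partitioned into
    consecutive groups of ``group_size``; the last group may be smaller, and
    groups under ``min_group`` members are dropped with a warning.  Averaging
    happens on the matrix's own (linear cp100k) scale, so pseudocell rows stay
    on the simplex.
    """
    labels = meta.loc[em.barcodes, group_key]
    if labels.isna().any():
        bad = em.barcodes[labels.isna().to_numpy()][:5].tolist()
        raise ValidationError(f"missing {group_key} labels for barcodes {bad}")
    rng = np.random.default_rng(seed)
    X = em.values.tocsr()
    rows, members = {}, {}
    eff_min = min(min_group, group_size)  # a full group is never dropped
    for ct in sorted(labels.unique()):
        idx = np.flatnonzero((labels == ct).to_numpy())
        rng.shuffle(idx)
        for start in range(0, len(idx), group_size):
            chunk = idx[start : start + group_size]
            if len(chunk) < eff_min:
                log.warning(
                    "dropping remainder group of %d < %d cells for %s",
                    len(chunk), eff_min, ct,
                )
                continue
            pc_id = f"{ct}.pc{start // group_size:03d}"
            rows[pc_id] = np.asarray(X[chunk].mean(axis=0)).ravel()
            members[pc_id] = em.barcodes[chunk].tolist()
    values = pd.DataFrame.from_dict(rows, orient="index", columns=em.genes)
    return PseudocellMatrix(values=values, members=members, group_key=group_key)
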