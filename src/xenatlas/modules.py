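"""Gene-trajectory module analysis across metamorphic stages.

The procedure: differentially expressed genes between stages are averaged per
stage, standardized, and softly clustered with fuzzy c-means; every cell is
then scored for each cluster's gene set against expression-matched control
genes; repeated subsampled Wilcoxon rank-sum tests against the first stage
give per-stage averaged p-values; after Benjamini-Hochberg correction,
clusters with any q below a strict threshold are classified into four
modules by one-sided tests:

* module 1 — highest expression at the metamorphic climax (NF59),
* module 2 — lowest expression at the climax,
* module 3 — consistently downregulated across stages,
* module 4 — consistently upregulated across stages.

Clusters passing no directional pattern stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError, log

MODULE_LABELS = {1: "climax_peak", 2: "climax_trough", 3: "monotone_down", 4: "monotone_up"}


# ---------------------------------------------------------------------------
# stage DEGs


def find_stage_degs(
    em: ExpressionMatrix,
    meta: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    logfc_threshold: float = 0.1,
    min_pct: float = 0.1,
    alpha: float = 0.05,
) -> pd.Index:
    """Genes differentially expressed between two stages.

    A gene is kept iff it is detected in at least ``min_pct`` of cells in one
    of the stages, its natural-log fold change ``ln(mean(2^x - 1) + 1)``
    difference exceeds ``logfc_threshold`` in magnitude, and its two-sided
    Wilcoxon rank-sum BH-adjusted p is below ``alpha`` (the BH family being
    the genes that pass the first two filters).
    """
    labels = meta.loc[em.barcodes, "stage"]
    ia = np.flatnonzero((labels == stage_a).to_numpy())
    ib = np.flatnonzero((labels == stage_b).to_numpy())
    for stage, idx in ((stage_a, ia), (stage_b, ib)):
        if len(idx) < 3:
            raise ValidationError(f"stage {stage!r} has {len(idx)} cells (< 3)")
    X = em.dense()
    Xa, Xb = X[ia], X[ib]
    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    lin_a = np.exp2(Xa) - 1.0
    lin_b = np.exp2(Xb) - 1.0
    lfc = np.log(lin_a.mean(axis=0) + 1.0) - np.log(lin_b.mean(axis=0) + 1.0)
    tested = ((pct_a >= min_pct) | (pct_b >= min_pct)) & (np.abs(lfc) >= logfc_threshold)
    if not tested.any():
        return pd.Index([], name="gene")
    cols = np.flatnonzero(tested)
    p = mannwhitneyu(Xa[:, cols], Xb[:, cols], alternative="two-sided", axis=0).pvalue
    p = np.atleast_1d(p)
    q = multipletests(p, method="fdr_bh")[1]
    keep = cols[q < alpha]
    return pd.Index(em.genes[keep], name="gene")


# ---------------------------------------------------------------------------
# stage averaging


def stage_average(
    em: ExpressionMatrix,
    meta: pd.DataFrame,
    stages,
    standardize: bool = True,
):
    """Per-stage averaged expression profiles for clustering.

    Values are de-logged (2^x - 1), averaged per stage, re-logged as
    log2(mean + 1), then (by default) each gene's row is standardized to zero
    mean and unit variance across stages.  Constant rows cannot be
    standardized; they are dropped and returned separately.

    Returns ``(profiles, dropped)``: a gene x stage DataFrame and the Index of
    excluded constant genes (empty when ``standardize=False``).
    """
    labels = meta.loc[em.barcodes, "stage"]
    lin = em.linear()
    cols = {}
    for s in stages:
        idx = np.flatnonzero((labels == s).to_numpy())
        if len(idx) == 0:
            raise ValidationError(f"stage {s!r} has no cells")
        cols[s] = np.log2(lin[idx].mean(axis=0) + 1.0)
    prof = pd.DataFrame(cols, index=em.genes)
    if not standardize:
        return prof, pd.Index([], name="gene")
    sd = prof.std(axis=1, ddof=1)
    dropped = prof.index[sd == 0]
    if len(dropped):
        log.warning("excluding %d constant genes from clustering", len(dropped))
    prof = prof.loc[sd > 0]
    prof = prof.sub(prof.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return prof, dropped


# ---------------------------------------------------------------------------
# fuzzy c-means


@dataclass
class FuzzyClustering:
    """Soft clustering of stage profiles: centers, memberships, objective."""

    centers: pd.DataFrame  # cluster x stage
    membership: pd.DataFrame  # gene x cluster
    fuzzifier: float
    n_iter: int
    objective: float
    objectives: list

    def __post_init__(self) -> None:
        U = self.membership.to_numpy()
        if not np.allclose(U.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("membership rows must sum to 1")
        obj = np.asarray(self.objectives)
        if len(obj) > 1 and np.any(np.diff(obj) > 1e-9 * np.maximum(obj[:-1], 1.0)):
            raise ValidationError("fuzzy c-means objective increased between iterations")

    def hard_assignment(self) -> pd.Series:
        """Cluster of maximal membership per gene."""
        return self.membership.idxmax(axis=1)


def _memberships(D: np.ndarray, m: float) -> np.ndarray:
    # u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)); exact zero distance
    # concentrates membership on the zero-distance cluster(s)
    zero = D <= 0
    U = np.empty_like(D)
    with np.errstate(divide="ignore"):
        W = D ** (-2.0 / (m - 1.0))
    ok = ~zero.any(axis=1)
    U[ok] = W[ok] / W[ok].sum(axis=1, keepdims=True)
    bad = ~ok
    if bad.any():
        U[bad] = zero[bad] / zero[bad].sum(axis=1, keepdims=True)
    return U


def fuzzy_cmeans(
    X: pd.DataFrame,
    c: int,
    m: float = 1.25,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> FuzzyClustering:
    """Fuzzy c-means over standardized gene x stage profiles.

    Standard alternating updates with Euclidean distance: memberships from
    current centers, then centers as membership^m-weighted means, until the
    largest center shift falls below ``tol``.  Centers initialize from ``c``
    distinct data rows (seeded).  The recorded objective sequence
    J = sum u^m d^2 is non-increasing by construction.
    """
    A = X.to_numpy(dtype=float)
    if not np.isfinite(A).all():
        raise ValidationError("non-finite values in clustering input")
    n = A.shape[0]
    if c < 2 or c >= n:
        raise ValidationError(f"need 2 <= c < n_genes, got c={c}, n={n}")
    if m <= 1:
        raise ValidationError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    centers = A[rng.choice(n, size=c, replace=False)].copy()
    # break exact duplicates in the initial centers
    centers += 1e-9 * rng.standard_normal(centers.shape)

    D = cdist(A, centers)
    objectives = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        U = _memberships(D, m)
        Um = U**m
        denom = Um.sum(axis=0)[:, None]
        new_centers = (Um.T @ A) / np.where(denom > 0, denom, 1.0)
        D = cdist(A, new_centers)
        objectives.append(float((Um * D**2).sum()))
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    U = _memberships(D, m)
    cluster_ids = [f"c{j:02d}" for j in range(c)]
    return FuzzyClustering(
        centers=pd.DataFrame(centers, index=cluster_ids, columns=X.columns),
        membership=pd.DataFrame(U, index=X.index, columns=cluster_ids),
        fuzzifier=m,
        n_iter=n_iter,
        objective=objectives[-1],
        objectives=objectives,
    )


# ---------------------------------------------------------------------------
# module scores


def module_score(
    em: ExpressionMatrix,
    gene_set,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-set score against expression-matched controls.

    Genes are binned into ``n_bins`` equal-frequency bins by average
    expression across all cells; each set gene contributes up to ``n_ctrl``
    control genes drawn from its bin (the whole bin when it is small).  The
    score is the mean expression over the set minus the mean over the pooled
    controls, per cell.
    """
    gene_set = [g for g in gene_set]
    if len(gene_set) == 0:
        raise ValidationError("empty gene set")
    missing = set(gene_set) - set(em.genes)
    if missing:
        raise ValidationError(f"gene set not in matrix: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    X = em.dense()
    avg = pd.Series(X.mean(axis=0), index=em.genes)
    n_bins_eff = min(n_bins, avg.nunique())
    bins = pd.qcut(avg.rank(method="first"), n_bins_eff, labels=False)
    bin_members = {b: avg.index[bins == b] for b in range(n_bins_eff)}
    control: list = []
    for g in gene_set:
        pool = bin_members[int(bins[g])]
        if len(pool) <= n_ctrl:
            control.extend(pool)
        else:
            control.extend(rng.choice(pool, size=n_ctrl, replace=False))
    set_idx = em.genes.get_indexer(gene_set)
    ctrl_idx = em.genes.get_indexer(control)
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=em.barcodes, name="module_score")


# ---------------------------------------------------------------------------
# resampled Wilcoxon testing


def _resampled_pair_p(
    scores: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    n: int,
    n_tests: int,
    rng: np.random.Generator,
    alternative: str,
) -> float:
    na, nb = min(n, len(idx_a)), min(n, len(idx_b))
    draws_a = np.stack([rng.choice(idx_a, size=na, replace=False) for _ in range(n_tests)])
    draws_b = np.stack([rng.choice(idx_b, size=nb, replace=False) for _ in range(n_tests)])
    res = mannwhitneyu(scores[draws_a], scores[draws_b], alternative=alternative, axis=1)
    return float(np.mean(res.pvalue))


def resampling_stage_test(
    scores: pd.Series,
    meta: pd.DataFrame,
    ref_stage: str,
    stages=None,
    n_tests: int = 1000,
    n_low: int = 150,
    n_high: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> pd.Series:
    """Averaged p of repeated subsampled Wilcoxon tests vs the reference stage.

    Per iteration, ``n = clamp(min stage size, n_low, n_high)`` cells are
    drawn without replacement from the reference stage and the same number
    from the comparison stage; the rank-sum p-values of ``n_tests`` such
    iterations are averaged per stage.
    """
    labels = meta.loc[scores.index, "stage"]
    if stages is None:
        stages = [s for s in labels.dropna().unique()]
        stages = sorted(stages)
    if ref_stage not in stages:
        stages = [ref_stage] + [s for s in stages if s != ref_stage]
    idx = {s: np.flatnonzero((labels == s).to_numpy()) for s in stages}
    for s, i in idx.items():
        if len(i) < 3:
            raise ValidationError(f"stage {s!r} has {len(i)} cells (< 3)")
        if len(i) < n_low:
            log.warning("stage %s has %d < %d cells; using all of them", s, len(i), n_low)
    n = int(min(n_high, max(n_low, min(len(i) for i in idx.values()))))
    rng = np.random.default_rng(seed)
    vals = scores.to_numpy(dtype=float)
    out = {}
    for s in stages:
        if s == ref_stage:
            continue
        out[s] = _resampled_pair_p(
            vals, idx[ref_stage], idx[s], n, n_tests, rng, alternative
        )
    return pd.Series(out, name="avg_p")


# ---------------------------------------------------------------------------
# module classification


@dataclass
class ModuleAssignment:
    """Cluster -> module calls with the supporting averaged p / q values."""

    cluster_module: dict  # cluster -> 1..4 or "unassigned"
    gene_module: pd.Series  # gene -> module (or "unassigned")
    stage_p: pd.DataFrame  # cluster x stage averaged two-sided p
    stage_q: pd.DataFrame  # BH-adjusted
    significant: dict  # cluster -> bool

    def __post_init__(self) -> None:
        for cl, mod in self.cluster_module.items():
            if mod not in (1, 2, 3, 4, "unassigned"):
                raise ValidationError(f"bad module label {mod!r} for {cl}")
            if mod != "unassigned" and not self.significant.get(cl, False):
                raise ValidationError(f"cluster {cl} assigned module {mod} but not significant")

    def genes_in_module(self, module) -> set:
        return set(self.gene_module.index[self.gene_module == module])

    def to_dict(self) -> dict:
        return {
            "cluster_module": {k: v for k, v in self.cluster_module.items()},
            "gene_module": {k: v for k, v in self.gene_module.items()},
            "stage_p": {c: self.stage_p.loc[c].to_dict() for c in self.stage_p.index},
            "stage_q": {c: self.stage_q.loc[c].to_dict() for c in self.stage_q.index},
            "significant": {k: bool(v) for k, v in self.significant.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleAssignment":
        def _coerce(v):
            return v if v == "unassigned" else int(v)

        return cls(
            cluster_module={k: _coerce(v) for k, v in d["cluster_module"].items()},
            gene_module=pd.Series(
                {k: _coerce(v) for k, v in d["gene_module"].items()}, dtype=object
            ),
            stage_p=pd.DataFrame.from_dict(d["stage_p"], orient="index"),
            stage_q=pd.DataFrame.from_dict(d["stage_q"], orient="index"),
            significant=d["significant"],
        )


def classify_modules(
    fc: FuzzyClustering,
    scores_by_cluster: dict,
    meta: pd.DataFrame,
    stages,
    climax_stage: str | None = None,
    q_threshold: float = 1e-10,
    direction_alpha: float = 0.05,
    n_tests: int = 1000,
    n_low: int = 150,
    n_high: int = 1000,
    seed: int = 0,
) -> ModuleAssignment:
    """Classify clusters into the four trajectory modules.

    Two-sided averaged p-values (every stage vs the first) are BH-corrected
    over all (cluster, stage) pairs; clusters with any q below ``q_threshold``
    are tested one-sidedly (same resampling machinery, averaged p compared to
    ``direction_alpha``) for the four patterns, in order: climax-peak,
    climax-trough, monotone-down, monotone-up.  Genes inherit the module of
    their maximal-membership cluster.
    """
    stages = list(stages)
    if len(stages) < 3:
        raise ValidationError("module classification needs >= 3 stages")
    if climax_stage is None:
        climax_stage = stages[-2]
    if climax_stage not in stages:
        raise ValidationError(f"climax stage {climax_stage!r} not among stages {stages}")
    ref = stages[0]
    clusters = list(scores_by_cluster)

    rows = {}
    for cl in clusters:
        rows[cl] = resampling_stage_test(
            scores_by_cluster[cl], meta, ref, stages=stages,
            n_tests=n_tests, n_low=n_low, n_high=n_high,
            seed=seed + 1 + clusters.index(cl),
        )
    stage_p = pd.DataFrame(rows).T
    flat = stage_p.to_numpy().ravel()
    q = multipletests(flat, method="fdr_bh")[1].reshape(stage_p.shape)
    stage_q = pd.DataFrame(q, index=stage_p.index, columns=stage_p.columns)
    significant = {cl: bool((stage_q.loc[cl] < q_threshold).any()) for cl in clusters}

    cluster_module = {}
    for ci, cl in enumerate(clusters):
        if not significant[cl]:
            cluster_module[cl] = "unassigned"
            continue
        scores = scores_by_cluster[cl]
        stage_idx = {
            s: np.flatnonzero((meta.loc[scores.index, "stage"] == s).to_numpy())
            for s in stages
        }
        n = int(min(n_high, max(n_low, min(len(i) for i in stage_idx.values()))))
        rng = np.random.default_rng(seed + 10_000 + ci)
        vals = scores.to_numpy(dtype=float)

        def pair_p(sa: str, sb: str, alternative: str) -> float:
            # p for "stage sa <alternative> stage sb" on the score distribution
            return _resampled_pair_p(
                vals, stage_idx[sa], stage_idx[sb], n, n_tests, rng, alternative
            )

        others = [s for s in stages if s != climax_stage]
        consecutive = list(zip(stages[:-1], stages[1:]))
        module: "int | str" = "unassigned"
        if all(pair_p(climax_stage, s, "greater") < direction_alpha for s in others):
            module = 1
        elif all(pair_p(climax_stage, s, "less") < direction_alpha for s in others):
            module = 2
        elif all(pair_p(sb, sa, "less") < direction_alpha for sa, sb in consecutive):
            module = 3
        elif all(pair_p(sb, sa, "greater") < direction_alpha for sa, sb in consecutive):
            module = 4
        cluster_module[cl] = module

    hard = fc.hard_assignment()
    gene_module = hard.map(lambda cl: cluster_module.get(cl, "unassigned")).astype(object)
    gene_module.name = "module"
    return ModuleAssignment(
        cluster_module=cluster_module,
        gene_module=gene_module,
        stage_p=stage_p,
        stage_q=stage_q,
        significant=significant,
    )


def shared_gene_frequency(modules_by_celltype: dict) -> pd.DataFrame:
    """Count, per gene and module, how many cell types carry the gene.

    ``modules_by_celltype`` maps cell type -> module -> gene set.  Returns a
    table with columns (gene, module, freq) sorted by freq descending then
    gene; genes absent everywhere do not appear.
    """
    counts: dict = {}
    for ct, by_mod in modules_by_celltype.items():
        for mod, genes in by_mod.items():
            for g in genes:
                counts[(g, mod)] = counts.get((g, mod), 0) + 1
    if not counts:
        return pd.DataFrame(columns=["gene", "module", "freq"])
    df = pd.DataFrame(
        [(g, m, f) for (g, m), f in counts.items()], columns=["gene", "module", "freq"]
    )
    return df.sort_values(["freq", "gene"], ascending=[False, True]).reset_index(drop=True)
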