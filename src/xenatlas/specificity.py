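"""Jensen-Shannon-divergence specificity scores for transcription factors.

A TF's cross-group expression profile (mean expression per lineage or cell
type, normalized to a probability vector) is compared against each group's
indicator distribution with the base-2 Jensen-Shannon divergence; the
specificity score is ``1 - sqrt(JSD)``, which is 1 exactly when the TF is
expressed in that single group and 0 when it is absent from it.  Z-scoring a
TF's scores across groups yields the ranking used to call group-specific TFs,
and ortholog maps intersect those calls across species into conserved TFs.

The reference distribution (a one-hot indicator per group) is the pivotal
modeling choice here: the score form ``1 - sqrt(JSD)`` only lands in [0, 1]
against an indicator with base-2 logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, OrthologMap, ValidationError, log


@dataclass
class SpecificityTable:
    """Gene x group specificity scores, raw ([0,1]) or z-scored per gene."""

    scores: pd.DataFrame
    scale: str  # "raw" | "zscore"
    group_kind: str = "lineage"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "zscore"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.scale == "raw":
            vals = self.scores.to_numpy()
            if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
                raise ValidationError("raw specificity scores must lie in [0, 1]")

    @property
    def groups(self) -> list:
        return list(self.scores.columns)

    def to_frame(self) -> pd.DataFrame:
        return self.scores


def _validate_dist(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{name} does not sum to 1 (sum={p.sum()!r})")
    return p


def jsd(p, q) -> float:
    """Base-2 Jensen-Shannon divergence between two distributions, in [0, 1].

    0*log(0) terms are treated as 0.
    """
    p = _validate_dist(p, "p")
    q = _validate_dist(q, "q")
    if p.shape != q.shape:
        raise ValidationError("p and q must have the same length")
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))

    return 0.5 * _kl(p) + 0.5 * _kl(q)


def group_mean_profile(
    em: ExpressionMatrix, meta: pd.DataFrame, group_key: str
) -> pd.DataFrame:
    """Mean expression of each gene per group, on the linear normalized scale.

    log2cp10k input is de-logged (2^x - 1) before averaging.
    """
    labels = meta.loc[em.barcodes, group_key]
    if labels.isna().any():
        raise ValidationError(f"missing {group_key} labels")
    X = em.linear()
    out = {}
    for g in sorted(labels.unique()):
        rows = np.flatnonzero((labels == g).to_numpy())
        if rows.size == 0:
            raise ValidationError(f"empty group {g!r}")
        out[g] = X[rows].mean(axis=0)
    return pd.DataFrame(out, index=em.genes)


def specificity_scores(
    profile: pd.DataFrame, tfs: "list | set | None" = None
) -> SpecificityTable:
    """Raw specificity ``1 - sqrt(JSD(p_g, e_l))`` for each gene and group.

    ``profile`` is a gene x group mean-expression matrix; rows are normalized
    to distributions.  All-zero rows are scored 0 everywhere and flagged with
    a warning.  ``tfs`` restricts the rows scored (the TF universe).
    """
    if profile.shape[1] < 2:
        raise ValidationError("specificity needs at least 2 groups")
    if tfs is not None:
        present = [t for t in tfs if t in profile.index]
        missing = set(tfs) - set(present)
        if missing:
            log.warning("%d TFs absent from the profile matrix", len(missing))
        profile = profile.loc[present]
    P = profile.to_numpy(dtype=float)
    if (P < 0).any():
        raise ValidationError("negative expression in profile matrix")
    row_sums = P.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        log.warning(
            "%d genes have zero expression in every group; scored 0", int(zero_rows.sum())
        )
    safe = np.where(zero_rows, 1.0, row_sums)
    P = P / safe[:, None]
    n_groups = P.shape[1]
    scores = np.zeros_like(P)
    # vectorized JSD against each group's indicator e_l:
    # m = p/2 except at l where m_l = (p_l + 1)/2
    for l in range(n_groups):
        m = P / 2.0
        m[:, l] = (P[:, l] + 1.0) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            logterm = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0) / m), 0.0)
        kl_pm = (P * logterm).sum(axis=1)
        kl_em = -np.log2(m[:, l])
        jsd_l = 0.5 * kl_pm + 0.5 * kl_em
        scores[:, l] = 1.0 - np.sqrt(np.clip(jsd_l, 0.0, 1.0))
    scores[zero_rows] = 0.0
    return SpecificityTable(
        scores=pd.DataFrame(scores, index=profile.index, columns=profile.columns),
        scale="raw",
    )


def zscore_scores(st: SpecificityTable) -> SpecificityTable:
    """Z-score each gene's scores across groups (sample sd, n-1).

    Constant rows become all zeros; z-scored input is returned unchanged in
    value (idempotent).
    """
    if st.scale != "raw" and st.scale != "zscore":  # pragma: no cover
        raise ValidationError("unexpected scale")
    X = st.scores.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    # rows constant up to float residue get all-zero z-scores
    ok = sd > 1e-12 * np.maximum(np.abs(mu), 1.0)
    Z = np.where(ok, (X - mu) / np.where(ok, sd, 1.0), 0.0)
    return SpecificityTable(
        scores=pd.DataFrame(Z, index=st.scores.index, columns=st.scores.columns),
        scale="zscore",
        group_kind=st.group_kind,
    )


def call_specific_tfs(
    st: SpecificityTable,
    raw: SpecificityTable | None = None,
    k: int = 20,
    z_threshold: float | None = None,
) -> dict:
    """Top-``k`` TFs per group by z-scored specificity.

    Ties break by raw score (when supplied) then by gene identifier, making
    the ranking fully deterministic.  ``z_threshold`` optionally drops calls
    below a z cut.  Returns group -> ranked gene list.
    """
    if st.scale != "zscore":
        raise ValidationError("call_specific_tfs expects z-scored input")
    if k > len(st.scores):
        log.warning("k=%d exceeds the %d TFs available; truncating", k, len(st.scores))
        k = len(st.scores)
    calls = {}
    for group in st.scores.columns:
        df = pd.DataFrame({"z": st.scores[group]})
        df["raw"] = raw.scores[group] if raw is not None else 0.0
        df.index.name = None
        df["gene"] = df.index
        df = df.sort_values(by=["z", "raw", "gene"], ascending=[False, False, True])
        top = df.head(k)
        if z_threshold is not None:
            top = top[top["z"] >= z_threshold]
        calls[group] = top.index.tolist()
    return calls


def conserved_tfs(
    calls_by_species: dict,
    maps: "list[OrthologMap]",
    anchor_species: str,
) -> dict:
    """Anchor-species TFs whose orthologs are called in every other species.

    An anchor TF is conserved in group *l* iff, for every non-anchor species,
    at least one of its orthologs (one2one or one2many) appears in that
    species' group-*l* call set.
    """
    others = [s for s in calls_by_species if s != anchor_species]

    def map_for(sp_name: str) -> OrthologMap:
        for m in maps:
            sps = set(m.pairs["species_a"]) | set(m.pairs["species_b"])
            if anchor_species in sps and sp_name in sps:
                return m
        raise ValidationError(f"no ortholog map connecting {anchor_species} and {sp_name}")

    sp_maps = {s: map_for(s) for s in others}
    anchor_calls = calls_by_species[anchor_species]
    out = {}
    for group, tfs in anchor_calls.items():
        conserved = set()
        for tf in tfs:
            ok = True
            for s in others:
                orth = sp_maps[s].orthologs(tf, anchor_species, s)
                called = set(calls_by_species[s].get(group, []))
                if not orth & called:
                    ok = False
                    break
            if ok:
                conserved.add(tf)
        out[group] = conserved
    return out
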