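"""Barcode quality filtering and ambient-RNA (batch gene background) correction.

Droplet platforms capture cell-free transcripts from the dissociation
supernatant alongside each cell's own mRNA.  Barcodes with fewer than 500
UMIs are taken to be empty beads exposed only to that free RNA; their average
gene detection defines a per-batch background profile.  For each cell the
profile is rescaled by the median fold difference between the cell's counts
and the background, rounded to the nearest integer, and subtracted, never
driving a count negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, ValidationError, log


@dataclass
class BackgroundProfile:
    """Per-batch mean expression over sub-threshold (empty-bead) barcodes."""

    batch: str
    umi_threshold: int
    bg_mean: np.ndarray
    n_background_barcodes: int
    genes: pd.Index
    detection_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bg_mean = np.asarray(self.bg_mean, dtype=float)
        if self.detection_rate is not None:
            self.detection_rate = np.asarray(self.detection_rate, dtype=float)
        if (self.bg_mean < 0).any():
            raise ValidationError("background means must be >= 0")
        if len(self.bg_mean) != len(self.genes):
            raise ValidationError("background profile length does not match genes")
        if self.n_background_barcodes < 1:
            raise ValidationError("a usable profile needs >= 1 background barcode")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bg_mean": self.bg_mean}, index=self.genes)


def filter_cells(cm: CountMatrix, min_transcripts: int = 500) -> CountMatrix:
    """Keep barcodes with at least ``min_transcripts`` total UMIs (order kept).

    The complementary sub-threshold barcodes are the empty beads used by
    :func:`estimate_background_profile`; estimate the profile from the
    unfiltered matrix before filtering.
    """
    keep = cm.totals() >= min_transcripts
    if not keep.any():
        log.warning("filter_cells removed every barcode (min_transcripts=%d)", min_transcripts)
    return cm.subset_barcodes(keep)


def estimate_background_profile(
    cm_all: CountMatrix, umi_threshold: int = 500, batch: str | None = None
) -> BackgroundProfile:
    """Mean gene detection over sub-threshold barcodes of one batch.

    ``cm_all`` must be the unfiltered matrix (it has to contain the empty
    beads).  With ``batch=None`` all barcodes are treated as one batch.
    """
    totals = cm_all.totals()
    sub = totals < umi_threshold
    if batch is not None:
        sub &= (cm_all.meta["batch"] == batch).to_numpy()
    n = int(sub.sum())
    if n == 0:
        raise ValidationError(
            f"no barcodes under {umi_threshold} UMIs"
            + (f" in batch {batch!r}" if batch is not None else "")
            + "; supply the unfiltered matrix including empty beads"
        )
    rows = cm_all.values[np.flatnonzero(sub)]
    bg = np.asarray(rows.sum(axis=0)).ravel() / n
    det = np.asarray((rows > 0).sum(axis=0)).ravel() / n
    return BackgroundProfile(
        batch=batch if batch is not None else "all",
        umi_threshold=umi_threshold,
        bg_mean=bg,
        n_background_barcodes=n,
        genes=cm_all.genes,
        detection_rate=det,
    )


def estimate_background_profiles(
    cm_all: CountMatrix, umi_threshold: int = 500
) -> dict:
    """One :class:`BackgroundProfile` per batch label present in the metadata."""
    batches = cm_all.meta["batch"].dropna().unique()
    return {b: estimate_background_profile(cm_all, umi_threshold, b) for b in batches}


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # counts and background are non-negative, so half-away == floor(x + 0.5)
    return np.floor(x + 0.5)


def correct_background(
    cm: CountMatrix,
    profile: "BackgroundProfile | dict",
    min_prevalence: float = 0.0,
) -> CountMatrix:
    """Subtract the scaled batch gene background from every cell.

    For cell *c* the scale is the median over genes with positive background
    of ``count(c,g) / bg_mean(g)`` (genes the cell does not detect contribute
    ratio 0).  The subtracted background is ``round(bg_mean(g) * scale(c))``
    with half rounded away from zero, clipped so corrected counts stay in
    ``[0, count]``.  Genes with zero background mean are untouched.

    ``profile`` may be a single :class:`BackgroundProfile` or a mapping
    batch -> profile; correction never crosses batch boundaries.
    ``min_prevalence`` optionally restricts subtraction to genes detected in
    at least that fraction of the empty beads (0 = off), the "extensively
    expressed in all beads" reading of batch genes.
    """
    if isinstance(profile, dict):
        out = cm.dense()
        batches = cm.meta["batch"]
        for b, prof in profile.items():
            rows = np.flatnonzero((batches == b).to_numpy())
            if rows.size == 0:
                continue
            sub = _correct_dense(out[rows], prof, cm.genes, min_prevalence)
            out[rows] = sub
        untouched = batches.isna() | ~batches.isin(list(profile))
        if untouched.any():
            log.warning(
                "%d barcodes had no matching batch profile and were left uncorrected",
                int(untouched.sum()),
            )
        return CountMatrix(sp.csr_matrix(out), cm.barcodes, cm.genes, cm.meta.copy())
    out = _correct_dense(cm.dense(), profile, cm.genes, min_prevalence)
    return CountMatrix(sp.csr_matrix(out), cm.barcodes, cm.genes, cm.meta.copy())


def _correct_dense(
    X: np.ndarray, profile: BackgroundProfile, genes: pd.Index, min_prevalence: float
) -> np.ndarray:
    if not profile.genes.equals(genes):
        raise ValidationError("profile gene order does not match the matrix")
    bg = profile.bg_mean
    mask = bg > 0
    if min_prevalence > 0:
        if profile.detection_rate is None:
            raise ValidationError("min_prevalence requires a profile with detection rates")
        mask &= profile.detection_rate >= min_prevalence
    if not mask.any():
        log.warning("all background means are zero; correction is the identity")
        return X
    ratios = X[:, mask] / bg[mask]
    scale = np.median(ratios, axis=1)
    background = _round_half_away(np.outer(scale, bg[mask]))
    corrected = X.astype(np.int64).copy()
    corrected[:, mask] = np.maximum(0, X[:, mask] - background).astype(np.int64)
    return corrected
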