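"""Cross-stage driver-TF scoring for a matched cell type.

For a cell type present at two developmental stages, each TF gets a
within-stage specificity vector Y (the 1 - sqrt(JSD) score across that
stage's cell types).  The driver score is

    h_g = T(S(Y1_g)) * T(S(Y2_g))

where S standardizes a vector to zero mean and unit variance (sample sd) and
T truncates negatives to zero, so only TFs specific to the matched type at
*both* stages score positively.  The top-k (default 5) TFs by h are the
candidate drivers of the stage transition.

Cell types are matched across stages by identical annotation label by
default; a user-supplied pairing table overrides that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError, log
from .specificity import group_mean_profile, specificity_scores


@dataclass
class DriverTFResult:
    cell_type: str
    stage_pair: tuple
    y1: pd.Series
    y2: pd.Series
    s1_std: pd.Series
    s2_std: pd.Series
    h: pd.Series
    top: pd.DataFrame  # ranked: columns (h, y1, y2, zero_flagged)

    def to_frame(self) -> pd.DataFrame:
        return self.top


def stage_specificity(
    em_stage: ExpressionMatrix, meta: pd.DataFrame, tfs
) -> pd.DataFrame:
    """Per-TF specificity Y across one stage's cell types.

    TFs with zero expression at the stage are dropped (they are not part of
    that stage's TF set) with a logged note.
    """
    labels = meta.loc[em_stage.barcodes, "cell_type"]
    if labels.dropna().nunique() < 2:
        raise ValidationError("stage specificity needs at least 2 cell types in the stage")
    profile = group_mean_profile(em_stage, meta, "cell_type")
    present = [t for t in tfs if t in profile.index]
    sub = profile.loc[present]
    expressed = sub.sum(axis=1) > 0
    if (~expressed).any():
        log.info(
            "dropping %d TFs with zero expression at this stage", int((~expressed).sum())
        )
    st = specificity_scores(sub.loc[expressed])
    st.group_kind = "cell_type"
    return st.scores


def _standardize(y: np.ndarray) -> np.ndarray:
    mu = y.mean()
    sd = y.std(ddof=1)
    if sd <= 1e-12 * max(abs(mu), 1.0):  # constant up to float residue
        return np.zeros_like(y)
    return (y - mu) / sd


def driver_score(y1: pd.Series, y2: pd.Series) -> pd.Series:
    """h = T(S(y1)) * T(S(y2)) over the TFs present at both stages."""
    common = y1.index.intersection(y2.index)
    if len(common) < 3:
        raise ValidationError("driver scoring needs >= 3 TFs shared by both stages")
    a = _standardize(y1.loc[common].to_numpy(dtype=float))
    b = _standardize(y2.loc[common].to_numpy(dtype=float))
    h = np.clip(a, 0, None) * np.clip(b, 0, None)
    return pd.Series(h, index=common, name="h")


def top_driver_tfs(
    h: pd.Series, k: int = 5, tiebreak: pd.Series | None = None
) -> pd.DataFrame:
    """Top-``k`` TFs by h, ties broken by ``tiebreak`` (y1+y2) then identifier.

    TFs with h = 0 appear only when fewer than k have h > 0, and carry
    ``zero_flagged=True``.
    """
    df = pd.DataFrame({"h": h})
    df["tiebreak"] = tiebreak.reindex(h.index) if tiebreak is not None else 0.0
    df.index.name = None
    df["gene"] = df.index
    df = df.sort_values(by=["h", "tiebreak", "gene"], ascending=[False, False, True])
    top = df.head(k).copy()
    top["zero_flagged"] = top["h"] <= 0
    if top["zero_flagged"].any():
        log.warning(
            "fewer than k=%d TFs have positive driver score; %d zero-score TFs flagged",
            k, int(top["zero_flagged"].sum()),
        )
    return top[["h", "tiebreak", "zero_flagged"]]


def find_driver_tfs(
    em1: ExpressionMatrix,
    em2: ExpressionMatrix,
    meta1: pd.DataFrame,
    meta2: pd.DataFrame,
    tfs,
    cell_type: str,
    stage_pair: tuple = ("stage1", "stage2"),
    pairing: "pd.DataFrame | None" = None,
    k: int = 5,
) -> DriverTFResult:
    """End-to-end driver scoring for one matched cell type across two stages.

    ``pairing`` optionally maps the stage-1 label to a differently named
    stage-2 label (columns: cell_type_1, cell_type_2).
    """
    ct2 = cell_type
    if pairing is not None:
        hit = pairing[pairing["cell_type_1"] == cell_type]
        if len(hit):
            ct2 = hit["cell_type_2"].iloc[0]
    Y1 = stage_specificity(em1, meta1, tfs)
    Y2 = stage_specificity(em2, meta2, tfs)
    if cell_type not in Y1.columns:
        raise ValidationError(f"cell type {cell_type!r} absent at stage {stage_pair[0]}")
    if ct2 not in Y2.columns:
        raise ValidationError(f"cell type {ct2!r} absent at stage {stage_pair[1]}")
    y1, y2 = Y1[cell_type], Y2[ct2]
    h = driver_score(y1, y2)
    common = h.index
    s1 = pd.Series(_standardize(y1.loc[common].to_numpy(float)), index=common)
    s2 = pd.Series(_standardize(y2.loc[common].to_numpy(float)), index=common)
    top = top_driver_tfs(h, k=k, tiebreak=y1.loc[common] + y2.loc[common])
    return DriverTFResult(
        cell_type=cell_type,
        stage_pair=tuple(stage_pair),
        y1=y1,
        y2=y2,
        s1_std=s1,
        s2_std=s2,
        h=h,
        top=top,
    )
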