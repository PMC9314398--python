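"""Synthetic droplet-atlas generator with planted ground truth.

Emulates the structures the downstream analyses assume in a metamorphosing
amphibian atlas: per-lineage negative-binomial expression programs across four
larval stages (optionally plus adult), a shared ambient "soup" profile mixed
into every cell, sub-threshold empty barcodes that are pure soup, planted
single-lineage transcription factors, and planted trajectory genes following
four module archetypes (climax-peaked, climax-trough, monotone down, monotone
up; the penultimate stage plays the role of the NF59 metamorphic climax).

Every generated quantity needed for parameter-recovery testing is returned as
:class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import CountMatrix, _empty_meta, log


class ConfigError(ValueError):
    """Inconsistent atlas configuration."""


def _default_lineages() -> dict:
    return {
        "epidermis": 500,
        "immune": 500,
        "neuron": 500,
        "muscle": 500,
        "endothelium": 500,
    }


@dataclass
class AtlasConfig:
    """Study conditions for one synthetic atlas.

    Parameters
    ----------
    n_genes
        Total genes, including TFs.
    n_tfs
        Genes labeled as transcription factors (the TF universe); the first
        ``n_tfs`` gene slots.
    lineages
        Mapping lineage label -> number of cells, split evenly across stages.
        Each lineage is one cell type.
    stages
        Ordered developmental stages; the penultimate one is the metamorphic
        climax. At least 3 stages are required when module genes are planted.
    ambient_fraction
        Expected fraction of each cell's observed UMIs that are ambient soup.
    n_empty_barcodes, empty_umi_range
        Pure-soup barcodes with totals drawn uniformly in the inclusive range,
        kept below the 500-UMI cell threshold.
    nb_dispersion
        Negative-binomial size parameter theta (var = m + m^2/theta), shared
        across genes.
    mean_umis_per_cell
        Expected observed total per real cell.
    planted_tfs_per_lineage, tf_fold_change
        Single-lineage TFs: expression multiplied by the fold in their lineage
        and divided by it elsewhere, making them near-exclusive markers.
    module_genes_per_archetype, module_effect_size
        Trajectory genes per archetype; the effect is a multiplicative bump of
        the given natural-log amplitude applied along the archetype profile.
    n_ambient_genes, ambient_concentration
        Lysis supernatant is dominated by a modest set of highly abundant
        transcripts of comparable magnitude: the soup covers the top
        ``n_ambient_genes`` genes of the library-size-weighted mixture of all
        programs, with relative abundances drawn from a symmetric Dirichlet
        of the given concentration (larger = flatter soup).
    gene_on_prob
        Probability that a non-planted filler gene is expressed in a given
        lineage (programs are sparse and largely disjoint across lineages).
    include_adult
        Append an "adult" stage that reuses each archetype's endpoint level.
    """

    n_genes: int = 1000
    n_tfs: int = 150
    lineages: dict = field(default_factory=_default_lineages)
    stages: tuple = ("NF48", "NF54", "NF59", "NF66")
    ambient_fraction: float = 0.10
    n_empty_barcodes: int = 2000
    empty_umi_range: tuple = (50, 400)
    nb_dispersion: float = 2.0
    mean_umis_per_cell: int = 2000
    planted_tfs_per_lineage: int = 20
    tf_fold_change: float = 8.0
    module_genes_per_archetype: int = 50
    module_effect_size: float = 1.0
    n_ambient_genes: int = 40
    ambient_concentration: float = 40.0
    gene_on_prob: float = 0.25
    include_adult: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ambient_fraction < 1.0):
            raise ConfigError("ambient_fraction must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.tf_fold_change <= 1:
            raise ConfigError("tf_fold_change must be > 1")
        if self.planted_tfs_per_lineage * len(self.lineages) > self.n_tfs:
            raise ConfigError(
                "planted TF demand exceeds n_tfs: "
                f"{self.planted_tfs_per_lineage} x {len(self.lineages)} > {self.n_tfs}"
            )
        if self.n_tfs + 4 * self.module_genes_per_archetype > self.n_genes:
            raise ConfigError("planted gene demand exceeds n_genes")
        if self.module_genes_per_archetype > 0 and len(self.all_stages) < 3:
            raise ConfigError("module archetypes require at least 3 stages")
        if not self.empty_umi_range[0] <= self.empty_umi_range[1]:
            raise ConfigError("empty_umi_range must be (low, high) with low <= high")

    @property
    def all_stages(self) -> tuple:
        return tuple(self.stages) + (("adult",) if self.include_adult else ())

    @classmethod
    def from_yaml(cls, path) -> "AtlasConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "empty_umi_range" in raw:
            raw["empty_umi_range"] = tuple(raw["empty_umi_range"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        d["empty_umi_range"] = list(d["empty_umi_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class GroundTruth:
    """Everything planted into a synthetic atlas, for recovery tests."""

    endogenous_counts: CountMatrix
    ambient_profile: np.ndarray
    per_cell_ambient_count: pd.Series
    planted_tf_sets: dict
    module_archetype: dict
    module_multipliers: pd.DataFrame
    empty_barcodes: set


def _archetype_log_profile(archetype: int, n_stages: int, amplitude: float) -> np.ndarray:
    """Natural-log stage offsets for one module archetype."""
    idx = np.arange(n_stages, dtype=float)
    climax = n_stages - 2
    if archetype == 1:
        prof = np.where(idx == climax, 1.0, 0.0)
    elif archetype == 2:
        prof = np.where(idx == climax, -1.0, 0.0)
    elif archetype == 3:
        prof = 1.0 - idx / (n_stages - 1)
    elif archetype == 4:
        prof = idx / (n_stages - 1)
    else:  # pragma: no cover
        raise ValueError(archetype)
    return amplitude * prof


def generate_atlas(cfg: AtlasConfig, seed: int | None = None):
    """Generate one synthetic atlas.

    Returns ``(observed, truth)`` where ``observed`` is the droplet-level
    :class:`~xenatlas.io.CountMatrix` (real cells followed by empty barcodes)
    and ``truth`` the planted :class:`GroundTruth`.  Observed counts equal
    endogenous + ambient draws exactly, per barcode per gene.  The same config
    and seed give bit-identical output.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    stages = cfg.all_stages
    n_stages = len(stages)
    lineage_names = list(cfg.lineages)
    n_lin = len(lineage_names)

    tf_ids = [f"tf{i:04d}" for i in range(cfg.n_tfs)]
    filler_ids = [f"g{i:05d}" for i in range(cfg.n_genes - cfg.n_tfs)]
    genes = pd.Index(tf_ids + filler_ids, name="gene")
    n_genes = cfg.n_genes

    is_tf = np.zeros(n_genes, bool)
    is_tf[: cfg.n_tfs] = True

    # --- planted gene slots -------------------------------------------------
    planted_tf_sets = {}
    planted_tf_idx = {}
    k = cfg.planted_tfs_per_lineage
    for j, lin in enumerate(lineage_names):
        idx = np.arange(j * k, (j + 1) * k)
        planted_tf_idx[lin] = idx
        planted_tf_sets[lin] = set(genes[idx])

    n_mod = cfg.module_genes_per_archetype
    module_archetype = {}
    module_idx = {}
    for a in range(1, 5):
        lo = cfg.n_tfs + (a - 1) * n_mod
        idx = np.arange(lo, lo + n_mod)
        module_idx[a] = idx
        for g in genes[idx]:
            module_archetype[g] = a
    module_gene_mask = np.zeros(n_genes, bool)
    for idx in module_idx.values():
        module_gene_mask[idx] = True

    # --- base abundances and lineage gates ----------------------------------
    # Planted TFs and module genes get moderate, well-detected baselines
    # (sigma 0.5 around the overall scale); generic filler genes are
    # heavy-tailed (sigma 1.5), which concentrates the soup on few genes.
    base = np.empty(n_genes)
    base[is_tf] = rng.lognormal(mean=0.0, sigma=0.5, size=is_tf.sum())
    base[~is_tf] = rng.lognormal(mean=0.0, sigma=1.5, size=(~is_tf).sum())
    base[module_gene_mask] = rng.lognormal(mean=0.0, sigma=0.5, size=module_gene_mask.sum())

    gates = np.empty((n_lin, n_genes))
    # TFs: broadly expressed with mild lineage variation
    gates[:, is_tf] = rng.lognormal(mean=0.0, sigma=0.5, size=(n_lin, int(is_tf.sum())))
    # filler genes: sparse on/off programs, largely disjoint across lineages
    filler = ~is_tf & ~module_gene_mask
    on = rng.random((n_lin, int(filler.sum()))) < cfg.gene_on_prob
    soft = rng.lognormal(mean=0.0, sigma=0.5, size=on.shape)
    gates[:, filler] = np.where(on, soft, 0.0)
    # module genes: expressed in every lineage (trajectory structure is shared)
    gates[:, module_gene_mask] = 1.0
    # planted single-lineage TFs: exact fold up in their lineage, fold down
    # elsewhere (the fold is the ground truth, so no extra lineage jitter)
    for j, lin in enumerate(lineage_names):
        idx = planted_tf_idx[lin]
        gates[:, idx] = 1.0 / cfg.tf_fold_change
        gates[j, idx] = cfg.tf_fold_change

    # --- stage multipliers ---------------------------------------------------
    stage_mult = np.ones((n_stages, n_genes))
    module_multipliers = {}
    for a in range(1, 5):
        prof = np.exp(_archetype_log_profile(a, n_stages, cfg.module_effect_size))
        stage_mult[:, module_idx[a]] = prof[:, None]
        for g in genes[module_idx[a]]:
            module_multipliers[g] = prof
    module_multipliers = pd.DataFrame(module_multipliers, index=list(stages)).T

    # --- per-cell expected endogenous means ----------------------------------
    endo_total = (1.0 - cfg.ambient_fraction) * cfg.mean_umis_per_cell
    profiles = {}  # (lineage_idx, stage_idx) -> per-gene mean vector
    weights = np.zeros(n_genes)
    for j, lin in enumerate(lineage_names):
        per_stage = cfg.lineages[lin] // n_stages
        extra = cfg.lineages[lin] - per_stage * n_stages
        for s in range(n_stages):
            m = base * gates[j] * stage_mult[s]
            tot = m.sum()
            if tot <= 0:
                raise ConfigError(f"lineage {lin} has an all-zero program")
            p = m / tot
            profiles[(j, s)] = p * endo_total
            n_cells_ls = per_stage + (1 if s < extra else 0)
            weights += n_cells_ls * p

    # --- ambient soup profile -------------------------------------------------
    # The soup backdrop lives on abundant unplanted genes: planted TFs and
    # module genes stay orthogonal to contamination so each recovery test
    # isolates one mechanism.
    ambient = np.zeros(n_genes)
    soup_candidates = np.flatnonzero(filler)
    if weights[soup_candidates].sum() > 0 and cfg.n_ambient_genes > 0:
        order = soup_candidates[np.argsort(weights[soup_candidates])[::-1]]
        top = order[: cfg.n_ambient_genes]
        alpha = cfg.ambient_concentration
        ambient[top] = rng.dirichlet(np.full(len(top), alpha))

    # --- assemble cells -------------------------------------------------------
    cell_rows = []
    meta_rows = []
    for j, lin in enumerate(lineage_names):
        per_stage = cfg.lineages[lin] // n_stages
        extra = cfg.lineages[lin] - per_stage * n_stages
        for s, stage in enumerate(stages):
            n_cells_ls = per_stage + (1 if s < extra else 0)
            for _ in range(n_cells_ls):
                cell_rows.append((j, s))
                meta_rows.append((lin, stage))
    n_cells = len(cell_rows)

    mean_matrix = np.empty((n_cells, n_genes))
    for i, (j, s) in enumerate(cell_rows):
        mean_matrix[i] = profiles[(j, s)]

    # NB via gamma-Poisson; theta shared across genes
    theta = cfg.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mean_matrix / theta)
    endo = rng.poisson(lam).astype(np.int64)

    endo_totals = endo.sum(axis=1)
    f = cfg.ambient_fraction
    if f > 0 and ambient.sum() > 0:
        amb_n = np.rint(f / (1.0 - f) * endo_totals).astype(np.int64)
        amb = rng.multinomial(amb_n, ambient)
    else:
        amb_n = np.zeros(n_cells, dtype=np.int64)
        amb = np.zeros_like(endo)
    observed_cells = endo + amb

    # --- empty barcodes --------------------------------------------------------
    lo, hi = cfg.empty_umi_range
    if cfg.n_empty_barcodes > 0 and ambient.sum() > 0:
        empty_totals = rng.integers(lo, hi, size=cfg.n_empty_barcodes, endpoint=True)
        empties = rng.multinomial(empty_totals, ambient)
    else:
        empty_totals = np.zeros(cfg.n_empty_barcodes, dtype=np.int64)
        empties = np.zeros((cfg.n_empty_barcodes, n_genes), dtype=np.int64)

    cell_ids = [f"cell{i:06d}" for i in range(n_cells)]
    empty_ids = [f"empty{i:06d}" for i in range(cfg.n_empty_barcodes)]
    barcodes = pd.Index(cell_ids + empty_ids, name="barcode")

    meta = _empty_meta(barcodes)
    meta["batch"] = "b1"
    for i, (lin, stage) in enumerate(meta_rows):
        meta.iloc[i, meta.columns.get_loc("stage")] = stage
        meta.iloc[i, meta.columns.get_loc("cell_type")] = lin
        meta.iloc[i, meta.columns.get_loc("lineage")] = lin

    observed = sp.csr_matrix(np.vstack([observed_cells, empties]))
    cm = CountMatrix(observed, barcodes, genes, meta)

    endo_full = np.vstack([endo, np.zeros_like(empties)])
    truth = GroundTruth(
        endogenous_counts=CountMatrix(sp.csr_matrix(endo_full), barcodes, genes, meta.copy()),
        ambient_profile=ambient,
        per_cell_ambient_count=pd.Series(
            np.concatenate([amb_n, empty_totals]), index=barcodes, name="ambient_umis"
        ),
        planted_tf_sets=planted_tf_sets,
        module_archetype=module_archetype,
        module_multipliers=module_multipliers,
        empty_barcodes=set(empty_ids),
    )
    log.debug(
        "generated atlas: %d cells, %d empties, %d genes (seed %d)",
        n_cells, cfg.n_empty_barcodes, n_genes, seed,
    )
    return cm, truth


def write_atlas(cm: CountMatrix, truth: GroundTruth, out_dir) -> None:
    """Write the observed matrix (mtx triplet), metadata TSV and truth JSON."""
    import json

    from .io import write_counts, write_metadata

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(cm, out, format="mtx_triplet")
    write_metadata(cm.meta, out / "metadata.tsv")
    payload = {
        "ambient_profile": truth.ambient_profile.tolist(),
        "per_cell_ambient_count": truth.per_cell_ambient_count.to_dict(),
        "planted_tf_sets": {k: sorted(v) for k, v in truth.planted_tf_sets.items()},
        "module_archetype": truth.module_archetype,
        "empty_barcodes": sorted(truth.empty_barcodes),
    }
    (out / "truth.json").write_text(json.dumps(payload))
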