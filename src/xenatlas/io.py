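"""Core containers and plain-text I/O for droplet count data.

The pipeline's raw substrate is a barcode x gene matrix of UMI counts with a
per-barcode metadata record (batch, developmental stage, tissue, cell type,
lineage).  On disk the sparse form follows the CellRanger-style Matrix Market
triplet: ``matrix.mtx`` with genes as rows and barcodes as columns (1-based
coordinates), plus ``barcodes.tsv`` and ``genes.tsv``.  In memory everything
is barcode x gene.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger("xenatlas")

STAGES = ("NF48", "NF54", "NF59", "NF66", "adult")
META_FIELDS = ("batch", "stage", "tissue", "cell_type", "lineage")

MTX_COMMENT = (
    "xenatlas count matrix: genes as rows, barcodes as columns on disk;"
    " transposed to barcode x gene in memory"
)


class FormatError(ValueError):
    """A file does not match the expected on-disk layout."""


class ValidationError(ValueError):
    """In-memory data violates a container invariant."""


def configure_logging(verbose: bool = False) -> None:
    """Send package logs to stderr; ``verbose`` switches to DEBUG."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


def _empty_meta(barcodes: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(
        {f: pd.array([pd.NA] * len(barcodes), dtype="object") for f in META_FIELDS},
        index=barcodes,
    )


@dataclass
class CountMatrix:
    """Integer UMI counts for barcodes x genes with per-barcode metadata.

    ``values`` is a CSR sparse matrix of non-negative integers; ``meta`` is
    indexed by barcode and covers exactly the barcodes present (missing
    annotation is ``pd.NA``, never the empty string).
    """

    values: sp.csr_matrix
    barcodes: pd.Index
    genes: pd.Index
    meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        self.values = self.values.tocsr()
        if not np.issubdtype(self.values.dtype, np.integer):
            data = self.values.data
            if data.size and not np.allclose(data, np.round(data)):
                raise ValidationError("count matrix contains non-integer entries")
            self.values = self.values.astype(np.int64)
        self.barcodes = pd.Index(map(str, self.barcodes), name="barcode")
        self.genes = pd.Index(map(str, self.genes), name="gene")
        if self.values.shape != (len(self.barcodes), len(self.genes)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("negative counts")
        if self.barcodes.has_duplicates:
            raise ValidationError("duplicate barcode identifiers")
        if self.genes.has_duplicates:
            raise ValidationError("duplicate gene identifiers")
        if self.meta is None:
            self.meta = _empty_meta(self.barcodes)
        else:
            if not self.meta.index.equals(self.barcodes):
                raise ValidationError("meta index must equal the barcode index")
            for f in META_FIELDS:
                if f not in self.meta.columns:
                    self.meta[f] = pd.NA

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def totals(self) -> np.ndarray:
        """Per-barcode total UMI counts."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def subset_barcodes(self, keep: np.ndarray | list) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.barcodes.get_indexer(keep)
            if (idx < 0).any():
                raise ValidationError("unknown barcodes in subset request")
        return CountMatrix(
            self.values[idx],
            self.barcodes[idx],
            self.genes,
            self.meta.iloc[idx].copy(),
        )

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.values.copy(), self.barcodes.copy(), self.genes.copy(), self.meta.copy()
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.barcodes.equals(other.barcodes)
            and self.genes.equals(other.genes)
            and (self.values != other.values).nnz == 0
            and self.meta.fillna("<NA>").equals(other.meta.fillna("<NA>"))
        )

    def to_anndata(self):
        """Bridge to the AnnData container for interop with scanpy-style tools."""
        import anndata as ad

        return ad.AnnData(
            X=self.values.copy(),
            obs=self.meta.copy(),
            var=pd.DataFrame(index=self.genes),
        )


@dataclass
class ExpressionMatrix:
    """Normalized barcode x gene expression.

    ``normalization`` is either ``log2cp10k`` — log2(counts-per-10k + 1), the
    log2(CPM/100 + 1) transform — or ``cp100k`` — counts scaled so each
    barcode sums to 100,000.
    """

    values: sp.csr_matrix
    barcodes: pd.Index
    genes: pd.Index
    normalization: str

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        self.values = self.values.tocsr().astype(float)
        self.barcodes = pd.Index(map(str, self.barcodes), name="barcode")
        self.genes = pd.Index(map(str, self.genes), name="gene")
        if self.normalization not in ("log2cp10k", "cp100k"):
            raise ValidationError(f"unknown normalization tag {self.normalization!r}")
        if self.values.nnz and self.normalization == "log2cp10k":
            if self.values.data.min() < 0:
                raise ValidationError("log2cp10k values must be >= 0")

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def linear(self) -> np.ndarray:
        """Values on the linear normalized scale (de-logged if needed)."""
        if self.normalization == "log2cp10k":
            x = self.values.copy()
            x.data = np.exp2(x.data) - 1.0
            return x.toarray()
        return self.values.toarray()

    def subset_barcodes(self, keep) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = self.barcodes.get_indexer(keep)
            if (idx < 0).any():
                raise ValidationError("unknown barcodes in subset request")
        return ExpressionMatrix(
            self.values[idx], self.barcodes[idx], self.genes, self.normalization
        )


@dataclass
class OrthologMap:
    """Ortholog pairs between two species.

    ``pairs`` holds columns (species_a, gene_a, species_b, gene_b, relation)
    with relation in {one2one, one2many}; duplicate (gene_a, gene_b) pairs per
    species pair are rejected.
    """

    pairs: pd.DataFrame

    COLUMNS = ("species_a", "gene_a", "species_b", "gene_b", "relation")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.pairs.columns)
        if missing:
            raise ValidationError(f"ortholog table missing columns {sorted(missing)}")
        bad = ~self.pairs["relation"].isin(["one2one", "one2many"])
        if bad.any():
            raise ValidationError("relation must be one2one or one2many")
        if self.pairs.duplicated(
            subset=["species_a", "species_b", "gene_a", "gene_b"]
        ).any():
            raise ValidationError("duplicate ortholog pair")

    def orthologs(self, gene: str, species_a: str, species_b: str) -> set:
        """Genes in species_b orthologous to ``gene`` of species_a (either direction)."""
        p = self.pairs
        fwd = p[(p.species_a == species_a) & (p.species_b == species_b) & (p.gene_a == gene)]
        rev = p[(p.species_a == species_b) & (p.species_b == species_a) & (p.gene_b == gene)]
        return set(fwd["gene_b"]) | set(rev["gene_a"])

    @classmethod
    def read_tsv(cls, path) -> "OrthologMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path, format: str = "mtx_triplet") -> CountMatrix:
    """Read a count matrix from disk.

    ``mtx_triplet`` expects a directory with ``matrix.mtx`` (genes x barcodes,
    1-based coordinates), ``barcodes.tsv`` and ``genes.tsv``.  ``dense_csv``
    expects a CSV with a header row of genes and barcodes in the first column.
    Metadata is initialized empty; attach it with :func:`attach_metadata`.
    """
    path = Path(path)
    if format == "mtx_triplet":
        mtx, bc_file, gene_file = (
            path / "matrix.mtx",
            path / "barcodes.tsv",
            path / "genes.tsv",
        )
        for f in (mtx, bc_file, gene_file):
            if not f.exists():
                raise FormatError(f"missing file {f}")
        m = mmread(mtx)
        if not np.issubdtype(m.dtype, np.integer):
            data = m.tocoo().data
            if data.size and not np.allclose(data, np.round(data)):
                raise ValidationError(f"non-integer entries in {mtx}")
        barcodes = pd.read_csv(bc_file, sep="\t", header=None)[0].astype(str)
        genes = pd.read_csv(gene_file, sep="\t", header=None)[0].astype(str)
        if m.shape[0] != len(genes):
            raise FormatError(
                f"{mtx} declares {m.shape[0]} rows but {gene_file} lists {len(genes)} genes"
            )
        if m.shape[1] != len(barcodes):
            raise FormatError(
                f"{mtx} declares {m.shape[1]} columns but {bc_file} lists "
                f"{len(barcodes)} barcodes"
            )
        return CountMatrix(sp.csr_matrix(m.T), pd.Index(barcodes), pd.Index(genes))
    if format == "dense_csv":
        df = pd.read_csv(path, index_col=0)
        arr = df.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"non-integer entries in {path}")
        return CountMatrix(
            sp.csr_matrix(arr.astype(np.int64)),
            pd.Index(df.index.astype(str)),
            pd.Index(df.columns.astype(str)),
        )
    raise ValueError(f"unknown format {format!r}")


def write_counts(cm: CountMatrix, path, format: str = "mtx_triplet") -> None:
    """Write a count matrix; inverse of :func:`read_counts` (metadata excluded)."""
    path = Path(path)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(
            path / "matrix.mtx",
            sp.coo_matrix(cm.values.T),
            comment=MTX_COMMENT,
            field="integer",
        )
        pd.Series(cm.barcodes).to_csv(path / "barcodes.tsv", index=False, header=False)
        pd.Series(cm.genes).to_csv(path / "genes.tsv", index=False, header=False)
        return
    if format == "dense_csv":
        pd.DataFrame(cm.dense(), index=cm.barcodes, columns=cm.genes).to_csv(path)
        return
    raise ValueError(f"unknown format {format!r}")


def attach_metadata(cm: CountMatrix, table: pd.DataFrame) -> CountMatrix:
    """Attach per-barcode annotation from a table keyed by barcode.

    Barcodes missing from the table keep missing-valued fields; table rows for
    unknown barcodes are ignored with a logged warning.
    """
    table = table.copy()
    if "barcode" in table.columns:
        table = table.set_index("barcode")
    table.index = table.index.astype(str)
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate barcode keys in metadata table: {dups[:5]}")
    unknown = table.index.difference(cm.barcodes)
    if len(unknown):
        log.warning(
            "metadata table contains %d barcodes absent from the matrix (ignored)",
            len(unknown),
        )
    meta = _empty_meta(cm.barcodes)
    common = table.index.intersection(cm.barcodes)
    for f in META_FIELDS:
        if f in table.columns:
            col = table.loc[common, f]
            col = col.where(col.notna() & (col.astype(str) != ""), pd.NA)
            meta.loc[common, f] = col
    return CountMatrix(cm.values, cm.barcodes, cm.genes, meta)


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata TSV with a header (barcode, batch, stage, ...)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=True, index_label="barcode", na_rep="NA")


def write_table(obj, path, format: str = "tsv") -> None:
    """Serialize a result table (DataFrame, mapping, or object with ``to_frame``
    / ``to_dict``) to tsv/csv/json so it reads back equal."""
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        frame = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
        frame.to_csv(path, sep=sep)
        return
    if format == "json":
        if isinstance(obj, pd.DataFrame):
            payload = json.loads(obj.to_json(orient="split"))
        elif hasattr(obj, "to_dict"):
            payload = obj.to_dict()
        else:
            payload = obj
        try:
            path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        except OSError as e:
            raise OSError(f"cannot write {path}: {e}") from e
        return
    raise ValueError(f"unknown format {format!r}")


def read_table(path, format: str = "tsv"):
    path = Path(path)
    if format in ("tsv", "csv"):
        return pd.read_csv(path, sep="\t" if format == "tsv" else ",", index_col=0)
    if format == "json":
        return json.loads(path.read_text())
    raise ValueError(f"unknown format {format!r}")
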