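"""Count-matrix IO and preprocessing.

Canonical orientation is cells in rows, genes in columns. Supported on-disk
formats are Matrix Market triplets (with ``.rows.txt``/``.cols.txt`` id
sidecars) and delimited text with a header row of gene ids and a first
column of cell ids.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from statefate.errors import (
    EmptyResultError,
    FormatError,
    PreconditionError,
    ValidationError,
)

LAYERS = ("raw", "subsampled", "lognorm")


@dataclasses.dataclass
class ExpressionMatrix:
    """Cells x genes expression matrix with identifiers and a layer tag.

    ``counts`` holds non-negative integers for the ``raw`` and ``subsampled``
    layers and floats for ``lognorm``.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame | None = None
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts contain non-finite entries")
        if np.any(self.counts < 0):
            raise ValidationError("counts contain negative entries")
        if self.layer in ("raw", "subsampled"):
            if not np.issubdtype(self.counts.dtype, np.integer):
                if np.any(self.counts != np.round(self.counts)):
                    raise ValidationError("count layers must hold integers")
                self.counts = self.counts.astype(np.int64)
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cell_ids, columns=self.gene_ids)


@dataclasses.dataclass
class GeneAnnotation:
    """Per-gene annotation: transcription-factor flag and pathway membership."""

    table: pd.DataFrame  # index: gene_id; columns: is_tf (bool), pathway (set[str])

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneAnnotation":
        tab = frame.copy()
        if "is_tf" not in tab.columns:
            raise ValidationError("annotation requires an is_tf column")
        tab["is_tf"] = tab["is_tf"].astype(bool)
        if "pathway" not in tab.columns:
            tab["pathway"] = [set() for _ in range(len(tab))]
        else:
            tab["pathway"] = [_parse_pathways(p) for p in tab["pathway"]]
        return cls(tab)

    def tf_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_tf"]])

    def pathway_genes(self, pathway: str) -> set[str]:
        return {g for g, ps in self.table["pathway"].items() if pathway in ps}

    def pathways(self) -> set[str]:
        out: set[str] = set()
        for ps in self.table["pathway"]:
            out |= ps
        return out


def _parse_pathways(value) -> set[str]:
    if isinstance(value, set):
        return value
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    text = str(value).strip()
    if not text:
        return set()
    return {p.strip() for p in text.split(";") if p.strip()}


def load_annotation(path: str | Path) -> GeneAnnotation:
    """Read a TSV with columns gene_id, is_tf, pathway (semicolon-separated)."""
    tab = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in tab.columns:
        raise FormatError(f"{path}: annotation requires a gene_id column")
    tab = tab.set_index("gene_id")
    if tab["is_tf"].dtype == object:
        tab["is_tf"] = tab["is_tf"].astype(str).str.lower().isin(("1", "true", "yes"))
    return GeneAnnotation.from_frame(tab)


def load_expression(
    path: str | Path,
    fmt: str | None = None,
    cells_in_rows: bool = True,
) -> ExpressionMatrix:
    """Read a count matrix from MTX/CSV/TSV into canonical orientation.

    For MTX, cell and gene ids are read from ``<stem>.rows.txt`` and
    ``<stem>.cols.txt`` sidecars when present, else generated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(
            path.suffix.lower(), "csv"
        )
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        if not np.all(mat == np.round(mat)):
            raise FormatError(f"{path}: non-integer entries in count matrix")
        mat = mat.astype(np.int64)
        rows = _read_ids(path.with_suffix(".rows.txt"), mat.shape[0], "r")
        cols = _read_ids(path.with_suffix(".cols.txt"), mat.shape[1], "c")
        if not cells_in_rows:
            mat, rows, cols = mat.T, cols, rows
        return ExpressionMatrix(mat, rows, cols)
    sep = "," if fmt == "csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValidationError(f"{path}: duplicate gene ids in header")
    frame = pd.read_csv(path, sep=sep, index_col=0)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in count matrix")
    if np.any(values != np.round(values)):
        raise FormatError(f"{path}: non-integer entries in count matrix")
    mat = values.astype(np.int64)
    rows = [str(i) for i in frame.index]
    cols = [str(c) for c in frame.columns]
    if not cells_in_rows:
        mat, rows, cols = mat.T, cols, rows
    try:
        return ExpressionMatrix(mat, rows, cols)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _read_ids(path: Path, n: int, prefix: str) -> list[str]:
    if path.exists():
        ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
        if len(ids) != n:
            raise FormatError(f"{path}: {len(ids)} ids for {n} entries")
        return ids
    return [f"{prefix}{i}" for i in range(n)]


def write_expression(mat: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a matrix in one of the formats load_expression reads."""
    path = Path(path)
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(path.suffix.lower(), "csv")
    if fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(mat.counts))
        path.with_suffix(".rows.txt").write_text("\n".join(mat.cell_ids) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(mat.gene_ids) + "\n")
    else:
        sep = "," if fmt == "csv" else "\t"
        mat.to_frame().to_csv(path, sep=sep)


def filter_cells_min_depth(mat: ExpressionMatrix, min_depth: int = 20000) -> ExpressionMatrix:
    """Keep cells whose total UMI count is at least ``min_depth`` (order preserved)."""
    if mat.layer != "raw":
        raise PreconditionError("depth filtering applies to the raw layer")
    keep = mat.cell_totals() >= min_depth
    if not keep.any():
        raise EmptyResultError(f"no cell reaches the minimum depth of {min_depth}")
    meta = mat.cell_meta.loc[keep] if mat.cell_meta is not None else None
    return ExpressionMatrix(
        mat.counts[keep],
        [c for c, k in zip(mat.cell_ids, keep) if k],
        mat.gene_ids,
        cell_meta=meta,
        layer="raw",
    )


def subsample_umis(mat: ExpressionMatrix, depth: int = 20000, seed: int = 0) -> ExpressionMatrix:
    """Downsample every cell to exactly ``depth`` UMIs without replacement.

    Each cell's retained counts follow a multivariate hypergeometric draw
    from its UMI multiset, so zero entries stay zero and the new total is
    exactly ``depth``. Deterministic given ``seed``.
    """
    totals = mat.cell_totals()
    low = totals < depth
    if low.any():
        bad = [c for c, b in zip(mat.cell_ids, low) if b]
        raise PreconditionError(
            f"cells below target depth {depth}: {', '.join(bad[:5])}"
            + ("..." if len(bad) > 5 else "")
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(mat.counts)
    for i in range(mat.n_cells):
        if totals[i] == depth:
            out[i] = mat.counts[i]
        else:
            out[i] = rng.multivariate_hypergeometric(
                mat.counts[i], depth, method="marginals"
            )
    return ExpressionMatrix(
        out, mat.cell_ids, mat.gene_ids, cell_meta=mat.cell_meta, layer="subsampled"
    )


def lognorm(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise log2(count + 1) on the subsampled layer."""
    if mat.layer == "lognorm":
        return mat
    if mat.layer != "subsampled":
        raise PreconditionError("lognorm expects the subsampled layer")
    if np.any(mat.counts < 0):
        raise ValidationError("negative counts")
    vals = np.log2(mat.counts.astype(np.float64) + 1.0)
    return ExpressionMatrix(
        vals, mat.cell_ids, mat.gene_ids, cell_meta=mat.cell_meta, layer="lognorm"
    )


def rescale_unit(values: np.ndarray) -> np.ndarray:
    """Min/max rescale to [0, 1]; constant input maps to zeros (plotting helper)."""
    values = np.asarray(values, dtype=float)
    span = values.max() - values.min()
    if span == 0:
        return np.zeros_like(values)
    return (values - values.min()) / span


def restrict_to_tfs(mat: ExpressionMatrix, annot: GeneAnnotation) -> ExpressionMatrix:
    """Keep only genes flagged as transcription factors (unannotated = non-TF)."""
    tfs = annot.tf_genes()
    keep = np.array([g in tfs for g in mat.gene_ids])
    if not keep.any():
        raise EmptyResultError("no transcription factors among the matrix genes")
    return ExpressionMatrix(
        mat.counts[:, keep],
        mat.cell_ids,
        [g for g, k in zip(mat.gene_ids, keep) if k],
        cell_meta=mat.cell_meta,
        layer=mat.layer,
    )


def subset_genes(mat: ExpressionMatrix, genes: Iterable[str]) -> ExpressionMatrix:
    """Restrict to an explicit gene list (in matrix order)."""
    genes = set(genes)
    keep = np.array([g in genes for g in mat.gene_ids])
    if not keep.any():
        raise EmptyResultError("gene subset is empty")
    return ExpressionMatrix(
        mat.counts[:, keep],
        mat.cell_ids,
        [g for g, k in zip(mat.gene_ids, keep) if k],
        cell_meta=mat.cell_meta,
        layer=mat.layer,
    )
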