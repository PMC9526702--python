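"""Protein abundance matrices and their on-disk formats.

The central container is :class:`ProteinMatrix`: a protein x sample table of
(possibly missing) abundances, per-sample metadata, and a ``scale_tag``
recording where the matrix sits in the preprocessing pipeline.  Tags move
forward only (``raw -> log2 -> log2-imputed -> zscored``), which lets each
downstream operation assert the matrix it receives is in a state it can
consume (e.g. z-scoring a matrix that still has missing values is rejected).

On disk a matrix is a TSV with proteins as rows, samples as columns, the
first column holding the gene symbol, and an empty cell meaning missing.
GCT 1.2 is supported as an alternative interchange format.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SCALE_TAGS = ("raw", "log2", "log2-imputed", "zscored")
_TAG_RANK = {t: i for i, t in enumerate(SCALE_TAGS)}


@dataclass
class ProteinMatrix:
    """Protein x sample abundance matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame with protein ids (gene symbols) as the index and sample ids
        as columns.  NaN marks a missing (non-valid) measurement.
    sample_meta
        DataFrame indexed by sample id.  Conventional columns: ``patient``,
        ``group`` (niche or subtype), ``platform``.
    scale_tag
        One of ``raw``, ``log2``, ``log2-imputed``, ``zscored``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_tag not in _TAG_RANK:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(index=self.values.columns.copy())
        else:
            missing = self.values.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"samples absent from sample_meta: {list(missing)[:5]}")
            self.sample_meta = self.sample_meta.loc[self.values.columns]

    # -- basic introspection -------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool(self.values.isna().to_numpy().any())

    # -- state transitions ---------------------------------------------------

    def advance_tag(self, new_tag: str) -> None:
        """Validate a forward-only scale-tag transition (in place)."""
        if new_tag not in _TAG_RANK:
            raise ValueError(f"unknown scale_tag {new_tag!r}")
        if _TAG_RANK[new_tag] < _TAG_RANK[self.scale_tag]:
            raise ValueError(
                f"scale_tag may only move forward: {self.scale_tag!r} -> {new_tag!r}"
            )
        self.scale_tag = new_tag

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            values=self.values.copy(),
            sample_meta=self.sample_meta.copy(),
            scale_tag=self.scale_tag,
        )

    def with_values(self, values: pd.DataFrame, scale_tag: str | None = None) -> "ProteinMatrix":
        return ProteinMatrix(
            values=values,
            sample_meta=self.sample_meta.loc[values.columns].copy(),
            scale_tag=self.scale_tag if scale_tag is None else scale_tag,
        )

    def subset_samples(self, sample_ids) -> "ProteinMatrix":
        ids = list(sample_ids)
        return ProteinMatrix(
            values=self.values[ids].copy(),
            sample_meta=self.sample_meta.loc[ids].copy(),
            scale_tag=self.scale_tag,
        )

    def subset_proteins(self, protein_ids) -> "ProteinMatrix":
        ids = list(protein_ids)
        return ProteinMatrix(
            values=self.values.loc[ids].copy(),
            sample_meta=self.sample_meta.copy(),
            scale_tag=self.scale_tag,
        )


# -- TSV ---------------------------------------------------------------------

GENE_COLUMN = "gene_symbol"


def write_matrix_tsv(matrix: ProteinMatrix, path: str | Path) -> None:
    """Write proteins-as-rows TSV; empty cell = missing value."""
    out = matrix.values.copy()
    out.index.name = GENE_COLUMN
    out.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def read_matrix_tsv(
    path: str | Path,
    sample_meta: pd.DataFrame | None = None,
    scale_tag: str = "raw",
) -> ProteinMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    return ProteinMatrix(
        values=values,
        sample_meta=sample_meta if sample_meta is not None else pd.DataFrame(),
        scale_tag=scale_tag,
    )


def write_sample_meta_tsv(matrix: ProteinMatrix, path: str | Path) -> None:
    meta = matrix.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(path, sep="\t")


def read_sample_meta_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta.index = meta.index.astype(str)
    return meta


# -- GCT 1.2 -----------------------------------------------------------------


def write_matrix_gct(matrix: ProteinMatrix, path: str | Path) -> None:
    """Write GCT 1.2 (``#1.2`` header, dims line, Name/Description columns)."""
    n_rows, n_cols = matrix.values.shape
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{n_rows}\t{n_cols}\n")
        out = matrix.values.copy()
        out.insert(0, "Description", "na")
        out.index.name = "Name"
        out.to_csv(fh, sep="\t", na_rep="", float_format="%.17g")


def read_matrix_gct(
    path: str | Path,
    sample_meta: pd.DataFrame | None = None,
    scale_tag: str = "raw",
) -> ProteinMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line {version!r}; expected '#1.2'")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError("malformed GCT dimensions line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        body = pd.read_csv(io.StringIO(fh.read()), sep="\t", index_col=0)
    body.index = body.index.astype(str)
    values = body.drop(columns=["Description"], errors="ignore")
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"GCT dims line says {n_rows}x{n_cols} but body is "
            f"{values.shape[0]}x{values.shape[1]}"
        )
    return ProteinMatrix(
        values=values,
        sample_meta=sample_meta if sample_meta is not None else pd.DataFrame(),
        scale_tag=scale_tag,
    )
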