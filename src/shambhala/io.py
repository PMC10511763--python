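"""Readers and writers for expression matrices (TSV / GCT 1.2) and annotations.

The TSV dialect is: a header row ``gene<TAB>sample1<TAB>sample2...`` followed
by one row per gene.  Duplicate gene rows are collapsed by the per-sample
maximum (with a logged warning); duplicate sample columns are an error.
Missing values are rejected in strict mode (default) or mean-imputed per gene
when ``impute_missing=True`` — the harmonization math assumes complete
matrices.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SampleTable

logger = logging.getLogger("shambhala")


def _check_header(path: Path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: malformed header, expected gene column plus >=1 sample column")
    samples = header[1:]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise ValueError(f"{path}: duplicated sample column name {s!r}")
        seen.add(s)
    return samples


def _locate_bad_cell(frame: pd.DataFrame) -> tuple[str, str]:
    for j, col in enumerate(frame.columns):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            return str(frame.index[bad.argmax()]), str(col)
    return "?", "?"


def read_expression_tsv(
    path: str | Path,
    scale_flag: str = "log2",
    role: str = "R",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load a gene x sample expression TSV.

    ``scale_flag="counts"`` converts values with ``log2(x + 1)``; the returned
    matrix is always on log2 scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_header(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame = raw.apply(pd.to_numeric, errors="coerce")
    non_numeric = frame.isna() & raw.notna()
    if non_numeric.to_numpy().any():
        gene, col = _locate_bad_cell(raw)
        raise ValueError(f"{path}: non-numeric value at gene {gene!r}, sample column {col!r}")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        logger.warning("%s: collapsing %d duplicated gene row(s) by per-sample max: %s",
                       path, len(dups), dups[:5])
        frame = frame.groupby(level=0, sort=False).max()
    if frame.isna().to_numpy().any():
        if not impute_missing:
            gene = frame.index[frame.isna().any(axis=1).argmax()]
            raise ValueError(
                f"{path}: missing value in gene row {gene!r} (strict mode; "
                "pass impute_missing=True to mean-impute)")
        means = frame.mean(axis=1)
        frame = frame.apply(lambda row: row.fillna(means[row.name]), axis=1)
    if scale_flag == "counts":
        if (frame.to_numpy() < 0).any():
            raise ValueError(f"{path}: negative values are not valid counts")
        frame = np.log2(frame + 1.0)
    elif scale_flag != "log2":
        raise ValueError(f"unknown scale_flag {scale_flag!r}")
    return ExpressionMatrix(frame, role=role, scale="log2")


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path, gene_column: str = "gene") -> Path:
    """Write a matrix so that a read/write round trip is exact to ~1e-12."""
    path = Path(path)
    frame = matrix.data.copy()
    frame.index.name = gene_column
    frame.to_csv(path, sep="\t", float_format="%.12g")
    return path


def read_gct(path: str | Path, role: str = "R", scale_flag: str = "log2") -> ExpressionMatrix:
    """Read a GCT 1.2 file (two header lines; Description column ignored)."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ValueError(f"{path}: not a GCT 1.2 file (first line {version!r})")
        fh.readline()  # dimensions line, unused
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    if frame.columns[0].lower() == "description":
        frame = frame.drop(columns=frame.columns[0])
    frame = frame.apply(pd.to_numeric)
    if frame.index.has_duplicates:
        logger.warning("%s: collapsing duplicated gene rows by per-sample max", path)
        frame = frame.groupby(level=0, sort=False).max()
    if scale_flag == "counts":
        frame = np.log2(frame + 1.0)
    return ExpressionMatrix(frame, role=role, scale="log2")


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for gene, row in matrix.data.iterrows():
            vals = "\t".join(f"{v:.12g}" for v in row.to_numpy())
            fh.write(f"{gene}\tna\t{vals}\n")
    return path


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a sample annotation TSV with columns sample_id, tissue_type, platform[, group]."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: annotation table needs a sample_id column")
    frame = frame.set_index("sample_id")
    return SampleTable(frame)


def write_sample_table(table: SampleTable, path: str | Path) -> Path:
    path = Path(path)
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
    return path


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
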