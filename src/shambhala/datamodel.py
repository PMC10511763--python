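"""Core containers for expression matrices, sample annotations and gene summaries.

Expression values are stored as a genes x samples :class:`pandas.DataFrame`
of floats on log2 scale (raw counts are converted to ``log2(x + 1)`` at load
time).  Matrices carry a *role* naming their place in the harmonization
pipeline: the raw dataset ``R``, the calibration dataset ``P``, its
quantile-normalized extension ``Pprime``, the block-transformed
``Pdoubleprime``, the reference definitive dataset ``Q`` and the harmonized
output ``H``.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("shambhala")

ROLES = ("R", "P", "Pprime", "Pdoubleprime", "Q", "H")
SCALES = ("log2", "counts")


@dataclasses.dataclass
class ExpressionMatrix:
    """Gene x sample matrix of expression values.

    Parameters
    ----------
    data:
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  All values must be finite floats.
    role:
        Pipeline role, one of :data:`ROLES`.
    scale:
        ``"log2"`` for log2-scale values (the working scale of every
        transform) or ``"counts"`` for raw counts awaiting conversion.
    """

    data: pd.DataFrame
    role: str = "R"
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown matrix role {self.role!r}; expected one of {ROLES}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("ExpressionMatrix.data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        self.data = self.data.astype(float)
        if self.data.size and not np.isfinite(self.data.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.data.to_numpy()))[0]
            raise ValueError(
                "non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` in the given order."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy(), role=self.role, scale=self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)].copy(), role=self.role, scale=self.scale)

    def with_role(self, role: str) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), role=role, scale=self.scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.copy(), role=self.role, scale=self.scale)


@dataclasses.dataclass
class GeneSummary:
    """Per-gene mean and standard deviation for one dataset role."""

    gene_ids: pd.Index
    mu: np.ndarray
    sigma: np.ndarray
    source_role: str = "Q"

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.gene_ids) == len(self.mu) == len(self.sigma)):
            raise ValueError("gene_ids, mu and sigma must have equal lengths")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    def reindex(self, genes: Sequence[str]) -> "GeneSummary":
        idx = self.gene_ids.get_indexer(list(genes))
        if np.any(idx < 0):
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes absent from summary: {missing[:5]}")
        return GeneSummary(pd.Index(genes), self.mu[idx], self.sigma[idx], self.source_role)


def gene_summaries(matrix: ExpressionMatrix, role: str | None = None) -> GeneSummary:
    """Per-gene mean and sample (n-1 denominator) standard deviation.

    Requires at least two samples; with a single sample the standard
    deviation is undefined and an error is raised.
    """
    if matrix.n_samples < 2:
        raise ValueError("gene_summaries requires >= 2 samples (sigma undefined otherwise)")
    vals = matrix.values
    mu = vals.mean(axis=1)
    sigma = vals.std(axis=1, ddof=1)
    return GeneSummary(matrix.gene_ids, mu, sigma, role or matrix.role)


@dataclasses.dataclass
class SampleTable:
    """Sample annotations: tissue type, platform and optional case/control group.

    The underlying frame is indexed by ``sample_id`` and keeps any extra
    annotation columns untouched.
    """

    data: pd.DataFrame

    REQUIRED = ("tissue_type", "platform")

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("SampleTable.data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id in annotation table: {dups[:5]}")
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"annotation table lacks required column {col!r}")
        if "group" not in self.data.columns:
            self.data = self.data.assign(group=pd.NA)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def require(self, sample_ids: Sequence[str]) -> None:
        """Check every id is annotated exactly once."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples missing from annotation table: {missing[:5]}")

    def labels(self, column: str, sample_ids: Sequence[str]) -> np.ndarray:
        self.require(sample_ids)
        if column not in self.data.columns:
            raise KeyError(f"no annotation column {column!r}")
        return self.data.loc[list(sample_ids), column].to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        self.require(sample_ids)
        return SampleTable(self.data.loc[list(sample_ids)].copy())
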