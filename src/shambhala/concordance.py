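"""Agreement statistics between score vectors from two computation routes.

For a pair of vectors (v1, v2) — e.g. median expression profiles of the same
tissue in a training and a validation dataset, or drug scores computed under
two normalizations — the battery reports the Spearman correlation, the
regression slopes with and without intercept (k1, k2), and their geometric
mean k (set to zero when k1 and k2 disagree in sign), plus sign-change
stability curves: the percentage of components whose sign flips beyond a
symmetric dead zone of width w around zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .datamodel import ExpressionMatrix


@dataclasses.dataclass
class ConcordanceResult:
    rho: float
    k1: float
    k2: float
    k: float
    b: float


@dataclasses.dataclass
class SignChangeCurve:
    w_grid: np.ndarray  # widths, in units of the pooled median absolute score
    pct: np.ndarray     # percentage of sign-changed components at each width
    mode: str           # "as_is" or "divided_by_k"
    unit: float         # the raw score value of one width unit


def median_profiles(matrix: ExpressionMatrix, labels: np.ndarray | list) -> dict:
    """Per-class per-gene median log-expression vectors (gene order preserved)."""
    labels = np.asarray(labels)
    if len(labels) != matrix.n_samples:
        raise ValueError("one label per sample required")
    out = {}
    for cls in np.unique(labels):
        out[cls] = np.median(matrix.values[:, labels == cls], axis=1)
    return out


def concordance_stats(v1: np.ndarray, v2: np.ndarray) -> ConcordanceResult:
    """Spearman rho plus regression slopes k1 (with offset), k2 (through origin)
    and the combined coefficient k.

    k = sign(k1) * sqrt(k1 * k2) when k1 * k2 > 0, else 0.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1 or len(v1) < 3:
        raise ValueError("v1 and v2 must be equal-length 1-d vectors of length >= 3")
    if np.ptp(v1) == 0:
        raise ValueError("v1 is constant; regression slope undefined")
    rho = float(stats.spearmanr(v1, v2).statistic)
    k1, b = np.polyfit(v1, v2, 1)
    k2 = float(v1 @ v2 / (v1 @ v1))
    prod = k1 * k2
    if prod > 0:
        k = float(np.sign(k1) * np.sqrt(prod))
    else:
        k = 0.0
    return ConcordanceResult(rho=rho, k1=float(k1), k2=k2, k=k, b=float(b))


def sign_change_curve(v1: np.ndarray, v2: np.ndarray, w_grid: np.ndarray | list,
                      mode: str = "as_is", k: float | None = None,
                      units: str = "median_abs") -> SignChangeCurve:
    """Percentage of sign-changed components vs the dead-zone width w.

    Component i is sign-changing when ``v1[i] < -w/2 and v2[i] > w/2`` or
    vice versa (strict inequalities; zeros never sign-change).  With
    ``units="median_abs"`` the grid is expressed in units of the median
    absolute value of the pooled vectors; ``units="raw"`` uses w directly.
    In ``divided_by_k`` mode v2 is replaced by v2 / k before counting.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("v1 and v2 must have equal length")
    w_grid = np.asarray(w_grid, dtype=float)
    if np.any(w_grid < 0):
        raise ValueError("widths must be >= 0")
    if mode == "divided_by_k":
        if k is None or k == 0:
            raise ValueError("divided_by_k mode requires a non-zero k")
        v2 = v2 / k
    elif mode != "as_is":
        raise ValueError(f"unknown mode {mode!r}")
    if units == "median_abs":
        unit = float(np.median(np.abs(np.concatenate([v1, v2]))))
        if unit == 0:
            unit = 1.0
    elif units == "raw":
        unit = 1.0
    else:
        raise ValueError(f"unknown units {units!r}")
    pct = np.empty_like(w_grid)
    for i, w in enumerate(w_grid):
        half = w * unit / 2.0
        flips = ((v1 < -half) & (v2 > half)) | ((v2 < -half) & (v1 > half))
        pct[i] = 100.0 * flips.sum() / len(v1)
    return SignChangeCurve(w_grid=w_grid, pct=pct, mode=mode, unit=unit)


def marker_genes_auc(matrix: ExpressionMatrix, binary_labels: np.ndarray | list,
                     threshold: float = 0.8) -> dict:
    """Per-gene two-class ROC AUC (orientation-folded); markers are genes with
    folded AUC strictly above the threshold.

    Returns {"auc": {gene: folded AUC}, "markers": [gene, ...]}.
    """
    labels = np.asarray(binary_labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("binary_labels must contain exactly two non-empty classes")
    pos = labels == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    aucs = {}
    for gi, gene in enumerate(matrix.gene_ids):
        ranks = stats.rankdata(matrix.values[gi])  # midpoint ranks handle ties
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs[str(gene)] = float(max(auc, 1.0 - auc))
    markers = sorted(g for g, a in aucs.items() if a > threshold)
    return {"auc": aucs, "markers": markers}
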