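"""The Shambhala uniformly-shaped harmonization pipeline.

Every raw profile is harmonized *independently*: the profile is merged as one
extra column into the calibration dataset P, the merged set is
quantile-normalized (P'), P' is transformed into the shape of the reference
definitive dataset Q by a block transform — the XPN block-linear model for
Shambhala-1 or the CuBlock per-block cubic quantile map for Shambhala-2 —
and the profile's column of the transformed set (P'') is kept.  After all
profiles are processed the assembled matrix is rescaled per gene by one of
three modes:

``PBR``  LE = mu_gQ + LE'' * sigma_gQ          (treats LE'' as standardized)
``QBR``  LE = mu_gQ + (LE'' - mu_gH) * sigma_gQ / sigma_gH
``RBR``  LE = mu_gR + (LE'' - mu_gH) * sigma_gR / sigma_gH

PBR uses only the Q summaries, so each harmonized column is invariant to
which other samples were in the batch; QBR/RBR depend on the batch through
the H (and R) summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .datamodel import ExpressionMatrix, GeneSummary, gene_summaries

logger = logging.getLogger("shambhala")

RESCALE_MODES = ("PBR", "QBR", "RBR")
METHODS = ("shambhala1", "shambhala2")


@dataclasses.dataclass
class XPNParams:
    """Block-linear (XPN) transform parameters.

    ``reference_weight`` is the weight of the reference dataset Q when the
    per-platform block parameters are combined; 1.0 anchors the fused model
    fully on Q so the output lands in Q's shape, 0.5 reproduces the classic
    symmetric cross-platform average.
    """

    gene_clusters: int = 25
    sample_clusters: int = 5
    n_repeats: int = 30
    max_iter: int = 30
    tol: float = 1e-6
    reference_weight: float = 1.0

    def validate(self) -> None:
        if self.gene_clusters < 2 or self.sample_clusters < 2:
            raise ValueError("XPN requires >= 2 gene clusters and >= 2 sample clusters")
        if not 0.0 <= self.reference_weight <= 1.0:
            raise ValueError("reference_weight must be in [0, 1]")


@dataclasses.dataclass
class CuBlockParams:
    """Per-block cubic quantile-map (CuBlock) parameters."""

    n_blocks: int = 8
    poly_degree: int = 3
    clamp: bool = True
    n_quantiles: int = 101
    min_block_values: int = 8

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.poly_degree != 3:
            raise ValueError("poly_degree is fixed at 3")


@dataclasses.dataclass
class HarmonizationConfig:
    method: str = "shambhala2"
    rescale_mode: str = "PBR"
    xpn: XPNParams = dataclasses.field(default_factory=XPNParams)
    cublock: CuBlockParams = dataclasses.field(default_factory=CuBlockParams)
    seed: int = 0
    sigma_floor: float = 1e-8
    qn_merge: str = "merge"  # "merge": weight-1 extra column; "project": onto P's fixed quantiles

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.rescale_mode not in RESCALE_MODES:
            raise ValueError(f"rescale_mode must be one of {RESCALE_MODES}")
        if self.sigma_floor <= 0:
            raise ValueError("sigma_floor must be > 0")
        if self.qn_merge not in ("merge", "project"):
            raise ValueError("qn_merge must be 'merge' or 'project'")
        self.xpn.validate()
        self.cublock.validate()


# ---------------------------------------------------------------------------
# gene intersection
# ---------------------------------------------------------------------------

def intersect_and_filter_genes(
    R: ExpressionMatrix,
    P: ExpressionMatrix,
    Q: ExpressionMatrix,
    top_n_by_p_median: int | None = None,
) -> list[str]:
    """Sorted intersection of the three gene sets.

    Expression filtering is implicit in the choice of P (its restricted gene
    list acts like an expression filter), so no threshold is applied by
    default.  ``top_n_by_p_median`` optionally keeps only the N genes with
    the highest median expression in P.
    """
    common = set(R.gene_ids) & set(P.gene_ids) & set(Q.gene_ids)
    if not common:
        raise ValueError(
            "empty gene intersection between R, P and Q — check that all three "
            "use the same gene identifier namespace")
    genes = sorted(common)
    if top_n_by_p_median is not None and top_n_by_p_median < len(genes):
        med = P.data.loc[genes].median(axis=1)
        genes = sorted(med.nlargest(top_n_by_p_median).index)
    logger.info("gene intersection: |R|=%d |P|=%d |Q|=%d -> %d genes",
                R.n_genes, P.n_genes, Q.n_genes, len(genes))
    return genes


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def _qn_values(vals: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Map every column of ``vals`` onto the sorted reference ``ref``.

    Ties within a column receive the mean of the reference values they span.
    """
    n, m = vals.shape
    out = np.empty_like(vals, dtype=float)
    for j in range(m):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        # average reference values over tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        groups = np.split(order, boundaries)
        for grp in groups:
            if len(grp) > 1:
                assigned[grp] = assigned[grp].mean()
        out[:, j] = assigned
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples so each shares the mean sorted profile."""
    if matrix.n_samples < 2:
        logger.warning("quantile_normalize on a single-sample matrix is the identity")
        return matrix.copy()
    vals = matrix.values
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = _qn_values(vals, ref)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids),
        role=matrix.role, scale="log2")


def quantile_project(column: np.ndarray, reference: ExpressionMatrix) -> np.ndarray:
    """Project one profile onto the fixed quantiles of ``reference``.

    Alternative to weight-1 merging: the new sample takes the reference's
    mean sorted vector in its own rank order and does not perturb it.
    """
    ref = np.sort(reference.values, axis=0).mean(axis=1)
    return _qn_values(column[:, None], ref)[:, 0]


# ---------------------------------------------------------------------------
# XPN block-linear transform (Shambhala-1)
# ---------------------------------------------------------------------------

def _fit_block_model(X: np.ndarray, alpha: np.ndarray, beta: np.ndarray,
                     K: int, L: int, max_iter: int, tol: float,
                     sigma_floor: float = 1e-8):
    """Iterative least squares for x_gi ~ A[alpha(g), beta(i)] * b_g + c_g.

    Returns (A, b, c, sigma); A entries for blocks with no samples are NaN.
    """
    G, n = X.shape
    b = np.ones(G)
    c = X.mean(axis=1)
    A = np.full((K, L), np.nan)
    counts = np.zeros((K, L))
    for l in range(L):
        counts[:, l] = np.bincount(alpha, minlength=K) * np.sum(beta == l)
    prev = None
    for _ in range(max_iter):
        # A step: per-block weighted mean of b_g * (x_gi - c_g)
        R = (X - c[:, None]) * b[:, None]
        bsq = b ** 2
        for k in range(K):
            gmask = alpha == k
            if not gmask.any():
                continue
            denom_g = bsq[gmask].sum()
            for l in range(L):
                smask = beta == l
                ns = int(smask.sum())
                if ns == 0 or denom_g <= 0:
                    continue
                A[k, l] = R[np.ix_(gmask, smask)].sum() / (ns * denom_g)
        # b, c step: per-gene OLS of X_g on t = A[alpha(g), beta(:)]
        T = A[alpha][:, beta]  # G x n
        tbar = np.nanmean(T, axis=1)
        xbar = X.mean(axis=1)
        Tc = T - tbar[:, None]
        var_t = np.einsum("ij,ij->i", Tc, Tc)
        cov = np.einsum("ij,ij->i", Tc, X - xbar[:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            b_new = np.where(var_t > 1e-12, cov / np.where(var_t > 0, var_t, 1.0), 0.0)
        c_new = xbar - b_new * tbar
        b, c = b_new, c_new
        cur = A[counts > 0]
        if prev is not None and np.nanmax(np.abs(cur - prev)) < tol:
            break
        prev = cur.copy()
    T = A[alpha][:, beta]
    resid = X - T * b[:, None] - c[:, None]
    sigma = np.maximum(resid.std(axis=1, ddof=1) if n > 1 else np.zeros(G), sigma_floor)
    return A, b, c, sigma


def xpn_transform(Pprime: ExpressionMatrix, Q: ExpressionMatrix,
                  params: XPNParams | None = None, seed: int = 0) -> ExpressionMatrix:
    """Block-linear (XPN) transform of P' toward the shape of Q.

    Genes are k-means clustered into K groups and samples into L groups on
    per-gene standardized pooled data; the block model
    ``x_gi ~ A[alpha(g), beta(i)] * b_g + c_g + sigma_g * eps`` is fitted per
    platform by iterative least squares, the platform parameters are combined
    with weight ``reference_weight`` on Q, and P' residuals are re-expressed
    under the combined model.  Results are averaged over ``n_repeats`` random
    clustering restarts.
    """
    params = params or XPNParams()
    params.validate()
    if not Pprime.gene_ids.equals(Q.gene_ids):
        raise ValueError("xpn_transform requires identical gene lists in P' and Q")
    K, L = params.gene_clusters, params.sample_clusters
    G = Pprime.n_genes
    nP, nQ = Pprime.n_samples, Q.n_samples
    if min(nP, nQ) < max(L, 3):
        raise ValueError(f"each dataset needs >= max(L, 3) = {max(L, 3)} samples")
    if K > G:
        raise ValueError("more gene clusters than genes")

    XP, XQ = Pprime.values, Q.values
    pooled = np.hstack([XP, XQ])
    mu = pooled.mean(axis=1, keepdims=True)
    sd = np.maximum(pooled.std(axis=1, keepdims=True, ddof=1), 1e-8)
    Z = (pooled - mu) / sd

    rng = np.random.default_rng(seed)
    acc = np.zeros_like(XP)
    w_q = params.reference_weight
    for _ in range(max(1, params.n_repeats)):
        gene_seed = int(rng.integers(0, 2**31 - 1))
        samp_seed = int(rng.integers(0, 2**31 - 1))
        alpha = KMeans(n_clusters=K, n_init=2, random_state=gene_seed).fit_predict(Z)
        # sample clusters fitted on Q (the reference), P' assigned to nearest centroid
        km_s = KMeans(n_clusters=L, n_init=2, random_state=samp_seed).fit(Z[:, nP:].T)
        beta_q = km_s.labels_
        beta_p = km_s.predict(Z[:, :nP].T)
        A_p, b_p, c_p, s_p = _fit_block_model(XP, alpha, beta_p, K, L, params.max_iter, params.tol)
        A_q, b_q, c_q, s_q = _fit_block_model(XQ, alpha, beta_q, K, L, params.max_iter, params.tol)
        # combine platform parameters; NaN blocks on the P side fall back to Q
        A_bar = np.where(np.isnan(A_p), A_q, (1 - w_q) * A_p + w_q * A_q)
        b_bar = (1 - w_q) * b_p + w_q * b_q
        c_bar = (1 - w_q) * c_p + w_q * c_q
        s_bar = (1 - w_q) * s_p + w_q * s_q
        T_p = A_p[alpha][:, beta_p]
        eps = (XP - T_p * b_p[:, None] - c_p[:, None]) / s_p[:, None]
        acc += A_bar[alpha][:, beta_p] * b_bar[:, None] + c_bar[:, None] + s_bar[:, None] * eps
    out = acc / max(1, params.n_repeats)
    return ExpressionMatrix(
        pd.DataFrame(out, index=Pprime.gene_ids, columns=Pprime.sample_ids),
        role="Pdoubleprime", scale="log2")


# ---------------------------------------------------------------------------
# CuBlock transform (Shambhala-2)
# ---------------------------------------------------------------------------

def _zscore_rows(vals: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    mu = vals.mean(axis=1, keepdims=True)
    sd = np.maximum(vals.std(axis=1, keepdims=True, ddof=1), floor)
    return (vals - mu) / sd


def _monotone_apply(coef: np.ndarray, x: np.ndarray, lo: float, hi: float,
                    n_grid: int = 512) -> np.ndarray:
    """Evaluate a fitted polynomial through its monotone envelope on [lo, hi]."""
    grid = np.linspace(lo, hi, n_grid)
    y = np.polyval(coef, grid)
    y = np.maximum.accumulate(y)
    return np.interp(x, grid, y)


def cublock_transform(Pprime: ExpressionMatrix, Q: ExpressionMatrix,
                      params: CuBlockParams | None = None, seed: int = 0) -> ExpressionMatrix:
    """Piecewise-cubic (CuBlock) transform of P' toward the shape of Q.

    Both datasets are z-scored per gene; genes of the pooled standardized
    data are k-means clustered into B blocks; within each block a cubic is
    least-squares fitted mapping P' block quantiles onto Q block quantiles
    and applied to the P' values of that block.  Q is the fixed reference.
    The output stays on the standardized scale — the subsequent rescaling
    step restores per-gene location and scale.
    """
    params = params or CuBlockParams()
    params.validate()
    if not Pprime.gene_ids.equals(Q.gene_ids):
        raise ValueError("cublock_transform requires identical gene lists in P' and Q")
    zP = _zscore_rows(Pprime.values)
    zQ = _zscore_rows(Q.values)
    B = params.n_blocks
    if B == 1:
        labels = np.zeros(Pprime.n_genes, dtype=int)
    else:
        pooled = np.hstack([zP, zQ])
        labels = KMeans(n_clusters=min(B, Pprime.n_genes), n_init=2,
                        random_state=seed % (2**31 - 1)).fit_predict(pooled)
    out = np.empty_like(zP)
    probs = np.linspace(0.0, 1.0, params.n_quantiles)
    for blk in np.unique(labels):
        gmask = labels == blk
        xp = zP[gmask].ravel()
        xq = zQ[gmask].ravel()
        if np.ptp(xp) < 1e-10:
            out[gmask] = zP[gmask] - xp.mean() + xq.mean()
            continue
        qp = np.quantile(xp, probs)
        qq = np.quantile(xq, probs)
        if min(xp.size, xq.size) < params.min_block_values:
            logger.warning("cublock block %s has < %d values; falling back to linear fit",
                           blk, params.min_block_values)
            deg = 1
        else:
            deg = params.poly_degree
        coef = np.polyfit(qp, qq, deg)
        vals = zP[gmask]
        if params.clamp and deg > 1:
            out[gmask] = _monotone_apply(coef, vals, float(xp.min()), float(xp.max()))
        else:
            out[gmask] = np.polyval(coef, vals)
    return ExpressionMatrix(
        pd.DataFrame(out, index=Pprime.gene_ids, columns=Pprime.sample_ids),
        role="Pdoubleprime", scale="log2")


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

def rescale(Hraw: ExpressionMatrix, mode: str, sumQ: GeneSummary,
            sumH: GeneSummary | None = None, sumR: GeneSummary | None = None,
            sigma_floor: float = 1e-8) -> ExpressionMatrix:
    """Apply P-, Q- or R-based rescaling to the assembled harmonized matrix."""
    if mode not in RESCALE_MODES:
        raise ValueError(f"unknown rescale mode {mode!r}")
    genes = Hraw.gene_ids
    sumQ = sumQ.reindex(genes)
    vals = Hraw.values
    if mode == "PBR":
        out = sumQ.mu[:, None] + vals * sumQ.sigma[:, None]
    else:
        if sumH is None:
            raise ValueError(f"{mode} rescaling needs the H summary")
        sumH = sumH.reindex(genes)
        if mode == "QBR":
            tgt_mu, tgt_sd = sumQ.mu, sumQ.sigma
        else:  # RBR
            if sumR is None:
                raise ValueError("RBR rescaling needs the R summary")
            sumR = sumR.reindex(genes)
            tgt_mu, tgt_sd = sumR.mu, sumR.sigma
        degenerate = sumH.sigma < sigma_floor
        safe_sd = np.where(degenerate, 1.0, sumH.sigma)
        out = tgt_mu[:, None] + (vals - sumH.mu[:, None]) * (tgt_sd / safe_sd)[:, None]
        if degenerate.any():
            logger.warning("%d gene(s) with sigma_H < %.1g mapped to the target mean",
                           int(degenerate.sum()), sigma_floor)
            out[degenerate] = np.broadcast_to(tgt_mu[degenerate][:, None],
                                              (int(degenerate.sum()), vals.shape[1]))
    return ExpressionMatrix(
        pd.DataFrame(out, index=genes, columns=Hraw.sample_ids), role="H", scale="log2")


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _sample_seed(master: int, sample_id: str) -> int:
    """Deterministic per-sample seed, invariant to batch composition."""
    digest = hashlib.sha256(f"{master}:{sample_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def harmonize_one(column: np.ndarray, sample_id: str, P: ExpressionMatrix,
                  Q: ExpressionMatrix, config: HarmonizationConfig) -> np.ndarray:
    """Harmonize a single profile (already restricted to the intersection genes)."""
    seed = _sample_seed(config.seed, sample_id)
    if config.qn_merge == "project":
        merged = np.hstack([_qn_values(P.values, np.sort(P.values, axis=0).mean(axis=1)),
                            quantile_project(column, P)[:, None]])
    else:
        stacked = np.hstack([P.values, column[:, None]])
        ref = np.sort(stacked, axis=0).mean(axis=1)
        merged = _qn_values(stacked, ref)
    cols = list(P.sample_ids) + [f"__{sample_id}"]
    Pprime = ExpressionMatrix(pd.DataFrame(merged, index=P.gene_ids, columns=cols),
                              role="Pprime", scale="log2")
    if config.method == "shambhala1":
        Pdp = xpn_transform(Pprime, Q, config.xpn, seed=seed)
    else:
        Pdp = cublock_transform(Pprime, Q, config.cublock, seed=seed)
    return Pdp.values[:, -1]


def shambhalize(R: ExpressionMatrix, P: ExpressionMatrix, Q: ExpressionMatrix,
                config: HarmonizationConfig | None = None) -> ExpressionMatrix:
    """Harmonize every profile of R against the auxiliary datasets P and Q."""
    config = config or HarmonizationConfig()
    config.validate()
    if P.n_samples < 10 or Q.n_samples < 10:
        raise ValueError("P and Q each need >= 10 samples")
    genes = intersect_and_filter_genes(R, P, Q)
    Rg, Pg, Qg = (m.subset_genes(genes) for m in (R, P, Q))
    cols = np.empty((len(genes), Rg.n_samples))
    for i, sid in enumerate(Rg.sample_ids):
        try:
            cols[:, i] = harmonize_one(Rg.values[:, i], str(sid), Pg, Qg, config)
        except Exception as exc:  # pragma: no cover - defensive re-raise with context
            raise RuntimeError(f"harmonization failed for sample {sid!r}: {exc}") from exc
    Hraw = ExpressionMatrix(pd.DataFrame(cols, index=genes, columns=Rg.sample_ids),
                            role="H", scale="log2")
    sumQ = gene_summaries(Qg, "Q")
    sumH = gene_summaries(Hraw, "H") if (config.rescale_mode != "PBR") else None
    sumR = gene_summaries(Rg, "R") if config.rescale_mode == "RBR" else None
    if config.rescale_mode != "PBR" and Hraw.n_samples < 2:
        raise ValueError(f"{config.rescale_mode} rescaling needs >= 2 samples in R")
    return rescale(Hraw, config.rescale_mode, sumQ, sumH, sumR, config.sigma_floor)
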