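"""End-to-end evaluation of the harmonizer on the synthetic benchmark.

Generates the default two-platform, four-tissue benchmark, harmonizes both
platform datasets with Shambhala-2 (P-based rescaling) against the bundled
auxiliary P/Q sets, and evaluates the full battery: WM quality ratios before
and after harmonization, cross-platform 1nn transfer accuracy, same-tissue
median-profile concordance, planted pathway-shift sign recovery, and BES
sign-change stability between the two platforms' control sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import transfer_accuracy
from .cluster_quality import quality_ratio
from .concordance import concordance_stats, median_profiles, sign_change_curve
from .datamodel import ExpressionMatrix
from .harmonize import HarmonizationConfig, shambhalize
from .scores import PathwayDB
from .synthdata import (
    SyntheticConfig,
    SyntheticTruth,
    generate_auxiliary,
    generate_multiplatform,
    generate_pathway_fixtures,
)

logger = logging.getLogger("shambhala")


def harmonized_benchmark(seed: int = 0, config: SyntheticConfig | None = None,
                         method: str = "shambhala2", rescale_mode: str = "PBR"):
    """Generate the benchmark and harmonize each platform dataset.

    Returns ``(mats, H, truth, pre, post)`` where ``pre``/``post`` are the
    merged unharmonized / harmonized matrices restricted to the surviving
    gene list.
    """
    cfg = config or SyntheticConfig(seed=seed)
    mats, truth = generate_multiplatform(cfg)
    P, Q = generate_auxiliary(cfg)
    hcfg = HarmonizationConfig(method=method, rescale_mode=rescale_mode,
                               seed=(seed + 1) % (2**31 - 1))
    H = [shambhalize(m, P, Q, hcfg) for m in mats]
    genes = list(H[0].gene_ids)
    pre = ExpressionMatrix(pd.concat([m.data.loc[genes] for m in mats], axis=1), role="R")
    post = ExpressionMatrix(pd.concat([h.data for h in H], axis=1), role="H")
    return mats, H, truth, pre, post


def pal_sign_recovery(H: ExpressionMatrix, truth: SyntheticTruth, pw_db: PathwayDB) -> float:
    """Fraction of planted pathway shifts whose PAL sign is recovered.

    For every case sample the per-gene LFC against the tissue-matched control
    medians is aggregated into the pathway's role-weighted activation; the
    pathway counts as recovered when the median PAL over cases carries the
    planted sign.
    """
    ann = truth.samples.data.loc[H.sample_ids]
    gi = {g: i for i, g in enumerate(H.gene_ids)}
    vals = H.values
    recovered = []
    for pw, led in truth.shift_ledger.items():
        roles = {g: w for g, w in pw_db.pathways[pw].items() if g in gi}
        if not roles:
            continue
        rows = np.array([gi[g] for g in roles])
        weights = np.array([roles[g] for g in roles])
        pals = []
        for tissue in ann["tissue_type"].unique():
            in_tissue = ann["tissue_type"] == tissue
            ctrl_idx = np.flatnonzero(in_tissue & (ann["group"] == "control"))
            case_idx = np.flatnonzero(in_tissue & (ann["group"] == "case"))
            if len(ctrl_idx) == 0 or len(case_idx) == 0:
                continue
            ctrl_med = np.median(vals[np.ix_(rows, ctrl_idx)], axis=1)
            lfc = vals[np.ix_(rows, case_idx)] - ctrl_med[:, None]
            pals.extend((weights @ lfc) / np.abs(weights).sum())
        recovered.append(np.sign(np.median(pals)) == led["sign"])
    return float(np.mean(recovered))


def cross_platform_bes(H0: ExpressionMatrix, H1: ExpressionMatrix,
                       truth: SyntheticTruth, config: SyntheticConfig):
    """Pooled drug-score (BES) vectors for every case, computed twice:
    against platform-0 controls (v1) and platform-1 controls (v2)."""
    from .scores import drug_efficiency, log_fold_change, pathway_activation

    pw_db, drug_db = generate_pathway_fixtures(config)
    ann = truth.samples.data
    v1_all, v2_all = [], []
    cases = [s for s in H0.sample_ids if ann.loc[s, "group"] == "case"]
    for case_id in cases:
        tissue = ann.loc[case_id, "tissue_type"]
        scores = []
        for ctrl_matrix in (H0, H1):
            ctrl_ids = [s for s in ctrl_matrix.sample_ids
                        if ann.loc[s, "tissue_type"] == tissue
                        and ann.loc[s, "group"] == "control"]
            lfc = log_fold_change(H0.subset_samples([case_id]),
                                  ctrl_matrix.subset_samples(ctrl_ids))
            pal = pathway_activation(lfc, pw_db)
            scores.append(drug_efficiency(pal, lfc, drug_db))
        ids = [d for d in scores[0].ids if d in set(scores[1].ids)]
        m0, m1 = scores[0].as_dict(), scores[1].as_dict()
        v1_all.extend(m0[d] for d in ids)
        v2_all.extend(m1[d] for d in ids)
    return np.array(v1_all), np.array(v2_all)


def run_benchmark(seed: int = 0, config: SyntheticConfig | None = None) -> dict:
    """Run the whole battery; every reported value is computed from scratch."""
    cfg = config or SyntheticConfig(seed=seed)
    mats, H, truth, pre, post = harmonized_benchmark(seed, cfg)
    ann = truth.samples
    qr_seed = (seed + 2) % (2**31 - 1)
    qr_pre = quality_ratio(pre, ann, seed=qr_seed)
    qr_post = quality_ratio(post, ann, seed=qr_seed)

    genes = list(H[0].gene_ids)
    lab = lambda m: ann.labels("tissue_type", m.sample_ids)
    acc_pre = transfer_accuracy(mats[0].subset_genes(genes), lab(mats[0]),
                                mats[1].subset_genes(genes), lab(mats[1]), "knn1")
    acc_post = transfer_accuracy(H[0], lab(H[0]), H[1], lab(H[1]), "knn1")

    mp0 = median_profiles(H[0], lab(H[0]))
    mp1 = median_profiles(H[1], lab(H[1]))
    stats_by_tissue = [concordance_stats(mp0[t], mp1[t]) for t in mp0]
    rho_post = float(np.median([s.rho for s in stats_by_tissue]))
    k_post = float(np.median([s.k for s in stats_by_tissue]))

    pw_db, _ = generate_pathway_fixtures(cfg)
    recovery = pal_sign_recovery(H[0], truth, pw_db)

    v1, v2 = cross_platform_bes(H[0], H[1], truth, cfg)
    bes_stats = concordance_stats(v1, v2)
    grid = np.array([0.0, 1.0, 2.0, 4.0])
    curve_asis = sign_change_curve(v1, v2, grid, mode="as_is")
    k_for_div = bes_stats.k if bes_stats.k != 0 else 1.0
    curve_div = sign_change_curve(v1, v2, grid, mode="divided_by_k", k=k_for_div)

    n_samples = pre.n_samples
    return {
        "config": cfg,
        "n_genes_harmonized": len(genes),
        "n_samples": n_samples,
        "quality_ratio_unharmonized": qr_pre.ratio,
        "quality_ratio_harmonized": qr_post.ratio,
        "quality_ratio_improvement_factor": qr_post.ratio / qr_pre.ratio,
        "wm_platform_unharmonized": qr_pre.wm_p,
        "wm_platform_harmonized": qr_post.wm_p,
        "wm_tissue_harmonized": qr_post.wm_s,
        "knn1_accuracy_unharmonized": acc_pre.total_accuracy,
        "knn1_accuracy_harmonized": acc_post.total_accuracy,
        "median_profile_spearman_harmonized": rho_post,
        "median_profile_k_harmonized": k_post,
        "pal_sign_recovery_fraction": recovery,
        "bes_spearman_cross_controls": bes_stats.rho,
        "bes_k_cross_controls": bes_stats.k,
        "bes_sign_change_pct_w1_as_is": float(curve_asis.pct[1]),
        "bes_sign_change_pct_w1_divided_by_k": float(curve_div.pct[1]),
    }
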