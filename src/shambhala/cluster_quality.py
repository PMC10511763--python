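"""Hierarchical clustering and the Watermelon Multisection (WM) quality metric.

WM scores how quickly the splits of a dendrogram, taken root-down, separate
known classes.  Walking from the root, each split refines the partition of
the leaves; the cumulative normalized information gain after j splits forms
the *observed* trajectory.  WM compares its area with the area of the
theoretically *maximal* (fastest-separation) trajectory and a permutation
*null* trajectory:

    WM = (A_obs - A_null) / (A_max - A_null)

so a dendrogram whose first splits isolate the classes scores 1 and a
dendrogram that distributes classes at random scores ~0.  The harmonization
quality ratio contrasts WM computed against tissue-type classes (WM_S) with
WM against platform classes (WM_P): R = WM_S / WM_P, higher is better.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .datamodel import ExpressionMatrix, SampleTable

logger = logging.getLogger("shambhala")


@dataclasses.dataclass
class Dendrogram:
    """Agglomerative tree over samples: a scipy linkage matrix plus leaf ids."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def to_newick(self) -> str:
        """Plain newick export with merge heights as branch lengths."""
        n = self.n_leaves
        names: dict[int, str] = {i: str(self.leaf_ids[i]) for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            names[n + k] = f"({names[a]}:{la:.6g},{names[b]}:{lb:.6g})"
            heights[n + k] = h
        return names[n + self.n_leaves - 2] + ";"


@dataclasses.dataclass
class IGTrajectory:
    """Observed / maximal / null information-gain trajectories and the WM value."""

    observed: np.ndarray
    maximal: np.ndarray
    null: np.ndarray | None = None
    wm: float | None = None
    wm_raw: float | None = None


@dataclasses.dataclass
class QualityRatio:
    wm_s: float
    wm_p: float
    ratio: float
    replicates: list[tuple[float, float, float]]


def hierarchical_cluster(matrix: ExpressionMatrix, distance: str = "correlation",
                         method: str = "average") -> Dendrogram:
    """Cluster samples; default distance 1 - Pearson correlation across genes."""
    if matrix.n_samples < 3:
        raise ValueError("hierarchical clustering needs >= 3 samples")
    X = matrix.values.T  # samples x genes
    if distance == "correlation":
        sds = X.std(axis=1)
        if np.any(sds == 0):
            bad = matrix.sample_ids[int(np.argmax(sds == 0))]
            raise ValueError(f"sample {bad!r} is constant; correlation distance undefined")
        D = pdist(X, metric="correlation")
    elif distance == "euclidean":
        D = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    Z = linkage(D, method=method)
    return Dendrogram(Z, [str(s) for s in matrix.sample_ids])


# ---------------------------------------------------------------------------
# information-gain trajectories
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot == 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _node_label_counts(dend: Dendrogram, codes: np.ndarray, m: int) -> np.ndarray:
    """Label count vectors for every node (leaves then internal), bottom-up."""
    n = dend.n_leaves
    counts = np.zeros((2 * n - 1, m))
    counts[np.arange(n), codes] = 1.0
    for k, (a, b, _, _) in enumerate(dend.merges):
        counts[n + k] = counts[int(a)] + counts[int(b)]
    return counts


def observed_trajectory(dend: Dendrogram, codes: np.ndarray, m: int) -> np.ndarray:
    """Cumulative normalized IG after j splits, j = 0 .. n-1.

    Splits are applied in reverse merge order (the root first); for monotone
    linkages this equals decreasing merge height, with ties broken by
    internal node index.
    """
    n = dend.n_leaves
    counts = _node_label_counts(dend, codes, m)
    H_total = _entropy(counts[2 * n - 2])
    ent = np.array([_entropy(c) for c in counts])
    sizes = counts.sum(axis=1)
    # conditional entropy starts at H_total (single cluster = root)
    h_cond = np.empty(n)
    h_cond[0] = H_total
    step = 0
    for k in range(n - 2, -1, -1):  # reverse merge order: root split first
        a, b = int(dend.merges[k, 0]), int(dend.merges[k, 1])
        parent = n + k
        delta = (sizes[a] * ent[a] + sizes[b] * ent[b] - sizes[parent] * ent[parent]) / n
        step += 1
        h_cond[step] = h_cond[step - 1] + delta
    if H_total <= 0:
        raise ValueError("labels have zero entropy (single class); WM undefined")
    return (H_total - h_cond) / H_total


def maximal_trajectory(codes: np.ndarray, m: int, n_leaves: int) -> np.ndarray:
    """Fastest-separation trajectory: 1 for j >= m-1; greedy class isolation below."""
    counts = np.bincount(codes, minlength=m).astype(float)
    counts = counts[counts > 0]
    m_eff = len(counts)
    n = counts.sum()
    H_total = _entropy(counts)
    order = np.argsort(-counts)
    traj = np.ones(n_leaves)
    traj[0] = 0.0
    for j in range(1, min(m_eff - 1, n_leaves)):
        rest = counts[order[j:]]
        h_cond = (rest.sum() / n) * _entropy(rest)
        traj[j] = (H_total - h_cond) / H_total
    return traj


def ig_trajectory(dend: Dendrogram, labels: np.ndarray | list) -> IGTrajectory:
    """Observed and maximal information-gain trajectories for a labelled tree."""
    labels = np.asarray(labels)
    if len(labels) != dend.n_leaves:
        raise ValueError("one label per leaf required")
    classes, codes = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 distinct labels; WM undefined for a single class")
    obs = observed_trajectory(dend, codes, len(classes))
    mx = maximal_trajectory(codes, len(classes), dend.n_leaves)
    return IGTrajectory(observed=obs, maximal=mx)


def wm_metric(dend: Dendrogram, labels: np.ndarray | list, n_perm: int = 100,
              seed: int = 0) -> IGTrajectory:
    """WM = (A_obs - A_null) / (A_max - A_null), areas over j = 1 .. n-1.

    The null trajectory is the mean observed trajectory over ``n_perm``
    label permutations on the same tree.  ``wm`` is clipped to [0, 1];
    ``wm_raw`` keeps the unclipped value.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a stable null")
    labels = np.asarray(labels)
    traj = ig_trajectory(dend, labels)
    classes, codes = np.unique(labels, return_inverse=True)
    rng = np.random.default_rng(seed)
    null_acc = np.zeros(dend.n_leaves)
    for _ in range(n_perm):
        null_acc += observed_trajectory(dend, rng.permutation(codes), len(classes))
    null = null_acc / n_perm
    a_obs = float(traj.observed[1:].mean())
    a_max = float(traj.maximal[1:].mean())
    a_null = float(null[1:].mean())
    if a_max - a_null <= 0:
        raise ValueError("degenerate tree: maximal trajectory does not exceed the null")
    wm_raw = (a_obs - a_null) / (a_max - a_null)
    traj.null = null
    traj.wm_raw = wm_raw
    traj.wm = float(np.clip(wm_raw, 0.0, 1.0))
    return traj


# ---------------------------------------------------------------------------
# subsampled quality ratio
# ---------------------------------------------------------------------------

def quality_ratio(matrix: ExpressionMatrix, samples: SampleTable, n_per_cell: int = 5,
                  n_repeats: int = 25, seed: int = 0, n_perm: int = 100,
                  distance: str = "euclidean", method: str = "average") -> QualityRatio:
    """Median WM_S / WM_P over repeated balanced subsamples.

    Each repeat draws ``n_per_cell`` samples per tissue x platform cell
    (cells with fewer samples are dropped with a warning), clusters them,
    and evaluates WM against tissue labels (WM_S) and platform labels (WM_P).

    The default distance here is Euclidean, unlike :func:`hierarchical_cluster`:
    platform batch structure lives largely in per-sample location/scale, which
    correlation distance is invariant to — a correlation-based quality ratio
    is blind to exactly the distortions harmonization removes.
    """
    samples.require(matrix.sample_ids)
    ann = samples.data.loc[matrix.sample_ids]
    cells: dict[tuple[str, str], list[str]] = {}
    for sid, row in ann.iterrows():
        cells.setdefault((row["tissue_type"], row["platform"]), []).append(sid)
    kept = {cell: ids for cell, ids in cells.items() if len(ids) >= n_per_cell}
    dropped = set(cells) - set(kept)
    if dropped:
        logger.warning("quality_ratio: dropping %d cell(s) with < %d samples: %s",
                       len(dropped), n_per_cell, sorted(dropped)[:4])
    tissues = {t for t, _ in kept}
    platforms = {p for _, p in kept}
    if len(tissues) < 2 or len(platforms) < 2:
        raise ValueError("need >= 2 tissues and >= 2 platforms after cell filtering")
    rng = np.random.default_rng(seed)
    reps: list[tuple[float, float, float]] = []
    for _ in range(n_repeats):
        chosen: list[str] = []
        for cell in sorted(kept):
            ids = kept[cell]
            chosen.extend(rng.choice(ids, size=n_per_cell, replace=False))
        sub = matrix.subset_samples(chosen)
        dend = hierarchical_cluster(sub, distance=distance, method=method)
        tissue_labels = ann.loc[chosen, "tissue_type"].to_numpy()
        platform_labels = ann.loc[chosen, "platform"].to_numpy()
        perm_seed = int(rng.integers(0, 2**31 - 1))
        wm_s = wm_metric(dend, tissue_labels, n_perm=n_perm, seed=perm_seed).wm
        wm_p = wm_metric(dend, platform_labels, n_perm=n_perm, seed=perm_seed + 1).wm
        # floor the denominator at a small positive value: a platform WM at or
        # below the null level means "no detectable platform clustering"
        reps.append((float(wm_s), float(wm_p), float(wm_s / max(wm_p, 1e-3))))
    arr = np.array(reps)
    med = np.median(arr, axis=0)
    return QualityRatio(wm_s=float(med[0]), wm_p=float(med[1]), ratio=float(med[2]),
                        replicates=[tuple(r) for r in reps])
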