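"""Seeded generator of multi-platform, multi-tissue expression benchmarks.

The generator emulates the structure the harmonizer and its evaluation
battery assume: a shared biological signal (per-gene baselines with a
low-expression tail, additive tissue offsets, planted case-vs-control
pathway shifts) rendered through per-platform technical distortion — a
monotone cubic compression/expansion of the globally standardized signal,
per-gene platform bias, per-sample gain and offset jitter (array intensity /
sequencing depth), additive noise, and optional Poisson count sampling for
sequencing-like platforms.  The monotone distortion preserves within-sample
gene ranks, so the harmonizer's job is isolated to aligning distribution
shapes across platforms.

All randomness flows from a single seed through fixed-stream child
generators, so every product (platform matrices, auxiliary P/Q, pathway and
drug fixtures, the planted-shift ledger) is mutually consistent and
reproducible.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SampleTable
from .scores import DrugTargetDB, PathwayDB

logger = logging.getLogger("shambhala")


@dataclasses.dataclass
class PlatformSpec:
    """Monotone distortion model for one platform.

    The standardized signal z is rendered as
    ``gain_i * (cubic * z**3 + linear * z) + offset_i`` (restored to the
    global scale), plus a fixed per-gene bias with sd ``gene_bias_sd`` and
    i.i.d. noise.  ``counts=True`` additionally passes values through
    ``log2(Poisson(2**y) + 1)``.
    """

    name: str
    cubic: float = 0.0
    linear: float = 1.0
    gene_bias_sd: float = 0.2
    gain_sd: float = 0.0
    offset_sd: float = 0.0
    counts: bool = False

    def validate(self) -> None:
        if self.cubic < 0 or self.linear < 0:
            raise ValueError("cubic and linear coefficients must be >= 0 (monotone distortion)")
        for fld in ("gene_bias_sd", "gain_sd", "offset_sd"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{fld} must be >= 0")


@dataclasses.dataclass
class PlantedShift:
    pathway: str
    delta: float = 2.0
    sign: int = 1


def _default_platforms() -> list[PlatformSpec]:
    return [
        PlatformSpec("array", cubic=0.0, linear=0.55, gene_bias_sd=0.2,
                     gain_sd=0.12, offset_sd=0.3, counts=False),
        PlatformSpec("rnaseq", cubic=0.35, linear=0.9, gene_bias_sd=0.1,
                     gain_sd=0.05, offset_sd=0.5, counts=True),
    ]


def _default_planted() -> list[PlantedShift]:
    return [PlantedShift(f"pw{i + 1:02d}", delta=2.0, sign=(1 if i % 2 == 0 else -1))
            for i in range(6)]


@dataclasses.dataclass
class SyntheticConfig:
    """Study conditions of the synthetic benchmark (defaults are the benchmark)."""

    n_genes: int = 3000
    n_tissues: int = 4
    n_per_cell: int = 10          # samples per tissue per platform
    tissue_sd: float = 1.0        # log2 units
    noise_sd: float = 0.4
    low_expr_fraction: float = 0.3
    case_fraction: float = 0.5
    platforms: list[PlatformSpec] = dataclasses.field(default_factory=_default_platforms)
    n_pathways: int = 10
    pathway_size: int = 8
    n_drugs: int = 12
    planted: list[PlantedShift] = dataclasses.field(default_factory=_default_planted)
    p_top_fraction: float = 0.5   # fraction of genes kept in the calibration set P
    n_aux_samples: int = 24
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 100:
            raise ValueError("n_genes must be >= 100")
        if self.n_per_cell < 3:
            raise ValueError("n_per_cell must be >= 3")
        if not 0 <= self.low_expr_fraction < 1:
            raise ValueError("low_expr_fraction must be in [0, 1)")
        for fld in ("tissue_sd", "noise_sd"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{fld} must be >= 0")
        if not 0 < self.p_top_fraction <= 1:
            raise ValueError("p_top_fraction must be in (0, 1]")
        pool = int(self.p_top_fraction * self.n_genes)
        if self.n_pathways * self.pathway_size > pool:
            raise ValueError("pathway fixtures exceed the surviving-gene pool")
        for p in self.platforms:
            p.validate()
        names = [p.name for p in self.platforms]
        if len(set(names)) != len(names):
            raise ValueError("platform names must be unique")
        known = {s.pathway for s in self.planted}
        valid = {f"pw{i + 1:02d}" for i in range(self.n_pathways)}
        if not known <= valid:
            raise ValueError(f"planted shifts reference unknown pathways: {sorted(known - valid)}")


@dataclasses.dataclass
class SyntheticTruth:
    samples: SampleTable
    baseline_mu: pd.Series
    shift_ledger: dict[str, dict]
    gene_shift: pd.Series  # total per-gene case shift


# ---------------------------------------------------------------------------
# deterministic world shared by all generator products
# ---------------------------------------------------------------------------

def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _gene_ids(config: SyntheticConfig) -> pd.Index:
    width = len(str(config.n_genes))
    return pd.Index([f"g{i + 1:0{width}d}" for i in range(config.n_genes)])


def _baselines(config: SyntheticConfig) -> pd.Series:
    """Two-component baseline mixture: expressed genes vs a low-expression tail."""
    rng = _rng(config, 1)
    G = config.n_genes
    mu = rng.normal(8.0, 2.0, size=G)
    n_low = int(round(config.low_expr_fraction * G))
    low_idx = rng.choice(G, size=n_low, replace=False)
    mu[low_idx] = rng.normal(3.0, 1.0, size=n_low)
    return pd.Series(mu, index=_gene_ids(config))


def _tissue_offsets(config: SyntheticConfig) -> np.ndarray:
    return _rng(config, 2).normal(0.0, config.tissue_sd,
                                  size=(config.n_genes, config.n_tissues))


def surviving_genes(config: SyntheticConfig) -> list[str]:
    """Genes of the calibration set P: top fraction by baseline mean."""
    mu = _baselines(config)
    n_keep = int(round(config.p_top_fraction * config.n_genes))
    return sorted(mu.nlargest(n_keep).index)


def generate_pathway_fixtures(config: SyntheticConfig) -> tuple[PathwayDB, DrugTargetDB]:
    """Pathway and drug fixtures over the surviving synthetic gene ids.

    Members (with +/-1 activator/repressor roles) are drawn from the genes
    that survive the P filter, so planted case shifts have knowable PAL/BES
    signs after harmonization.
    """
    config.validate()
    rng = _rng(config, 3)
    pool = np.array(surviving_genes(config))
    chosen = rng.choice(pool, size=config.n_pathways * config.pathway_size, replace=False)
    pathways: dict[str, dict[str, float]] = {}
    for i in range(config.n_pathways):
        members = chosen[i * config.pathway_size:(i + 1) * config.pathway_size]
        roles = np.where(rng.random(config.pathway_size) < 0.7, 1.0, -1.0)
        pathways[f"pw{i + 1:02d}"] = dict(zip(map(str, members), roles))
    db = PathwayDB(pathways)
    drugs: dict[str, tuple[list[str], list[str]]] = {}
    pw_ids = list(pathways)
    for d in range(config.n_drugs):
        n_pw = int(rng.integers(1, 3))
        linked = sorted(rng.choice(pw_ids, size=min(n_pw, len(pw_ids)), replace=False))
        member_pool = sorted({g for p in linked for g in pathways[p]})
        n_tg = int(rng.integers(1, 4))
        targets = sorted(rng.choice(member_pool, size=min(n_tg, len(member_pool)), replace=False))
        drugs[f"drug{d + 1:02d}"] = (list(map(str, targets)), list(map(str, linked)))
    return db, DrugTargetDB(drugs)


def _shift_ledger(config: SyntheticConfig, db: PathwayDB) -> tuple[dict[str, dict], pd.Series]:
    gene_shift = pd.Series(0.0, index=_gene_ids(config))
    ledger: dict[str, dict] = {}
    for shift in config.planted:
        members = db.pathways[shift.pathway]
        shifts = {g: shift.sign * shift.delta * np.sign(w) for g, w in members.items()}
        ledger[shift.pathway] = {"sign": shift.sign, "delta": shift.delta,
                                 "gene_shifts": shifts}
        for g, s in shifts.items():
            gene_shift[g] += s
    return ledger, gene_shift


def _render(signal: np.ndarray, spec: PlatformSpec, noise_sd: float,
            rng: np.random.Generator, center: float, scale: float,
            gene_bias: np.ndarray) -> np.ndarray:
    """Apply the platform distortion model to a noise-free signal matrix."""
    G, n = signal.shape
    z = (signal - center) / scale
    gains = 1.0 + rng.normal(0.0, spec.gain_sd, size=n)
    offsets = rng.normal(0.0, spec.offset_sd, size=n)
    distorted = spec.cubic * z ** 3 + spec.linear * z
    y = center + scale * (gains[None, :] * distorted) + offsets[None, :]
    y = y + gene_bias[:, None] + rng.normal(0.0, noise_sd, size=(G, n))
    if spec.counts:
        lam = np.clip(2.0 ** np.clip(y, None, 24.0), 0.0, None)
        y = np.log2(rng.poisson(lam) + 1.0)
    return y


def generate_multiplatform(config: SyntheticConfig) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """One expression matrix per platform plus the ground-truth record."""
    config.validate()
    genes = _gene_ids(config)
    mu = _baselines(config)
    tissue = _tissue_offsets(config)
    pw_db, _ = generate_pathway_fixtures(config)
    ledger, gene_shift = _shift_ledger(config, pw_db)

    n_ctrl = int(np.ceil(config.n_per_cell * (1.0 - config.case_fraction)))
    ann_rows = []
    matrices = []
    # one shared standardization of the noise-free signal keeps the distortion
    # identical in z-space across platforms
    base_cols = []
    for t in range(config.n_tissues):
        base_cols.append(mu.to_numpy() + tissue[:, t])
    pooled = np.stack(base_cols, axis=1)
    center = float(pooled.mean())
    scale = float(pooled.std())

    for p_idx, spec in enumerate(config.platforms):
        rng = _rng(config, 10 + p_idx)
        gene_bias = rng.normal(0.0, spec.gene_bias_sd, size=config.n_genes)
        cols = []
        ids = []
        for t in range(config.n_tissues):
            for j in range(config.n_per_cell):
                group = "control" if j < n_ctrl else "case"
                sid = f"{spec.name}_t{t + 1}_s{j + 1}"
                sig = mu.to_numpy() + tissue[:, t]
                if group == "case":
                    sig = sig + gene_shift.to_numpy()
                cols.append(sig)
                ids.append(sid)
                ann_rows.append({"sample_id": sid, "tissue_type": f"tissue{t + 1}",
                                 "platform": spec.name, "group": group})
        signal = np.stack(cols, axis=1)
        vals = _render(signal, spec, config.noise_sd, rng, center, scale, gene_bias)
        matrices.append(ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=ids),
                                         role="R", scale="log2"))
    ann = pd.DataFrame(ann_rows).set_index("sample_id")
    # annotation covers every platform; each matrix uses its own subset
    table = SampleTable(ann)
    truth = SyntheticTruth(samples=table, baseline_mu=mu, shift_ledger=ledger,
                           gene_shift=gene_shift)
    return matrices, truth


def generate_auxiliary(config: SyntheticConfig) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """The calibration (P) and reference definitive (Q) auxiliary datasets.

    P is array-like (compressed dynamic range) and restricted to the top
    fraction of genes by baseline mean — its gene list performs the implicit
    expression filtering.  Q is sequencing-like with the full gene list.
    Both span all tissues with control samples only.
    """
    config.validate()
    genes = _gene_ids(config)
    mu = _baselines(config)
    tissue = _tissue_offsets(config)
    pooled = mu.to_numpy()[:, None] + tissue
    center = float(pooled.mean())
    scale = float(pooled.std())

    def _aux(spec: PlatformSpec, stream: int, keep: list[str] | None, role: str) -> ExpressionMatrix:
        rng = _rng(config, stream)
        gene_bias = rng.normal(0.0, spec.gene_bias_sd, size=config.n_genes)
        cols, ids = [], []
        for i in range(config.n_aux_samples):
            t = i % config.n_tissues
            cols.append(mu.to_numpy() + tissue[:, t])
            ids.append(f"{role}_t{t + 1}_s{i + 1}")
        signal = np.stack(cols, axis=1)
        vals = _render(signal, spec, config.noise_sd, rng, center, scale, gene_bias)
        frame = pd.DataFrame(vals, index=genes, columns=ids)
        if keep is not None:
            frame = frame.loc[keep]
        return ExpressionMatrix(frame, role=role, scale="log2")

    p_spec = PlatformSpec("auxP", cubic=0.0, linear=0.6, gene_bias_sd=0.15,
                          gain_sd=0.1, offset_sd=0.25, counts=False)
    q_spec = PlatformSpec("auxQ", cubic=0.25, linear=1.0, gene_bias_sd=0.1,
                          gain_sd=0.05, offset_sd=0.3, counts=True)
    P = _aux(p_spec, 20, surviving_genes(config), "P")
    Q = _aux(q_spec, 21, None, "Q")
    return P, Q
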