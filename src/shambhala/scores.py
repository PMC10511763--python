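"""Case-vs-control derivative scores: gene LFC, pathway PAL, drug BES.

The per-gene log-fold change LFC_g is the case profile minus the aggregated
(median by default) control profile.  Pathway activation (PAL) aggregates
role-weighted LFC over the pathway's member genes, with role weights +1 for
activators and -1 for repressors:

    PAL_p = sum_g ARR_gp * LFC_g / sum_g |ARR_gp|

The balanced drug efficiency score (BES) combines the drug's target genes
with its linked pathways; a positive BES predicts potential benefit:

    BES_d = 1/2 * mean_p PAL_p + 1/2 * mean_g LFC_g

These PAL/BES forms are documented package defaults behind a small pluggable
surface — they honor the sign conventions and the pathways-plus-targets
structure of the Oncobox-style scoring they emulate, while the proprietary
normalization constants of production databases are out of scope.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from .datamodel import ExpressionMatrix

logger = logging.getLogger("shambhala")


@dataclasses.dataclass
class PathwayDB:
    """pathway id -> {gene id: signed role weight (+1 activator / -1 repressor)}."""

    pathways: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has no members")
            for g, w in members.items():
                if not np.isfinite(w) or w == 0:
                    raise ValueError(f"pathway {pid!r}: role weight for {g!r} must be finite, non-zero")


@dataclasses.dataclass
class DrugTargetDB:
    """drug id -> (target gene ids, linked pathway ids)."""

    drugs: dict[str, tuple[list[str], list[str]]]

    def __post_init__(self) -> None:
        for did, (targets, _) in self.drugs.items():
            if not targets:
                raise ValueError(f"drug {did!r} has no target genes")


@dataclasses.dataclass
class ScoreVector:
    level: str  # gene_LFC | pathway_PAL | drug_BES
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("score ids must be unique")
        if len(self.ids) != len(self.values):
            raise ValueError("ids and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.ids, self.values.tolist()))


# ---------------------------------------------------------------------------
# database parsers (extended GMT / drug TSV)
# ---------------------------------------------------------------------------

def read_pathway_gmt(path: str | Path) -> PathwayDB:
    """Read pathways from an extended GMT dialect.

    ``pathway<TAB>description<TAB>gene:role ...`` with role in {+1, -1};
    plain GMT is accepted, the role defaulting to +1.
    """
    pathways: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs pathway, description and >=1 member")
            members: dict[str, float] = {}
            for tok in parts[2:]:
                if not tok:
                    continue
                if ":" in tok:
                    gene, role = tok.rsplit(":", 1)
                    members[gene] = float(role)
                else:
                    members[tok] = 1.0
            pathways[parts[0]] = members
    return PathwayDB(pathways)


def write_pathway_gmt(db: PathwayDB, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for pid, members in db.pathways.items():
            toks = "\t".join(f"{g}:{int(w) if float(w).is_integer() else w}" for g, w in members.items())
            fh.write(f"{pid}\tna\t{toks}\n")
    return path


def read_drug_db(path: str | Path) -> DrugTargetDB:
    """Read a drug-target TSV: ``drug<TAB>targets(comma-sep)<TAB>pathways(comma-sep)``."""
    drugs: dict[str, tuple[list[str], list[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: drug line needs drug id and targets")
            targets = [t for t in parts[1].split(",") if t]
            pathways = [p for p in parts[2].split(",") if p] if len(parts) > 2 else []
            drugs[parts[0]] = (targets, pathways)
    return DrugTargetDB(drugs)


def write_drug_db(db: DrugTargetDB, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for did, (targets, pathways) in db.drugs.items():
            fh.write(f"{did}\t{','.join(targets)}\t{','.join(pathways)}\n")
    return path


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def log_fold_change(case: np.ndarray | ExpressionMatrix, controls: ExpressionMatrix,
                    gene_ids: list[str] | None = None, aggregate: str = "median") -> ScoreVector:
    """Case-to-control LFC per gene: case log2 value minus aggregated control value."""
    if isinstance(case, ExpressionMatrix):
        if case.n_samples != 1:
            raise ValueError("case must be a single-sample profile")
        gene_ids = [str(g) for g in case.gene_ids]
        case_vals = case.values[:, 0]
    else:
        case_vals = np.asarray(case, dtype=float)
        if gene_ids is None:
            raise ValueError("gene_ids required when case is a plain array")
    if list(map(str, controls.gene_ids)) != list(gene_ids):
        raise ValueError("case and control gene lists differ")
    if aggregate == "median":
        ctrl = np.median(controls.values, axis=1)
    elif aggregate == "mean":
        ctrl = controls.values.mean(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return ScoreVector("gene_LFC", list(gene_ids), case_vals - ctrl)


def pathway_activation(lfc: ScoreVector, db: PathwayDB) -> ScoreVector:
    """Role-weighted mean LFC per pathway over members present in the LFC vector."""
    if not db.pathways:
        raise ValueError("empty pathway database")
    lfc_map = lfc.as_dict()
    ids, vals = [], []
    for pid, members in db.pathways.items():
        surv = {g: w for g, w in members.items() if g in lfc_map}
        if not surv:
            logger.warning("pathway %s has no surviving members; dropped", pid)
            continue
        num = sum(w * lfc_map[g] for g, w in surv.items())
        den = sum(abs(w) for w in surv.values())
        ids.append(pid)
        vals.append(num / den)
    return ScoreVector("pathway_PAL", ids, np.array(vals))


def drug_efficiency(pal: ScoreVector, lfc: ScoreVector, db: DrugTargetDB) -> ScoreVector:
    """Balanced efficiency score per drug: half pathway PAL mean, half target LFC mean.

    Drugs with no surviving target gene are reported (logged) but not scored;
    drugs with no linked scored pathway fall back to the target term alone.
    """
    pal_map = pal.as_dict()
    lfc_map = lfc.as_dict()
    ids, vals = [], []
    skipped = []
    for did, (targets, pathways) in db.drugs.items():
        t_vals = [lfc_map[g] for g in targets if g in lfc_map]
        if not t_vals:
            skipped.append(did)
            continue
        p_vals = [pal_map[p] for p in pathways if p in pal_map]
        target_term = float(np.mean(t_vals))
        if p_vals:
            score = 0.5 * float(np.mean(p_vals)) + 0.5 * target_term
        else:
            logger.warning("drug %s has no linked scored pathway; using target term only", did)
            score = target_term
        ids.append(did)
        vals.append(score)
    if skipped:
        logger.warning("%d drug(s) with no surviving target gene not scored: %s",
                       len(skipped), skipped[:5])
    return ScoreVector("drug_BES", ids, np.array(vals))


def target_survival_report(db: DrugTargetDB | PathwayDB, surviving_genes: list[str]) -> dict:
    """Coverage of drug targets / pathway members by the surviving gene list.

    Per drug: fraction of targets surviving and an all-survived flag; per
    pathway: fraction surviving and a strictly-greater-than-75% flag; plus
    global percentages.
    """
    surv = set(surviving_genes)
    report: dict = {"entries": {}}
    if isinstance(db, DrugTargetDB):
        flags = []
        for did, (targets, _) in db.drugs.items():
            frac = sum(g in surv for g in targets) / len(targets)
            ok = frac == 1.0
            report["entries"][did] = {"fraction_survived": frac, "all_targets_survived": ok}
            flags.append(ok)
        report["pct_all_targets_survived"] = 100.0 * np.mean(flags) if flags else 0.0
    else:
        flags = []
        for pid, members in db.pathways.items():
            frac = sum(g in surv for g in members) / len(members)
            ok = frac > 0.75
            report["entries"][pid] = {"fraction_survived": frac, "over_75pct_survived": ok}
            flags.append(ok)
        report["pct_over_75pct_survived"] = 100.0 * np.mean(flags) if flags else 0.0
    return report


def rank_drugs(bes: ScoreVector, top_n: int) -> list[str]:
    """Drugs sorted by BES descending, ties broken lexicographically by id."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    order = sorted(zip(bes.ids, bes.values), key=lambda t: (-t[1], t[0]))
    return [did for did, _ in order[:top_n]]
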