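"""Drug scoring against disease-specific modules.

conf(d,p) is the signed probability-weighted evidence sum; weight(p) is the
log node-importance k*ln(strength) - ln(degree) on the full PPI network;
P-score = conf * weight; RP-score = exp(weight) on the module network.  A
drug's per-module Drug Effect Score (DES) sums, over its module targets,
sign * log2-magnitudes * priority, where the sign is +1 exactly when the
drug's net action opposes the gene's dysregulation.  DESS integrates DES
over selected modules weighted by their enrichment scores.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import (
    DiseaseModuleNetwork,
    DrugScoreTable,
    DrugTargetEvidence,
    EnrichmentResult,
    PPINetwork,
    ValidationError,
)

log = logging.getLogger(__name__)


def conf_dp(evidence: DrugTargetEvidence) -> float:
    """Signed probability-weighted evidence sum; empty evidence scores 0."""
    return float(sum(prob * sign for prob, sign in evidence.evidence))


def weight_p(ppi: PPINetwork, protein: str, k_const: float = 2.0) -> float:
    """k * ln(sum of incident confidences) - ln(degree).

    Undefined (error) for proteins without PPI edges; callers skip those.
    """
    deg = ppi.degree(protein)
    if deg == 0:
        raise ValidationError(f"weight undefined: {protein!r} has no PPI edges")
    s = ppi.strength(protein)
    if s == 0.0:
        return -math.inf
    return k_const * math.log(s) - math.log(deg)


def p_score(conf: float, weight: float) -> float:
    """Pharmacology score: conf(d,p) * weight(p)."""
    return conf * weight


def rp_score(modnet: DiseaseModuleNetwork, protein: str, k_const: float = 2.0) -> float:
    """exp(weight) computed on the module network; with k=2, strength^2/degree."""
    if protein not in modnet.genes:
        raise ValidationError(f"{protein!r} not in module {modnet.module!r}")
    deg = modnet.network.degree(protein)
    s = modnet.network.strength(protein)
    if s == 0.0:
        return 0.0
    return math.exp(k_const * math.log(s) - math.log(deg))


def _l2(x: float) -> float:
    """log2 floored at 0 so term sign is carried solely by the reversal sign."""
    if x <= 1.0:
        return 0.0
    return math.log2(x)


def des(
    conf_by_target: dict[str, float],
    modnet: DiseaseModuleNetwork,
    pscore_by_target: dict[str, float],
) -> float:
    """Drug Effect Score of one drug on one module.

    Sums over the drug's targets present in the module network with nonzero
    conf and nonzero dysregulation: sign * log2|P-score| * log2(RP-score) *
    priority, with sign = -sign(conf) * g (positive when the drug opposes
    the dysregulation) and both log2 factors floored at 0.
    """
    total = 0.0
    for gene, conf in conf_by_target.items():
        if gene not in modnet.genes or conf == 0.0:
            continue
        g = modnet.direction[gene]
        if g == 0:
            continue
        pscore = pscore_by_target.get(gene)
        if pscore is None:  # target absent from the PPI network: weight undefined
            continue
        reversal = -float(np.sign(conf)) * g
        total += (
            reversal
            * _l2(abs(pscore))
            * _l2(modnet.rp_score[gene])
            * modnet.priority[gene]
        )
    return total


def dess(des_by_module: dict[str, float], enrichments: list[EnrichmentResult]) -> float:
    """Sum of DES * f(pts) over selected (positively enriched) modules."""
    return float(
        sum(
            des_by_module.get(e.module, 0.0) * e.f_pts
            for e in enrichments
            if e.selected
        )
    )


def score_drugs(
    evidence: list[DrugTargetEvidence],
    ppi: PPINetwork,
    modnets: list[DiseaseModuleNetwork],
    enrichments: list[EnrichmentResult],
    k_const: float = 2.0,
) -> DrugScoreTable:
    """Score every drug in the evidence table against the selected modules."""
    selected = {e.module for e in enrichments if e.selected}
    modnets = [m for m in modnets if m.module in selected]
    by_drug: dict[str, dict] = {}
    for rec in evidence:
        entry = by_drug.setdefault(
            rec.drug_id, {"name": rec.drug_name, "conf": {}}
        )
        entry["conf"][rec.target] = conf_dp(rec)

    weights: dict[str, float] = {}

    def target_pscore(gene: str, conf: float) -> float | None:
        if gene not in weights:
            weights[gene] = weight_p(ppi, gene, k_const) if gene in ppi else math.nan
        w = weights[gene]
        return None if math.isnan(w) else p_score(conf, w)

    rows = []
    for drug_id in sorted(by_drug):
        entry = by_drug[drug_id]
        row: dict = {"drug_id": drug_id, "drug_name": entry["name"]}
        des_by_module = {}
        for modnet in modnets:
            pscores = {
                gene: ps
                for gene, conf in entry["conf"].items()
                if (ps := target_pscore(gene, conf)) is not None
            }
            des_by_module[modnet.module] = des(entry["conf"], modnet, pscores)
            row[f"des_{modnet.module}"] = des_by_module[modnet.module]
            row[f"n_targets_{modnet.module}"] = sum(
                1 for g in entry["conf"] if g in modnet.genes
            )
        row["dess"] = dess(des_by_module, enrichments)
        rows.append(row)
    if not rows:
        raise ValidationError("no drugs to score")
    table = pd.DataFrame(rows).set_index("drug_id")
    return DrugScoreTable(table)


def rank_and_select(scores: DrugScoreTable, top_fraction: float = 0.01) -> DrugScoreTable:
    """Rank by DESS descending (ties by drug id) and flag the top fraction.

    The top count is max(1, floor(fraction * n_drugs)).
    """
    table = scores.table
    if len(table) < 1:
        raise ValidationError("need at least one scored drug")
    table = (
        table.reset_index()
        .sort_values(["dess", "drug_id"], ascending=[False, True], kind="mergesort")
        .set_index("drug_id")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    n_top = max(1, math.floor(top_fraction * len(table)))
    table["top"] = table["rank"] <= n_top
    return DrugScoreTable(table)


def build_extended_drug_network(
    scores: DrugScoreTable,
    modnets: list[DiseaseModuleNetwork],
    evidence: list[DrugTargetEvidence],
    ppi: PPINetwork,
    conf_threshold: float = 0.75,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge export for the selected drugs and their module targets.

    Nodes are the top-flagged drugs, their module targets, and one PPI layer
    around those targets (at conf >= threshold).  Drug-target edges carry
    the action sign (+ stimulation / - inhibition); PPI edges carry conf.
    """
    top_drugs = set(scores.table.index[scores.table["top"]])
    if not top_drugs:
        raise ValidationError("no selected drugs for the extended network")
    module_genes: set[str] = set()
    direction: dict[str, int] = {}
    rp: dict[str, float] = {}
    for modnet in modnets:
        module_genes |= modnet.genes
        direction.update(modnet.direction)
        rp.update(modnet.rp_score)

    edge_rows = []
    gene_nodes: set[str] = set()
    for rec in evidence:
        if rec.drug_id not in top_drugs or rec.target not in module_genes:
            continue
        conf = conf_dp(rec)
        if conf == 0.0:
            continue
        action = "stimulation" if conf > 0 else "inhibition"
        edge_rows.append((rec.drug_id, rec.target, action, conf))
        gene_nodes.add(rec.target)

    # one-layer PPI extension around the drug targets
    for target in sorted(gene_nodes):
        for neighbor, conf in sorted(ppi.incident(target).items()):
            if conf >= conf_threshold:
                a, b = sorted((target, neighbor))
                edge_rows.append((a, b, "ppi", conf))
    extension = {
        r[1] for r in edge_rows if r[2] == "ppi"
    } | {r[0] for r in edge_rows if r[2] == "ppi"}
    gene_nodes |= extension

    node_rows = [
        (d, "drug", 0, 0.0) for d in sorted(top_drugs)
    ] + [
        (g, "gene", direction.get(g, 0), rp.get(g, 0.0)) for g in sorted(gene_nodes)
    ]
    nodes = pd.DataFrame(node_rows, columns=["node", "kind", "direction", "rp_score"])
    edges = pd.DataFrame(
        sorted(set(edge_rows)), columns=["source", "target", "action", "conf"]
    )
    return nodes, edges


def write_drug_scores(scores: DrugScoreTable, path) -> None:
    scores.table.to_csv(path, sep="\t", index_label="drug_id", float_format="%.17g")


def read_drug_scores(path) -> DrugScoreTable:
    return DrugScoreTable(pd.read_csv(path, sep="\t", index_col="drug_id", float_precision="round_trip"))
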