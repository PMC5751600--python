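"""In-memory orchestration of the full analysis, used by the CLI stages.

Every stage is a pure function of (inputs, config), so a run is reproducible
from its recorded configuration and seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import coexpr, diffexpr, disease, drugs
from .io import (
    DiseaseModuleNetwork,
    DrugScoreTable,
    DrugTargetEvidence,
    EnrichmentResult,
    ExpressionMatrix,
    PPINetwork,
    RegulatoryNetwork,
    RunConfig,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: RunConfig
    de: pd.DataFrame
    dispersion: pd.DataFrame
    trimmed_samples: list[str]
    soft_power: int
    r2_by_power: dict[int, float]
    partition: coexpr.CoexpressionPartition
    trait: coexpr.ModuleTraitCorrelation | None
    expanded: RegulatoryNetwork
    candidate_genes: set[str]
    enrichments: list[EnrichmentResult]
    module_networks: list[DiseaseModuleNetwork] = field(default_factory=list)
    scores: DrugScoreTable | None = None


def run_all(
    expression: ExpressionMatrix,
    seed_genes: list[str],
    regulatory: RegulatoryNetwork,
    ppi: PPINetwork,
    evidence: list[DrugTargetEvidence],
    config: RunConfig | None = None,
    with_trait: bool = True,
) -> PipelineResult:
    """Run differential expression -> modules -> enrichment -> drug ranking."""
    cfg = config or RunConfig()

    dispersion = diffexpr.check_sample_dispersion(expression, cfg.dispersion_sd_mult)
    expression, trimmed = coexpr.trim_outlier_samples(expression, cfg.sample_cut_height)

    de = diffexpr.moderated_test(expression, cfg.alpha, use_fdr=cfg.use_fdr)
    candidates = de.index[de["candidate"]].tolist()
    if len(candidates) < max(3, cfg.min_module_size):
        raise ValidationError(
            f"only {len(candidates)} differentially expressed genes at alpha={cfg.alpha}"
        )
    cand_expr = expression.subset_genes(candidates)

    if cfg.soft_power is not None:
        beta, r2_by_power = cfg.soft_power, {}
    else:
        beta, r2_by_power = coexpr.pick_soft_threshold(
            cand_expr, cfg.powers, cfg.r2_target
        )
    tom = coexpr.compute_tom(cand_expr, beta)
    partition = coexpr.detect_modules(
        tom, cfg.min_module_size, cfg.tree_cut_height, beta
    )
    partition.r2_by_power = r2_by_power

    trait = None
    if with_trait and partition.modules:
        trait = coexpr.module_trait_correlation(cand_expr, partition)

    expanded = disease.expand_seed_network(seed_genes, regulatory)
    candidate_set = disease.expanded_genes(seed_genes, expanded)
    enrichments = disease.rank_modules(partition, candidate_set, cfg.log_base)

    module_networks = []
    for enr in enrichments:
        if not enr.selected:
            continue
        try:
            module_networks.append(
                disease.build_module_network(
                    partition.module_genes(enr.module),
                    ppi,
                    cfg.ppi_threshold,
                    de,
                    seed_genes,
                    candidate_set,
                    cfg.k_const,
                    module=enr.module,
                )
            )
        except ValidationError as exc:
            log.warning("skipping module %s: %s", enr.module, exc)

    scores = None
    if evidence and module_networks:
        scores = drugs.rank_and_select(
            drugs.score_drugs(evidence, ppi, module_networks, enrichments, cfg.k_const),
            cfg.top_fraction,
        )
    return PipelineResult(
        config=cfg,
        de=de,
        dispersion=dispersion,
        trimmed_samples=trimmed,
        soft_power=beta,
        r2_by_power=r2_by_power,
        partition=partition,
        trait=trait,
        expanded=expanded,
        candidate_genes=candidate_set,
        enrichments=enrichments,
        module_networks=module_networks,
        scores=scores,
    )
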