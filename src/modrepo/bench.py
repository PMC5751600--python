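"""Recovery benchmarks on synthetic bundles with known ground truth.

Used by the acceptance suite and the acceptance report script; each
benchmark runs the real pipeline code on a freshly generated bundle.
"""
from __future__ import annotations

import numpy as np

from . import coexpr, disease, drugs, pipeline, synth
from .io import DrugTargetEvidence, RunConfig


def module_recovery_ari(seed: int, soft_power: int = 6,
                        min_module_size: int = 20,
                        cut_height: float = 0.9) -> float:
    """Adjusted Rand index of detected modules against the planted blocks."""
    bundle = synth.generate(synth.SynthConfig(seed=seed))
    em = bundle.expression
    tom = coexpr.compute_tom(em, soft_power)
    partition = coexpr.detect_modules(tom, min_module_size, cut_height, soft_power)
    truth = [bundle.truth.block_of[g] for g in em.genes]
    found = [partition.labels[g] for g in em.genes]
    return _adjusted_rand_index(truth, found)


def _adjusted_rand_index(a, b) -> float:
    # contingency-table ARI; avoids a scikit-learn dependency in the package
    a_labels = {v: i for i, v in enumerate(dict.fromkeys(a))}
    b_labels = {v: i for i, v in enumerate(dict.fromkeys(b))}
    table = np.zeros((len(a_labels), len(b_labels)), dtype=np.int64)
    for x, y in zip(a, b):
        table[a_labels[x], b_labels[y]] += 1

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = sum(comb2(int(v)) for v in table.flat)
    sum_a = sum(comb2(int(v)) for v in table.sum(axis=1))
    sum_b = sum(comb2(int(v)) for v in table.sum(axis=0))
    n = comb2(len(a))
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def drug_recovery(seed: int, n_decoys: int = 200) -> dict:
    """Score the designed therapeutic against sign-randomized decoys.

    Runs the full pipeline on a default bundle, then rescoring the
    therapeutic's target set with ``n_decoys`` random sign patterns.
    Returns the therapeutic DESS, the decoy DESS array, and the fraction of
    decoys the therapeutic strictly outranks.
    """
    bundle = synth.generate(synth.SynthConfig(seed=seed))
    cfg = RunConfig(seed=seed, soft_power=6)
    result = pipeline.run_all(
        bundle.expression, bundle.seed_genes, bundle.regulatory, bundle.ppi,
        bundle.drug_evidence, cfg, with_trait=False,
    )
    thera = [r for r in bundle.drug_evidence
             if r.drug_id == bundle.truth.therapeutic_drug]
    if not result.module_networks:
        return {"therapeutic": 0.0, "decoys": np.zeros(n_decoys), "beaten": 0.0}

    def dess_of(records) -> float:
        table = drugs.score_drugs(
            records, bundle.ppi, result.module_networks, result.enrichments,
            cfg.k_const,
        ).table
        return float(table["dess"].iloc[0])

    thera_dess = dess_of(thera)
    rng = np.random.default_rng(seed + 10_000)
    decoy_dess = np.empty(n_decoys)
    for i in range(n_decoys):
        flips = {rec.target: int(rng.choice([-1, 1])) for rec in thera}
        decoys = [
            DrugTargetEvidence(
                "DECOY", "decoy", rec.target,
                [(prob, flips[rec.target]) for prob, _ in rec.evidence],
            )
            for rec in thera
        ]
        decoy_dess[i] = dess_of(decoys)
    beaten = float(np.mean(thera_dess > decoy_dess))
    return {"therapeutic": thera_dess, "decoys": decoy_dess, "beaten": beaten}


def null_candidate_fraction(seed: int, n_genes: int = 2000, alpha: float = 0.05) -> float:
    """Fraction of null genes flagged at ``alpha`` by the moderated test."""
    from . import diffexpr

    cfg = synth.SynthConfig(
        n_blocks=40, block_size=n_genes // 40, n_dysregulated=0,
        shift=0.0, rho_in=0.0, rho_out=0.0, seed=seed,
    )
    bundle = synth.generate(cfg)
    de = diffexpr.moderated_test(bundle.expression, alpha)
    return float(de["candidate"].mean())
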