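"""Disease-specific module selection.

Seeds from GWAS are expanded one regulatory layer (induced subgraph); each
co-expression module is scored by the signed log of the hypergeometric point
probability of its overlap with the expanded-network genes, and positive
scores mark disease-specific modules.  Selected modules get a
high-confidence PPI subnetwork annotated with dysregulation direction,
candidate priority, and RP-scores.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import (
    GREY,
    DiseaseModuleNetwork,
    EnrichmentResult,
    PPINetwork,
    RegulatoryNetwork,
    ValidationError,
)

log = logging.getLogger(__name__)


def expand_seed_network(seeds, regulatory: RegulatoryNetwork) -> RegulatoryNetwork:
    """One-layer extension: seeds plus their regulatory neighbours, with the
    induced subgraph of the edge list on that node set.

    Seeds without incident edges stay in the network as isolated nodes
    (their count is logged) — callers should use :func:`expanded_genes` for
    the full node set.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValidationError("empty seed gene list")
    nodes = set(seeds)
    for src, dst, _ in regulatory.edges:
        if src in seeds:
            nodes.add(dst)
        if dst in seeds:
            nodes.add(src)
    edges = [(s, d, g) for s, d, g in regulatory.edges if s in nodes and d in nodes]
    covered = {g for e in edges for g in e[:2]}
    isolated = seeds - covered
    if isolated:
        log.info("%d seed genes have no regulatory edges: %s",
                 len(isolated), sorted(isolated)[:5])
    net = RegulatoryNetwork(edges)
    net.isolated_seeds = sorted(isolated)  # type: ignore[attr-defined]
    return net


def expanded_genes(seeds, expanded: RegulatoryNetwork) -> set[str]:
    """Node set of the expanded network, including edge-less seeds."""
    return set(seeds) | expanded.nodes


def f_pts(N: int, K: int, n: int, k: int, log_base: float = 10.0) -> float:
    """Signed log of the hypergeometric point probability at overlap k.

    Returns sign(K/N - k/n) * log_base(C(K,k) C(N-K,n-k) / C(N,n)).  The pmf
    is below 1, so its log is negative and over-represented modules
    (k/n > K/N) score positive.  sign(0) yields exactly 0.
    """
    if not (0 <= k <= min(K, n) and 0 <= n <= N and 0 <= K <= N):
        raise ValidationError(f"invalid counts N={N} K={K} n={n} k={k}")
    if n == 0 or N == 0:
        return 0.0
    sign = (K * n > k * N) - (K * n < k * N)  # exact integer comparison
    if sign == 0:
        return 0.0
    logpmf = hypergeom.logpmf(k, N, K, n) / math.log(log_base)
    return float(sign * logpmf)


def rank_modules(
    partition, candidate_genes, log_base: float = 10.0
) -> list[EnrichmentResult]:
    """Score every non-grey module and rank by f(pts), descending.

    N counts every gene that entered module detection (unassigned/grey genes
    included, matching a reported total that exceeds the module-size sum);
    K is their overlap with the expanded-network candidates; each module
    contributes its size n and its candidate overlap k.  Modules with
    positive scores are selected.
    """
    candidates = set(candidate_genes)
    modules = partition.modules
    if not modules:
        raise ValidationError("partition has no assigned modules")
    N = len(partition.labels)
    K = sum(1 for g in partition.labels if g in candidates)
    if K == 0:
        log.warning("no module gene overlaps the candidate set; "
                    "all scores driven by the sign convention")
    results = []
    for module in modules:
        genes = partition.module_genes(module)
        n = len(genes)
        k = sum(1 for g in genes if g in candidates)
        results.append(
            EnrichmentResult(module, N, K, n, k, f_pts(N, K, n, k, log_base))
        )
    return _assign_ranks(results)


def _assign_ranks(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    results.sort(key=lambda r: (-r.f_pts, r.module))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def enrichment_from_counts(rows, log_base: float = 10.0) -> list[EnrichmentResult]:
    """Score and rank modules directly from (module, N, K, n, k) count rows."""
    results = [
        EnrichmentResult(m, N, K, n, k, f_pts(N, K, n, k, log_base))
        for m, N, K, n, k in rows
    ]
    return _assign_ranks(results)


def build_module_network(
    module_genes,
    ppi: PPINetwork,
    conf_threshold: float,
    de_result: pd.DataFrame,
    seed_genes,
    expanded_set,
    k_const: float = 2.0,
    module: str = "module",
) -> DiseaseModuleNetwork:
    """High-confidence PPI subnetwork of a module with gene annotations.

    Keeps edges with both endpoints in the module and conf >= threshold,
    drops genes left isolated, and annotates each survivor with its
    dysregulation direction/delta, its priority (1 for GWAS seeds, 1/2 for
    one-layer extension genes, 1/4 otherwise), and its RP-score computed on
    the module network.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValidationError("conf threshold must be in [0,1]")
    network = ppi.subnetwork(set(module_genes), min_conf=conf_threshold)
    if len(network) == 0:
        raise ValidationError(f"module {module!r} network is empty after filtering")
    seeds = set(seed_genes)
    expanded = set(expanded_set)
    direction, delta, priority, rp = {}, {}, {}, {}
    for gene in network.nodes:
        if gene in de_result.index:
            direction[gene] = int(de_result.at[gene, "direction"])
            delta[gene] = float(de_result.at[gene, "delta"])
        else:
            direction[gene] = 0
            delta[gene] = 0.0
        if gene in seeds:
            priority[gene] = 1.0
        elif gene in expanded:
            priority[gene] = 0.5
        else:
            priority[gene] = 0.25
        rp[gene] = node_rp_score(network, gene, k_const)
    return DiseaseModuleNetwork(module, network, direction, delta, priority, rp)


def node_rp_score(network: PPINetwork, gene: str, k_const: float = 2.0) -> float:
    """exp(k * ln(strength) - ln(degree)) over edges incident to ``gene``;
    with k = 2 this is strength^2 / degree."""
    deg = network.degree(gene)
    if deg == 0:
        raise ValidationError(f"RP-score undefined for degree-0 gene {gene!r}")
    s = network.strength(gene)
    if s == 0.0:
        return 0.0
    return math.exp(k_const * math.log(s) - math.log(deg))


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_enrichment(results, path) -> None:
    pd.DataFrame(
        [(r.module, r.N, r.K, r.n, r.k, r.f_pts, r.rank, r.selected) for r in results],
        columns=["module", "N", "K", "n", "k", "f_pts", "rank", "selected"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_enrichment(path) -> list[EnrichmentResult]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    results = [
        EnrichmentResult(
            str(r.module), int(r.N), int(r.K), int(r.n), int(r.k),
            float(r.f_pts), int(r.rank),
        )
        for r in df.itertuples()
    ]
    return results


def write_module_network(modnet: DiseaseModuleNetwork, node_path, edge_path) -> None:
    nodes = pd.DataFrame(
        [
            (
                g,
                modnet.direction[g],
                modnet.delta[g],
                modnet.priority[g],
                modnet.rp_score[g],
            )
            for g in sorted(modnet.genes)
        ],
        columns=["gene", "direction", "delta", "priority", "rp_score"],
    )
    nodes.to_csv(node_path, sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(modnet.network.edges, columns=["p", "q", "conf"]).to_csv(
        edge_path, sep="\t", index=False, float_format="%.17g"
    )


def read_module_network(module: str, node_path, edge_path) -> DiseaseModuleNetwork:
    nodes = pd.read_csv(node_path, sep="\t", dtype={"gene": str}, float_precision="round_trip")
    edges = pd.read_csv(edge_path, sep="\t", dtype={"p": str, "q": str}, float_precision="round_trip")
    network = PPINetwork(zip(edges["p"], edges["q"], edges["conf"]))
    return DiseaseModuleNetwork(
        module,
        network,
        dict(zip(nodes["gene"], nodes["direction"].astype(int))),
        dict(zip(nodes["gene"], nodes["delta"].astype(float))),
        dict(zip(nodes["gene"], nodes["priority"].astype(float))),
        dict(zip(nodes["gene"], nodes["rp_score"].astype(float))),
    )
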