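"""Synthetic input bundles with known ground truth.

Expression is a block-correlated Gaussian (within-block correlation rho_in)
with per-tissue case shifts planted in a subset of blocks; regulatory edges
attach preferentially to seed genes; PPI confidences are Beta-distributed,
higher within blocks; the drug roster contains sign-randomized decoys plus
one designed therapeutic whose target actions oppose every planted shift.
Identical seeds produce bit-identical bundles.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .io import (
    DrugTargetEvidence,
    ExpressionMatrix,
    PPINetwork,
    ProbeMap,
    RegulatoryNetwork,
    ValidationError,
)

THERAPEUTIC_DRUG_ID = "D0000"


@dataclass
class SynthConfig:
    n_blocks: int = 12
    block_size: int = 60
    n_dysregulated: int = 2     # disease blocks: shifted AND seed-enriched
    n_background_shifted: int = 4  # shifted blocks with no seed preference
    shift: float = 1.5          # case mean shift in units of noise SD
    noise_sd: float = 1.0
    rho_in: float = 0.8
    rho_out: float = 0.0
    tissues: tuple[str, ...] = ("FG", "LS", "MS")
    samples_per_tissue: int = 24  # split evenly case/control
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    n_seed_genes: int = 30
    seed_dysreg_frac: float = 0.6
    reg_edges_per_seed: int = 6
    reg_dysreg_pref: float = 0.7
    reg_background_edges: int = 150
    ppi_within_prob: float = 0.15
    ppi_within_beta: tuple[float, float] = (8.0, 2.0)
    ppi_between_beta: tuple[float, float] = (2.0, 5.0)
    ppi_background_m: int = 2
    n_drugs: int = 40
    targets_per_drug: int = 8
    evidence_per_target: int = 2
    therapeutic_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dysregulated + self.n_background_shifted > self.n_blocks:
            raise ValidationError("more shifted blocks than blocks")
        if self.samples_per_tissue < 4 or self.samples_per_tissue % 2:
            raise ValidationError("samples_per_tissue must be even and >= 4")
        if not 0 <= self.rho_out <= self.rho_in < 1:
            raise ValidationError("need 0 <= rho_out <= rho_in < 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("tissues", "ppi_within_beta", "ppi_between_beta"):
            d[key] = list(d[key])
        return d


@dataclass
class SyntheticTruth:
    block_of: dict[str, str]          # gene -> planted block label
    dysregulated: dict[str, int]      # disease block -> shift direction (+-1)
    background_shifted: dict[str, int]  # non-disease shifted block -> direction
    seed_genes: list[str]
    therapeutic_drug: str
    seed: int


@dataclass
class SyntheticBundle:
    config: SynthConfig
    expression: ExpressionMatrix
    seed_genes: list[str]
    regulatory: RegulatoryNetwork
    ppi: PPINetwork
    drug_evidence: list[DrugTargetEvidence]
    truth: SyntheticTruth
    probe_expression: ExpressionMatrix | None = None
    probe_map: ProbeMap | None = None


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate(config: SynthConfig | None = None, with_probes: bool = False) -> SyntheticBundle:
    """Build a full input bundle plus ground truth from ``config``."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.n_blocks * cfg.block_size
    genes = _gene_names(n_genes)
    blocks = [f"B{b:02d}" for b in range(1, cfg.n_blocks + 1)]
    block_of = {g: blocks[i // cfg.block_size] for i, g in enumerate(genes)}

    n_shifted = cfg.n_dysregulated + cfg.n_background_shifted
    shifted_idx = rng.choice(cfg.n_blocks, size=n_shifted, replace=False)
    dys_dir = {
        blocks[i]: int(rng.choice([-1, 1]))
        for i in sorted(shifted_idx[: cfg.n_dysregulated])
    }
    bg_dir = {
        blocks[i]: int(rng.choice([-1, 1]))
        for i in sorted(shifted_idx[cfg.n_dysregulated:])
    }
    shift_dir = {**dys_dir, **bg_dir}

    expression = _generate_expression(cfg, rng, genes, block_of, shift_dir)
    seed_genes = _pick_seed_genes(cfg, rng, genes, block_of, dys_dir)
    regulatory = _generate_regulatory(cfg, rng, genes, block_of, dys_dir, seed_genes)
    ppi = _generate_ppi(cfg, rng, genes, block_of)
    evidence = _generate_drugs(cfg, rng, genes, block_of, dys_dir, ppi)

    truth = SyntheticTruth(
        block_of=block_of,
        dysregulated=dys_dir,
        background_shifted=bg_dir,
        seed_genes=seed_genes,
        therapeutic_drug=THERAPEUTIC_DRUG_ID,
        seed=cfg.seed,
    )
    bundle = SyntheticBundle(
        cfg, expression, seed_genes, regulatory, ppi, evidence, truth
    )
    if with_probes:
        bundle.probe_expression, bundle.probe_map = _probe_layer(rng, expression)
    return bundle


def _generate_expression(cfg, rng, genes, block_of, dys_dir) -> ExpressionMatrix:
    n_genes = len(genes)
    half = cfg.samples_per_tissue // 2
    sample_ids, tissue_col, status_col = [], [], []
    cols = []
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_genes)
    block_index = np.array([int(block_of[g][1:]) - 1 for g in genes])
    w_in = np.sqrt(max(cfg.rho_in - cfg.rho_out, 0.0))
    w_out = np.sqrt(cfg.rho_out)
    w_noise = np.sqrt(1.0 - cfg.rho_in)
    for tissue in cfg.tissues:
        for status in (io.CASE, io.CONTROL):
            for i in range(half):
                sample_ids.append(f"{tissue}_{status}_{i + 1:02d}")
                tissue_col.append(tissue)
                status_col.append(status)
                factors = rng.normal(size=cfg.n_blocks)
                shared = rng.normal()
                eps = rng.normal(size=n_genes)
                x = (
                    w_in * factors[block_index]
                    + w_out * shared
                    + w_noise * eps
                ) * cfg.noise_sd + baseline
                if status == io.CASE:
                    for block, direction in dys_dir.items():
                        mask = block_index == int(block[1:]) - 1
                        x[mask] += cfg.shift * cfg.noise_sd * direction
                cols.append(x)
    values = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene"), columns=sample_ids
    )
    meta = pd.DataFrame(
        {"tissue": tissue_col, "status": status_col},
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionMatrix(values, meta)


def _pick_seed_genes(cfg, rng, genes, block_of, dys_dir) -> list[str]:
    dys_genes = [g for g in genes if block_of[g] in dys_dir]
    other = [g for g in genes if block_of[g] not in dys_dir]
    n_dys = min(int(round(cfg.seed_dysreg_frac * cfg.n_seed_genes)), len(dys_genes))
    n_other = min(cfg.n_seed_genes - n_dys, len(other))
    picked = []
    if n_dys:
        picked += list(rng.choice(dys_genes, size=n_dys, replace=False))
    if n_other:
        picked += list(rng.choice(other, size=n_other, replace=False))
    return sorted(picked)


def _generate_regulatory(cfg, rng, genes, block_of, dys_dir, seed_genes) -> RegulatoryNetwork:
    dys_genes = [g for g in genes if block_of[g] in dys_dir]
    edges: dict[tuple[str, str], int | None] = {}

    def add(src: str, dst: str) -> None:
        if src == dst or (src, dst) in edges or (dst, src) in edges:
            return
        sign = {0: 1, 1: -1, 2: None}[int(rng.integers(3))]
        edges[(src, dst)] = sign

    for seed_gene in seed_genes:
        for _ in range(cfg.reg_edges_per_seed):
            if rng.random() < cfg.reg_dysreg_pref and dys_genes:
                partner = dys_genes[int(rng.integers(len(dys_genes)))]
            else:
                partner = genes[int(rng.integers(len(genes)))]
            if rng.random() < 0.5:
                add(seed_gene, partner)
            else:
                add(partner, seed_gene)
    for _ in range(cfg.reg_background_edges):
        a = genes[int(rng.integers(len(genes)))]
        b = genes[int(rng.integers(len(genes)))]
        add(a, b)
    return RegulatoryNetwork([(s, d, g) for (s, d), g in sorted(edges.items())])


def _generate_ppi(cfg, rng, genes, block_of) -> PPINetwork:
    import networkx as nx

    edges: dict[tuple[str, str], float] = {}
    a_in, b_in = cfg.ppi_within_beta
    a_out, b_out = cfg.ppi_between_beta

    def put(p: str, q: str, conf: float) -> None:
        key = (p, q) if p < q else (q, p)
        if key not in edges:
            edges[key] = float(np.clip(conf, 0.0, 1.0))

    # dense-ish high-confidence edges within each planted block
    by_block: dict[str, list[str]] = {}
    for g in genes:
        by_block.setdefault(block_of[g], []).append(g)
    for members in by_block.values():
        m = len(members)
        draw = rng.random(size=(m, m))
        for i in range(m):
            for j in range(i + 1, m):
                if draw[i, j] < cfg.ppi_within_prob:
                    put(members[i], members[j], rng.beta(a_in, b_in))

    # scale-free-ish background across all genes, mostly low confidence
    bg = nx.barabasi_albert_graph(
        len(genes), cfg.ppi_background_m, seed=int(rng.integers(2**31))
    )
    for i, j in sorted(bg.edges()):
        put(genes[i], genes[j], rng.beta(a_out, b_out))

    return PPINetwork([(p, q, c) for (p, q), c in sorted(edges.items())])


def _generate_drugs(cfg, rng, genes, block_of, dys_dir, ppi) -> list[DrugTargetEvidence]:
    records: list[DrugTargetEvidence] = []

    # designed therapeutic: targets the strongest module genes, action opposes
    # the planted shift in every case
    n_per_block = max(1, cfg.targets_per_drug // max(len(dys_dir), 1))
    thera_targets: list[tuple[str, int]] = []
    for block, direction in sorted(dys_dir.items()):
        members = [g for g in genes if block_of[g] == block]
        members.sort(key=lambda g: (-ppi.strength(g), g))
        for g in members[:n_per_block]:
            thera_targets.append((g, -direction))
    for target, action in thera_targets:
        ev = [(cfg.therapeutic_prob, action) for _ in range(cfg.evidence_per_target)]
        records.append(
            DrugTargetEvidence(THERAPEUTIC_DRUG_ID, "therapeutic", target, ev)
        )

    for d in range(1, cfg.n_drugs):
        drug_id = f"D{d:04d}"
        targets = rng.choice(len(genes), size=cfg.targets_per_drug, replace=False)
        for t in sorted(targets):
            ev = [
                (float(rng.uniform(0.5, 1.0)), int(rng.choice([-1, 1])))
                for _ in range(cfg.evidence_per_target)
            ]
            records.append(DrugTargetEvidence(drug_id, f"decoy-{d}", genes[t], ev))
    return sorted(records, key=lambda r: (r.drug_id, r.target))


def _probe_layer(rng, em: ExpressionMatrix) -> tuple[ExpressionMatrix, ProbeMap]:
    """Probe-level matrix whose per-gene probe mean equals the gene matrix."""
    rows, probe_ids, mapping = [], [], {}
    for gene in em.genes:
        n_probes = int(rng.integers(1, 4))
        offsets = rng.normal(0, 0.1, size=n_probes)
        offsets -= offsets.mean()  # probe means average back to the gene value
        base = em.values.loc[gene].to_numpy()
        for j in range(n_probes):
            pid = f"{gene}_at{j}"
            probe_ids.append(pid)
            mapping[pid] = gene
            rows.append(base + offsets[j])
    values = pd.DataFrame(
        np.vstack(rows), index=pd.Index(probe_ids, name="gene"), columns=em.samples
    )
    return ExpressionMatrix(values, em.meta.copy()), ProbeMap(mapping)


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "seeds": outdir / "seed_genes.txt",
        "regulatory": outdir / "regulatory.tsv",
        "ppi": outdir / "ppi.tsv",
        "drug_evidence": outdir / "drug_evidence.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "synth_config.json",
    }
    io.write_expression(bundle.expression, paths["expression"], paths["samples"])
    paths["seeds"].write_text("".join(g + "\n" for g in bundle.seed_genes))
    io.write_regulatory(bundle.regulatory, paths["regulatory"])
    io.write_ppi(bundle.ppi, paths["ppi"])
    io.write_drug_evidence(bundle.drug_evidence, paths["drug_evidence"])
    truth_rows = [
        (
            g,
            b,
            bundle.truth.dysregulated.get(
                b, bundle.truth.background_shifted.get(b, 0)
            ),
            int(b in bundle.truth.dysregulated),
        )
        for g, b in sorted(bundle.truth.block_of.items())
    ]
    pd.DataFrame(
        truth_rows, columns=["gene", "block", "shift_direction", "disease"]
    ).to_csv(
        paths["truth"], sep="\t", index=False
    )
    meta = bundle.config.to_dict()
    meta["therapeutic_drug"] = bundle.truth.therapeutic_drug
    paths["config"].write_text(json.dumps(meta, indent=2) + "\n")
    if bundle.probe_expression is not None:
        paths["probe_expression"] = outdir / "probe_expression.tsv"
        paths["probe_map"] = outdir / "probe_map.tsv"
        io.write_expression(
            bundle.probe_expression, paths["probe_expression"], outdir / "samples.tsv"
        )
        io.write_probe_map(bundle.probe_map, paths["probe_map"])
    return paths


def read_seed_genes(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
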