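"""Domain types, TSV readers/writers, and run configuration.

All pipeline stages exchange plain TSV files so each stage can be run,
inspected, and tested independently.  Readers validate on construction and
reject malformed rows with the offending row identified in the error; every
reader/writer pair round-trips valid files exactly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
STATUS_LABELS = frozenset({CASE, CONTROL})

#: unassigned-module label, following the WGCNA colour convention
GREY = "grey"


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample log-intensity matrix with per-sample tissue/status.

    ``values`` is a DataFrame indexed by gene symbol with sample-id columns;
    ``meta`` is indexed by sample id with columns ``tissue`` and ``status``
    (status in {case, control}).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        genes = self.values.index
        if genes.duplicated().any():
            dup = genes[genes.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dup[:5]}")
        samples = list(self.values.columns)
        if len(set(samples)) != len(samples):
            raise ValidationError("duplicate sample ids in matrix header")
        missing = [s for s in samples if s not in self.meta.index]
        if missing:
            raise ValidationError(f"metadata missing for samples: {missing}")
        bad = set(self.meta["status"]) - STATUS_LABELS
        if bad:
            raise ValidationError(f"unknown status labels: {sorted(bad)}")
        # align metadata to matrix column order
        self.meta = self.meta.loc[samples]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            rows = self.values.index[
                ~np.isfinite(self.values.to_numpy(dtype=float)).all(axis=1)
            ].tolist()
            raise ValidationError(f"non-finite values in gene rows: {rows[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.meta["tissue"].unique())

    def samples_where(self, tissue: str | None = None, status: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        if tissue is not None:
            mask &= self.meta["tissue"] == tissue
        if status is not None:
            mask &= self.meta["status"] == status
        return list(self.meta.index[mask])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.meta.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.meta.loc[samples])

    def __eq__(self, other) -> bool:  # exact round-trip equality
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.meta[["tissue", "status"]].equals(other.meta[["tissue", "status"]])
        )


def read_expression(matrix_path, meta_path) -> ExpressionMatrix:
    """Read an expression TSV (first column ``gene``) plus sample metadata."""
    values = pd.read_csv(matrix_path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if values.columns[0] != "gene":
        raise ValidationError(f"expected first column 'gene', got {values.columns[0]!r}")
    values = values.set_index("gene")
    try:
        values = values.astype(float)
    except ValueError as exc:
        for gene, row in values.iterrows():
            try:
                row.astype(float)
            except ValueError:
                raise ValidationError(f"unparsable value in gene row {gene!r}") from exc
        raise
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, float_precision="round_trip")
    required = {"sample", "tissue", "status"}
    if not required.issubset(meta.columns):
        raise ValidationError(f"metadata must have columns {sorted(required)}")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValidationError(f"duplicate sample id in metadata: {dup}")
    meta = meta.set_index("sample")
    return ExpressionMatrix(values, meta)


def write_expression(em: ExpressionMatrix, matrix_path, meta_path) -> None:
    em.values.to_csv(matrix_path, sep="\t", index_label="gene", float_format="%.17g")
    em.meta[["tissue", "status"]].to_csv(meta_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Probe map
# ---------------------------------------------------------------------------

@dataclass
class ProbeMap:
    """Many-to-one probe-id -> gene-symbol mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for probe, gene in self.mapping.items():
            if not gene or not str(gene).strip():
                raise ValidationError(f"probe {probe!r} maps to empty gene symbol")
        self.mapping = {str(p).strip(): str(g).strip() for p, g in self.mapping.items()}


def read_probe_map(path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", dtype=str, float_precision="round_trip")
    if not {"probe", "gene"}.issubset(df.columns):
        raise ValidationError("probe map must have columns probe, gene")
    if df["probe"].duplicated().any():
        raise ValidationError("duplicate probe ids in probe map")
    return ProbeMap(dict(zip(df["probe"], df["gene"])))


def write_probe_map(pm: ProbeMap, path) -> None:
    pd.DataFrame(
        {"probe": list(pm.mapping), "gene": list(pm.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regulatory network (directed, optionally signed)
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryNetwork:
    """Directed gene-gene regulatory edges; sign is +1, -1 or None (unknown)."""

    edges: list[tuple[str, str, int | None]]

    def __post_init__(self) -> None:
        seen = set()
        for src, dst, sign in self.edges:
            if sign not in (1, -1, None):
                raise ValidationError(f"bad sign {sign!r} on edge {src}->{dst}")
            if (src, dst) in seen:
                raise ValidationError(f"duplicate regulatory edge {src}->{dst}")
            seen.add((src, dst))

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e[:2]}

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for src, dst, _ in self.edges:
            if src == gene:
                out.add(dst)
            elif dst == gene:
                out.add(src)
        return out


_SIGN_TO_TOKEN = {1: "+1", -1: "-1", None: "NA"}
_TOKEN_TO_SIGN = {"+1": 1, "1": 1, "-1": -1, "NA": None, "": None}


def read_regulatory(path) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, float_precision="round_trip")
    if not {"src", "dst"}.issubset(df.columns):
        raise ValidationError("regulatory edge list must have columns src, dst")
    edges = []
    for i, row in df.iterrows():
        token = str(row.get("sign", "NA"))
        if token not in _TOKEN_TO_SIGN:
            raise ValidationError(f"malformed sign token {token!r} at row {i}")
        edges.append((row["src"].strip(), row["dst"].strip(), _TOKEN_TO_SIGN[token]))
    return RegulatoryNetwork(edges)


def write_regulatory(net: RegulatoryNetwork, path) -> None:
    pd.DataFrame(
        [(s, d, _SIGN_TO_TOKEN[g]) for s, d, g in net.edges],
        columns=["src", "dst", "sign"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PPI network (undirected, confidence-weighted)
# ---------------------------------------------------------------------------

class PPINetwork:
    """Undirected PPI edges with confidence in [0, 1].

    Edges are keyed by lexicographically ordered endpoint pair so duplicates
    are detectable regardless of input orientation.
    """

    def __init__(self, edges) -> None:
        self._conf: dict[tuple[str, str], float] = {}
        self._adj: dict[str, dict[str, float]] = {}
        for p, q, conf in edges:
            self.add_edge(p, q, conf)

    def add_edge(self, p: str, q: str, conf: float) -> None:
        conf = float(conf)
        if not 0.0 <= conf <= 1.0:
            raise ValidationError(f"PPI conf {conf} outside [0,1] for edge ({p},{q})")
        if p == q:
            raise ValidationError(f"PPI self-loop on {p!r}")
        key = (p, q) if p < q else (q, p)
        if key in self._conf:
            raise ValidationError(f"duplicate PPI edge {key}")
        self._conf[key] = conf
        self._adj.setdefault(p, {})[q] = conf
        self._adj.setdefault(q, {})[p] = conf

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(p, q, c) for (p, q), c in sorted(self._conf.items())]

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    def __len__(self) -> int:
        return len(self._conf)

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def degree(self, gene: str) -> int:
        return len(self._adj.get(gene, {}))

    def strength(self, gene: str) -> float:
        """Sum of confidences over edges incident to ``gene``."""
        return float(sum(self._adj.get(gene, {}).values()))

    def incident(self, gene: str) -> dict[str, float]:
        return dict(self._adj.get(gene, {}))

    def subnetwork(self, genes, min_conf: float = 0.0) -> "PPINetwork":
        genes = set(genes)
        return PPINetwork(
            (p, q, c)
            for (p, q), c in self._conf.items()
            if p in genes and q in genes and c >= min_conf
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self._conf == other._conf


def read_ppi(path) -> PPINetwork:
    df = pd.read_csv(path, sep="\t", dtype={"p": str, "q": str}, float_precision="round_trip")
    if not {"p", "q", "conf"}.issubset(df.columns):
        raise ValidationError("PPI edge list must have columns p, q, conf")
    return PPINetwork(zip(df["p"], df["q"], df["conf"].astype(float)))


def write_ppi(net: PPINetwork, path) -> None:
    pd.DataFrame(net.edges, columns=["p", "q", "conf"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Drug-target evidence
# ---------------------------------------------------------------------------

@dataclass
class DrugTargetEvidence:
    """Evidence items for one (drug, target) pair: (prob in [0,1], sign +-1)."""

    drug_id: str
    drug_name: str
    target: str
    evidence: list[tuple[float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prob, sign in self.evidence:
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(
                    f"evidence prob {prob} outside [0,1] for {self.drug_id}->{self.target}"
                )
            if sign not in (1, -1):
                raise ValidationError(
                    f"evidence sign {sign!r} not +-1 for {self.drug_id}->{self.target}"
                )

    @property
    def n_evidence(self) -> int:
        return len(self.evidence)


def read_drug_evidence(path) -> list[DrugTargetEvidence]:
    """Read one evidence row per line, grouped into (drug, target) records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, float_precision="round_trip")
    required = {"drug_id", "drug_name", "target", "prob", "sign"}
    if not required.issubset(df.columns):
        raise ValidationError(f"drug evidence must have columns {sorted(required)}")
    records: dict[tuple[str, str], DrugTargetEvidence] = {}
    for i, row in df.iterrows():
        token = row["sign"]
        if token not in ("+1", "1", "-1"):
            raise ValidationError(f"malformed sign token {token!r} at row {i}")
        key = (row["drug_id"], row["target"])
        rec = records.get(key)
        if rec is None:
            rec = records[key] = DrugTargetEvidence(
                row["drug_id"], row["drug_name"], row["target"]
            )
        rec.evidence.append((float(row["prob"]), 1 if token in ("+1", "1") else -1))
        DrugTargetEvidence(rec.drug_id, rec.drug_name, rec.target, rec.evidence)
    return sorted(records.values(), key=lambda r: (r.drug_id, r.target))


def write_drug_evidence(records, path) -> None:
    rows = [
        (r.drug_id, r.drug_name, r.target, prob, _SIGN_TO_TOKEN[sign], "assay")
        for r in records
        for prob, sign in r.evidence
    ]
    pd.DataFrame(
        rows, columns=["drug_id", "drug_name", "target", "prob", "sign", "evidence_type"]
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Enrichment / module network / drug score result types
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Signed log-hypergeometric enrichment of one module.

    N: total genes over all assigned modules; K: overlap of those genes with
    the expanded-network candidates; n: module size; k: module-candidate
    overlap.
    """

    module: str
    N: int
    K: int
    n: int
    k: int
    f_pts: float
    rank: int = 0
    selected: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.n <= self.N and self.K <= self.N):
            raise ValidationError(
                f"invalid counts for module {self.module}: "
                f"N={self.N} K={self.K} n={self.n} k={self.k}"
            )
        self.selected = self.f_pts > 0


@dataclass
class DiseaseModuleNetwork:
    """A selected module's high-confidence PPI subnetwork with gene annotations.

    Retained genes all have degree >= 1; ``direction`` is the dysregulation
    sign g_i, ``delta`` the accumulated log-fold-change, ``priority`` is in
    {1, 1/2, 1/4}, ``rp_score`` >= 0.
    """

    module: str
    network: PPINetwork
    direction: dict[str, int]
    delta: dict[str, float]
    priority: dict[str, float]
    rp_score: dict[str, float]

    def __post_init__(self) -> None:
        for gene in self.genes:
            if self.network.degree(gene) < 1:
                raise ValidationError(f"gene {gene} isolated in module {self.module}")
            if self.rp_score[gene] < 0:
                raise ValidationError(f"negative RP-score for {gene}")
            if self.priority[gene] not in (1.0, 0.5, 0.25):
                raise ValidationError(f"bad priority {self.priority[gene]} for {gene}")

    @property
    def genes(self) -> set[str]:
        return self.network.nodes


@dataclass
class DrugScoreTable:
    """Per-drug module scores (DES), integrated score (DESS), rank, top flag."""

    table: pd.DataFrame  # index drug_id; columns drug_name, des_<m>..., dess, rank, top

    @property
    def modules(self) -> list[str]:
        return [c[4:] for c in self.table.columns if c.startswith("des_")]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable thresholds for a full pipeline run; embedded in all outputs."""

    alpha: float = 0.05
    use_fdr: bool = False
    sample_cut_height: float = 100.0
    dispersion_sd_mult: float = 3.0
    powers: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.8
    soft_power: int | None = None  # None = choose by scale-free fit
    min_module_size: int = 20
    tree_cut_height: float = 0.9
    ppi_threshold: float = 0.75
    k_const: float = 2.0
    log_base: float = 10.0
    top_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError("alpha must be in (0,1]")
        if not 0 <= self.ppi_threshold <= 1:
            raise ValidationError("ppi_threshold must be in [0,1]")
        if not 0 < self.top_fraction <= 1:
            raise ValidationError("top_fraction must be in (0,1]")
        if self.log_base <= 1:
            raise ValidationError("log_base must exceed 1")
        if len(self.powers) < 1:
            raise ValidationError("need at least one candidate power")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["powers"] = list(d["powers"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "powers" in d:
            d["powers"] = tuple(d["powers"])
        return cls(**d)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
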