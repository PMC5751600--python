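"""Co-expression module detection.

Unsigned weighted network: adjacency a_ij = |cor(x_i, x_j)|^beta, topological
overlap TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), and
average-linkage clustering of the 1 - TOM dissimilarity with a static cut.
Module labels follow the size-ordered colour palette (largest module is
"turquoise").
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .io import CASE, CONTROL, GREY, ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)

#: size-ordered module label palette (WGCNA colour convention)
PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass
class CoexpressionPartition:
    """Gene -> module-label assignment plus detection provenance."""

    labels: dict[str, str]
    beta: int | None = None
    r2_by_power: dict[int, float] = field(default_factory=dict)
    min_module_size: int = 0
    cut_height: float = 0.0

    def module_genes(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    @property
    def modules(self) -> list[str]:
        """Assigned module labels (grey excluded), largest first."""
        sizes: dict[str, int] = {}
        for m in self.labels.values():
            if m != GREY:
                sizes[m] = sizes.get(m, 0) + 1
        return sorted(sizes, key=lambda m: (-sizes[m], m))

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.labels.values():
            out[m] = out.get(m, 0) + 1
        return out


def trim_outlier_samples(
    em: ExpressionMatrix, cut_height: float
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove samples severed from the main cluster above ``cut_height``.

    Average-linkage tree on pairwise Euclidean sample distances; branches
    that merge above the cut form separate clusters and every cluster except
    the largest is removed.
    """
    samples = em.samples
    if len(samples) < 3:
        raise ValidationError("need >= 3 samples to trim outliers")
    d = pdist(em.values.to_numpy(dtype=float).T, metric="euclidean")
    if np.all(d == 0) or not np.isfinite(cut_height):
        return em, []
    z = linkage(d, method="average")
    assignment = fcluster(z, t=cut_height, criterion="distance")
    counts = np.bincount(assignment)
    # ties broken toward the cluster containing the first sample
    best = int(np.argmax(counts))
    keep = [s for s, c in zip(samples, assignment) if c == best]
    removed = [s for s in samples if s not in set(keep)]
    if not keep:
        raise ValidationError("sample cut removed all samples")
    if removed:
        log.info("trimmed %d outlier samples: %s", len(removed), removed)
    return em.subset_samples(keep), removed


def _adjacency(values: np.ndarray, beta: float, genes=None) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0):
        if genes is not None:
            bad = [g for g, s in zip(genes, sd) if s == 0]
            raise ValidationError(f"zero-variance genes: {bad[:5]}")
        raise ValidationError("zero-variance gene in expression matrix")
    cor = np.corrcoef(values)
    a = np.abs(np.clip(cor, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def pick_soft_threshold(
    em: ExpressionMatrix,
    powers=tuple(range(1, 21)),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, dict[int, float]]:
    """Choose the soft-thresholding exponent by scale-free topology fit.

    For each candidate power the connectivity distribution is binned and the
    fit R^2 is the squared correlation of log10(frequency) against
    log10(bin centre).  Returns the smallest power reaching ``r2_target``,
    falling back to the best-fitting power, together with all R^2 values.
    """
    powers = sorted(set(int(b) for b in powers))
    if not powers:
        raise ValidationError("empty candidate power list")
    values = em.values.to_numpy(dtype=float)
    r2_by_power: dict[int, float] = {}
    for beta in powers:
        a = _adjacency(values, beta, em.genes)
        k = a.sum(axis=1)
        r2_by_power[beta] = _scale_free_r2(k, n_bins)
    chosen = next((b for b in powers if r2_by_power[b] >= r2_target), None)
    if chosen is None:
        chosen = max(powers, key=lambda b: r2_by_power[b])
    return chosen, r2_by_power


def _scale_free_r2(connectivity: np.ndarray, n_bins: int) -> float:
    k = connectivity[connectivity > 0]
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = (freq > 0) & (centers > 0)
    if ok.sum() < 3:
        raise ValidationError("fewer than 3 populated connectivity bins")
    r = np.corrcoef(np.log10(centers[ok]), np.log10(freq[ok]))[0, 1]
    return float(r ** 2)


def compute_tom(em: ExpressionMatrix, beta: float) -> pd.DataFrame:
    """Unsigned TOM dissimilarity (1 - TOM) with zero diagonal."""
    if len(em.genes) < 2:
        raise ValidationError("need >= 2 genes for a TOM")
    a = _adjacency(em.values.to_numpy(dtype=float), beta, em.genes)
    k = a.sum(axis=1)
    shared = a @ a  # diagonal of a is 0, so u = i, j terms vanish
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    return pd.DataFrame(diss, index=em.genes, columns=em.genes)


def detect_modules(
    diss: pd.DataFrame, min_module_size: int, cut_height: float, beta: int | None = None
) -> CoexpressionPartition:
    """Average-linkage clustering of a TOM dissimilarity with a static cut.

    Clusters smaller than ``min_module_size`` become grey; surviving modules
    are labelled largest-first from the colour palette.
    """
    genes = list(diss.index)
    d = diss.to_numpy(dtype=float)
    if np.all(d == 0):
        raise ValidationError("degenerate all-zero dissimilarity")
    z = linkage(squareform(d, checks=False), method="average")
    assignment = fcluster(z, t=cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for gene, cid in zip(genes, assignment):
        clusters.setdefault(int(cid), []).append(gene)
    kept = [c for c in clusters.values() if len(c) >= min_module_size]
    # largest first; ties by first member for determinism
    kept.sort(key=lambda c: (-len(c), c[0]))
    if len(kept) > len(PALETTE):
        raise ValidationError(f"more than {len(PALETTE)} modules; raise min size")
    labels = {g: GREY for g in genes}
    for color, members in zip(PALETTE, kept):
        for g in members:
            labels[g] = color
    return CoexpressionPartition(
        labels=labels,
        beta=beta,
        min_module_size=min_module_size,
        cut_height=cut_height,
    )


@dataclass
class ModuleTraitCorrelation:
    """Eigengene values and their sample-group / case-control associations."""

    eigengenes: pd.DataFrame  # modules x samples
    group_corr: pd.DataFrame  # module, tissue, status, r, p
    tissue_tests: pd.DataFrame  # module, tissue, t, p


def module_eigengene(em: ExpressionMatrix, genes) -> pd.Series:
    """First principal component across samples of the standardized submatrix.

    Sign-oriented to correlate positively with the module mean profile.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValidationError("module of size 1 has no eigengene")
    x = em.values.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise ValidationError("zero-variance gene in module")
    xz = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(xz, full_matrices=False)
    eig = vt[0]
    mean_profile = xz.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=em.samples, name="eigengene")


def module_trait_correlation(
    em: ExpressionMatrix, partition: CoexpressionPartition
) -> ModuleTraitCorrelation:
    """Correlate module eigengenes with per-group expression patterns.

    Per (module, tissue, status) group: Pearson r between the eigengene and
    the module mean expression over the group's samples, with the asymptotic
    p-value.  Per (module, tissue): two-sample t-test of case vs control
    eigengene values.
    """
    missing = [g for g in partition.labels if g not in set(em.genes)]
    if missing:
        raise ValidationError(f"partition genes absent from matrix: {missing[:5]}")
    eig_rows = {}
    corr_rows = []
    test_rows = []
    for module in partition.modules:
        genes = partition.module_genes(module)
        eig = module_eigengene(em, genes)
        eig_rows[module] = eig
        mean_profile = em.values.loc[genes].mean(axis=0)
        for tissue in em.tissues:
            for status in (CASE, CONTROL):
                samples = em.samples_where(tissue=tissue, status=status)
                if len(samples) < 3:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(eig[samples], mean_profile[samples])
                corr_rows.append((module, tissue, status, r, p))
            case = eig[em.samples_where(tissue=tissue, status=CASE)]
            ctrl = eig[em.samples_where(tissue=tissue, status=CONTROL)]
            t, p = stats.ttest_ind(case, ctrl)
            test_rows.append((module, tissue, float(t), float(p)))
    return ModuleTraitCorrelation(
        eigengenes=pd.DataFrame(eig_rows).T,
        group_corr=pd.DataFrame(
            corr_rows, columns=["module", "tissue", "status", "r", "p"]
        ),
        tissue_tests=pd.DataFrame(test_rows, columns=["module", "tissue", "t", "p"]),
    )


def write_partition(partition: CoexpressionPartition, path) -> None:
    pd.DataFrame(
        sorted(partition.labels.items()), columns=["gene", "module"]
    ).to_csv(path, sep="\t", index=False)


def read_partition(path) -> CoexpressionPartition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CoexpressionPartition(labels=dict(zip(df["gene"], df["module"])))
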