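"""Probe aggregation, sample-dispersion check, and moderated differential
expression.

The moderated test shrinks per-gene residual variances toward a prior fitted
by method of moments on the log sample variances (empirical Bayes), forms one
case-vs-control moderated t per tissue, and combines the per-tissue contrasts
into a moderated F with the shrunken denominator degrees of freedom.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CASE, CONTROL, ExpressionMatrix, ProbeMap, ValidationError

log = logging.getLogger(__name__)


def aggregate_probes(probe_matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by averaging probe rows.

    Probes absent from the map are dropped (count logged).  Raises if no
    probe maps to any gene.
    """
    mapping = probe_map.mapping
    probes = probe_matrix.values.index
    mapped = [p for p in probes if p in mapping]
    n_dropped = len(probes) - len(mapped)
    if n_dropped:
        log.info("dropping %d unmapped probe rows", n_dropped)
    if not mapped:
        raise ValidationError("no probe ids overlap the probe map")
    sub = probe_matrix.values.loc[mapped]
    genes = pd.Index([mapping[p] for p in mapped], name="gene")
    merged = sub.groupby(genes, sort=True).mean()
    return ExpressionMatrix(merged, probe_matrix.meta.copy())


def check_sample_dispersion(em: ExpressionMatrix, sd_mult: float = 3.0) -> pd.DataFrame:
    """Report per-sample mean intensity, its dispersion, and outlier flags.

    A sample is flagged when its mean deviates from the grand mean by more
    than ``sd_mult`` standard deviations of the per-sample means.  Removal is
    left to the caller.
    """
    if len(em.samples) < 2:
        raise ValidationError("need >= 2 samples for a dispersion check")
    means = em.values.mean(axis=0)
    sd = float(means.std(ddof=1))
    if sd == 0.0:
        z = pd.Series(0.0, index=means.index)
    else:
        z = (means - means.mean()) / sd
    return pd.DataFrame(
        {
            "sample": means.index,
            "mean": means.to_numpy(),
            "z": z.to_numpy(),
            "flagged": np.abs(z.to_numpy()) > sd_mult,
            "dispersion": sd,
        }
    ).set_index("sample")


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y; trigamma is decreasing and convex.
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit prior degrees of freedom d0 and prior variance s0^2.

    Method of moments on z = log(s2): under the scaled-F model,
    E[z] = log(s0^2) + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(df/2) + trigamma(d0/2).  Returns (inf, s0^2) when
    the observed spread is no larger than the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValidationError("need >= 2 positive sample variances to fit the prior")
    z = np.log(s2[ok])
    e = z - float(special.digamma(df / 2.0)) + math.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return math.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(
        np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return d0, s0_2


def moderated_test(
    em: ExpressionMatrix,
    alpha: float = 0.05,
    use_fdr: bool = False,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-tissue moderated t and overall moderated F across tissue contrasts.

    Residual variance is pooled over all (tissue, status) groups; a prior
    (d0, s0^2) is fitted across genes and each gene's variance shrunk to
    s2_post = (d0*s0^2 + df*s2) / (d0 + df).  Each tissue contributes one
    case-minus-control contrast; the overall statistic is the mean squared
    moderated t over tissues, referred to F(n_tissues, d0 + df).

    ``d0_override`` forces the prior degrees of freedom: 0 recovers the
    ordinary F-test, ``inf`` tests against s0^2 alone.

    Returns a DataFrame indexed by gene with columns ``lfc_<tissue>``...,
    ``stat``, ``p``, ``candidate``, ``delta``, ``direction``.
    """
    tissues = em.tissues
    values = em.values.to_numpy(dtype=float)
    n_genes = values.shape[0]

    lfc = {}
    ss_resid = np.zeros(n_genes)
    n_obs = 0
    n_groups = 0
    se_mult = {}
    for tissue in tissues:
        cols = {}
        for status in (CASE, CONTROL):
            samples = em.samples_where(tissue=tissue, status=status)
            if len(samples) < 2:
                raise ValidationError(
                    f"tissue {tissue!r} has {len(samples)} {status} samples; need >= 2"
                )
            cols[status] = em.values[samples].to_numpy(dtype=float)
        for arr in cols.values():
            ss_resid += ((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            n_obs += arr.shape[1]
            n_groups += 1
        lfc[tissue] = cols[CASE].mean(axis=1) - cols[CONTROL].mean(axis=1)
        se_mult[tissue] = 1.0 / cols[CASE].shape[1] + 1.0 / cols[CONTROL].shape[1]

    df_resid = n_obs - n_groups
    s2 = ss_resid / df_resid

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_2 = fit_variance_prior(s2, df_resid)
    else:
        d0, s0_2 = fit_variance_prior(s2, df_resid)

    if math.isinf(d0):
        s2_post = np.full(n_genes, s0_2)
        df_total = math.inf
    elif d0 == 0.0:
        s2_post = s2
        df_total = df_resid
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    t2_sum = np.zeros(n_genes)
    out = {}
    for tissue in tissues:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc[tissue] / np.sqrt(s2_post * se_mult[tissue])
        t = np.where(np.isfinite(t), t, 0.0)
        t2_sum += t ** 2
        out[f"lfc_{tissue}"] = lfc[tissue]
        out[f"t_{tissue}"] = t

    n_contrasts = len(tissues)
    fstat = t2_sum / n_contrasts
    if math.isinf(df_total):
        p = stats.chi2.sf(fstat * n_contrasts, n_contrasts)
    else:
        p = stats.f.sf(fstat, n_contrasts, df_total)

    delta = np.sum([lfc[t] for t in tissues], axis=0)
    if use_fdr:
        p_adj = _benjamini_hochberg(p)
        candidate = p_adj <= alpha
    else:
        candidate = p <= alpha

    out.update(
        stat=fstat,
        p=p,
        candidate=candidate,
        delta=delta,
        direction=np.sign(delta).astype(int),
    )
    return pd.DataFrame(out, index=pd.Index(em.genes, name="gene"))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene", float_precision="round_trip")
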