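"""Expression normalization and sample-level summaries.

FPKM (fragments per kilobase of exon per million mapped fragments) is the
working expression unit downstream: fpkm = count / (length_kb * libsize_M).
GC-content bias is profiled per sample by binning genes on GC fraction,
computing the relative enrichment F_il of sample i's count share in bin l
over the pooled share, and fitting a regression spline to log2 F_il; the
correction divides counts by the predicted enrichment at each gene's GC.

The expression-mode mixture (active vs repressed genes) is a two-component
Gaussian mixture on log10(FPKM+1) fit by EM with a monotonicity assertion
on the log-likelihood at every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.interpolate import LSQUnivariateSpline
from scipy.spatial.distance import squareform

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "compute_fpkm",
    "log_transform",
    "GCBinProfile",
    "gc_correction",
    "MixtureFit",
    "expression_mode_mixture",
    "correlation_heatmap_order",
    "GenePrecision",
    "gene_precision",
    "filter_top_expressed",
]


def compute_fpkm(
    counts: ExpressionMatrix,
    gene_lengths: np.ndarray | None = None,
    library_sizes: np.ndarray | None = None,
) -> ExpressionMatrix:
    """counts / (gene length in kb x library size in millions)."""
    if counts.value_kind != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    lengths = counts.gene_lengths if gene_lengths is None else np.asarray(gene_lengths, float)
    libs = counts.library_sizes if library_sizes is None else np.asarray(library_sizes, float)
    if lengths is None or libs is None:
        raise ValueError("gene lengths and library sizes are required for FPKM")
    if np.any(lengths <= 0):
        raise ValueError("non-positive gene length")
    if np.any(libs <= 0):
        raise ValueError("non-positive library size")
    fpkm = counts.values / (lengths[:, None] / 1e3) / (libs[None, :] / 1e6)
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=fpkm,
        value_kind="fpkm",
        gene_lengths=lengths,
        library_sizes=libs,
    )


def log_transform(fpkm: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(FPKM + pseudocount)."""
    if fpkm.value_kind != "fpkm":
        raise ValueError("log_transform expects an FPKM matrix")
    return ExpressionMatrix(
        gene_ids=list(fpkm.gene_ids),
        sample_ids=list(fpkm.sample_ids),
        values=np.log2(fpkm.values + pseudocount),
        value_kind="log2fpkm",
        gene_lengths=fpkm.gene_lengths,
        library_sizes=fpkm.library_sizes,
    )


# ---------------------------------------------------------------------------
# GC-bias profiling and correction
# ---------------------------------------------------------------------------


@dataclass
class GCBinProfile:
    """Per-sample GC enrichment profile.

    ``enrichment[i, l]`` is F_il, the count share of sample i in GC bin l
    relative to the pooled share; an unbiased sample sits near 1 in every
    bin.  ``predict(i, gc)`` evaluates the fitted spline (on the linear
    enrichment scale) at arbitrary GC fractions.
    """

    bin_edges: np.ndarray
    bin_gc_means: np.ndarray
    enrichment: np.ndarray  # samples x bins
    splines: list

    def predict(self, sample_index: int, gc: np.ndarray) -> np.ndarray:
        gc = np.clip(np.asarray(gc, float), self.bin_gc_means[0], self.bin_gc_means[-1])
        log2f = self.splines[sample_index](gc)
        return np.exp2(log2f)


def _equal_count_bins(gc: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(gc, np.linspace(0, 1, n_bins + 1))
    qs[0] -= 1e-9
    qs[-1] += 1e-9
    edges = np.unique(qs)
    if len(edges) - 1 < n_bins:
        logger.info("merged %d empty/degenerate GC bins", n_bins - (len(edges) - 1))
    return edges


def _fit_df_spline(x: np.ndarray, y: np.ndarray, df: int):
    """Cubic regression spline with the given degrees of freedom.

    df = (number of interior knots) + 4 for a cubic B-spline basis, so
    df=5 means one interior knot at the median.
    """
    n_knots = max(df - 4, 0)
    if n_knots > 0:
        knots = np.quantile(x, np.linspace(0, 1, n_knots + 2)[1:-1])
    else:
        knots = np.array([])
    return LSQUnivariateSpline(x, y, knots, k=3)


def gc_correction(
    counts: ExpressionMatrix,
    gene_gc: np.ndarray,
    n_bins: int = 25,
    spline_df: int = 5,
) -> tuple[ExpressionMatrix, GCBinProfile]:
    """Profile and remove per-sample GC-content bias from a counts matrix.

    The corrected counts preserve each sample's total (renormalized after
    dividing by the predicted enrichment).  With a single bin the predicted
    enrichment is constant, so the correction is a global scalar.
    """
    gene_gc = np.asarray(gene_gc, float)
    if np.any((gene_gc <= 0) | (gene_gc >= 1)):
        raise ValueError("GC fractions must lie strictly in (0, 1)")
    y = counts.values.astype(float)
    edges = _equal_count_bins(gene_gc, n_bins)
    bin_idx = np.clip(np.digitize(gene_gc, edges) - 1, 0, len(edges) - 2)
    n_eff_bins = len(edges) - 1

    totals = y.sum(axis=0)  # per sample
    pooled = y.sum(axis=1)  # per gene
    pooled_total = pooled.sum()

    bin_gc_means = np.array([gene_gc[bin_idx == l].mean() for l in range(n_eff_bins)])
    enrich = np.zeros((y.shape[1], n_eff_bins))
    for l in range(n_eff_bins):
        sel = bin_idx == l
        share_pooled = pooled[sel].sum() / pooled_total
        for i in range(y.shape[1]):
            share_i = y[sel, i].sum() / totals[i]
            enrich[i, l] = share_i / share_pooled if share_pooled > 0 else 1.0

    splines = []
    corrected = np.empty_like(y)
    for i in range(y.shape[1]):
        log2f = np.log2(np.clip(enrich[i], 1e-6, None))
        if n_eff_bins >= 5:
            spl = _fit_df_spline(bin_gc_means, log2f, spline_df)
        else:
            # too few bins for a spline: piecewise-constant fallback
            const = log2f.copy()

            def spl(gc, _c=const, _m=bin_gc_means):
                idx = np.clip(np.searchsorted(_m, np.atleast_1d(gc)), 0, len(_c) - 1)
                return _c[idx]

        splines.append(spl)
        pred = np.exp2(np.asarray(spl(np.clip(gene_gc, bin_gc_means[0], bin_gc_means[-1]))))
        col = y[:, i] / pred
        corrected[:, i] = col * (totals[i] / col.sum())

    profile = GCBinProfile(
        bin_edges=edges,
        bin_gc_means=bin_gc_means,
        enrichment=enrich,
        splines=splines,
    )
    out = ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=corrected,
        value_kind="fpkm" if counts.value_kind == "fpkm" else "fpkm",
        gene_lengths=counts.gene_lengths,
        library_sizes=counts.library_sizes,
    )
    # corrected values are no longer integral counts; carry them as a
    # continuous matrix under the "fpkm" kind's non-negativity contract
    return out, profile


# ---------------------------------------------------------------------------
# Expression-mode mixture (active vs repressed genes)
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    means: np.ndarray  # (low, high)
    sds: np.ndarray
    weights: np.ndarray
    posterior_repressed: np.ndarray
    loglik: float
    n_iterations: int


def expression_mode_mixture(
    values: np.ndarray,
    max_iter: int = 50_000,
    tol: float = 1e-8,
    seed: int = 0,
) -> MixtureFit:
    """Two-component Gaussian mixture on per-sample log10(FPKM+1) values.

    Returns the posterior probability that each gene belongs to the
    lower-mean ("repressed") component.  The EM log-likelihood is asserted
    non-decreasing at every iteration.
    """
    x = np.asarray(values, float)
    if x.ndim != 1:
        raise ValueError("expected a per-sample 1-D vector")
    if np.ptp(x) == 0:
        raise ValueError("no mixture: all values identical")
    q = np.quantile(x, [0.25, 0.75])
    mu = q.astype(float).copy()
    if mu[0] == mu[1]:
        mu[1] = mu[0] + 1e-3
    sd = np.full(2, max(x.std() / 2, 1e-6))
    w = np.array([0.5, 0.5])
    prev_ll = -np.inf
    min_sd = 1e-6 * max(x.std(), 1.0)
    for it in range(1, max_iter + 1):
        logp = np.stack(
            [np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)]
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        if ll + 1e-9 < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        resp = np.exp(logp - lse)
        nk = resp.sum(axis=1)
        w = nk / len(x)
        mu = (resp @ x) / nk
        sd = np.sqrt(np.maximum((resp @ (x**2)) / nk - mu**2, min_sd**2))
        if ll - prev_ll < tol and it > 1:
            prev_ll = ll
            break
        prev_ll = ll
    else:
        raise RuntimeError(f"mixture EM did not converge in {max_iter} iterations")
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    logp = np.stack(
        [np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)]
    )
    m = logp.max(axis=0)
    lse = m + np.log(np.exp(logp - m).sum(axis=0))
    post_low = np.exp(logp[0] - lse)
    return MixtureFit(
        means=mu, sds=sd, weights=w,
        posterior_repressed=post_low, loglik=prev_ll, n_iterations=it,
    )


# ---------------------------------------------------------------------------
# Correlation heatmap ordering
# ---------------------------------------------------------------------------


def correlation_heatmap_order(
    log2fpkm: ExpressionMatrix,
) -> tuple[pd.DataFrame, list[str]]:
    """Sample-sample Pearson correlation and complete-linkage leaf order.

    The dendrogram is built on distance 1 - r; samples are pre-sorted
    lexicographically so ties resolve deterministically.
    """
    order0 = np.argsort(np.asarray(log2fpkm.sample_ids))
    ids = [log2fpkm.sample_ids[i] for i in order0]
    vals = log2fpkm.values[:, order0].astype(float)
    corr = np.corrcoef(vals.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    link = hierarchy.linkage(condensed, method="complete")
    leaves = hierarchy.leaves_list(link)
    leaf_order = [ids[i] for i in leaves]
    corr_df = pd.DataFrame(corr, index=ids, columns=ids)
    return corr_df, leaf_order


# ---------------------------------------------------------------------------
# Per-gene precision
# ---------------------------------------------------------------------------


@dataclass
class GenePrecision:
    tau: np.ndarray  # per-gene precision, capped
    n_capped: int
    cap: float


def gene_precision(
    log2fpkm: np.ndarray,
    replicate_groups: np.ndarray,
) -> GenePrecision:
    """tau_j = 1 / pooled within-group variance of gene j.

    Genes whose within-group variance is zero would get infinite weight;
    their tau is capped at the 99th percentile of the finite values.
    """
    y = np.asarray(log2fpkm, float)
    groups = np.asarray(replicate_groups)
    pooled_ss = np.zeros(y.shape[0])
    pooled_df = 0
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() < 2:
            continue
        sub = y[:, sel]
        pooled_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        pooled_df += sel.sum() - 1
    if pooled_df == 0:
        raise ValueError("no replicate group with >= 2 samples")
    var = pooled_ss / pooled_df
    with np.errstate(divide="ignore"):
        tau = 1.0 / var
    finite = np.isfinite(tau)
    if not finite.any():
        raise ValueError("all genes have zero within-group variance")
    cap = float(np.percentile(tau[finite], 99))
    n_capped = int(np.sum(~finite | (tau > cap)))
    tau = np.minimum(np.where(finite, tau, cap), cap)
    return GenePrecision(tau=tau, n_capped=n_capped, cap=cap)


def filter_top_expressed(matrix: ExpressionMatrix, percentile: float) -> ExpressionMatrix:
    """Drop the top ``percentile`` % of genes by mean expression."""
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    if percentile == 0:
        return matrix
    means = matrix.values.mean(axis=1)
    cutoff = np.percentile(means, 100 - percentile)
    keep = means < cutoff
    return matrix.subset_genes(keep)
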