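"""Three-way classification of reprogramming outcomes from RNA-seq counts.

For one somatic tissue the samples form a triple: the adult progenitor
cells (A), the iPSC lines derived from them (I), and ESC lines (E).  Gene
counts are modeled negative-binomially with per-sample size factors and a
fixed per-gene dispersion, and every gene is scored under five mean
constraints:

    H0 (invariant expression, IE):  q_A = q_I = q_E
    CR (correctly reprogrammed):    q_I = q_E  (adult differs)
    TM (transcriptional memory):    q_A = q_I  (ESC differs)
    AR (aberrant reprogramming):    q_A = q_E  (iPSC differs)
    CX (complex):                   all free

Each alternative is compared with H0 by a likelihood-ratio chi-square test
(df = number of extra mean parameters).  Because CX nests the other
alternatives its raw likelihood always wins, so the classification rule
uses the minimum p-value — the degrees-of-freedom penalty is what makes
the rule non-degenerate.  CX genes are sub-classified as partial memory
(PTM) when the fitted iPSC mean lies strictly between the adult and ESC
means, otherwise partial aberrant (PAR).

FDR control is by permutation of class labels; category proportions over
the whole transcriptome are estimated by an empirical-Bayes mixture EM on
BIC-approximated marginal likelihoods.  The same framework applies to the
ratio of a gene's top two isoforms through a beta-binomial likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "HYPOTHESES",
    "size_factors",
    "DispersionFit",
    "estimate_dispersions",
    "nb_loglik",
    "fit_nb_mean",
    "classify_genes",
    "PermutationFDR",
    "fdr_from_min_p",
    "permutation_fdr",
    "significant_genes",
    "MixtureProportions",
    "hierarchical_proportions",
    "isoform_ratio_test",
    "quantifier_agreement_filter",
]

HYPOTHESES = ("H0", "CR", "TM", "AR", "CX")
_N_MEAN_PARAMS = {"H0": 1, "CR": 2, "TM": 2, "AR": 2, "CX": 3}
_DF = {"CR": 1, "TM": 1, "AR": 1, "CX": 2}
CLASSES = ("adult", "iPSC", "ESC")


def size_factors(counts: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors."""
    y = np.asarray(counts, float)
    positive = (y > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with nonzero counts in every sample")
    logs = np.log(y[positive])
    ref = logs.mean(axis=1)
    return np.exp(np.median(logs - ref[:, None], axis=0))


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------


@dataclass
class DispersionFit:
    alpha: np.ndarray          # per-gene dispersion used downstream
    alpha_mom: np.ndarray      # raw method-of-moments values (may be negative)
    trend: tuple[float, float]  # (a0, a1) in alpha(mu) = a0/mu + a1
    mean_norm: np.ndarray      # per-gene mean of normalized counts
    kept: np.ndarray           # mask of genes not excluded (all-zero dropped)


def estimate_dispersions(
    counts: np.ndarray,
    class_labels: np.ndarray,
    sf: np.ndarray | None = None,
    shrinkage: float = 0.7,
    min_alpha: float = 1e-8,
) -> DispersionFit:
    """Per-gene NB dispersion with shrinkage toward a mean-dispersion trend.

    Method-of-moments within each class (so class mean differences do not
    inflate the estimate), pooled across classes, then a DESeq-like trend
    alpha(mu) = a0/mu + a1 is fitted by least squares and each gene is
    shrunk toward it on the linear scale.  Genes with no usable moment
    estimate take the trend value; all-zero genes are excluded.
    """
    y = np.asarray(counts, float)
    labels = np.asarray(class_labels)
    if sf is None:
        sf = size_factors(y)
    x = y / sf[None, :]
    kept = y.sum(axis=1) > 0
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info("excluding %d all-zero genes from dispersion estimation", n_dropped)

    g = y.shape[0]
    num = np.zeros(g)
    den = np.zeros(g)
    for c in np.unique(labels):
        sel = labels == c
        if sel.sum() < 2:
            continue
        m = x[:, sel].mean(axis=1)
        v = x[:, sel].var(axis=1, ddof=1)
        inv_s = float(np.mean(1.0 / sf[sel]))
        with np.errstate(divide="ignore", invalid="ignore"):
            a_c = (v - m * inv_s) / m**2
        ok = m > 0
        w = sel.sum() - 1
        num[ok] += w * a_c[ok]
        den[ok] += w
    with np.errstate(invalid="ignore"):
        alpha_mom = np.where(den > 0, num / np.maximum(den, 1), np.nan)

    mean_norm = x.mean(axis=1)
    usable = kept & np.isfinite(alpha_mom) & (mean_norm > 0)
    if usable.sum() >= 10:
        a_design = np.column_stack([1.0 / mean_norm[usable], np.ones(usable.sum())])
        coef, *_ = np.linalg.lstsq(a_design, alpha_mom[usable], rcond=None)
        a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    else:
        # too few genes for a trend: per-gene values stand on their own
        a0, a1 = 0.0, float(np.nanmean(np.clip(alpha_mom, min_alpha, None)))
        if not np.isfinite(a1):
            a1 = min_alpha
    with np.errstate(divide="ignore"):
        trend_vals = np.where(mean_norm > 0, a0 / np.maximum(mean_norm, 1e-12) + a1, a1)
    alpha = np.where(
        np.isfinite(alpha_mom),
        shrinkage * trend_vals + (1.0 - shrinkage) * alpha_mom,
        trend_vals,
    )
    alpha = np.clip(alpha, min_alpha, None)
    return DispersionFit(
        alpha=alpha, alpha_mom=alpha_mom, trend=(a0, a1), mean_norm=mean_norm, kept=kept
    )


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized over genes)
# ---------------------------------------------------------------------------


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood; ``alpha`` broadcasts over rows."""
    r = 1.0 / np.asarray(alpha, float)
    if r.ndim == 1:
        r = r[:, None]
    mu = np.asarray(mu, float)
    t1 = special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
    t2 = special.xlogy(r, r) - special.xlogy(r, r + mu)
    t3 = special.xlogy(y, mu) - special.xlogy(y, r + mu)
    return (t1 + t2 + t3).sum(axis=1)


def fit_nb_mean(
    y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 60, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ML estimate of the common mean q (mu_i = s_i q) per gene row.

    Fisher-scoring on log q; returns (q_hat, loglik, info) where ``info``
    is the Fisher information of log q at the optimum (the asymptotic
    precision of the log-mean estimate).  All-zero rows get q = 0 with the
    exact limiting likelihood and zero information.
    """
    y = np.asarray(y, float)
    total = y.sum(axis=1)
    r = 1.0 / np.asarray(alpha, float)
    q = np.maximum(total, 0.5) / sf.sum()
    active = total > 0
    logq = np.log(q)
    for _ in range(n_iter):
        mu = np.exp(logq)[:, None] * sf[None, :]
        grad = (y - mu * (y + r[:, None]) / (r[:, None] + mu)).sum(axis=1)
        info = (mu * r[:, None] / (r[:, None] + mu)).sum(axis=1)
        step = np.where(active, grad / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -4.0, 4.0)
        logq = logq + step
        if np.max(np.abs(step)) < tol:
            break
    q_hat = np.where(active, np.exp(logq), 0.0)
    mu = q_hat[:, None] * sf[None, :]
    ll = nb_loglik(y, mu, alpha)
    fisher = np.where(active, (mu * r[:, None] / (r[:, None] + mu)).sum(axis=1), 0.0)
    return q_hat, ll, fisher


def _class_masks(labels: np.ndarray) -> dict[str, np.ndarray]:
    labels = np.asarray(labels)
    masks = {c: labels == c for c in CLASSES}
    for c, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"need >= 2 samples in class {c!r} (got {int(m.sum())})")
    return masks


def _subset_fits(
    y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, masks: dict[str, np.ndarray]
) -> dict[tuple[str, ...], tuple[np.ndarray, np.ndarray]]:
    out = {}
    for subset in [
        ("adult",), ("iPSC",), ("ESC",),
        ("adult", "iPSC"), ("iPSC", "ESC"), ("adult", "ESC"),
        ("adult", "iPSC", "ESC"),
    ]:
        m = np.zeros(len(sf), dtype=bool)
        for c in subset:
            m |= masks[c]
        out[subset] = fit_nb_mean(y[:, m], sf[m], alpha)
    return out


def _hypothesis_logliks(fits) -> dict[str, np.ndarray]:
    return {
        "H0": fits[("adult", "iPSC", "ESC")][1],
        "CR": fits[("adult",)][1] + fits[("iPSC", "ESC")][1],
        "TM": fits[("adult", "iPSC")][1] + fits[("ESC",)][1],
        "AR": fits[("iPSC",)][1] + fits[("adult", "ESC")][1],
        "CX": fits[("adult",)][1] + fits[("iPSC",)][1] + fits[("ESC",)][1],
    }


def min_p_values(
    y: np.ndarray, labels: np.ndarray, sf: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Minimum LR p-value over the four alternatives, per gene (fast path)."""
    masks = _class_masks(labels)
    fits = _subset_fits(np.asarray(y, float), sf, alpha, masks)
    lls = _hypothesis_logliks(fits)
    min_p = np.ones(y.shape[0])
    for h in ("CR", "TM", "AR", "CX"):
        lr = np.maximum(2.0 * (lls[h] - lls["H0"]), 0.0)
        min_p = np.minimum(min_p, stats.chi2.sf(lr, _DF[h]))
    return min_p


def classify_genes(
    counts: np.ndarray,
    class_labels: np.ndarray,
    sf: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    p_threshold: float = 1e-3,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Score and classify every gene under the five hypotheses.

    ``p_threshold`` is the operating point (normally the permutation-FDR
    threshold t*): genes with min_p >= threshold are invariant (IE).
    """
    y = np.asarray(counts, float)
    labels = np.asarray(class_labels)
    if sf is None:
        sf = size_factors(y)
    if alpha is None:
        alpha = estimate_dispersions(y, labels, sf).alpha
    masks = _class_masks(labels)
    fits = _subset_fits(y, sf, alpha, masks)
    lls = _hypothesis_logliks(fits)

    q_a = fits[("adult",)][0]
    q_i = fits[("iPSC",)][0]
    q_e = fits[("ESC",)][0]

    g = y.shape[0]
    p_vals = {}
    logp_vals = {}
    lrs = {}
    for h in ("CR", "TM", "AR", "CX"):
        lr = np.maximum(2.0 * (lls[h] - lls["H0"]), 0.0)
        lrs[h] = lr
        # log-scale survival function: strong signals underflow sf() to an
        # exact 0 and would tie; logsf keeps the alternatives ordered
        logp_vals[h] = stats.chi2.logsf(lr, _DF[h])
        p_vals[h] = stats.chi2.sf(lr, _DF[h])

    alt_names = np.array(["CR", "TM", "AR", "CX"])
    logp_mat = np.column_stack([logp_vals[h] for h in alt_names])
    lr_mat = np.column_stack([lrs[h] for h in alt_names])
    # argmin p on the log scale, exact ties broken toward the larger LR
    best_idx = np.empty(g, dtype=int)
    min_logp = logp_mat.min(axis=1)
    for j in range(g):
        cand = np.flatnonzero(logp_mat[j] == min_logp[j])
        best_idx[j] = cand[np.argmax(lr_mat[j, cand])]
    best_alt = alt_names[best_idx]
    min_p = np.exp(min_logp)

    category = np.where(min_p >= p_threshold, "IE", best_alt)
    is_cx = category == "CX"
    between = ((q_i > np.minimum(q_a, q_e)) & (q_i < np.maximum(q_a, q_e)))
    category = np.where(is_cx & between, "PTM", category)
    category = np.where(is_cx & ~between, "PAR", category)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(q_i) - np.log2(q_e)

    # per-alternative contrasts on the log-mean scale with asymptotic
    # variances from the Fisher information, for Bayes-factor weighting
    def _log_q(subset):
        q, _, info = fits[subset]
        floor = 0.5 / sf.sum()
        return np.log(np.maximum(q, floor)), np.where(info > 0, 1.0 / info, 1e6)

    lq_a, va = _log_q(("adult",))
    lq_i, vi = _log_q(("iPSC",))
    lq_e, ve = _log_q(("ESC",))
    lq_ie, vie = _log_q(("iPSC", "ESC"))
    lq_ai, vai = _log_q(("adult", "iPSC"))
    lq_ae, vae = _log_q(("adult", "ESC"))

    df = pd.DataFrame(
        {
            "gene_id": gene_ids if gene_ids is not None else [f"g{j}" for j in range(g)],
            "q_adult": q_a,
            "q_ipsc": q_i,
            "q_esc": q_e,
            "loglik_H0": lls["H0"],
            "loglik_CR": lls["CR"],
            "loglik_TM": lls["TM"],
            "loglik_AR": lls["AR"],
            "loglik_CX": lls["CX"],
            "p_CR": p_vals["CR"],
            "p_TM": p_vals["TM"],
            "p_AR": p_vals["AR"],
            "p_CX": p_vals["CX"],
            "min_p": min_p,
            "best_alt": best_alt,
            "category": category,
            "log2fc_ipsc_vs_esc": log2fc,
            "alpha": np.asarray(alpha, float),
            "beta_CR": lq_a - lq_ie,
            "var_CR": va + vie,
            "beta_TM": lq_ai - lq_e,
            "var_TM": vai + ve,
            "beta_AR": lq_i - lq_ae,
            "var_AR": vi + vae,
            "beta_CX_a": lq_a - lq_e,
            "beta_CX_i": lq_i - lq_e,
            "var_CX_aa": va + ve,
            "var_CX_ii": vi + ve,
            "var_CX_ai": ve,
        }
    )
    return df


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------


@dataclass
class PermutationFDR:
    thresholds: np.ndarray     # sorted candidate thresholds (observed min_p)
    fdr_raw: np.ndarray        # clipped ratio estimate at each threshold
    fdr: np.ndarray            # monotonized curve (used for q-values / t*)
    t_star: float | None       # largest t with monotone FDR(t) <= target
    q_values: np.ndarray       # per-gene monotonized FDR at its min_p
    target: float
    n_perm: int

    def fdr_at(self, t: float, monotone: bool = False) -> float:
        """Estimated FDR at threshold t (1.0 where nothing is rejected).

        The default is the direct ratio estimate at t; the monotonized
        curve (``monotone=True``) is a running minimum over larger
        thresholds, appropriate for q-value reporting but biased low as a
        point estimate of the FDR at one threshold.
        """
        idx = np.searchsorted(self.thresholds, t, side="right") - 1
        if idx < 0:
            return 1.0
        curve = self.fdr if monotone else self.fdr_raw
        return float(curve[min(idx, len(curve) - 1)])


def fdr_from_min_p(
    observed_min_p: np.ndarray,
    perm_min_p: np.ndarray,
    target: float = 0.05,
    n_perm: int | None = None,
) -> PermutationFDR:
    """Permutation FDR curve from observed and permuted minimum p-values.

    FDR(t) = (mean permuted rejections at t) / (observed rejections at t),
    clipped to [0, 1]; the monotonized (non-decreasing in t) version of
    the curve yields per-gene q-values and the operating threshold t*.
    Where the observed rejection count is zero the estimate is reported
    as 1.
    """
    obs = np.sort(np.asarray(observed_min_p, float))
    perm = np.sort(np.asarray(perm_min_p, float).ravel())
    if n_perm is None:
        n_perm = perm_min_p.shape[0] if np.ndim(perm_min_p) == 2 else 1
    thresholds = np.unique(obs)
    n_obs = np.searchsorted(obs, thresholds, side="right")
    n_perm_le = np.searchsorted(perm, thresholds, side="right") / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(n_obs > 0, n_perm_le / np.maximum(n_obs, 1), 1.0)
    raw = np.clip(raw, 0.0, 1.0)
    mono = np.minimum.accumulate(raw[::-1])[::-1]
    ok = mono <= target
    t_star = float(thresholds[ok][-1]) if ok.any() else None
    idx = np.searchsorted(thresholds, np.asarray(observed_min_p, float), side="left")
    q_values = mono[np.clip(idx, 0, len(mono) - 1)]
    return PermutationFDR(
        thresholds=thresholds, fdr_raw=raw, fdr=mono, t_star=t_star,
        q_values=q_values, target=target, n_perm=n_perm,
    )


def permutation_fdr(
    counts: np.ndarray,
    class_labels: np.ndarray,
    sf: np.ndarray | None = None,
    alpha: np.ndarray | None = None,
    n_perm: int = 100,
    seed: int = 0,
    target: float = 0.05,
    reestimate_dispersion: bool = True,
) -> PermutationFDR:
    """Estimate the FDR curve by permuting class labels across samples.

    Size factors stay attached to their samples; only the class labels
    move.  Dispersions are re-estimated under each permuted labeling by
    default: the observed statistics use dispersions estimated within the
    observed grouping, and reusing those same estimates for the permuted
    groupings makes the permuted minimum p-values stochastically larger
    than the observed ones even on null data (the estimate is mildly
    anti-conservative otherwise).
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable FDR estimate")
    y = np.asarray(counts, float)
    labels = np.asarray(class_labels)
    if sf is None:
        sf = size_factors(y)
    if alpha is None:
        alpha = estimate_dispersions(y, labels, sf).alpha
    observed = min_p_values(y, labels, sf, alpha)
    rng = np.random.default_rng(seed)
    perm_min_p = np.empty((n_perm, y.shape[0]))
    for b in range(n_perm):
        perm_labels = rng.permutation(labels)
        a = (
            estimate_dispersions(y, perm_labels, sf).alpha
            if reestimate_dispersion
            else alpha
        )
        perm_min_p[b] = min_p_values(y, perm_labels, sf, a)
    return fdr_from_min_p(observed, perm_min_p, target=target, n_perm=n_perm)


def significant_genes(
    classifications: pd.DataFrame,
    q_values: np.ndarray | None = None,
    q_threshold: float = 0.05,
    min_fold: float = 1.5,
) -> dict:
    """Tabulate significant memory/aberrant genes by category and direction.

    A gene is reported iff its q-value passes the threshold and the fitted
    iPSC/ESC means differ by at least ``min_fold`` (inclusive bound).
    Direction: activation iff q_ipsc > q_esc.  Correctly-reprogrammed and
    invariant genes are not part of the table.
    """
    df = classifications.copy()
    if q_values is not None:
        df = df.assign(q_value=np.asarray(q_values, float))
    if "q_value" not in df:
        raise ValueError("q_values required (pass or precompute on the frame)")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["q_ipsc"] / df["q_esc"]
        fold = np.where(ratio >= 1, ratio, 1.0 / ratio)
    fold = np.where(
        (df["q_ipsc"] == 0) & (df["q_esc"] == 0), 1.0, np.where(np.isfinite(fold), fold, np.inf)
    )
    sig = (
        (df["q_value"] <= q_threshold)
        & (fold >= min_fold)
        & df["category"].isin(["AR", "PAR", "TM", "PTM"])
    )
    out = df[sig].copy()
    out["direction"] = np.where(out["q_ipsc"] > out["q_esc"], "activation", "silencing")
    table = (
        out.groupby(["category", "direction"]).size().unstack(fill_value=0)
        .reindex(index=["AR", "PAR", "TM", "PTM"], fill_value=0)
        .reindex(columns=["activation", "silencing"], fill_value=0)
    )
    return {"genes": out, "table": table, "n_significant": int(sig.sum())}


# ---------------------------------------------------------------------------
# Hierarchical mixture of hypothesis proportions
# ---------------------------------------------------------------------------


@dataclass
class MixtureProportions:
    pi: dict[str, float]       # over {IE, CR, TM, AR, CX}
    posterior: np.ndarray      # genes x 5 membership probabilities
    converged: bool
    n_iterations: int
    objective_trace: list[float] = field(default_factory=list)


def _log_abf_weights(classifications: pd.DataFrame, prior_sd: float) -> np.ndarray:
    """Per-gene log marginal-likelihood ratios vs H0 (Wakefield ABFs).

    Each alternative's extra mean parameters are summarized by their
    estimated log-mean contrast(s) beta with asymptotic covariance Sigma;
    with a N(0, w^2 I) prior on the contrast the Bayes factor against H0 is
    N(beta; 0, Sigma + w^2 I) / N(beta; 0, Sigma).  Under H0 the expected
    Bayes factor is 1, so null genes cannot inflate the alternative
    proportions the way exponentiated penalized likelihoods do.
    """
    g = len(classifications)
    w2 = prior_sd**2
    out = np.zeros((g, len(HYPOTHESES)))
    for col, h in enumerate(("CR", "TM", "AR")):
        b = classifications[f"beta_{h}"].to_numpy(float)
        v = classifications[f"var_{h}"].to_numpy(float)
        out[:, HYPOTHESES.index(h)] = (
            0.5 * np.log(v / (v + w2)) + 0.5 * b**2 * (1.0 / v - 1.0 / (v + w2))
        )
    ba = classifications["beta_CX_a"].to_numpy(float)
    bi = classifications["beta_CX_i"].to_numpy(float)
    saa = classifications["var_CX_aa"].to_numpy(float)
    sii = classifications["var_CX_ii"].to_numpy(float)
    sai = classifications["var_CX_ai"].to_numpy(float)
    det0 = saa * sii - sai**2
    det1 = (saa + w2) * (sii + w2) - sai**2
    # quadratic forms beta' Sigma^-1 beta for Sigma and Sigma + w^2 I
    q0 = (sii * ba**2 - 2 * sai * ba * bi + saa * bi**2) / det0
    q1 = ((sii + w2) * ba**2 - 2 * sai * ba * bi + (saa + w2) * bi**2) / det1
    out[:, HYPOTHESES.index("CX")] = 0.5 * np.log(det0 / det1) + 0.5 * (q0 - q1)
    return out


def hierarchical_proportions(
    classifications: pd.DataFrame,
    n_samples: int,
    max_iter: int = 5000,
    tol: float = 1e-8,
    method: str = "abf",
    prior_sd: float = 1.0,
) -> MixtureProportions:
    """Estimate transcriptome-wide category proportions without thresholds.

    Per-gene marginal likelihoods Lambda_gk enter a mixture whose weights
    pi maximize sum_g log sum_k pi_k Lambda_gk by EM.  With
    ``method="abf"`` (default) the Lambdas are asymptotic Bayes factors
    with a N(0, prior_sd^2) effect-size prior per contrast — a proper
    marginal likelihood whose null expectation is 1, keeping the estimate
    of the rare categories honest.  ``method="bic"`` uses the cruder
    penalized-likelihood approximation Lambda_gk = exp(ll_gk -
    k_params/2 * log n), which has a heavy null tail and overstates rare
    alternatives by a few percent.  The EM objective is asserted
    non-decreasing.
    """
    if method == "bic":
        ll = classifications[[f"loglik_{h}" for h in HYPOTHESES]].to_numpy(float)
        pen = np.array([_N_MEAN_PARAMS[h] for h in HYPOTHESES]) * 0.5 * np.log(n_samples)
        log_lam = ll - pen[None, :]
    elif method == "abf":
        log_lam = _log_abf_weights(classifications, prior_sd)
    else:
        raise ValueError(f"unknown method {method!r}")
    log_lam = log_lam - log_lam.max(axis=1, keepdims=True)
    lam = np.exp(log_lam)

    k = lam.shape[1]
    pi = np.full(k, 1.0 / k)
    prev = -np.inf
    trace: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        mix = lam * pi[None, :]
        row = mix.sum(axis=1)
        obj = float(np.log(row).sum())
        if obj + 1e-9 < prev:
            raise RuntimeError(f"EM objective decreased at iteration {it}")
        trace.append(obj)
        w = mix / row[:, None]
        pi = w.mean(axis=0)
        if obj - prev < tol and it > 1:
            converged = True
            break
        prev = obj
    if not converged:
        raise RuntimeError(
            f"hierarchical EM did not converge in {max_iter} iterations; "
            f"last objectives {trace[-5:]}"
        )
    names = ["IE", "CR", "TM", "AR", "CX"]
    return MixtureProportions(
        pi={n: float(p) for n, p in zip(names, pi)},
        posterior=w,
        converged=converged,
        n_iterations=it,
        objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# Isoform-ratio analogue (beta-binomial on the top-two-isoform fraction)
# ---------------------------------------------------------------------------


def quantifier_agreement_filter(agreement: pd.DataFrame) -> tuple[set, int]:
    """Genes where two quantifiers agree on the top-two isoform ranking.

    ``agreement`` has columns gene_id, quantifier, iso1, iso2 (ranked ids).
    Returns (agreeing gene set, number excluded).
    """
    ranks = agreement.pivot_table(
        index="gene_id", columns="quantifier", values=["iso1", "iso2"], aggfunc="first"
    )
    quants = agreement["quantifier"].unique()
    if len(quants) != 2:
        raise ValueError("need exactly two quantifiers")
    a, b = quants
    agree = (ranks[("iso1", a)] == ranks[("iso1", b)]) & (
        ranks[("iso2", a)] == ranks[("iso2", b)]
    )
    genes = set(ranks.index[agree.fillna(False)])
    return genes, int((~agree.fillna(False)).sum())


def _bb_loglik(k: np.ndarray, n: np.ndarray, p: float, theta: float) -> float:
    a = np.clip(p, 1e-9, 1 - 1e-9) * theta
    b = (1 - np.clip(p, 1e-9, 1 - 1e-9)) * theta
    return float(stats.betabinom.logpmf(k, n, a, b).sum())


def _fit_bb_group(k: np.ndarray, n: np.ndarray, theta: float) -> tuple[float, float]:
    """ML isoform-1 fraction for one sample group at fixed concentration."""
    p0 = (k.sum() + 0.5) / (n.sum() + 1.0)

    def nll(logit_p):
        p = special.expit(logit_p)
        return -_bb_loglik(k, n, p, theta)

    res = optimize.minimize_scalar(
        nll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    p = float(special.expit(res.x))
    return p, -float(res.fun)


def isoform_ratio_test(
    iso1_counts: np.ndarray,
    top2_totals: np.ndarray,
    class_labels: np.ndarray,
    agreement: pd.DataFrame | None = None,
    gene_ids: list[str] | None = None,
    p_threshold: float = 1e-3,
) -> dict:
    """Five-hypothesis classification of the top-isoform fraction.

    ``iso1_counts`` / ``top2_totals`` are genes x samples count matrices of
    the most abundant isoform and the top-two total.  Only genes where two
    quantifiers agree on the isoform ranking are tested (others are
    excluded and counted).  The likelihood is beta-binomial with a per-gene
    concentration estimated once under the unconstrained fit and held fixed
    across hypotheses, mirroring the fixed-dispersion rule of the count
    model.
    """
    k_mat = np.asarray(iso1_counts, float)
    n_mat = np.asarray(top2_totals, float)
    labels = np.asarray(class_labels)
    g = k_mat.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(g)]

    tested = np.ones(g, dtype=bool)
    n_excluded = 0
    if agreement is not None:
        agree_genes, n_excluded = quantifier_agreement_filter(agreement)
        tested = np.array([gid in agree_genes for gid in gene_ids])

    masks = {c: labels == c for c in CLASSES}
    patterns = {
        "H0": [("adult", "iPSC", "ESC")],
        "CR": [("adult",), ("iPSC", "ESC")],
        "TM": [("adult", "iPSC"), ("ESC",)],
        "AR": [("iPSC",), ("adult", "ESC")],
        "CX": [("adult",), ("iPSC",), ("ESC",)],
    }

    records = []
    for j in np.flatnonzero(tested):
        kj, nj = k_mat[j], n_mat[j]
        use = nj > 0
        if use.sum() < 4:
            continue

        # concentration from the unconstrained (CX) fit
        def cx_nll(log_theta):
            theta = float(np.exp(log_theta))
            tot = 0.0
            for subset in patterns["CX"]:
                m = np.zeros(len(labels), dtype=bool)
                for c in subset:
                    m |= masks[c]
                m &= use
                _, ll = _fit_bb_group(kj[m], nj[m], theta)
                tot += ll
            return -tot

        res = optimize.minimize_scalar(
            cx_nll, bounds=(np.log(0.5), np.log(1e4)), method="bounded",
            options={"xatol": 1e-6},
        )
        theta = float(np.exp(res.x))

        lls = {}
        p_fit: dict[str, dict] = {}
        for h, subsets in patterns.items():
            tot = 0.0
            p_fit[h] = {}
            for subset in subsets:
                m = np.zeros(len(labels), dtype=bool)
                for c in subset:
                    m |= masks[c]
                m &= use
                p, ll = _fit_bb_group(kj[m], nj[m], theta)
                tot += ll
                for c in subset:
                    p_fit[h][c] = p
            lls[h] = tot

        p_vals = {}
        lr_vals = {}
        for h in ("CR", "TM", "AR", "CX"):
            lr = max(2.0 * (lls[h] - lls["H0"]), 0.0)
            lr_vals[h] = lr
            p_vals[h] = float(stats.chi2.sf(lr, _DF[h]))
        min_p = min(p_vals.values())
        best = max(
            (h for h in p_vals if p_vals[h] == min_p), key=lambda h: lr_vals[h]
        )
        if min_p >= p_threshold:
            cat = "IE"
        else:
            cat = best
            if cat == "CX":
                pa, pi_, pe = (p_fit["CX"][c] for c in CLASSES)
                cat = "PTM" if min(pa, pe) < pi_ < max(pa, pe) else "PAR"
        records.append(
            {
                "gene_id": gene_ids[j],
                "p_adult": p_fit["CX"]["adult"],
                "p_ipsc": p_fit["CX"]["iPSC"],
                "p_esc": p_fit["CX"]["ESC"],
                "theta": theta,
                **{f"loglik_{h}": lls[h] for h in HYPOTHESES},
                **{f"p_{h}": p_vals[h] for h in ("CR", "TM", "AR", "CX")},
                "min_p": min_p,
                "category": cat,
            }
        )
    return {
        "results": pd.DataFrame(records),
        "n_excluded_disagreement": n_excluded,
        "n_tested": len(records),
    }
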