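"""Five-random-effect linear mixed model for pooled log2-FPKM expression.

Per gene j the expression vector across samples is modeled as

    y_j = b1 + Z2 b2 + Z3 b3 + Z4 b4 + Z5 b5 + eps

with independent Gaussian random effects: b2 over the five cell-class
levels (fibroblast, keratinocyte, EPC, iPSC, ESC), b3 over the iPSC tissue
of origin (F, K, E), b4 over donor-within-cell-class (separate donor levels
for adult and iPSC samples; ESC lines come from donors outside the study
and carry no donor effect), and b5 over sequencing batch.  Variance is
structured: the three adult levels of b2 share one variance (``adult_tissue``)
and the two pluripotent levels another (``pluripotent``); b4 splits into
``donor_adult`` and ``donor_ipsc``.

Genes are centered (profiling out the intercept b1; the fit works on an
orthonormal contrast basis so the profiling is exact) and rescaled by the
median per-gene SD, so the shared variance parameters are fractions of a
typical gene's variance and the pooled log-likelihood is

    sum_j log Normal(y_j; 0, V(theta)),   V = sum_k theta_k Z_k Z_k' + R

with R the residual covariance: a single sigma^2 (homoscedastic), one
sigma^2 per cell class (heteroscedastic "model 1": adult / iPSC / ESC), or
one per tissue-resolved group (model 2: F/K/E-adult, F/K/E-iPSC, ESC).
Intraclass correlation %VE for component k is delta^2_k/(delta^2_k +
sigma^2_rel) where sigma^2_rel is the residual variance of the samples the
component acts on.

Estimation is direct maximum likelihood: L-BFGS-B on log-variance
parameters with analytic gradients and multiple random restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSet",
    "VarianceParams",
    "VarianceDecomposition",
    "build_design",
    "standardize_genes",
    "pooled_loglik",
    "profiled_loglik",
    "model_covariance",
    "fit_mixed_model",
    "variance_explained",
    "refit_excluding",
    "covariance_layers",
    "COMPONENTS",
    "RESIDUAL_MODELS",
]

COMPONENTS = (
    "adult_tissue",  # delta^2_21: adult-tissue levels of the cell-class factor
    "pluripotent",   # delta^2_22: iPSC/ESC levels of the cell-class factor
    "origin",        # delta^2_32: iPSC tissue of origin
    "donor_adult",   # delta^2_41
    "donor_ipsc",    # delta^2_42
    "batch",         # delta^2_5
)

RESIDUAL_MODELS = ("homo", "het1", "het2")

_HET1_GROUPS = ("adult", "iPSC", "ESC")
_HET2_GROUPS = (
    "F-adult", "K-adult", "E-adult",
    "F-iPSC", "K-iPSC", "E-iPSC",
    "ESC",
)

_TISSUE_TO_CODE = {"fibroblast": "F", "keratinocyte": "K", "EPC": "E"}


@dataclass
class DesignSet:
    """Indicator matrices and grouping labels for one sample layout.

    ``blocks[name]`` is the n x m indicator matrix of the levels sharing the
    variance parameter *name*.  Every nonzero row sums to 1.
    """

    sample_ids: list[str]
    blocks: dict[str, np.ndarray]
    block_levels: dict[str, list[str]]
    residual_groups: dict[str, np.ndarray]  # model -> int codes per sample
    residual_levels: dict[str, list[str]]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def z2(self) -> np.ndarray:
        """The full 5-level cell-class indicator (adult tissues + iPSC + ESC)."""
        return np.hstack([self.blocks["adult_tissue"], self.blocks["pluripotent"]])

    def z4(self) -> np.ndarray:
        """Donor-within-cell-class indicator (adult donor levels then iPSC)."""
        return np.hstack([self.blocks["donor_adult"], self.blocks["donor_ipsc"]])


def _indicator(labels: list[str | None], levels: list[str]) -> np.ndarray:
    z = np.zeros((len(labels), len(levels)))
    index = {lv: k for k, lv in enumerate(levels)}
    for i, lab in enumerate(labels):
        if lab is not None:
            z[i, index[lab]] = 1.0
    return z


def build_design(meta: pd.DataFrame) -> DesignSet:
    """Construct the model's indicator matrices from a sample-metadata table."""
    meta = meta.reset_index(drop=True)
    unknown = set(meta["cell_class"]) - {"adult", "iPSC", "ESC"}
    if unknown:
        raise ValueError(f"unknown cell_class values: {sorted(unknown)}")

    adult = meta["cell_class"] == "adult"
    ipsc = meta["cell_class"] == "iPSC"
    esc = meta["cell_class"] == "ESC"

    adult_tissue_labels = [
        row["adult_tissue"] if row["cell_class"] == "adult" else None
        for _, row in meta.iterrows()
    ]
    pluri_labels = [
        cc if cc in ("iPSC", "ESC") else None for cc in meta["cell_class"]
    ]
    origin_labels = [
        row["tissue_of_origin"] if row["cell_class"] == "iPSC" else None
        for _, row in meta.iterrows()
    ]

    adult_donors = sorted(meta.loc[adult, "donor"].unique())
    ipsc_donors = sorted(meta.loc[ipsc, "donor"].unique())
    donor_adult_labels = [
        row["donor"] if row["cell_class"] == "adult" else None
        for _, row in meta.iterrows()
    ]
    donor_ipsc_labels = [
        row["donor"] if row["cell_class"] == "iPSC" else None
        for _, row in meta.iterrows()
    ]

    batches = sorted(meta["batch"].astype(int).unique())
    batch_labels = [str(b) for b in meta["batch"].astype(int)]

    blocks = {
        "adult_tissue": _indicator(adult_tissue_labels, ["fibroblast", "keratinocyte", "EPC"]),
        "pluripotent": _indicator(pluri_labels, ["iPSC", "ESC"]),
        "origin": _indicator(origin_labels, ["F", "K", "E"]),
        "donor_adult": _indicator(donor_adult_labels, adult_donors),
        "donor_ipsc": _indicator(donor_ipsc_labels, ipsc_donors),
        "batch": _indicator(batch_labels, [str(b) for b in batches]),
    }
    block_levels = {
        "adult_tissue": ["fibroblast", "keratinocyte", "EPC"],
        "pluripotent": ["iPSC", "ESC"],
        "origin": ["F", "K", "E"],
        "donor_adult": adult_donors,
        "donor_ipsc": ipsc_donors,
        "batch": [str(b) for b in batches],
    }

    het1_codes = np.zeros(len(meta), dtype=int)
    het1_codes[np.asarray(ipsc)] = 1
    het1_codes[np.asarray(esc)] = 2

    het2_labels = []
    for _, row in meta.iterrows():
        if row["cell_class"] == "adult":
            het2_labels.append(f"{_TISSUE_TO_CODE[row['adult_tissue']]}-adult")
        elif row["cell_class"] == "iPSC":
            het2_labels.append(f"{row['tissue_of_origin']}-iPSC")
        else:
            het2_labels.append("ESC")
    het2_codes = np.array([_HET2_GROUPS.index(lab) for lab in het2_labels])

    residual_groups = {
        "homo": np.zeros(len(meta), dtype=int),
        "het1": het1_codes,
        "het2": het2_codes,
    }
    residual_levels = {
        "homo": ["all"],
        "het1": list(_HET1_GROUPS),
        "het2": list(_HET2_GROUPS),
    }
    return DesignSet(
        sample_ids=list(meta["sample_id"]),
        blocks=blocks,
        block_levels=block_levels,
        residual_groups=residual_groups,
        residual_levels=residual_levels,
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


@dataclass
class VarianceParams:
    """Fitted (or true) variance parameters on the standardized log2 scale."""

    delta2: dict[str, float]
    residual: dict[str, float]
    residual_model: str = "homo"
    loglik: float = float("nan")

    def residual_for_sample_codes(self, codes: np.ndarray, levels: list[str]) -> np.ndarray:
        sig = np.array([self.residual[lv] for lv in levels])
        return sig[codes]


def model_covariance(design: DesignSet, params: VarianceParams) -> np.ndarray:
    """V(theta) = sum_k delta2_k Z_k Z_k' + diag(residual by group)."""
    n = design.n_samples
    v = np.zeros((n, n))
    for name, d2 in params.delta2.items():
        z = design.blocks[name]
        v += d2 * (z @ z.T)
    codes = design.residual_groups[params.residual_model]
    levels = design.residual_levels[params.residual_model]
    v[np.diag_indices(n)] += params.residual_for_sample_codes(codes, levels)
    return v


def pooled_loglik(y: np.ndarray, design: DesignSet, params: VarianceParams) -> float:
    """sum_j log Normal(y_j; 0, V(theta)) over gene rows of ``y``."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    v = model_covariance(design, params)
    n = design.n_samples
    g = y.shape[0]
    chol = np.linalg.cholesky(v)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    solved = np.linalg.solve(chol, y.T)  # n x G
    quad = np.sum(solved**2)
    return -0.5 * (g * n * np.log(2.0 * np.pi) + g * logdet + quad)


def standardize_genes(y: np.ndarray, drop_zero_variance: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Center each gene row and rescale by the median per-gene SD.

    Centering profiles out the per-gene intercept; the common (median)
    scale puts the shared variance parameters on an interpretable
    per-gene-variance scale without coupling each gene's scale to its own
    realized effect draws — per-gene unit scaling would shrink genes whose
    random effects happened to come out large and attenuate the variance
    fractions.  Zero-variance genes carry no information about variance
    fractions and are dropped (logged).

    Returns the standardized matrix and the boolean mask of retained genes.
    """
    y = np.asarray(y, dtype=float)
    centered = y - y.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, ddof=1)
    keep = sd > 0
    if drop_zero_variance and not keep.all():
        logger.info("dropping %d zero-variance genes before fitting", (~keep).sum())
    out = centered[keep] / np.median(sd[keep])
    return out, keep


def _contrast_basis(n: int) -> np.ndarray:
    """Orthonormal basis K of the centered subspace: K'K = I, K'1 = 0."""
    a = np.eye(n) - np.ones((n, n)) / n
    evals, evecs = np.linalg.eigh(a)
    return evecs[:, evals > 0.5]


@dataclass
class VarianceDecomposition:
    """A fitted variance decomposition."""

    params: VarianceParams
    design: DesignSet
    ve: dict[str, float]
    n_genes: int
    converged: bool
    n_restarts: int
    trace: list[dict] = field(default_factory=list)

    def covariance(self) -> np.ndarray:
        return model_covariance(self.design, self.params)


def _component_scope(design: DesignSet, component: str) -> np.ndarray:
    """Boolean mask of the samples a variance component acts on."""
    z = design.blocks[component]
    return z.sum(axis=1) > 0


def _residual_for_scope(params: VarianceParams, design: DesignSet, scope: np.ndarray) -> float:
    codes = design.residual_groups[params.residual_model]
    levels = design.residual_levels[params.residual_model]
    per_sample = params.residual_for_sample_codes(codes, levels)
    if not scope.any():
        return float(np.mean(per_sample))
    return float(np.mean(per_sample[scope]))


def variance_explained(fit_params: VarianceParams, design: DesignSet, component: str) -> float:
    """Intraclass correlation delta^2_k / (delta^2_k + sigma^2_rel).

    For heteroscedastic fits sigma^2_rel is the sample-count-weighted mean
    residual variance over the samples the component acts on.
    """
    d2 = fit_params.delta2[component]
    scope = _component_scope(design, component)
    sigma2 = _residual_for_scope(fit_params, design, scope)
    return d2 / (d2 + sigma2)


def _unpack(x: np.ndarray, components: list[str], n_res: int) -> tuple[np.ndarray, np.ndarray]:
    theta = np.exp(x)
    return theta[: len(components)], theta[len(components):len(components) + n_res]


def _neg_loglik_and_grad(
    x: np.ndarray,
    s_mat: np.ndarray,
    g_genes: int,
    masks: list[np.ndarray],
    m_dim: int,
):
    """Profiled (contrast-space) negative pooled log-likelihood and gradient.

    All mask matrices — component covariances and residual-group diagonals
    alike — are pre-projected onto the contrast basis, so V is their
    theta-weighted sum and the gradient has one uniform form:
    d nll / d theta_b = 0.5 * (G tr(Vinv M_b) - tr(Vinv M_b Vinv S)).
    """
    theta = np.exp(x)
    v = np.zeros((m_dim, m_dim))
    for k, m in enumerate(masks):
        v += theta[k] * m
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return 1e12, np.zeros_like(x)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    vinv = np.linalg.inv(v)
    quad = float(np.sum(vinv * s_mat))
    nll = 0.5 * (g_genes * m_dim * np.log(2 * np.pi) + g_genes * logdet + quad)
    a = vinv @ s_mat @ vinv
    grad = np.zeros_like(x)
    for k, m in enumerate(masks):
        grad[k] = 0.5 * (g_genes * np.sum(vinv * m) - np.sum(a * m)) * theta[k]
    return nll, grad


def profiled_loglik(y: np.ndarray, design: DesignSet, params: VarianceParams) -> float:
    """Pooled log-likelihood with the per-gene intercept profiled out.

    Standardizes ``y`` exactly as :func:`fit_mixed_model` does and evaluates
    sum_j log Normal(K'y_j; 0, K'V(theta)K) on the orthonormal contrast
    basis K.  Lets a fit under one residual model be compared, at mapped
    parameters, with a fit under another on identical footing.
    """
    y_std, _ = standardize_genes(np.atleast_2d(np.asarray(y, dtype=float)))
    n = design.n_samples
    k_basis = _contrast_basis(n)
    v = model_covariance(design, params)
    vk = k_basis.T @ v @ k_basis
    yk = y_std @ k_basis
    g, m_dim = yk.shape
    chol = np.linalg.cholesky(vk)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    solved = np.linalg.solve(chol, yk.T)
    return -0.5 * (g * m_dim * np.log(2 * np.pi) + g * logdet + np.sum(solved**2))


def fit_mixed_model(
    y: np.ndarray,
    design: DesignSet,
    residual_model: str = "homo",
    components: list[str] | None = None,
    n_restarts: int = 5,
    tol: float = 1e-8,
    seed: int = 0,
    max_iter: int = 2000,
) -> VarianceDecomposition:
    """Fit the pooled mixed model by direct maximum likelihood.

    Parameters
    ----------
    y
        gene x sample log2-FPKM matrix; genes are standardized internally.
    residual_model
        "homo", "het1" (adult/iPSC/ESC residuals) or "het2" (seven groups).
    components
        Variance components to include (default: all with at least one
        occupied level); used by :func:`refit_excluding`.
    """
    if residual_model not in RESIDUAL_MODELS:
        raise ValueError(f"unknown residual model {residual_model!r}")
    if components is None:
        components = [c for c in COMPONENTS if design.blocks[c].sum() > 0]
    else:
        for c in components:
            if c not in COMPONENTS:
                raise ValueError(f"unknown component {c!r}")

    y_std, keep = standardize_genes(np.atleast_2d(np.asarray(y, dtype=float)))
    g_genes = y_std.shape[0]
    if g_genes == 0:
        raise ValueError("no genes with nonzero variance")
    n = design.n_samples
    k_basis = _contrast_basis(n)
    yk = y_std @ k_basis
    m_dim = n - 1
    s_mat = yk.T @ yk

    codes = design.residual_groups[residual_model]
    levels = design.residual_levels[residual_model]
    occupied = [lv for k, lv in enumerate(levels) if (codes == k).any()]
    masks = []
    for c in components:
        z = design.blocks[c]
        masks.append(k_basis.T @ (z @ z.T) @ k_basis)
    for lv in occupied:
        d = (codes == levels.index(lv)).astype(float)
        masks.append((k_basis.T * d[None, :]) @ k_basis)

    rng = np.random.default_rng(seed)
    best = None
    trace: list[dict] = []
    n_par = len(components) + len(occupied)
    starts = [np.full(n_par, np.log(0.5))]
    starts += [rng.uniform(np.log(1e-3), np.log(2.0), size=n_par) for _ in range(n_restarts - 1)]
    for x0 in starts:
        res = optimize.minimize(
            _neg_loglik_and_grad,
            x0,
            args=(s_mat, g_genes, masks, m_dim),
            jac=True,
            method="L-BFGS-B",
            bounds=[(np.log(1e-10), np.log(1e4))] * n_par,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        trace.append({"x0": x0.copy(), "nll": float(res.fun), "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"mixed-model fit failed to converge; trace: {trace}")
    if not any(t["success"] for t in trace):
        raise RuntimeError(f"mixed-model fit did not converge in any restart; trace: {trace}")

    theta_c, theta_r = _unpack(best.x, components, len(occupied))
    delta2 = {c: 0.0 for c in COMPONENTS if design.blocks[c].sum() > 0}
    for c, th in zip(components, theta_c):
        delta2[c] = float(th)
    residual = {lv: float(th) for lv, th in zip(occupied, theta_r)}
    for lv in levels:
        residual.setdefault(lv, float("nan"))
    params = VarianceParams(
        delta2=delta2,
        residual=residual,
        residual_model=residual_model,
        loglik=-float(best.fun),
    )
    ve = {c: variance_explained(params, design, c) for c in delta2}
    return VarianceDecomposition(
        params=params,
        design=design,
        ve=ve,
        n_genes=g_genes,
        converged=True,
        n_restarts=len(starts),
        trace=trace,
    )


def refit_excluding(
    y: np.ndarray,
    design: DesignSet,
    component_to_drop: str,
    residual_model: str = "homo",
    **fit_kwargs,
) -> dict:
    """Fit with and without one component; report the paired %VE contrast.

    Used to reproduce the confounding diagnostic: when donor is omitted
    from the model, variance genuinely driven by genetic background is
    absorbed by whichever components are partially collinear with donor
    (tissue of origin, iPSC-vs-ESC).
    """
    full = fit_mixed_model(y, design, residual_model=residual_model, **fit_kwargs)
    kept = [c for c in full.params.delta2 if c != component_to_drop]
    reduced = fit_mixed_model(
        y, design, residual_model=residual_model, components=kept, **fit_kwargs
    )
    return {
        "with": full,
        "without": reduced,
        "ve_with": full.ve,
        "ve_without": reduced.ve,
        "dropped": component_to_drop,
    }


def covariance_layers(fit: VarianceDecomposition) -> dict[str, np.ndarray]:
    """Per-component covariance layers Z_k D_k Z_k' plus the residual diagonal.

    The layers sum to the model-implied covariance exactly.
    """
    layers = {}
    for name, d2 in fit.params.delta2.items():
        z = fit.design.blocks[name]
        layers[name] = d2 * (z @ z.T)
    codes = fit.design.residual_groups[fit.params.residual_model]
    levels = fit.design.residual_levels[fit.params.residual_model]
    layers["residual"] = np.diag(
        fit.params.residual_for_sample_codes(codes, levels)
    )
    return layers
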