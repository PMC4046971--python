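"""Synthetic study generators with full ground truth.

Every downstream stage of the pipeline is exercised on data from this
module: a complete expression study with the five-component random-effect
structure, three-way (adult / iPSC / ESC) count triples with planted
reprogramming outcomes, phased allelic counts with imprinting states, and
eSNP genotypes with a specified fraction of donor variance explained.

The default study layout mirrors the panel design the pipeline targets:
4 donors (S2, S5, S7 male; S4 female), three somatic tissues, 18 adult
samples (6 fibroblast, 3 keratinocyte, 9 EPC — three passages each),
25 iPSC lines (9 F-iPSC, 6 K-iPSC, 10 E-iPSC), 4 ESC samples from two
lines (H9, Val9), and two sequencing batches: 47 samples in all.

One global seed fans out to per-component child streams through
``numpy.random.SeedSequence(seed).spawn``, so each sub-simulation is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, validate_sample_metadata
from .variance_components import COMPONENTS, VarianceParams, build_design

__all__ = [
    "default_study_design",
    "confounded_ipsc_design",
    "default_variance_params",
    "SimulationConfig",
    "StudyTruth",
    "simulate_study",
    "simulate_three_way_counts",
    "simulate_allelic_counts",
    "write_phased_vcf",
    "simulate_eqtl",
    "sample_nb",
]

DONORS = ("S2", "S4", "S5", "S7")
DE_CATEGORIES = ("IE", "CR", "TM", "AR", "CX")


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------


def _meta_row(sample_id, donor, cell_class, adult_tissue, origin, batch, label):
    return {
        "sample_id": sample_id,
        "donor": donor,
        "cell_class": cell_class,
        "adult_tissue": adult_tissue,
        "tissue_of_origin": origin,
        "batch": batch,
        "replicate_label": label,
    }


def default_study_design() -> pd.DataFrame:
    """The 47-sample panel layout (18 adult + 25 iPSC + 4 ESC, 2 batches)."""
    rows = []
    # adult samples: three passages per (donor, tissue) culture
    adult_plan = [
        ("fibroblast", ["S2", "S4"]),        # 6
        ("keratinocyte", ["S2"]),            # 3
        ("EPC", ["S2", "S5", "S7"]),         # 9
    ]
    for tissue, donors in adult_plan:
        for donor in donors:
            for p in (1, 2, 3):
                rows.append(
                    _meta_row(
                        f"{tissue[:3]}-{donor}-p{p}", donor, "adult",
                        tissue, "none", 0, f"p{p}",
                    )
                )
    # iPSC lines: 9 F, 6 K, 10 E
    ipsc_plan = [
        ("F", [("S2", 3), ("S4", 3), ("S5", 3)]),
        ("K", [("S2", 3), ("S4", 3)]),
        ("E", [("S2", 3), ("S5", 3), ("S7", 4)]),
    ]
    for origin, donors in ipsc_plan:
        for donor, k in donors:
            for line in range(1, k + 1):
                rows.append(
                    _meta_row(
                        f"{origin}-iPSC-{donor}-{line}", donor, "iPSC",
                        "none", origin, 0, f"line{line}",
                    )
                )
    # ESC: two lines, two growths each; ESC donors are not study donors
    for line in ("H9", "Val9"):
        for rep in (1, 2):
            rows.append(
                _meta_row(f"ESC-{line}-{rep}", line, "ESC", "none", "none", 0, f"g{rep}")
            )
    meta = pd.DataFrame(rows)
    meta["batch"] = [1 + (i % 2) for i in range(len(meta))]
    return validate_sample_metadata(meta)


def confounded_ipsc_design(lines_per_donor: int = 4) -> pd.DataFrame:
    """An iPSC-only layout with donors nested inside tissue of origin.

    Two donors per origin, none shared between origins: any transcriptional
    covariance between lines of the same donor is indistinguishable from an
    origin effect once the donor component is removed from the model.  Used
    to reproduce the confounding contrast (origin VE inflates when donor is
    dropped).
    """
    rows = []
    plan = [("F", ("D1", "D2")), ("K", ("D3", "D4")), ("E", ("D5", "D6"))]
    for origin, donors in plan:
        for donor in donors:
            for line in range(1, lines_per_donor + 1):
                rows.append(
                    _meta_row(
                        f"{origin}-iPSC-{donor}-{line}", donor, "iPSC",
                        "none", origin, 0, f"line{line}",
                    )
                )
    meta = pd.DataFrame(rows)
    meta["batch"] = [1 + (i % 2) for i in range(len(meta))]
    return validate_sample_metadata(meta)


def _ve_to_delta2(ve: float, sigma2: float = 1.0) -> float:
    return ve / (1.0 - ve) * sigma2


def default_variance_params(residual_model: str = "homo") -> VarianceParams:
    """True variance parameters in the regime the pipeline is built to detect.

    Intraclass correlations: adult tissues 0.50, iPSC-vs-ESC 0.01, tissue
    of origin 0.04, donor (adult) 0.42, donor (iPSC) 0.38, batch 0.02, all
    against a unit residual on the log2 scale.
    """
    ve = {
        "adult_tissue": 0.50,
        "pluripotent": 0.01,
        "origin": 0.04,
        "donor_adult": 0.42,
        "donor_ipsc": 0.38,
        "batch": 0.02,
    }
    delta2 = {k: _ve_to_delta2(v) for k, v in ve.items()}
    if residual_model == "homo":
        residual = {"all": 1.0}
    elif residual_model == "het1":
        residual = {"adult": 1.0, "iPSC": 1.0, "ESC": 1.0}
    else:
        residual = {g: 1.0 for g in (
            "F-adult", "K-adult", "E-adult", "F-iPSC", "K-iPSC", "E-iPSC", "ESC",
        )}
    return VarianceParams(delta2=delta2, residual=residual, residual_model=residual_model)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Complete specification of one synthetic study."""

    n_genes: int = 2000
    design: pd.DataFrame = field(default_factory=default_study_design)
    variance_params: VarianceParams = field(default_factory=default_variance_params)
    de_proportions: dict[str, float] = field(
        default_factory=lambda: {"IE": 0.97, "CR": 0.01, "TM": 0.01, "AR": 0.005, "CX": 0.005}
    )
    de_effect_log2fc: float = 2.0  # 4-fold
    nb_dispersion_trend: tuple[float, float] = (2.0, 0.01)  # alpha(mu) = a0/mu + a1
    imprinting_spec: list[tuple] = field(default_factory=list)
    eqtl_spec: list[tuple] = field(default_factory=list)
    seed: int = 0
    baseline_log2fpkm_mean: float = 5.0
    baseline_log2fpkm_sd: float = 1.5
    size_factor_log_sd: float = 0.1
    mean_library_size: float = 2.0e7

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        total = sum(self.de_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"de_proportions must sum to 1 (got {total})")
        if any(v < 0 for v in self.variance_params.delta2.values()):
            raise ValueError("variance parameters must be >= 0")

    def child_rngs(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


def sample_nb(
    rng: np.random.Generator, mean: np.ndarray, trend: tuple[float, float]
) -> np.ndarray:
    """Negative-binomial counts with dispersion alpha(mu) = a0/mu + a1."""
    mean = np.asarray(mean, float)
    a0, a1 = trend
    mu = np.clip(mean, 1e-8, None)
    alpha = a0 / mu + a1
    r = 1.0 / np.clip(alpha, 1e-12, None)
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Full-study simulation
# ---------------------------------------------------------------------------


@dataclass
class StudyTruth:
    """Ground truth recorded during a full-study simulation."""

    variance_params: VarianceParams
    intercepts: np.ndarray  # per gene, log2 FPKM
    effects: dict[str, np.ndarray]  # component -> genes x levels draws
    latent_log2fpkm: np.ndarray  # genes x samples
    size_factors: np.ndarray
    library_sizes: np.ndarray
    gene_lengths: np.ndarray


def simulate_study(config: SimulationConfig) -> dict:
    """Generate a full synthetic study (counts + log2 FPKM + truth tables).

    Per gene: latent log2 mean = intercept + sum_k Z_k b_k + residual, with
    b_k drawn N(0, delta2_k I) per gene and group-specific residual
    variance; counts are NB around FPKM x length_kb x (library size in
    millions) x size factor, with a DESeq-like mean-dispersion trend.
    """
    meta = validate_sample_metadata(config.design)
    design = build_design(meta)
    n = design.n_samples
    g = config.n_genes
    rng_fx, rng_res, rng_counts, rng_tech = config.child_rngs(4)

    params = config.variance_params
    intercepts = rng_fx.normal(
        config.baseline_log2fpkm_mean, config.baseline_log2fpkm_sd, size=g
    )
    latent = np.tile(intercepts[:, None], (1, n)).astype(float)
    effects: dict[str, np.ndarray] = {}
    for name, d2 in params.delta2.items():
        z = design.blocks[name]
        b = rng_fx.normal(0.0, np.sqrt(d2), size=(g, z.shape[1]))
        effects[name] = b
        latent += b @ z.T

    codes = design.residual_groups[params.residual_model]
    levels = design.residual_levels[params.residual_model]
    sigma = np.sqrt(params.residual_for_sample_codes(codes, levels))
    latent += rng_res.normal(0.0, 1.0, size=(g, n)) * sigma[None, :]

    size_factors = np.exp(rng_tech.normal(0.0, config.size_factor_log_sd, size=n))
    library_sizes = config.mean_library_size * size_factors
    gene_lengths = np.exp(rng_tech.normal(np.log(1500.0), 0.5, size=g))

    fpkm_true = np.exp2(latent)
    mu = fpkm_true * (gene_lengths[:, None] / 1e3) * (library_sizes[None, :] / 1e6)
    counts_vals = sample_nb(rng_counts, mu, config.nb_dispersion_trend)

    gene_ids = [f"gene{j:05d}" for j in range(g)]
    counts = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=design.sample_ids,
        values=counts_vals,
        value_kind="counts",
        gene_lengths=gene_lengths,
        library_sizes=library_sizes,
    )
    truth = StudyTruth(
        variance_params=params,
        intercepts=intercepts,
        effects=effects,
        latent_log2fpkm=latent,
        size_factors=size_factors,
        library_sizes=library_sizes,
        gene_lengths=gene_lengths,
    )
    return {"counts": counts, "metadata": meta, "design": design, "truth": truth}


# ---------------------------------------------------------------------------
# Three-way (adult / iPSC / ESC) count triples with planted outcomes
# ---------------------------------------------------------------------------


def simulate_three_way_counts(
    n_genes: int,
    n_per_class: tuple[int, int, int] = (6, 9, 4),
    de_proportions: dict[str, float] | None = None,
    effect_log2fc: float = 2.0,
    mean_depth: float = 500.0,
    dispersion_trend: tuple[float, float] = (2.0, 0.01),
    size_factor_log_sd: float = 0.1,
    seed: int = 0,
) -> dict:
    """Counts for one somatic tissue's (adult, iPSC, ESC) comparison.

    Planted categories: CR shifts the adult mean away from a shared
    iPSC = ESC level; TM shifts ESC away from adult = iPSC; AR shifts iPSC
    away from adult = ESC; CX makes all three distinct, with the iPSC mean
    strictly between adult and ESC for half the CX genes (partial memory,
    PTM truth) and outside the interval for the other half (partial
    aberrant, PAR truth).  Shift signs are random per gene.
    """
    if de_proportions is None:
        de_proportions = {"IE": 0.97, "CR": 0.01, "TM": 0.01, "AR": 0.005, "CX": 0.005}
    if abs(sum(de_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("de_proportions must sum to 1")
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng_cat, rng_base, rng_counts, rng_tech = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)
    ]
    n_a, n_i, n_e = n_per_class
    labels = np.array(["adult"] * n_a + ["iPSC"] * n_i + ["ESC"] * n_e)

    # deterministic category counts matching the requested proportions
    cats_order = [c for c in DE_CATEGORIES if de_proportions.get(c, 0) > 0]
    counts_per_cat = {c: int(np.floor(de_proportions[c] * n_genes)) for c in cats_order}
    shortfall = n_genes - sum(counts_per_cat.values())
    for c in cats_order:
        if shortfall == 0:
            break
        counts_per_cat[c] += 1
        shortfall -= 1
    categories = np.concatenate(
        [np.repeat(c, counts_per_cat[c]) for c in cats_order]
    )
    rng_cat.shuffle(categories)

    base = np.exp2(rng_base.normal(np.log2(mean_depth), 1.0, size=n_genes))
    e = effect_log2fc
    shift = np.zeros((n_genes, 3))  # columns: adult, iPSC, ESC (log2)
    signs = rng_cat.choice([-1.0, 1.0], size=n_genes)
    subtype = np.array(["" for _ in range(n_genes)], dtype=object)
    for j, cat in enumerate(categories):
        s = signs[j]
        if cat == "CR":
            shift[j] = (s * e, 0.0, 0.0)
        elif cat == "TM":
            shift[j] = (0.0, 0.0, s * e)
        elif cat == "AR":
            shift[j] = (0.0, s * e, 0.0)
        elif cat == "CX":
            if rng_cat.random() < 0.5:
                shift[j] = (s * e, s * e / 2.0, 0.0)  # iPSC strictly between
                subtype[j] = "PTM"
            else:
                shift[j] = (s * e, -s * e / 2.0, 0.0)  # iPSC outside
                subtype[j] = "PAR"

    class_col = {"adult": 0, "iPSC": 1, "ESC": 2}
    mu_class = base[:, None] * np.exp2(shift)  # genes x 3
    size_factors = np.exp(rng_tech.normal(0.0, size_factor_log_sd, size=len(labels)))
    mu = mu_class[:, [class_col[c] for c in labels]] * size_factors[None, :]
    values = sample_nb(rng_counts, mu, dispersion_trend)

    gene_ids = [f"gene{j:05d}" for j in range(n_genes)]
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "category": categories,
            "subtype": subtype,
            "base_mean": base,
            "shift_adult": shift[:, 0],
            "shift_ipsc": shift[:, 1],
            "shift_esc": shift[:, 2],
        }
    )
    counts = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"{lab}{i}" for i, lab in enumerate(labels)],
        values=values,
        value_kind="counts",
    )
    return {
        "counts": counts,
        "class_labels": labels,
        "size_factors": size_factors,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Allelic counts with imprinting states
# ---------------------------------------------------------------------------


def simulate_allelic_counts(
    imprinting_spec: list[tuple[str, dict[str, float]]],
    depth: float = 100.0,
    n_snps_per_gene: int = 3,
    design: pd.DataFrame | None = None,
    seed: int = 0,
) -> dict:
    """Phased allelic counts per heterozygous SNP with known paternal fraction.

    ``imprinting_spec`` lists ``(gene_id, {cell_class: true paternal
    fraction})``.  Each (sample, SNP) receives a Poisson(depth / n_snps)
    coverage and a Binomial paternal count at the gene/class truth.  The
    accompanying phased-site table (convertible to VCF via
    :func:`write_phased_vcf`) is consistent with the truth: haplotype 1 is
    the paternal haplotype for every donor.
    """
    if design is None:
        design = default_study_design()
    meta = validate_sample_metadata(design)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    vcf_rows = []
    truth_rows = []
    donors = sorted(meta.loc[meta["cell_class"] != "ESC", "donor"].unique())
    for gi, (gene, class_p) in enumerate(imprinting_spec):
        for si in range(n_snps_per_gene):
            pos = 1_000_000 * (gi + 1) + 100 * si + 1
            vcf_rows.append(
                {
                    "chrom": "chr1",
                    "pos": pos,
                    "snp_id": f"{gene}_snp{si}",
                    "ref": "A",
                    "alt": "G",
                    # hap1 (paternal) carries ref for every donor
                    **{d: "0|1" for d in donors},
                }
            )
        for _, srow in meta.iterrows():
            if srow["cell_class"] == "ESC":
                continue
            p = class_p.get(srow["cell_class"])
            if p is None:
                continue
            truth_rows.append(
                {
                    "gene_id": gene,
                    "sample_id": srow["sample_id"],
                    "cell_class": srow["cell_class"],
                    "p_paternal": p,
                }
            )
            for si in range(n_snps_per_gene):
                cov = rng.poisson(depth / n_snps_per_gene)
                pat = rng.binomial(cov, p) if cov > 0 else 0
                rows.append(
                    {
                        "sample_id": srow["sample_id"],
                        "gene_id": gene,
                        "snp_id": f"{gene}_snp{si}",
                        "position": 1_000_000 * (gi + 1) + 100 * si + 1,
                        "hap1_count": pat,
                        "hap2_count": cov - pat,
                        "paternal_hap": "hap1",
                    }
                )
    return {
        "allelic_counts": pd.DataFrame(rows),
        "phased_sites": pd.DataFrame(vcf_rows),
        "truth": pd.DataFrame(truth_rows),
        "donors": donors,
    }


def write_phased_vcf(phased_sites: pd.DataFrame, donors: list[str], path: str) -> None:
    """Write a minimal phased VCF 4.2 for the simulated het sites."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = phased_sites["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(donors) + "\n")
        for _, row in phased_sites.sort_values(["chrom", "pos"]).iterrows():
            gts = "\t".join(str(row[d]) for d in donors)
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# eQTL simulation
# ---------------------------------------------------------------------------


def simulate_eqtl(
    n_genes: int,
    variance_fraction: float = 0.17,
    design: pd.DataFrame | None = None,
    noise_sd: float = 1.0,
    within_donor_sd: float = 0.2,
    maf: float = 0.3,
    seed: int = 0,
) -> dict:
    """eSNP genotypes and iPSC expression with a planted additive effect.

    The dosage effect beta is chosen per gene so that, across donors,
    var(beta G) / var(beta G + noise) equals ``variance_fraction`` exactly
    on the realized dosages.  Expression is emitted per iPSC sample with a
    small within-donor deviation so donor averaging is exercised.
    """
    if not 0.0 <= variance_fraction <= 1.0:
        raise ValueError("variance_fraction must be in [0, 1]")
    if design is None:
        design = default_study_design()
    meta = validate_sample_metadata(design)
    ipsc = meta[meta["cell_class"] == "iPSC"].reset_index(drop=True)
    donors = sorted(ipsc["donor"].unique())
    n_d = len(donors)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    gene_ids = [f"eqtl_gene{j:04d}" for j in range(n_genes)]
    dosages = np.zeros((n_genes, n_d), dtype=int)
    for j in range(n_genes):
        while True:
            g = rng.binomial(2, maf, size=n_d)
            if len(np.unique(g)) >= 2:
                dosages[j] = g
                break

    g_centered = dosages - dosages.mean(axis=1, keepdims=True)
    sd_g = g_centered.std(axis=1, ddof=0)
    f = variance_fraction
    if f >= 1.0:
        beta = 1.0 / sd_g
        eff_noise_sd = 0.0
    elif f == 0.0:
        beta = np.zeros(n_genes)
        eff_noise_sd = noise_sd
    else:
        beta = np.sqrt(f / (1.0 - f)) * noise_sd / sd_g
        eff_noise_sd = noise_sd
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    beta = beta * signs

    donor_noise = rng.normal(0.0, 1.0, size=(n_genes, n_d)) * eff_noise_sd
    if f > 0 and f < 1:
        # remove the sampled noise's chance correlation with dosage and fix its
        # realized variance, so the planted variance fraction is exact per gene
        for j in range(n_genes):
            x = g_centered[j]
            e = donor_noise[j] - donor_noise[j].mean()
            e = e - (e @ x) / (x @ x) * x
            sd = e.std(ddof=0)
            if sd > 0:
                donor_noise[j] = e / sd * eff_noise_sd
    donor_expr = beta[:, None] * g_centered + donor_noise

    sample_expr = np.zeros((n_genes, len(ipsc)))
    d_index = {d: k for k, d in enumerate(donors)}
    for i, row in ipsc.iterrows():
        sample_expr[:, i] = donor_expr[:, d_index[row["donor"]]]
    sample_expr += rng.normal(0.0, within_donor_sd, size=sample_expr.shape)

    # orientation: the recorded high-expression allele is the one with beta > 0
    high_allele_dosage = np.where(beta >= 0, 1, -1)
    eqtls = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "esnp_id": [f"rs{j:06d}" for j in range(n_genes)],
            "chrom": "chr1",
            "pos": 10_000 + np.arange(n_genes),
            "ascert_p": rng.uniform(1e-12, 0.05, size=n_genes),
            **{
                f"dosage_{d}": (
                    np.where(high_allele_dosage > 0, dosages[:, k], 2 - dosages[:, k])
                )
                for k, d in enumerate(donors)
            },
        }
    )
    expr = pd.DataFrame(sample_expr, index=gene_ids, columns=ipsc["sample_id"])
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "beta": beta,
            "variance_fraction": variance_fraction,
        }
    )
    return {
        "eqtls": eqtls,
        "expression": expr,
        "metadata": ipsc,
        "donors": donors,
        "truth": truth,
    }
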