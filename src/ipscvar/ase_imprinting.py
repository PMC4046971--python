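"""Phased allele-specific expression, allelic imbalance and imprinting.

Allelic imbalance (AI) for a gene in a sample is the fraction of its reads
arising from the paternal haplotype, computed by summing phased read counts
over the heterozygous SNPs inside the gene.  Imprinted genes show
mono-allelic expression (AI near 0 or 1); reversion to bi-allelic
expression in iPSC lines derived from a tissue where the gene was
mono-allelic is flagged as loss of imprinting (LOI).

Reference-mapping bias correction is out of scope: haplotype counts are
taken as given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "aggregate_gene_ase",
    "test_imbalance",
    "imprinting_concordance",
    "classify_imprinting",
    "loss_of_imprinting",
]

GENE_ASE_COLUMNS = [
    "sample_id", "gene_id", "paternal_total", "maternal_total",
    "ai", "ci_low", "ci_high", "n_snps",
]


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a binomial fraction."""
    a = (1 - level) / 2
    lo = stats.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def aggregate_gene_ase(
    allelic_counts: pd.DataFrame,
    min_coverage: int = 20,
    min_snps: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate phased per-SNP counts to per-(sample, gene) haplotype totals.

    ``allelic_counts`` needs columns sample_id, gene_id, snp_id,
    hap1_count, hap2_count and paternal_hap ("hap1"/"hap2", constant within
    a gene x sample; mixed or unknown labels make the gene unusable for that
    sample and it is skipped with a warning).  Entries failing the coverage
    or SNP-count thresholds are excluded and counted.
    """
    required = {"sample_id", "gene_id", "snp_id", "hap1_count", "hap2_count", "paternal_hap"}
    missing = required - set(allelic_counts.columns)
    if missing:
        raise ValueError(f"allelic count table missing columns: {sorted(missing)}")
    rows = []
    n_low_coverage = 0
    n_few_snps = 0
    n_phase_inconsistent = 0
    for (sample, gene), grp in allelic_counts.groupby(["sample_id", "gene_id"], sort=True):
        labels = set(grp["paternal_hap"])
        if not labels <= {"hap1", "hap2"} or len(labels) != 1:
            n_phase_inconsistent += 1
            logger.warning("skipping %s/%s: inconsistent haplotype labels", sample, gene)
            continue
        if labels == {"hap1"}:
            pat = int(grp["hap1_count"].sum())
            mat = int(grp["hap2_count"].sum())
        else:
            pat = int(grp["hap2_count"].sum())
            mat = int(grp["hap1_count"].sum())
        n_snps = len(grp)
        if n_snps < min_snps:
            n_few_snps += 1
            continue
        total = pat + mat
        if total < min_coverage:
            n_low_coverage += 1
            continue
        ai = pat / total
        lo, hi = _binom_ci(pat, total)
        rows.append((sample, gene, pat, mat, ai, lo, hi, n_snps))
    out = pd.DataFrame(rows, columns=GENE_ASE_COLUMNS)
    stats_out = {
        "n_kept": len(out),
        "n_low_coverage": n_low_coverage,
        "n_few_snps": n_few_snps,
        "n_phase_inconsistent": n_phase_inconsistent,
    }
    return out, stats_out


def test_imbalance(gene_ase: pd.DataFrame) -> pd.DataFrame:
    """Two-sided exact binomial test of AI against 0.5 per (sample, gene)."""
    p = [
        stats.binomtest(
            int(row["paternal_total"]),
            int(row["paternal_total"] + row["maternal_total"]),
            0.5,
        ).pvalue
        for _, row in gene_ase.iterrows()
    ]
    out = gene_ase.copy()
    out["p_imbalance"] = p
    return out


def imprinting_concordance(
    adult_ase: pd.DataFrame,
    ipsc_ase: pd.DataFrame,
) -> dict:
    """Concordance of AI between adult tissue and derived iPSC lines.

    iPSC AI is averaged over lines with coverage weights; only genes
    testable in both compartments contribute.  Returns Pearson r, r^2 and
    the p-value of the correlation, plus the paired table.
    """
    ipsc = ipsc_ase.copy()
    ipsc["coverage"] = ipsc["paternal_total"] + ipsc["maternal_total"]
    ipsc_avg = (
        ipsc.groupby("gene_id")
        .apply(
            lambda g: np.average(g["ai"], weights=g["coverage"]),
            include_groups=False,
        )
        .rename("ai_ipsc")
    )
    adult = adult_ase.copy()
    adult["coverage"] = adult["paternal_total"] + adult["maternal_total"]
    adult_avg = (
        adult.groupby("gene_id")
        .apply(
            lambda g: np.average(g["ai"], weights=g["coverage"]),
            include_groups=False,
        )
        .rename("ai_adult")
    )
    paired = pd.concat([adult_avg, ipsc_avg], axis=1, join="inner").dropna()
    if len(paired) < 3:
        raise ValueError(f"only {len(paired)} genes testable in both compartments")
    r, p = stats.pearsonr(paired["ai_adult"], paired["ai_ipsc"])
    return {"r": float(r), "r2": float(r**2), "p": float(p), "paired": paired}


def classify_imprinting(
    gene_ase_row: pd.Series,
    mono_threshold: float = 0.9,
    bi_interval: tuple[float, float] = (0.2, 0.8),
) -> str:
    """Imprinting status of one (sample, gene) AI estimate.

    mono-allelic: AI >= 0.9 or <= 0.1 with the 95% CI excluding 0.5;
    bi-allelic: CI contained in (0.2, 0.8); otherwise ambiguous.
    """
    ai = gene_ase_row["ai"]
    lo, hi = gene_ase_row["ci_low"], gene_ase_row["ci_high"]
    if (ai >= mono_threshold or ai <= 1 - mono_threshold) and not (lo <= 0.5 <= hi):
        return "mono-allelic"
    if bi_interval[0] < lo and hi < bi_interval[1]:
        return "bi-allelic"
    return "ambiguous"


def loss_of_imprinting(adult_status: str, ipsc_statuses: list[str]) -> bool:
    """LOI: adult mono-allelic, majority of derived iPSC lines bi-allelic."""
    if adult_status != "mono-allelic" or not ipsc_statuses:
        return False
    n_bi = sum(s == "bi-allelic" for s in ipsc_statuses)
    return n_bi > len(ipsc_statuses) / 2
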