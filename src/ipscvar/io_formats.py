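"""Readers/writers for the pipeline's file formats and the read-pair QC filter.

The quality filter operates on aligned paired-end fragments: a fragment is
retained when at least one of its mates is confidently and cleanly aligned
(mapping quality above 10, no indel in the alignment, at most three
mismatches) and the fragment itself is a plausible cDNA insert (mates on the
same chromosome, template length between 150 bp and 1 Mb).  Spliced
alignments (``N`` CIGAR operations) are not counted as gaps — introns are
expected in RNA-seq alignments; only insertions/deletions disqualify a mate.

All tabular I/O is plain TSV; VCF and SAM go through :mod:`pysam`.
Genomic coordinates are handled 1-based inclusive throughout (SAM/VCF
convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ReadPairRecord",
    "FilterStats",
    "filter_read_pairs",
    "read_pairs_from_sam",
    "filter_sam_file",
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "validate_sample_metadata",
    "PhasedGenotypes",
    "read_phased_vcf",
]

# ---------------------------------------------------------------------------
# Read-pair QC filter
# ---------------------------------------------------------------------------

MIN_INSERT = 150
MAX_INSERT = 1_000_000
MIN_MAPQ = 11  # "quality score of >10", strict
MAX_MISMATCHES = 3


@dataclass
class ReadPairRecord:
    """One aligned read pair (fragment)."""

    read_id: str
    chrom1: str
    chrom2: str
    mapq1: int
    mapq2: int
    mismatches1: int
    mismatches2: int
    has_gap1: bool
    has_gap2: bool
    insert_size: int  # |TLEN|, bp

    def __post_init__(self) -> None:
        if self.mapq1 < 0 or self.mapq2 < 0:
            raise ValueError(f"negative MAPQ in pair {self.read_id!r}")
        if self.mismatches1 < 0 or self.mismatches2 < 0:
            raise ValueError(f"negative mismatch count in pair {self.read_id!r}")
        if self.chrom1 == self.chrom2 and self.insert_size < 0:
            raise ValueError(f"negative insert size in pair {self.read_id!r}")


@dataclass
class FilterStats:
    """Partition of the input stream by outcome.

    ``kept + trans_chromosomal + insert + quality + unpaired`` equals the
    number of input fragments, exactly.
    """

    kept: int = 0
    trans_chromosomal: int = 0
    insert: int = 0
    quality: int = 0
    unpaired: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.trans_chromosomal + self.insert + self.quality + self.unpaired

    def as_dict(self) -> dict[str, int]:
        return {
            "kept": self.kept,
            "trans_chromosomal": self.trans_chromosomal,
            "insert": self.insert,
            "quality": self.quality,
            "unpaired": self.unpaired,
        }


def _mate_clean(mapq: int, mismatches: int, has_gap: bool) -> bool:
    return mapq >= MIN_MAPQ and not has_gap and mismatches <= MAX_MISMATCHES


def pair_passes(pair: ReadPairRecord) -> tuple[bool, str]:
    """Evaluate the QC rules for one pair.

    Returns ``(kept, reason)`` where *reason* is ``"kept"`` or the first
    failed rule in the fixed order trans-chromosomal → insert → quality.
    """
    if pair.chrom1 != pair.chrom2:
        return False, "trans_chromosomal"
    if not (MIN_INSERT <= pair.insert_size <= MAX_INSERT):
        return False, "insert"
    ok1 = _mate_clean(pair.mapq1, pair.mismatches1, pair.has_gap1)
    ok2 = _mate_clean(pair.mapq2, pair.mismatches2, pair.has_gap2)
    if not (ok1 or ok2):
        return False, "quality"
    return True, "kept"


def filter_read_pairs(
    pairs: Iterable[ReadPairRecord],
) -> tuple[list[ReadPairRecord], FilterStats]:
    """Apply the fragment QC rules to a stream of read pairs."""
    stats = FilterStats()
    kept: list[ReadPairRecord] = []
    for pair in pairs:
        ok, reason = pair_passes(pair)
        if ok:
            stats.kept += 1
            kept.append(pair)
        else:
            setattr(stats, reason, getattr(stats, reason) + 1)
    return kept, stats


def _has_indel(read: pysam.AlignedSegment) -> bool:
    # CIGAR ops 1 = I, 2 = D; 3 = N (splice) is deliberately not a gap
    return any(op in (1, 2) for op, _ in (read.cigartuples or []))


def _mismatches(read: pysam.AlignedSegment, fallback: dict[str, int] | None) -> int:
    if read.has_tag("NM"):
        return int(read.get_tag("NM"))
    if fallback is not None and read.query_name in fallback:
        return fallback[read.query_name]
    raise ValueError(
        f"read {read.query_name!r} lacks an NM tag and no side-band "
        "mismatch table was supplied"
    )


def read_pairs_from_sam(
    path: str,
    mismatch_table: dict[str, int] | None = None,
) -> Iterator[tuple[ReadPairRecord, tuple[pysam.AlignedSegment, pysam.AlignedSegment] | None]]:
    """Stream read pairs from a name-sorted SAM file.

    Yields ``(record, (mate1, mate2))``; an unpaired read yields a record
    whose second mate fields are sentinel values and ``None`` for the
    alignment tuple — :func:`filter_sam_file` counts these as ``unpaired``.
    Secondary/supplementary alignments are skipped.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for read in fh:
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            name = read.query_name
            if name not in pending:
                pending[name] = read
            else:
                first = pending.pop(name)
                r1, r2 = (first, read) if first.is_read1 else (read, first)
                rec = ReadPairRecord(
                    read_id=name,
                    chrom1=r1.reference_name or "*",
                    chrom2=r2.reference_name or "*",
                    mapq1=r1.mapping_quality,
                    mapq2=r2.mapping_quality,
                    mismatches1=_mismatches(r1, mismatch_table),
                    mismatches2=_mismatches(r2, mismatch_table),
                    has_gap1=_has_indel(r1),
                    has_gap2=_has_indel(r2),
                    insert_size=abs(r1.template_length),
                )
                yield rec, (r1, r2)
        for name, read in pending.items():
            rec = ReadPairRecord(
                read_id=name,
                chrom1=read.reference_name or "*",
                chrom2="*",
                mapq1=read.mapping_quality,
                mapq2=0,
                mismatches1=_mismatches(read, mismatch_table),
                mismatches2=0,
                has_gap1=_has_indel(read),
                has_gap2=False,
                insert_size=0,
            )
            yield rec, None


def filter_sam_file(
    in_path: str,
    out_path: str | None = None,
    mismatch_table: dict[str, int] | None = None,
) -> FilterStats:
    """Filter a name-sorted SAM file, optionally writing kept pairs."""
    stats = FilterStats()
    with pysam.AlignmentFile(in_path, "r", check_sq=False) as template:
        header = template.header
    out = pysam.AlignmentFile(out_path, "wh", header=header) if out_path else None
    try:
        for rec, mates in read_pairs_from_sam(in_path, mismatch_table):
            if mates is None:
                stats.unpaired += 1
                continue
            ok, reason = pair_passes(rec)
            if ok:
                stats.kept += 1
                if out is not None:
                    out.write(mates[0])
                    out.write(mates[1])
            else:
                setattr(stats, reason, getattr(stats, reason) + 1)
    finally:
        if out is not None:
            out.close()
    return stats


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

VALUE_KINDS = ("counts", "fpkm", "log2fpkm")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with optional annotation.

    ``values`` is genes (rows) × samples (columns).  Counts must be
    non-negative integers; FPKM non-negative floats; log2 FPKM unrestricted.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str
    gene_lengths: np.ndarray | None = None  # bp
    library_sizes: np.ndarray | None = None  # mapped fragments

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Index(self.gene_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        bad = np.argwhere(np.isnan(self.values.astype(float)))
        if bad.size:
            g, s = bad[0]
            raise ValueError(f"NaN at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}")
        if self.value_kind in ("counts", "fpkm"):
            bad = np.argwhere(self.values < 0)
            if bad.size:
                g, s = bad[0]
                raise ValueError(
                    f"negative value at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
        if self.value_kind == "counts":
            if not np.allclose(self.values, np.round(self.values)):
                bad = np.argwhere(~np.isclose(self.values, np.round(self.values)))
                g, s = bad[0]
                raise ValueError(
                    f"non-integer count at gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )
            self.values = np.round(self.values).astype(np.int64)
        if self.gene_lengths is not None:
            self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
            if self.gene_lengths.shape != (len(self.gene_ids),):
                raise ValueError("gene_lengths length mismatch")
        if self.library_sizes is not None:
            self.library_sizes = np.asarray(self.library_sizes, dtype=float)
            if self.library_sizes.shape != (len(self.sample_ids),):
                raise ValueError("library_sizes length mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "ExpressionMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep])
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx],
            value_kind=self.value_kind,
            gene_lengths=None if self.gene_lengths is None else self.gene_lengths[idx],
            library_sizes=self.library_sizes,
        )


def read_expression_matrix(path: str, value_kind: str) -> ExpressionMatrix:
    """Read a gene × sample TSV (header row = sample ids, first col = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[], keep_default_na=False)
    try:
        values = df.apply(pd.to_numeric).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=values,
        value_kind=value_kind,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "sample_id",
    "donor",
    "cell_class",
    "adult_tissue",
    "tissue_of_origin",
    "batch",
    "replicate_label",
]

CELL_CLASSES = ("adult", "iPSC", "ESC")
ADULT_TISSUES = ("fibroblast", "keratinocyte", "EPC", "none")
ORIGINS = ("F", "K", "E", "none")


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the structural invariants of a sample-metadata table."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta = meta.copy()
    meta["batch"] = meta["batch"].astype(int)
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    for _, row in meta.iterrows():
        sid = row["sample_id"]
        if row["cell_class"] not in CELL_CLASSES:
            raise ValueError(f"{sid}: unknown cell_class {row['cell_class']!r}")
        if row["adult_tissue"] not in ADULT_TISSUES:
            raise ValueError(f"{sid}: unknown adult_tissue {row['adult_tissue']!r}")
        if row["tissue_of_origin"] not in ORIGINS:
            raise ValueError(f"{sid}: unknown tissue_of_origin {row['tissue_of_origin']!r}")
        if row["cell_class"] == "adult":
            if row["adult_tissue"] == "none" or row["tissue_of_origin"] != "none":
                raise ValueError(f"{sid}: adult sample must have a tissue and no origin")
        elif row["cell_class"] == "iPSC":
            if row["tissue_of_origin"] == "none" or row["adult_tissue"] != "none":
                raise ValueError(f"{sid}: iPSC sample must have an origin and no adult tissue")
        else:  # ESC
            if row["adult_tissue"] != "none" or row["tissue_of_origin"] != "none":
                raise ValueError(f"{sid}: ESC sample must have neither tissue nor origin")
    return meta


def read_sample_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_metadata(meta)


def write_sample_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------


@dataclass
class PhasedGenotypes:
    """Per-donor phased genotypes at heterozygous SNP sites.

    ``het_sites[donor]`` is a DataFrame with columns
    ``chrom, pos, snp_id, ref, alt, hap1_allele, hap2_allele`` where
    hap1/hap2 are the actual nucleotide strings on each haplotype.  The
    paternal/maternal designation of hap1 vs hap2 is a label carried through
    from the input phasing, never inferred here.
    """

    het_sites: dict[str, pd.DataFrame]
    n_skipped_unphased: int = 0
    n_sites: int = 0


def read_phased_vcf(path: str, donors: Sequence[str]) -> PhasedGenotypes:
    """Extract phased heterozygous genotypes for the requested donors."""
    rows: dict[str, list] = {d: [] for d in donors}
    n_unphased = 0
    n_sites = 0
    with pysam.VariantFile(path) as vcf:
        present = list(vcf.header.samples)
        missing = [d for d in donors if d not in present]
        if missing:
            raise ValueError(f"donors absent from VCF: {missing}")
        for rec in vcf:
            n_sites += 1
            alleles = rec.alleles
            for donor in donors:
                call = rec.samples[donor]
                gt = call.get("GT")
                if gt is None or None in gt or len(gt) != 2:
                    continue
                a1, a2 = gt
                if a1 == a2:
                    continue  # homozygous
                if not call.phased:
                    n_unphased += 1
                    continue
                rows[donor].append(
                    (
                        rec.chrom,
                        rec.pos,
                        rec.id or f"{rec.chrom}:{rec.pos}",
                        rec.ref,
                        ",".join(rec.alts or ()),
                        alleles[a1],
                        alleles[a2],
                    )
                )
    if n_unphased:
        warnings.warn(f"skipped {n_unphased} unphased heterozygous genotypes")
    het = {
        d: pd.DataFrame(
            rows[d],
            columns=["chrom", "pos", "snp_id", "ref", "alt", "hap1_allele", "hap2_allele"],
        )
        for d in donors
    }
    return PhasedGenotypes(het_sites=het, n_skipped_unphased=n_unphased, n_sites=n_sites)
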