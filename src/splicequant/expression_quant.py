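"""Gene-level TPM profiling and flattened exon-bin counting.

TPM (transcripts per kilobase million) divides each gene's read count by its
effective length (union-exonic length), then rescales the resulting rates so
they sum to 1e6 per sample.  Exon-bin counting follows the flattened-bin
convention: a record increments every disjoint bin that any of its aligned
blocks overlaps by at least one base, once per bin, and relative usage is
the within-gene composition of those bin counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .gene_models import ExonBin
from .junction_quant import _iter_records, _REF_CONSUMING, _SKIP

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCountRow",
    "ExpressionProfile",
    "ExonBinCountTable",
    "compute_tpm",
    "count_exon_bins",
    "compare_exon_usage",
    "read_gene_counts",
    "write_expression_profile",
    "write_bin_table",
]


@dataclass(frozen=True)
class GeneCountRow:
    gene_id: str
    raw_count: int
    effective_length: int

    def __post_init__(self) -> None:
        if self.raw_count < 0:
            raise ValueError(f"gene {self.gene_id}: negative count {self.raw_count}")
        if self.effective_length <= 0:
            raise ValueError(
                f"gene {self.gene_id}: effective_length must be positive"
            )


@dataclass
class ExpressionProfile:
    sample_id: str
    tpm: dict[str, float]
    log2_tpm1: dict[str, float]


@dataclass
class ExonBinCountTable:
    sample_id: str
    counts: dict[str, int]
    relative_usage: dict[str, float]
    gene_read_counts: dict[str, int] = field(default_factory=dict)


def _gene_of(bin_id: str) -> str:
    return bin_id.rsplit(":", 1)[0]


def compute_tpm(
    rows: Sequence[GeneCountRow], *, sample_id: str = "sample"
) -> ExpressionProfile:
    """Length- and depth-normalize gene counts to TPM and log2(TPM+1).

    rate_g = count_g / effective_length_g; TPM_g = 1e6 * rate_g / sum(rates).
    An all-zero sample yields all-zero TPM with a warning (the normalization
    is undefined there).
    """
    if not rows:
        raise ValueError("compute_tpm requires at least one gene row")
    rates = {r.gene_id: r.raw_count / r.effective_length for r in rows}
    total = sum(rates.values())
    if total == 0:
        logger.warning(
            "sample %s: all gene counts zero; TPM normalization undefined, "
            "reporting zeros",
            sample_id,
        )
        tpm = {g: 0.0 for g in rates}
    else:
        tpm = {g: rate * 1e6 / total for g, rate in rates.items()}
    log2_tpm1 = {g: math.log2(v + 1.0) for g, v in tpm.items()}
    return ExpressionProfile(sample_id, tpm, log2_tpm1)


def _aligned_blocks(rec: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """1-based (first, last) reference spans of a record, split at skips."""
    blocks: list[tuple[int, int]] = []
    start = cursor = rec.reference_start + 1
    for op, length in rec.cigartuples:
        if op == _SKIP:
            if cursor > start:
                blocks.append((start, cursor - 1))
            cursor += length
            start = cursor
        elif op in _REF_CONSUMING:
            cursor += length
    if cursor > start:
        blocks.append((start, cursor - 1))
    return blocks


def count_exon_bins(
    alignments,
    bins: Sequence[ExonBin],
    *,
    sample_id: str = "sample",
) -> ExonBinCountTable:
    """Count records per flattened exon bin.

    A record increments a bin iff any of its aligned blocks (skip regions
    excluded) overlaps the bin by >= 1 base, at most once per record.  A
    record spanning a skipped cassette therefore hits the flanking bins but
    not the cassette bin.  ``gene_read_counts`` holds, per gene, the number
    of records that hit at least one of that gene's bins (the gene-count
    assignment rule used for TPM input).  Relative usage divides each bin
    count by the summed bin counts of its gene.
    """
    counts = {b.bin_id: 0 for b in bins}
    gene_reads: dict[str, int] = {}
    ordered = sorted(bins, key=lambda b: b.interval.start)
    for rec in _iter_records(alignments):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        hit: set[str] = set()
        for lo, hi in _aligned_blocks(rec):
            for b in ordered:
                if b.interval.start > hi:
                    break
                if b.interval.chrom == rec.reference_name and b.interval.end >= lo:
                    hit.add(b.bin_id)
        for bin_id in hit:
            counts[bin_id] += 1
        for gene in {_gene_of(b) for b in hit}:
            gene_reads[gene] = gene_reads.get(gene, 0) + 1
    gene_totals: dict[str, int] = {}
    for bin_id, c in counts.items():
        gene_totals[_gene_of(bin_id)] = gene_totals.get(_gene_of(bin_id), 0) + c
    usage = {
        bin_id: (c / gene_totals[_gene_of(bin_id)] if gene_totals[_gene_of(bin_id)] else 0.0)
        for bin_id, c in counts.items()
    }
    return ExonBinCountTable(sample_id, counts, usage, gene_reads)


def compare_exon_usage(
    a: ExonBinCountTable,
    b: ExonBinCountTable,
    *,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-bin relative usage in two samples with a pseudocounted log2 ratio.

    The pseudocount is added to both raw bin counts before usages are formed
    so the log ratio stays finite on zero bins; bins belonging to a gene
    with zero total counts in either sample are flagged.
    """
    if set(a.counts) != set(b.counts):
        raise ValueError("bin sets differ between the two tables")

    def _totals(table: ExonBinCountTable, pseudo: float) -> dict[str, float]:
        out: dict[str, float] = {}
        for bin_id, c in table.counts.items():
            g = _gene_of(bin_id)
            out[g] = out.get(g, 0.0) + c + pseudo
        return out

    pseudo_a, pseudo_b = _totals(a, pseudocount), _totals(b, pseudocount)
    raw_a, raw_b = _totals(a, 0.0), _totals(b, 0.0)
    rows = []
    for bin_id in sorted(a.counts):
        g = _gene_of(bin_id)
        ua = (a.counts[bin_id] + pseudocount) / pseudo_a[g]
        ub = (b.counts[bin_id] + pseudocount) / pseudo_b[g]
        zero_a = raw_a[g] == 0
        zero_b = raw_b[g] == 0
        rows.append(
            {
                "bin_id": bin_id,
                "usage_a": a.relative_usage[bin_id],
                "usage_b": b.relative_usage[bin_id],
                "pseudo_usage_a": ua,
                "pseudo_usage_b": ub,
                "log2_ratio": math.log2(ua / ub),
                "zero_gene_in_a": zero_a,
                "zero_gene_in_b": zero_b,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_gene_counts(path: str | Path) -> list[GeneCountRow]:
    """Read a gene count TSV with columns gene_id, count, effective_length."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = {"gene_id", "count", "effective_length"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(expected)}, got {list(df.columns)}"
        )
    return [
        GeneCountRow(str(r.gene_id), int(r.count), int(r.effective_length))
        for r in df.itertuples()
    ]


def write_expression_profile(profile: ExpressionProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttpm\tlog2_tpm1\n")
        for gene in sorted(profile.tpm):
            fh.write(
                f"{gene}\t{profile.tpm[gene]:.6f}\t{profile.log2_tpm1[gene]:.6f}\n"
            )


def write_bin_table(
    table: ExonBinCountTable, bins: Sequence[ExonBin], path: str | Path
) -> None:
    by_id = {b.bin_id: b for b in bins}
    with open(path, "w") as fh:
        fh.write("bin_id\tchrom\tstart\tend\tcount\trelative_usage\n")
        for bin_id in sorted(table.counts):
            iv = by_id[bin_id].interval
            fh.write(
                f"{bin_id}\t{iv.chrom}\t{iv.start}\t{iv.end}"
                f"\t{table.counts[bin_id]}\t{table.relative_usage[bin_id]:.6f}\n"
            )
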