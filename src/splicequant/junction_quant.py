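"""Junction-read counting and the cassette usage (4R/3R-style) statistic.

Reads whose alignment skips an intron evidence a specific exon--exon joint;
``X_{i,j}`` denotes the count of reads spanning the junction between exons
``i`` and ``j``.  For a cassette exon with two inclusion junctions and one
exclusion junction the usage percentage is

    usage% = 100 * (mean of inclusion-junction counts) / exclusion count

which, for the MAPT 3R/4R cassette, is 100 * (0.5 * (X_{9,10} + X_{10,11}))
/ X_{9,11}.  Under uniform fragment sampling the statistic is 100*f/(1-f)
in expectation, where f is the molar inclusion (4R) fraction, so the
inclusion fraction is recovered as f_hat = usage / (100 + usage).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from .gene_models import CassetteEvent, JunctionKey

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionCountTable",
    "CassetteUsageResult",
    "UsageSummary",
    "extract_junctions",
    "read_junction_table",
    "write_junction_table",
    "normalize_depth",
    "compute_usage",
    "summarize_samples",
    "write_usage_report",
]

# CIGAR operation codes that consume the reference
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X
_SKIP = 3  # N


@dataclass
class JunctionCountTable:
    """Per-sample raw (and optionally depth-normalized) junction counts."""

    sample_id: str
    counts: dict[JunctionKey, int] = field(default_factory=dict)
    library_size: int = 0
    normalized: dict[JunctionKey, float] | None = None

    def get(self, key: JunctionKey) -> int:
        return self.counts.get(key, 0)

    def scaled(self, factor: float) -> "JunctionCountTable":
        """Scale every raw count (used in tests of ratio invariance)."""
        return JunctionCountTable(
            self.sample_id,
            {k: int(round(v * factor)) for k, v in self.counts.items()},
            int(round(self.library_size * factor)),
        )


@dataclass
class CassetteUsageResult:
    """Usage percentage for one cassette event in one sample."""

    sample_id: str
    event: str
    x_inclusion: tuple[float, ...]
    x_exclusion: float
    defined: bool
    usage_percent: float | None
    inclusion_fraction_hat: float | None

    def __post_init__(self) -> None:
        if self.defined:
            assert self.usage_percent is not None and self.usage_percent >= 0.0


@dataclass
class UsageSummary:
    mean: float
    sd: float | None  # sample s.d. (n-1); None when n == 1
    n: int
    n_undefined: int


# ---------------------------------------------------------------------------
# extraction from spliced alignments
# ---------------------------------------------------------------------------

def _iter_records(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
) -> Iterator[pysam.AlignedSegment]:
    if isinstance(alignments, (str, Path)):
        with pysam.AlignmentFile(str(alignments), check_sq=False) as fh:
            yield from fh
    else:
        yield from alignments


def extract_junctions(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    *,
    min_anchor: int = 1,
    sample_id: str = "sample",
) -> JunctionCountTable:
    """Count junction-spanning reads from spliced alignments.

    Every skip (``N``) operation in a record contributes one count to the
    junction whose flanks are the last aligned base before the skip and the
    first aligned base after it, provided both flanking aligned blocks span
    at least ``min_anchor`` reference bases.  Unmapped, secondary and
    supplementary records are ignored; ``library_size`` is the number of
    primary mapped records processed (the depth-normalization denominator).

    ``alignments`` may be a SAM/BAM path, an open ``pysam.AlignmentFile`` or
    any iterable of ``pysam.AlignedSegment``.
    """
    if min_anchor < 1:
        raise ValueError(f"min_anchor must be >= 1, got {min_anchor}")
    table = JunctionCountTable(sample_id)
    n_records = 0
    for rec in _iter_records(alignments):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        cigar = rec.cigartuples
        if cigar is None:
            raise ValueError(
                f"record {rec.query_name!r} is mapped but has no alignment string"
            )
        n_records += 1
        chrom = rec.reference_name
        pos = rec.reference_start + 1  # 1-based leftmost aligned base
        # split the alignment into reference blocks separated by skips
        blocks: list[tuple[int, int]] = []  # (first, last) 1-based aligned base
        gaps: list[int] = []  # skip length after block i
        block_start = pos
        cursor = pos
        for op, length in cigar:
            if op == _SKIP:
                if cursor == block_start:
                    raise ValueError(
                        f"record {rec.query_name!r}: skip with empty flanking block"
                    )
                blocks.append((block_start, cursor - 1))
                gaps.append(length)
                cursor += length
                block_start = cursor
            elif op in _REF_CONSUMING:
                cursor += length
        if cursor > block_start:
            blocks.append((block_start, cursor - 1))
        elif gaps:
            raise ValueError(
                f"record {rec.query_name!r}: alignment ends in a skip"
            )
        for i, gap in enumerate(gaps):
            left, right = blocks[i], blocks[i + 1]
            if (
                left[1] - left[0] + 1 >= min_anchor
                and right[1] - right[0] + 1 >= min_anchor
            ):
                key = JunctionKey(chrom, left[1], right[0])
                table.counts[key] = table.counts.get(key, 0) + 1
    table.library_size = n_records
    return table


# ---------------------------------------------------------------------------
# count-file dialects
# ---------------------------------------------------------------------------

_STAR_STRAND = {"0": ".", "1": "+", "2": "-"}


def read_junction_table(
    path: str | Path,
    dialect: str = "plain_tsv",
    *,
    library_size: int | None = None,
    sample_id: str | None = None,
    intron_coords: bool = False,
) -> JunctionCountTable:
    """Read a junction count table in one of three dialects.

    ``plain_tsv``
        columns ``chrom  donor  acceptor  strand  count`` with flanking
        exonic positions; an optional ``# library_size: N`` comment line is
        honoured as a sidecar library size.
    ``star_sj``
        STAR ``SJ.out.tab`` (9 columns); intron first/last positions are
        converted to exonic flanks (-1/+1) and the unique-read column used.
    ``jcounts``
        featureCounts ``.jcounts`` layout; the first numeric column after
        the two site descriptors is used.

    ``intron_coords=True`` applies the same -1/+1 shift to the plain and
    jcounts dialects for files written in the intron-boundary convention.
    """
    path = Path(path)
    table = JunctionCountTable(sample_id or path.stem)
    sidecar_libsize: int | None = None

    def key(chrom: str, lo: int, hi: int, strand: str, shift: bool) -> JunctionKey:
        if shift:
            lo, hi = lo - 1, hi + 1
        lo, hi = min(lo, hi), max(lo, hi)  # accept either print order
        return JunctionKey(chrom, lo, hi, strand)

    with open(path) as fh:
        if dialect == "plain_tsv":
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if line.startswith("#"):
                    if "library_size" in line:
                        sidecar_libsize = int(line.split(":", 1)[1])
                    continue
                if not line or line.startswith("chrom\t"):
                    continue
                cols = line.split("\t")
                if len(cols) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns")
                try:
                    k = key(cols[0], int(cols[1]), int(cols[2]), cols[3], intron_coords)
                    count = int(cols[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                table.counts[k] = table.counts.get(k, 0) + count
        elif dialect == "star_sj":
            for lineno, line in enumerate(fh, 1):
                cols = line.split()
                if not cols:
                    continue
                if len(cols) != 9:
                    raise ValueError(
                        f"{path}:{lineno}: expected 9 SJ.out.tab columns"
                    )
                try:
                    k = key(
                        cols[0],
                        int(cols[1]),
                        int(cols[2]),
                        _STAR_STRAND.get(cols[3], "."),
                        True,  # SJ.out.tab is always intron-boundary
                    )
                    count = int(cols[6])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                table.counts[k] = table.counts.get(k, 0) + count
        elif dialect == "jcounts":
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 9:
                raise ValueError(f"{path}: jcounts header has too few columns")
            for lineno, line in enumerate(fh, 2):
                line = line.rstrip("\n")
                if not line:
                    continue
                cols = line.split("\t")
                try:
                    k = key(
                        cols[2], int(cols[3]), int(cols[6]), cols[4], intron_coords
                    )
                    count = int(float(cols[8]))
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                table.counts[k] = table.counts.get(k, 0) + count
        else:
            raise ValueError(
                f"unknown dialect {dialect!r}; expected plain_tsv, star_sj or jcounts"
            )
    if library_size is not None:
        table.library_size = library_size
    elif sidecar_libsize is not None:
        table.library_size = sidecar_libsize
    else:
        table.library_size = sum(table.counts.values())
    return table


def write_junction_table(table: JunctionCountTable, path: str | Path) -> None:
    """Write the plain TSV dialect with a library-size sidecar comment."""
    with open(path, "w") as fh:
        fh.write(f"# library_size: {table.library_size}\n")
        fh.write("chrom\tdonor\tacceptor\tstrand\tcount\n")
        for k in sorted(
            table.counts, key=lambda j: (j.chrom, j.donor_exonic_pos, j.acceptor_exonic_pos)
        ):
            fh.write(
                f"{k.chrom}\t{k.donor_exonic_pos}\t{k.acceptor_exonic_pos}"
                f"\t{k.strand}\t{table.counts[k]}\n"
            )


# ---------------------------------------------------------------------------
# normalization and the usage statistic
# ---------------------------------------------------------------------------

def normalize_depth(
    table: JunctionCountTable, library_size: int | None = None
) -> JunctionCountTable:
    """Fill per-million depth-normalized counts; raw counts are untouched."""
    size = library_size if library_size is not None else table.library_size
    if size <= 0:
        raise ValueError(f"library_size must be positive, got {size}")
    normalized = {k: v * 1e6 / size for k, v in table.counts.items()}
    return replace(table, library_size=size, normalized=normalized)


def compute_usage(
    table: JunctionCountTable, event: CassetteEvent
) -> CassetteUsageResult:
    """Compute the cassette usage percentage for one event.

    Junctions absent from the table count as zero (with a warning): a pure
    single-isoform sample legitimately leaves the other isoform's junctions
    unobserved.  With a zero exclusion count the ratio is undefined and the
    result is flagged rather than raising.
    """
    for junc in event.all_junctions():
        if junc not in table.counts:
            logger.warning(
                "sample %s: junction %s absent from table; counted as 0",
                table.sample_id,
                junc,
            )
    x_inc = tuple(float(table.get(j)) for j in event.inclusion_junctions)
    x_exc = float(table.get(event.exclusion_junction))
    if x_exc == 0:
        return CassetteUsageResult(
            table.sample_id, event.name, x_inc, x_exc, False, None, None
        )
    usage = 100.0 * (sum(x_inc) / len(x_inc)) / x_exc
    return CassetteUsageResult(
        table.sample_id,
        event.name,
        x_inc,
        x_exc,
        True,
        usage,
        usage / (100.0 + usage),
    )


def summarize_samples(results: Sequence[CassetteUsageResult]) -> UsageSummary:
    """Mean, sample s.d. (n-1 denominator) and n over defined results."""
    defined = [r.usage_percent for r in results if r.defined]
    n_undef = len(results) - len(defined)
    if not defined:
        raise ValueError("no sample yields a defined usage ratio")
    n = len(defined)
    mean = sum(defined) / n
    sd = (
        math.sqrt(sum((u - mean) ** 2 for u in defined) / (n - 1))
        if n > 1
        else None
    )
    return UsageSummary(mean, sd, n, n_undef)


def write_usage_report(
    results: Sequence[CassetteUsageResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tevent\tinclusion_counts\texclusion_count"
            "\tusage_percent\tinclusion_fraction_hat\tdefined\n"
        )
        for r in results:
            inc = ";".join(f"{x:g}" for x in r.x_inclusion)
            usage = f"{r.usage_percent:.6f}" if r.defined else "NA"
            f_hat = f"{r.inclusion_fraction_hat:.6f}" if r.defined else "NA"
            fh.write(
                f"{r.sample_id}\t{r.event}\t{inc}\t{r.x_exclusion:g}"
                f"\t{usage}\t{f_hat}\t{str(r.defined).lower()}\n"
            )
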