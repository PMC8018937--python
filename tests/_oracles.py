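"""Independent brute-force oracles and random-instance generators.

These deliberately avoid the code paths they check: exon-bin flattening is
re-derived by per-base labeling, bin counting by testing every
(block, bin) pair, and random gene models are built from scratch.
"""

from __future__ import annotations

import numpy as np
import pysam

from splicequant.gene_models import (
    ExonBin,
    GeneModel,
    GenomicInterval,
)


def per_base_bin_oracle(model: GeneModel) -> list[tuple[int, int, frozenset]]:
    """Label each exonic base with its isoform set; merge maximal runs."""
    lo = min(e.start for exons in model.isoforms.values() for e in exons)
    hi = max(e.end for exons in model.isoforms.values() for e in exons)
    labels = {}
    for pos in range(lo, hi + 1):
        members = frozenset(
            name
            for name, exons in model.isoforms.items()
            if any(e.start <= pos <= e.end for e in exons)
        )
        if members:
            labels[pos] = members
    runs = []
    for pos in sorted(labels):
        if runs and runs[-1][1] == pos - 1 and runs[-1][2] == labels[pos]:
            runs[-1][1] = pos
        else:
            runs.append([pos, pos, labels[pos]])
    return [(a, b, m) for a, b, m in runs]


def brute_force_bin_counts(
    records: list[pysam.AlignedSegment], bins: list[ExonBin]
) -> dict[str, int]:
    """Test every (aligned block, bin) pair for >= 1 base of overlap."""
    counts = {b.bin_id: 0 for b in bins}
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        # reference blocks split at N, directly from the CIGAR
        blocks = []
        pos = rec.reference_start + 1
        start = pos
        for op, length in rec.cigartuples:
            if op == 3:
                blocks.append((start, pos - 1))
                pos += length
                start = pos
            elif op in {0, 2, 7, 8}:
                pos += length
        if pos > start:
            blocks.append((start, pos - 1))
        hit = set()
        for b in bins:
            for lo, hi in blocks:
                if (
                    b.interval.chrom == rec.reference_name
                    and lo <= b.interval.end
                    and hi >= b.interval.start
                ):
                    hit.add(b.bin_id)
        for bin_id in hit:
            counts[bin_id] += 1
    return counts


def random_gene_model(rng: np.random.Generator, *, with_event: bool = False) -> GeneModel:
    """A random small gene model: <= 5 isoforms, exons within [1, 2000].

    Exons are drawn on a shared boundary grid so isoforms genuinely overlap;
    introns are >= 2 bases so junction keys stay valid.
    """
    n_iso = int(rng.integers(1, 6))
    # shared candidate exons: 3-7 non-overlapping intervals
    n_exons = int(rng.integers(3, 8))
    cuts = np.sort(rng.choice(np.arange(1, 2000), size=2 * n_exons, replace=False))
    candidates = []
    for i in range(n_exons):
        start, end = int(cuts[2 * i]), int(cuts[2 * i + 1])
        if candidates and start <= candidates[-1][1] + 2:
            start = candidates[-1][1] + 3  # keep >= 2-base introns
        if start > end:
            continue
        candidates.append((start, end))
    isoforms = {}
    for k in range(n_iso):
        keep = [c for c in candidates if rng.random() < 0.7]
        if not keep:
            keep = [candidates[int(rng.integers(0, len(candidates)))]]
        # occasionally extend an exon end to create partial overlaps
        exons = []
        for j, (s, e) in enumerate(keep):
            if rng.random() < 0.3:
                nxt = keep[j + 1][0] if j + 1 < len(keep) else 2005
                e = min(e + int(rng.integers(1, 30)), nxt - 3)
                e = max(e, s)
            exons.append(GenomicInterval("chrR", s, e, "+"))
        isoforms[f"iso{k}"] = tuple(exons)
    return GeneModel("RANDGENE", "chrR", "+", isoforms)


def make_record(
    header: pysam.AlignmentHeader,
    name: str,
    pos: int,
    cigar: str,
    *,
    flag: int = 0,
    chrom_index: int = 0,
) -> pysam.AlignedSegment:
    """Build a SAM record at 1-based position ``pos`` from a CIGAR string."""
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = flag
    rec.reference_id = chrom_index
    rec.reference_start = pos - 1
    rec.mapping_quality = 60
    rec.cigarstring = cigar
    qlen = rec.infer_query_length()
    if qlen:
        rec.query_sequence = "A" * qlen
    return rec
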