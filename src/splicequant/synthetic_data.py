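"""Seeded generators for spliced reads, junction tables and qPCR plates.

The read simulator draws uniform-coverage reads from a mixture of isoforms
of a cassette-exon gene.  ``proportions`` are molar isoform fractions; a
read's isoform is drawn with probability proportional to
``proportion * (transcript_length - read_length + 1)`` (fragment-uniform
sampling over the pooled transcripts, the standard RNA-seq generative
model), and its start is uniform over the positions admitting a full-length
read.  Under this model every junction of an isoform is crossed with the
same probability, so the cassette usage statistic
``100 * mean(inclusion counts) / exclusion count`` has expectation
``100 * f / (1 - f)`` in the inclusion fraction ``f``.

No sequencing-error, GC-bias, fragment-length or paired-end modelling:
reads are emitted pre-aligned as SAM records with exact spliced alignment
strings, alongside a truth ledger of every junction each read spans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .gene_models import GeneModel, JunctionKey, load_fixture
from .junction_quant import JunctionCountTable
from .qpcr_quant import PERFECT_SLOPE

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_reads",
    "simulate_junction_table",
    "simulate_qpcr",
    "write_read_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Configuration of one read-simulation run.

    Defaults mirror the porcine induced-neuron study design the package
    targets: a three-exon cassette gene with a 93 bp cassette (the length of
    the MAPT exon-10 repeat cassette), 75 bp reads, inclusion fraction
    f = 0.148 (the molar 4R fraction whose 4R/3R ratio is ~17.4%), and
    1e5 reads per sample.
    """

    model: GeneModel = None  # type: ignore[assignment]
    proportions: dict[str, float] = field(
        default_factory=lambda: {"inc": 0.148, "exc": 0.852}
    )
    n_reads: int = 100_000
    read_length: int = 75
    min_anchor: int = 1
    seed: int = 0
    depth_mode: str = "fixed"  # or "poisson": N ~ Poisson(n_reads)

    def __post_init__(self) -> None:
        if self.model is None:
            self.model = load_fixture("toy_maptlike")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"proportions sum to {total!r}, expected 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("proportions must be non-negative")
        unknown = set(self.proportions) - set(self.model.isoforms)
        if unknown:
            raise ValueError(f"proportions name unknown isoforms {sorted(unknown)}")
        if self.read_length < 2 * self.min_anchor:
            raise ValueError("read_length must be >= 2 * min_anchor")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.depth_mode not in {"fixed", "poisson"}:
            raise ValueError(f"unknown depth_mode {self.depth_mode!r}")
        for name in self.proportions:
            t_len = self.model.isoform_length(name)
            if t_len < self.read_length:
                raise ValueError(
                    f"isoform {name}: transcript length {t_len} shorter than "
                    f"read_length {self.read_length}"
                )

    def inclusion_fraction(self, event_name: str | None = None) -> float:
        """Molar fraction of isoforms carrying all inclusion junctions."""
        event = (
            self.model.event(event_name)
            if event_name
            else self.model.events[0]
        )
        f = 0.0
        for name, prop in self.proportions.items():
            juncs = set(self.model.isoform_junctions(name))
            if set(event.inclusion_junctions) <= juncs:
                f += prop
        return f


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    seed: int
    isoform_read_counts: dict[str, int]
    junction_counts: dict[JunctionKey, int]  # the ledger
    expected_usage_percent: dict[str, float | None]  # per event, 100 f/(1-f)
    inclusion_fraction: dict[str, float]


def _expected_usage(config: SimConfig) -> tuple[dict, dict]:
    expected: dict[str, float | None] = {}
    fractions: dict[str, float] = {}
    for event in config.model.events:
        f = config.inclusion_fraction(event.name)
        fractions[event.name] = f
        expected[event.name] = (
            100.0 * f / (1.0 - f) if f < 1.0 else None
        )
    return expected, fractions


def _isoform_weights(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Read-level isoform probabilities: molar fraction x valid starts."""
    names = sorted(config.proportions)
    w = np.array(
        [
            config.proportions[n]
            * (config.model.isoform_length(n) - config.read_length + 1)
            for n in names
        ],
        dtype=float,
    )
    return names, w / w.sum()


def _total_reads(config: SimConfig, rng: np.random.Generator) -> int:
    if config.depth_mode == "poisson":
        return int(rng.poisson(config.n_reads))
    return config.n_reads


def _read_blocks(
    exons: Sequence, start: int, length: int
) -> list[tuple[int, int]]:
    """Genomic (first, last) blocks of a read at 1-based transcript ``start``."""
    blocks: list[tuple[int, int]] = []
    offset = 0  # transcript bases before current exon
    remaining = length
    pos = start
    for exon in exons:
        e_len = exon.end - exon.start + 1
        if pos > offset + e_len:
            offset += e_len
            continue
        within = pos - offset - 1  # 0-based offset into this exon
        take = min(remaining, e_len - within)
        g_start = exon.start + within
        blocks.append((g_start, g_start + take - 1))
        remaining -= take
        pos += take
        offset += e_len
        if remaining == 0:
            break
    assert remaining == 0, "read ran off transcript end"
    return blocks


def simulate_reads(
    config: SimConfig,
) -> tuple[dict[str, str], list[pysam.AlignedSegment], SimTruth]:
    """Simulate spliced reads from an isoform mixture.

    Returns the synthetic reference (chrom -> sequence), primary mapped SAM
    records with exact match/skip alignment strings, and the truth ledger.
    The ledger counts, per junction, the reads whose flanking aligned blocks
    both reach ``min_anchor`` bases -- exactly what junction extraction must
    reproduce at the same anchor setting.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    model = config.model
    ref_len = max(e.end for exons in model.isoforms.values() for e in exons) + 100
    reference = {
        model.chrom: "".join(rng.choice(_BASES, size=ref_len))
    }
    transcripts = {
        name: "".join(
            reference[model.chrom][e.start - 1 : e.end] for e in exons
        )
        for name, exons in model.isoforms.items()
    }
    names, weights = _isoform_weights(config)
    n = _total_reads(config, rng)
    per_isoform = rng.multinomial(n, weights)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": model.chrom, "LN": ref_len}],
        }
    )
    records: list[pysam.AlignedSegment] = []
    ledger: dict[JunctionKey, int] = {}
    read_no = 0
    for name, n_iso in zip(names, per_isoform):
        exons = model.isoforms[name]
        t_len = model.isoform_length(name)
        starts = rng.integers(1, t_len - config.read_length + 2, size=n_iso)
        for s in starts:
            read_no += 1
            blocks = _read_blocks(exons, int(s), config.read_length)
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"sim_{name}_{read_no:07d}"
            rec.reference_id = 0
            rec.reference_start = blocks[0][0] - 1
            rec.mapping_quality = 60
            rec.flag = 0
            cigar = []
            for i, (lo, hi) in enumerate(blocks):
                if i:
                    gap = lo - blocks[i - 1][1] - 1
                    cigar.append((3, gap))  # N
                cigar.append((0, hi - lo + 1))  # M
            rec.cigartuples = cigar
            rec.query_sequence = transcripts[name][
                int(s) - 1 : int(s) - 1 + config.read_length
            ]
            records.append(rec)
            for (l_lo, l_hi), (r_lo, r_hi) in zip(blocks, blocks[1:]):
                if (
                    l_hi - l_lo + 1 >= config.min_anchor
                    and r_hi - r_lo + 1 >= config.min_anchor
                ):
                    key = JunctionKey(model.chrom, l_hi, r_lo, model.strand)
                    ledger[key] = ledger.get(key, 0) + 1
    expected, fractions = _expected_usage(config)
    truth = SimTruth(
        config.seed,
        dict(zip(names, (int(x) for x in per_isoform))),
        ledger,
        expected,
        fractions,
    )
    return reference, records, truth


def _crossing_probability(
    config: SimConfig, isoform: str, junction_index: int
) -> float:
    """Exact P(a uniform read of this isoform spans its j-th junction).

    Counts start positions whose flanking aligned blocks both reach
    ``min_anchor``; anchors saturate at the flanking exon lengths, matching
    the read-level ledger definition.
    """
    exons = config.model.isoforms[isoform]
    L, a = config.read_length, config.min_anchor
    t_len = config.model.isoform_length(isoform)
    exon_lens = [e.end - e.start + 1 for e in exons]
    t = sum(exon_lens[: junction_index + 1])  # transcript pos of last base before gap
    s = np.arange(1, t_len - L + 2)
    left = np.minimum(t - s + 1, exon_lens[junction_index])
    right = np.minimum(s + L - 1 - t, exon_lens[junction_index + 1])
    ok = (s <= t) & (s + L - 1 >= t + 1) & (left >= a) & (right >= a)
    return float(ok.sum()) / len(s)


def simulate_junction_table(
    config: SimConfig, *, sample_id: str = "sim"
) -> tuple[JunctionCountTable, SimTruth]:
    """Draw junction counts directly, skipping read generation.

    Per isoform, reads are allocated multinomially as in
    :func:`simulate_reads`; each junction's spanning count is then binomial
    with the exact crossing probability implied by read length, anchors and
    exon lengths.  Junction counts of one isoform are drawn independently
    (their weak coupling through shared reads is ignored); marginal means
    and variances match the read-level process.
    """
    rng = np.random.default_rng(config.seed)
    names, weights = _isoform_weights(config)
    n = _total_reads(config, rng)
    per_isoform = rng.multinomial(n, weights)
    counts: dict[JunctionKey, int] = {}
    for name, n_iso in zip(names, per_isoform):
        juncs = config.model.isoform_junctions(name)
        for j_idx, key in enumerate(juncs):
            p = _crossing_probability(config, name, j_idx)
            c = int(rng.binomial(n_iso, p))
            counts[key] = counts.get(key, 0) + c
    expected, fractions = _expected_usage(config)
    truth = SimTruth(
        config.seed,
        dict(zip(names, (int(x) for x in per_isoform))),
        dict(counts),
        expected,
        fractions,
    )
    table = JunctionCountTable(sample_id, counts, library_size=max(n, 1))
    return table, truth


def simulate_qpcr(
    quantities: Mapping[tuple[str, str], float],
    *,
    slope: float = PERFECT_SLOPE,
    intercept: float = 20.0,
    sigma: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    dilution_factors: Sequence[float] = (1.0, 0.5, 0.25, 0.125, 0.0625),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate Cq tables from known relative quantities.

    ``quantities`` maps (sample_id, target) to a positive relative amount.
    Cq = intercept + slope * log10(amount) + Normal(0, sigma), in technical
    replicates; the dilution-series table is generated from the same curve,
    so a noise-free run is inverted exactly by the standard-curve pipeline.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if slope >= 0:
        raise ValueError("slope must be negative")
    rng = np.random.default_rng(seed)
    sample_rows = []
    for (sample_id, target), q in sorted(quantities.items()):
        if q <= 0:
            raise ValueError(f"quantity for {(sample_id, target)} must be > 0")
        for rep in range(1, n_replicates + 1):
            cq = intercept + slope * math.log10(q) + rng.normal(0.0, sigma)
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "target": target,
                    "replicate": rep,
                    "cq": cq,
                }
            )
    targets = sorted({t for _, t in quantities})
    dilution_rows = []
    for target in targets:
        for d in dilution_factors:
            for rep in range(1, n_replicates + 1):
                cq = intercept + slope * math.log10(d) + rng.normal(0.0, sigma)
                dilution_rows.append(
                    {
                        "target": target,
                        "dilution_factor": d,
                        "replicate": rep,
                        "cq": cq,
                    }
                )
    return pd.DataFrame(sample_rows), pd.DataFrame(dilution_rows)


def write_read_dataset(
    config: SimConfig, outdir: str | Path, *, sample_id: str = "sim"
) -> dict[str, str]:
    """Run :func:`simulate_reads` and write FASTA/SAM/TSV plus a manifest.

    Returns the manifest (relative file names), which is also written as
    ``manifest.yaml`` in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, records, truth = simulate_reads(config)
    fasta = outdir / "reference.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    sam = outdir / f"{sample_id}.sam"
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": chrom, "LN": len(seq)} for chrom, seq in reference.items()
            ],
        }
    )
    with pysam.AlignmentFile(str(sam), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)
    truth_path = outdir / "truth_junctions.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tdonor\tacceptor\tstrand\tcount\n")
        for key in sorted(
            truth.junction_counts,
            key=lambda j: (j.chrom, j.donor_exonic_pos, j.acceptor_exonic_pos),
        ):
            fh.write(
                f"{key.chrom}\t{key.donor_exonic_pos}\t{key.acceptor_exonic_pos}"
                f"\t{key.strand}\t{truth.junction_counts[key]}\n"
            )
    iso_path = outdir / "truth_isoforms.tsv"
    with open(iso_path, "w") as fh:
        fh.write("isoform\treads\tproportion\n")
        for name in sorted(truth.isoform_read_counts):
            fh.write(
                f"{name}\t{truth.isoform_read_counts[name]}"
                f"\t{config.proportions.get(name, 0.0):.6f}\n"
            )
    manifest = {
        "sample_id": sample_id,
        "seed": config.seed,
        "n_reads": config.n_reads,
        "read_length": config.read_length,
        "min_anchor": config.min_anchor,
        "depth_mode": config.depth_mode,
        "gene_id": config.model.gene_id,
        "proportions": {k: float(v) for k, v in config.proportions.items()},
        "expected_usage_percent": {
            k: (float(v) if v is not None else None)
            for k, v in truth.expected_usage_percent.items()
        },
        "files": {
            "reference": fasta.name,
            "alignments": sam.name,
            "truth_junctions": truth_path.name,
            "truth_isoforms": iso_path.name,
        },
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
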