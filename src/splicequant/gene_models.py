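"""Gene models with cassette-exon events.

A :class:`GeneModel` describes one gene: its exon structure per isoform, its
strand, and a set of named cassette-exon events.  A cassette event is an exon
that is either wholly included (producing two exon--exon junctions) or wholly
skipped (producing one).  Junctions are stored as the pair of flanking exonic
bases -- the last base of the upstream exon and the first base of the
downstream exon, in ascending genomic order regardless of strand -- so that
junctions recovered from spliced alignments match the model directly.

Models are read from a small YAML document (see :func:`load_gene_model`) or
assembled from GFF3 exon lines plus a tab-separated event table
(:func:`load_gene_model_from_gff3`).  Shipped fixtures cover the porcine and
human MAPT 3R/4R cassette (exon 10 of the microtubule-binding repeat region)
and a small synthetic cassette gene used throughout the test-suite.

Coordinates are 1-based and inclusive at every public surface; half-open
external conventions are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "GenomicInterval",
    "JunctionKey",
    "CassetteEvent",
    "GeneModel",
    "ExonBin",
    "ModelValidationError",
    "load_gene_model",
    "save_gene_model",
    "gene_model_from_dict",
    "gene_model_to_dict",
    "load_gene_model_from_gff3",
    "load_fixture",
    "fixture_names",
    "flatten_exon_bins",
]

FIXTURES = ("pig_mapt", "human_mapt", "toy_maptlike")


class ModelValidationError(ValueError):
    """A gene-model file parsed but violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed 1-based genomic interval ``[start, end]`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ModelValidationError("chrom must be non-empty")
        if self.start > self.end:
            raise ModelValidationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ModelValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class JunctionKey:
    """An exon--exon junction identified by its flanking exonic bases.

    ``donor_exonic_pos`` is the last exonic base of the genome-left exon and
    ``acceptor_exonic_pos`` the first exonic base of the genome-right exon,
    always in ascending order.  Strand is carried for reporting but excluded
    from equality/hashing: junctions recovered from alignments are
    strand-agnostic.
    """

    chrom: str
    donor_exonic_pos: int
    acceptor_exonic_pos: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.donor_exonic_pos >= self.acceptor_exonic_pos:
            raise ModelValidationError(
                f"junction donor {self.donor_exonic_pos} must lie left of "
                f"acceptor {self.acceptor_exonic_pos}"
            )

    @property
    def intron(self) -> tuple[int, int]:
        """First and last intronic base (STAR ``SJ.out.tab`` convention)."""
        return self.donor_exonic_pos + 1, self.acceptor_exonic_pos - 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.donor_exonic_pos}-{self.acceptor_exonic_pos}"


@dataclass(frozen=True)
class CassetteEvent:
    """A named cassette-exon event.

    Inclusion of the cassette produces every junction in
    ``inclusion_junctions`` (two for a single cassette exon); skipping
    produces the single ``exclusion_junction``.
    """

    name: str
    inclusion_junctions: tuple[JunctionKey, ...]
    exclusion_junction: JunctionKey

    def __post_init__(self) -> None:
        if len(self.inclusion_junctions) < 1:
            raise ModelValidationError(f"event {self.name}: no inclusion junctions")
        if self.exclusion_junction in self.inclusion_junctions:
            raise ModelValidationError(
                f"event {self.name}: exclusion junction duplicates an inclusion junction"
            )
        chroms = {j.chrom for j in self.all_junctions()}
        if len(chroms) != 1:
            raise ModelValidationError(
                f"event {self.name}: junctions span multiple chromosomes {sorted(chroms)}"
            )

    def all_junctions(self) -> tuple[JunctionKey, ...]:
        return (*self.inclusion_junctions, self.exclusion_junction)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    isoforms: dict[str, tuple[GenomicInterval, ...]]
    events: tuple[CassetteEvent, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if not self.gene_id:
            raise ModelValidationError("gene_id must be non-empty")
        for name, exons in self.isoforms.items():
            if not exons:
                raise ModelValidationError(f"isoform {name}: empty exon list")
            for exon in exons:
                if exon.chrom != self.chrom:
                    raise ModelValidationError(
                        f"isoform {name}: exon on {exon.chrom}, gene on {self.chrom}"
                    )
            ordered = sorted(exons, key=lambda e: e.start)
            for left, right in zip(ordered, ordered[1:]):
                if left.end >= right.start:
                    raise ModelValidationError(
                        f"isoform {name}: overlapping exons "
                        f"[{left.start},{left.end}] and [{right.start},{right.end}]"
                    )
            self.isoforms[name] = tuple(ordered)
        starts = {e.start for exons in self.isoforms.values() for e in exons}
        ends = {e.end for exons in self.isoforms.values() for e in exons}
        for event in self.events:
            for junc in event.all_junctions():
                if junc.chrom != self.chrom:
                    raise ModelValidationError(
                        f"event {event.name}: junction on {junc.chrom}, gene on {self.chrom}"
                    )
                if junc.donor_exonic_pos not in ends:
                    raise ModelValidationError(
                        f"event {event.name}: donor position {junc.donor_exonic_pos} "
                        "is not an exon end of any isoform"
                    )
                if junc.acceptor_exonic_pos not in starts:
                    raise ModelValidationError(
                        f"event {event.name}: acceptor position {junc.acceptor_exonic_pos} "
                        "is not an exon start of any isoform"
                    )

    # -- derived quantities ----------------------------------------------
    @property
    def exon_union(self) -> tuple[GenomicInterval, ...]:
        """Merged union of all isoform exons, ascending."""
        intervals = sorted(
            (e for exons in self.isoforms.values() for e in exons),
            key=lambda e: (e.start, e.end),
        )
        merged: list[list[int]] = []
        for iv in intervals:
            if merged and iv.start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], iv.end)
            else:
                merged.append([iv.start, iv.end])
        return tuple(
            GenomicInterval(self.chrom, s, e, self.strand) for s, e in merged
        )

    @property
    def effective_length(self) -> int:
        """Union-exonic length in bases (the TPM effective gene length)."""
        return sum(iv.length for iv in self.exon_union)

    def isoform_length(self, name: str) -> int:
        return sum(e.length for e in self.isoforms[name])

    def event(self, name: str) -> CassetteEvent:
        for ev in self.events:
            if ev.name == name:
                return ev
        raise KeyError(f"no event named {name!r} in gene {self.gene_id}")

    def isoform_junctions(self, name: str) -> tuple[JunctionKey, ...]:
        """Junctions implied by consecutive exons of one isoform."""
        exons = self.isoforms[name]
        return tuple(
            JunctionKey(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(exons, exons[1:])
        )


@dataclass(frozen=True)
class ExonBin:
    """A maximal exonic interval with a constant set of contributing isoforms."""

    interval: GenomicInterval
    bin_id: str
    contributing_isoforms: frozenset[str]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def gene_model_from_dict(doc: Mapping, *, source: str = "<dict>") -> GeneModel:
    try:
        gene_id = str(doc["gene_id"])
        chrom = str(doc["chrom"])
        strand = str(doc["strand"])
        iso_doc = doc["isoforms"]
    except KeyError as exc:
        raise ModelValidationError(f"{source}: missing required field {exc}") from exc
    isoforms: dict[str, tuple[GenomicInterval, ...]] = {}
    for name, pairs in iso_doc.items():
        exons = []
        for pair in pairs:
            if len(pair) != 2:
                raise ModelValidationError(
                    f"{source}: isoform {name}: exon entry {pair!r} is not [start, end]"
                )
            exons.append(GenomicInterval(chrom, int(pair[0]), int(pair[1]), strand))
        isoforms[name] = tuple(exons)
    events = []
    for ev_name, ev_doc in (doc.get("events") or {}).items():
        inclusion = tuple(
            JunctionKey(chrom, int(d), int(a), strand)
            for d, a in ev_doc["inclusion"]
        )
        d, a = ev_doc["exclusion"]
        exclusion = JunctionKey(chrom, int(d), int(a), strand)
        events.append(CassetteEvent(ev_name, inclusion, exclusion))
    return GeneModel(gene_id, chrom, strand, isoforms, tuple(events))


def gene_model_to_dict(model: GeneModel) -> dict:
    return {
        "gene_id": model.gene_id,
        "chrom": model.chrom,
        "strand": model.strand,
        "isoforms": {
            name: [[e.start, e.end] for e in exons]
            for name, exons in model.isoforms.items()
        },
        "events": {
            ev.name: {
                "inclusion": [
                    [j.donor_exonic_pos, j.acceptor_exonic_pos]
                    for j in ev.inclusion_junctions
                ],
                "exclusion": [
                    ev.exclusion_junction.donor_exonic_pos,
                    ev.exclusion_junction.acceptor_exonic_pos,
                ],
            }
            for ev in model.events
        },
    }


def load_gene_model(path: str | Path) -> GeneModel:
    """Load a gene model from its YAML document.

    The document carries ``gene_id``, ``chrom``, ``strand``, ``isoforms``
    (name -> list of ``[start, end]``) and optionally ``events`` (name ->
    ``inclusion`` list + ``exclusion`` pair of flanking exonic positions).
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ModelValidationError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ModelValidationError(f"{path}: expected a mapping at top level")
    return gene_model_from_dict(doc, source=str(path))


def save_gene_model(model: GeneModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(gene_model_to_dict(model), fh, sort_keys=False)


def load_gene_model_from_gff3(
    gff3_path: str | Path,
    event_table_path: str | Path | None = None,
    *,
    gene_id: str | None = None,
) -> GeneModel:
    """Assemble a GeneModel from GFF3 ``exon`` lines plus an event TSV.

    Exon lines must carry ``Parent=`` (the isoform/transcript id) in column 9;
    GFF3 is 1-based inclusive so coordinates pass through unchanged.  The
    event table has columns ``event  role  chrom  donor  acceptor  strand``
    with ``role`` one of ``inclusion``/``exclusion``.
    """
    isoforms: dict[str, list[GenomicInterval]] = {}
    chrom = strand = None
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ModelValidationError(
                    f"{gff3_path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}"
                )
            if cols[2].lower() != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            parent = attrs.get("Parent") or attrs.get("transcript_id")
            if parent is None:
                raise ModelValidationError(
                    f"{gff3_path}:{lineno}: exon line lacks Parent attribute"
                )
            chrom = chrom or cols[0]
            strand = strand or cols[6]
            isoforms.setdefault(parent, []).append(
                GenomicInterval(cols[0], int(cols[3]), int(cols[4]), cols[6])
            )
    if not isoforms:
        raise ModelValidationError(f"{gff3_path}: no exon lines found")

    events: dict[str, dict[str, list]] = {}
    if event_table_path is not None:
        with open(event_table_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("event\t"):
                    continue
                cols = line.split("\t")
                if len(cols) != 6:
                    raise ModelValidationError(
                        f"{event_table_path}:{lineno}: expected 6 columns"
                    )
                name, role, ev_chrom, donor, acceptor, ev_strand = cols
                if role not in {"inclusion", "exclusion"}:
                    raise ModelValidationError(
                        f"{event_table_path}:{lineno}: role must be "
                        f"inclusion/exclusion, got {role!r}"
                    )
                key = JunctionKey(ev_chrom, int(donor), int(acceptor), ev_strand)
                events.setdefault(name, {"inclusion": [], "exclusion": []})[
                    role
                ].append(key)
    built = []
    for name, roles in events.items():
        if len(roles["exclusion"]) != 1:
            raise ModelValidationError(
                f"event {name}: expected exactly one exclusion junction, "
                f"got {len(roles['exclusion'])}"
            )
        built.append(
            CassetteEvent(name, tuple(roles["inclusion"]), roles["exclusion"][0])
        )
    return GeneModel(
        gene_id or f"{chrom}:gene",
        chrom,
        strand,
        {k: tuple(v) for k, v in isoforms.items()},
        tuple(built),
    )


def fixture_names() -> tuple[str, ...]:
    return FIXTURES


def load_fixture(name: str) -> GeneModel:
    """Load a packaged gene-model fixture.

    ``pig_mapt`` and ``human_mapt`` carry the MAPT 3R/4R cassette (exon 10)
    junction coordinates on Sscrofa11.1 chr12 and GRCh38 chr17; the far edges
    of the flanking exons in these two fixtures are nominal synthetic extents
    (only the junction-facing boundaries are meaningful).  ``toy_maptlike``
    is a fully synthetic three-exon cassette gene used by the simulator.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    ref = resources.files("splicequant.data").joinpath(f"{name}.yaml")
    doc = yaml.safe_load(ref.read_text())
    return gene_model_from_dict(doc, source=f"fixture:{name}")


# ---------------------------------------------------------------------------
# exon-bin flattening
# ---------------------------------------------------------------------------

def flatten_exon_bins(model: GeneModel) -> list[ExonBin]:
    """Flatten overlapping isoform exons into disjoint counting bins.

    Every isoform-exon boundary induces a bin boundary, so each bin is a
    maximal exonic run over which the set of contributing isoforms is
    constant.  Bins are returned in ascending genomic order and labelled
    ``<gene_id>:E001`` onward.
    """
    exons = [
        (name, e) for name, ivs in model.isoforms.items() for e in ivs
    ]
    if not exons:
        return []
    # candidate cut points: every exon start, and every exon end + 1
    cuts: set[int] = set()
    for _, e in exons:
        cuts.add(e.start)
        cuts.add(e.end + 1)
    ordered = sorted(cuts)
    bins: list[ExonBin] = []
    raw: list[tuple[int, int, frozenset[str]]] = []
    for lo, hi in zip(ordered, ordered[1:]):
        members = frozenset(
            name for name, e in exons if e.start <= lo and hi - 1 <= e.end
        )
        if members:
            raw.append((lo, hi - 1, members))
    # merge adjacent segments with identical membership (interior cuts from
    # unrelated exons elsewhere in the gene must not split a bin)
    merged: list[list] = []
    for lo, hi, members in raw:
        if merged and merged[-1][2] == members and merged[-1][1] + 1 == lo:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi, members])
    for ordinal, (lo, hi, members) in enumerate(merged, 1):
        bins.append(
            ExonBin(
                GenomicInterval(model.chrom, lo, hi, model.strand),
                f"{model.gene_id}:E{ordinal:03d}",
                members,
            )
        )
    return bins
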