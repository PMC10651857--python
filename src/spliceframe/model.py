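"""Core domain types for event-based alternative-splicing analysis.

An alternative-splicing *event* is a local pair of mutually exclusive
exon-intron structures ("isoform 1" and "isoform 2") of one gene, one of six
types: exon skip, alternative 3'/5' splice site, intron retention, mutually
exclusive exons, and multiple exon skip.  Percent spliced-in (PSI) is always
computed for isoform 2, so PSI near 1 means isoform 2 dominates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

EVENT_TYPES = (
    "exon_skip",
    "alt_3prime",
    "alt_5prime",
    "intron_retention",
    "mutex_exons",
    "mult_exon_skip",
)

#: types where the exon-count rule ("the isoform with more exons is isoform 2")
#: applies; mutex events are ordered by the genomic start of the exclusive exon.
_EXON_COUNT_TYPES = frozenset(EVENT_TYPES) - {"mutex_exons"}


class SpliceframeError(Exception):
    """Base class for data/model errors (maps to CLI exit code 1)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive genomic interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise SpliceframeError(
                f"interval start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise SpliceframeError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and not (
            self.end < other.start or other.end < self.start
        )


@dataclass
class SpliceEvent:
    """One alternative-splicing event: two isoforms as ordered exon lists.

    Exon lists are in transcription order (ascending genomic coordinates on
    '+', descending on '-').  After :func:`normalize_isoforms`, isoform 2 is
    the longer isoform (more exons for skip-type events, more nucleotides
    for intron retention and alternative splice sites), and for mutually
    exclusive exons isoform 1 carries the exclusive exon with the smaller
    genomic start.
    """

    event_id: str
    gene: str
    event_type: str
    chrom: str
    strand: str
    iso1_exons: list[GenomicInterval]
    iso2_exons: list[GenomicInterval]
    novel_iso1: bool = False
    novel_iso2: bool = False
    swapped: bool = False  # set when normalization exchanged the labels

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise SpliceframeError(
                f"{self.event_id}: unknown event type {self.event_type!r}"
            )
        for exons in (self.iso1_exons, self.iso2_exons):
            if not exons:
                raise SpliceframeError(f"{self.event_id}: empty isoform exon list")
        self.iso1_exons = _sort_transcription_order(self.iso1_exons, self.strand)
        self.iso2_exons = _sort_transcription_order(self.iso2_exons, self.strand)

    @property
    def genomic_name(self) -> str:
        return make_genomic_name(self)

    def isoform_length(self, isoform: int) -> int:
        exons = self.iso1_exons if isoform == 1 else self.iso2_exons
        return sum(len(e) for e in exons)


def _sort_transcription_order(
    exons: list[GenomicInterval], strand: str
) -> list[GenomicInterval]:
    ordered = sorted(exons, key=lambda e: e.start, reverse=(strand == "-"))
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise SpliceframeError(
                f"overlapping exons within one isoform: {a} / {b}"
            )
    return ordered


def normalize_isoforms(event: SpliceEvent) -> SpliceEvent:
    """Return the event with isoform labels in canonical order.

    Isoform 2 is the longer isoform: the exon-richer one for skip-type
    events, the nucleotide-longer (retained) form for intron retention, and
    the nucleotide-longer variant for alternative splice-site events (whose
    isoforms have equal exon counts).  Mutually exclusive events instead put
    the genomically first exclusive exon in isoform 1.  Idempotent.  When a
    swap occurs ``swapped`` is set so downstream read counts can be
    exchanged to match.
    """
    swap = False
    if event.event_type == "mutex_exons":
        excl1, excl2 = _mutex_exclusive_exons(event)
        if excl1 is not None and excl2 is not None and excl1.start > excl2.start:
            swap = True
    elif event.event_type == "intron_retention":
        swap = event.isoform_length(2) < event.isoform_length(1)
    elif len(event.iso2_exons) != len(event.iso1_exons):
        swap = len(event.iso2_exons) < len(event.iso1_exons)
    else:
        swap = event.isoform_length(2) < event.isoform_length(1)
    if not swap:
        return event
    return replace(
        event,
        iso1_exons=event.iso2_exons,
        iso2_exons=event.iso1_exons,
        novel_iso1=event.novel_iso2,
        novel_iso2=event.novel_iso1,
        swapped=not event.swapped,
    )


def _mutex_exclusive_exons(
    event: SpliceEvent,
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """The exon unique to each isoform of a mutually-exclusive-exon event."""
    set1 = set(event.iso1_exons)
    set2 = set(event.iso2_exons)
    only1 = sorted(set1 - set2)
    only2 = sorted(set2 - set1)
    return (only1[0] if only1 else None, only2[0] if only2 else None)


def make_genomic_name(event: SpliceEvent) -> str:
    """Deterministic coordinate-based event name.

    Format ``{type}:{chrom}:{strand}:{iso1 blocks}|{iso2 blocks}`` with each
    block ``start-end`` and blocks comma-joined in transcription order.
    Injective over distinct normalized events.
    """

    def blocks(exons: list[GenomicInterval]) -> str:
        return ",".join(f"{e.start}-{e.end}" for e in exons)

    return (
        f"{event.event_type}:{event.chrom}:{event.strand}:"
        f"{blocks(event.iso1_exons)}|{blocks(event.iso2_exons)}"
    )


def compute_psi(
    reads_iso1: int, reads_iso2: int, min_coverage: int = 10
) -> float:
    """PSI of isoform 2: reads_iso2 / (reads_iso1 + reads_iso2).

    Returns ``nan`` (missing) when total coverage is below ``min_coverage``,
    to avoid unstable estimates at low read support.
    """
    if reads_iso1 < 0 or reads_iso2 < 0:
        raise SpliceframeError("read counts must be non-negative")
    total = reads_iso1 + reads_iso2
    if total < min_coverage:
        return math.nan
    return reads_iso2 / total


@dataclass
class SampleMeasurement:
    """Per event x sample isoform read support and derived PSI."""

    event_id: str
    sample_id: str
    group: str
    reads_iso1: int
    reads_iso2: int
    psi: float = field(default=math.nan)

    @classmethod
    def with_psi(
        cls,
        event_id: str,
        sample_id: str,
        group: str,
        reads_iso1: int,
        reads_iso2: int,
        min_coverage: int = 10,
    ) -> "SampleMeasurement":
        return cls(
            event_id,
            sample_id,
            group,
            reads_iso1,
            reads_iso2,
            compute_psi(reads_iso1, reads_iso2, min_coverage),
        )


@dataclass
class Transcript:
    transcript_id: str
    exons: list[GenomicInterval]
    cds_start_offset: int = 0  # nt from transcription start to translation start

    def __post_init__(self) -> None:
        if self.cds_start_offset < 0:
            raise SpliceframeError(
                f"{self.transcript_id}: negative CDS start offset"
            )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    gene: str
    biotype: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass(frozen=True)
class DomainRecord:
    """Protein domain annotation in 1-based amino-acid coordinates."""

    gene: str
    accession: str
    name: str
    aa_start: int
    aa_end: int
    source_db: str = ""

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise SpliceframeError(
                f"domain {self.accession}: aa_start > aa_end"
            )


@dataclass
class FilterConfig:
    """Thresholds of the three pre-test filters.

    Defaults: events need >=10 samples with valid PSI in every group, pooled
    PSI standard deviation >=0.05, total per-sample coverage >=10 for a valid
    PSI, and the host gene must be protein coding.
    """

    min_valid_per_group: int = 10
    min_psi_sd: float = 0.05
    min_coverage: int = 10
    require_protein_coding: bool = True

    def __post_init__(self) -> None:
        if min(self.min_valid_per_group, self.min_psi_sd, self.min_coverage) < 0:
            raise SpliceframeError("filter thresholds must be >= 0")
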