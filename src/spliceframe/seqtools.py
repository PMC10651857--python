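"""Strand-aware exon DNA extraction and codon translation helpers.

Sequences handed to downstream steps are always in transcript orientation
(5'->3'): minus-strand intervals are reverse-complemented at extraction.
Frames are numbered 1/2/3 for codon offsets 0/1/2 on the transcript-oriented
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq
from pyfaidx import Fasta

from .model import GenomicInterval, SpliceframeError

FRAMES = (1, 2, 3)


@dataclass(frozen=True)
class ExonSequence:
    """Exon DNA in transcript orientation (already reverse-complemented
    for '-' strand intervals)."""

    interval: GenomicInterval
    dna: str

    def __post_init__(self) -> None:
        if len(self.dna) != len(self.interval):
            raise SpliceframeError(
                f"sequence length {len(self.dna)} != interval span "
                f"{len(self.interval)}"
            )


class Genome:
    """Random access to a genome FASTA (indexed via faidx when available)."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), sequence_always_upper=True, rebuild=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive fetch on the forward strand."""
        if chrom not in self._fasta:
            raise SpliceframeError(f"chromosome {chrom!r} not in genome")
        if not (1 <= start <= end <= len(self._fasta[chrom])):
            raise SpliceframeError(
                f"coordinates {chrom}:{start}-{end} outside chromosome "
                f"(length {len(self._fasta[chrom])})"
            )
        return str(self._fasta[chrom][start - 1 : end]).upper()


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def extract_exon_dna(genome: Genome, interval: GenomicInterval) -> ExonSequence:
    """Fetch the exon sequence, reverse-complemented on the '-' strand."""
    seq = genome.fetch(interval.chrom, interval.start, interval.end)
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return ExonSequence(interval, seq)


def translate(dna: str, frame: int = 1) -> str:
    """Translate with the standard code from the given frame (1|2|3).

    Stops are '*', codons containing N become 'X', and 1-2 trailing
    nucleotides are dropped.  Translation does not halt at stop codons.
    """
    if frame not in FRAMES:
        raise SpliceframeError(f"frame must be 1, 2 or 3, got {frame}")
    sub = dna[frame - 1 :]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def translate_all_frames(dna: str) -> dict[int, str]:
    return {f: translate(dna, f) for f in FRAMES}


def assemble_isoform_dna(exon_sequences: list[ExonSequence]) -> str:
    """Concatenate exon sequences already in transcription (5'->3') order."""
    return "".join(e.dna for e in exon_sequences)


def isoform_dna(genome: Genome, exons: list[GenomicInterval]) -> str:
    """Extract and assemble an isoform's DNA from its ordered exon list."""
    return assemble_isoform_dna([extract_exon_dna(genome, e) for e in exons])
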