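"""Protein-level comparison of the two isoforms of an event.

Both isoforms are translated in the predicted frame (stops retained as '*',
no truncation) and the pair of peptides is decomposed into four segments:
the longest common prefix (same start), the isoform-specific middles, and
the longest common suffix of the post-prefix remainders (same end).  The
decomposition is exact: prefix + middle + suffix reassembles each input.
Frameshifts are flagged when the isoforms' non-shared nucleotide lengths
differ by a non-multiple of 3, and the first stop codon of each isoform is
mapped back to a genomic coordinate through the exon structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import SpliceEvent, SpliceframeError
from .seqtools import Genome, isoform_dna, translate


@dataclass
class ProteinDiff:
    event_id: str
    frame: int
    aa_iso1: str
    aa_iso2: str
    same_start_aa: str
    diff_aa_iso1: str
    diff_aa_iso2: str
    same_end_aa: str
    stop_pos_iso1: int | None  # 1-based residue index of first '*'
    stop_pos_iso2: int | None
    stop_genomic_iso1: int | None  # first base of the stop codon
    stop_genomic_iso2: int | None
    frameshift: bool


def translate_isoforms(
    event: SpliceEvent, frame: int, genome: Genome
) -> tuple[str, str]:
    """Translate both assembled isoforms from the shared frame.

    Internal stop codons are kept as '*' so the output reflects the full
    read-through peptide; consumers can cut at the reported stop position.
    """
    if frame not in (1, 2, 3):
        raise SpliceframeError(f"cannot translate with unresolved frame {frame!r}")
    return (
        translate(isoform_dna(genome, event.iso1_exons), frame),
        translate(isoform_dna(genome, event.iso2_exons), frame),
    )


def diff_isoforms(aa_iso1: str, aa_iso2: str) -> tuple[str, str, str, str]:
    """Four-segment decomposition (same_start, diff1, diff2, same_end).

    The prefix is the longest common prefix of the two peptides; the suffix
    is the longest common suffix of what remains, so the segments never
    overlap and ties favor the prefix.
    """
    k = 0
    limit = min(len(aa_iso1), len(aa_iso2))
    while k < limit and aa_iso1[k] == aa_iso2[k]:
        k += 1
    rem1, rem2 = aa_iso1[k:], aa_iso2[k:]
    s = 0
    limit = min(len(rem1), len(rem2))
    while s < limit and rem1[len(rem1) - 1 - s] == rem2[len(rem2) - 1 - s]:
        s += 1
    suffix = rem1[len(rem1) - s :] if s else ""
    return (
        aa_iso1[:k],
        rem1[: len(rem1) - s],
        rem2[: len(rem2) - s],
        suffix,
    )


def detect_frameshift(event: SpliceEvent) -> bool:
    """True iff the isoform length difference is not a multiple of 3.

    The shared flanking segments are identical in both isoforms, so the
    total nucleotide length difference equals the middle (non-shared)
    difference, and a non-multiple of 3 shifts the codon phase downstream.
    """
    return (event.isoform_length(1) - event.isoform_length(2)) % 3 != 0


def map_aa_to_genomic(
    event: SpliceEvent, frame: int, residue_index: int, isoform: int
) -> int:
    """Genomic position of the first base of a residue's codon.

    ``residue_index`` is 1-based on the isoform's translation in ``frame``.
    The transcript offset (frame - 1) + 3 * (residue - 1) is walked through
    the isoform's exons in transcription order, strand-aware.
    """
    if isoform not in (1, 2):
        raise SpliceframeError("isoform must be 1 or 2")
    exons = event.iso1_exons if isoform == 1 else event.iso2_exons
    offset = (frame - 1) + 3 * (residue_index - 1)
    total = sum(len(e) for e in exons)
    if residue_index < 1 or offset + 3 > total:
        raise SpliceframeError(
            f"{event.event_id}: residue {residue_index} beyond isoform {isoform} "
            f"peptide (frame {frame})"
        )
    for exon in exons:
        if offset < len(exon):
            if event.strand == "+":
                return exon.start + offset
            return exon.end - offset
        offset -= len(exon)
    raise AssertionError("unreachable")


def _first_stop(aa: str) -> int | None:
    idx = aa.find("*")
    return idx + 1 if idx >= 0 else None


def protein_diff(
    event: SpliceEvent, frame: int, genome: Genome
) -> ProteinDiff:
    """Full protein-level comparison for one event in a resolved frame."""
    aa1, aa2 = translate_isoforms(event, frame, genome)
    same_start, diff1, diff2, same_end = diff_isoforms(aa1, aa2)
    stop1, stop2 = _first_stop(aa1), _first_stop(aa2)
    return ProteinDiff(
        event_id=event.event_id,
        frame=frame,
        aa_iso1=aa1,
        aa_iso2=aa2,
        same_start_aa=same_start,
        diff_aa_iso1=diff1,
        diff_aa_iso2=diff2,
        same_end_aa=same_end,
        stop_pos_iso1=stop1,
        stop_pos_iso2=stop2,
        stop_genomic_iso1=(
            map_aa_to_genomic(event, frame, stop1, 1) if stop1 else None
        ),
        stop_genomic_iso2=(
            map_aa_to_genomic(event, frame, stop2, 2) if stop2 else None
        ),
        frameshift=detect_frameshift(event),
    )


def diffs_table(diffs: list[ProteinDiff]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [d.event_id for d in diffs],
            "aa_iso1": [d.aa_iso1 for d in diffs],
            "aa_iso2": [d.aa_iso2 for d in diffs],
            "same_start_aa": [d.same_start_aa for d in diffs],
            "diff_aa_iso1": [d.diff_aa_iso1 for d in diffs],
            "diff_aa_iso2": [d.diff_aa_iso2 for d in diffs],
            "same_end_aa": [d.same_end_aa for d in diffs],
            "stop_in_iso1": [d.stop_pos_iso1 for d in diffs],
            "stop_in_iso2": [d.stop_pos_iso2 for d in diffs],
            "stop_genomic_iso1": [d.stop_genomic_iso1 for d in diffs],
            "stop_genomic_iso2": [d.stop_genomic_iso2 for d in diffs],
            "frameshift": [d.frameshift for d in diffs],
        }
    )
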