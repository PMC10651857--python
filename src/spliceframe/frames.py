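"""Reading-frame prediction for alternative-splicing events.

Translating a full isoform in all frames usually hits stop codons in more
than one frame, so the frame is predicted from the event's first 5' exon,
which both isoforms share.  Two independent methods are used:

* ORF method — translate the exon in all three frames; if exactly one frame
  is free of stop codons, that frame is called.
* Peptide-match method — translate the exon in all three frames, truncate at
  the first stop, and search each peptide as an exact substring of the
  gene's known proteins; if exactly one frame has matches and the other two
  have none, that frame is called.

If both are ambiguous, a fallback counts internal stop codons of the full
assembled isoform in all frames and calls the single clean frame, if any.
Events that remain ambiguous get frame "X".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .model import GenomicInterval, SpliceEvent, SpliceframeError
from .seqtools import FRAMES, Genome, extract_exon_dna, isoform_dna, translate

logger = logging.getLogger(__name__)

UNKNOWN = "X"


def _label(frame: int | None) -> str:
    return UNKNOWN if frame is None else str(frame)


@dataclass
class FramePrediction:
    """Per-event frame call with the evidence of each method."""

    event_id: str
    frame: str  # "1" | "2" | "3" | "X"
    orf_method_frame: str
    peptide_method_frame: str
    fallback_frame: str
    resolved_by: str  # both_agree | orf_only | peptide_only | fallback |
    #                   unresolved | conflict
    match_counts: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})


def first_5prime_exon(event: SpliceEvent) -> GenomicInterval | None:
    """The 5'-most exon segment shared by both isoforms.

    If both isoforms start with the same exon, that exon is returned.  When
    the first exons share their 5' boundary but differ in length (intron
    retention, where isoform 1's first exon is a prefix of isoform 2's
    merged exon; alternative 5' sites, where the donor moves), the shared 5'
    prefix is returned.  Returns None when no 5' segment is shared.
    """
    e1 = event.iso1_exons[0]
    e2 = event.iso2_exons[0]
    if e1 == e2:
        return e1
    if event.strand == "+":
        if e1.start == e2.start:
            return GenomicInterval(e1.chrom, e1.start, min(e1.end, e2.end), "+")
    else:
        if e1.end == e2.end:
            return GenomicInterval(e1.chrom, max(e1.start, e2.start), e1.end, "-")
    return None


def orf_method(first_exon_dna: str) -> int | None:
    """Call the frame iff exactly one frame translates without a stop codon.

    Frames with an empty translation (exon shorter than frame offset + 3)
    carry no evidence and are not counted as open.
    """
    if len(first_exon_dna) < 3:
        return None
    open_frames = []
    for f in FRAMES:
        pep = translate(first_exon_dna, f)
        if pep and "*" not in pep:
            open_frames.append(f)
    return open_frames[0] if len(open_frames) == 1 else None


def peptide_match_method(
    first_exon_dna: str,
    known_proteins: list[str],
    min_match_len: int = 7,
) -> tuple[int | None, dict[int, int]]:
    """Call the frame by exact peptide matching against known proteins.

    Each frame's translation is truncated at its first stop (the stop itself
    excluded); peptides shorter than ``min_match_len`` are skipped.  The
    match count of a frame is the number of known proteins containing its
    peptide as an exact substring.  A frame is called iff it has matches and
    the other two frames have zero.
    """
    counts = {f: 0 for f in FRAMES}
    if not known_proteins:
        logger.info("no known proteins supplied; peptide method returns X")
        return None, counts
    for f in FRAMES:
        pep = translate(first_exon_dna, f).split("*")[0]
        if len(pep) < min_match_len:
            continue
        counts[f] = sum(1 for prot in known_proteins if pep in prot)
    hits = [f for f in FRAMES if counts[f] > 0]
    return (hits[0], counts) if len(hits) == 1 else (None, counts)


def combine_methods(
    orf_frame: int | None, peptide_frame: int | None
) -> tuple[int | None, str]:
    """Reconcile the two methods into a frame call and its provenance."""
    if orf_frame is not None and peptide_frame is not None:
        if orf_frame == peptide_frame:
            return orf_frame, "both_agree"
        logger.warning(
            "frame conflict: ORF method %s vs peptide method %s",
            orf_frame, peptide_frame,
        )
        return None, "conflict"
    if orf_frame is not None:
        return orf_frame, "orf_only"
    if peptide_frame is not None:
        return peptide_frame, "peptide_only"
    return None, "unresolved"


def _internal_stop_count(peptide: str) -> int:
    """Stops excluding a single terminal stop as the last codon."""
    stops = peptide.count("*")
    if peptide.endswith("*"):
        stops -= 1
    return stops


def fallback_full_isoform(
    iso2_dna: str, iso1_dna: str | None = None, require_both: bool = False
) -> int | None:
    """Call the single frame in which the full isoform has no internal stop.

    Counts stop codons of the assembled isoform-2 DNA in all three frames; a
    terminal stop as the last codon does not count.  With ``require_both``
    the frame must also be clean on isoform 1.
    """
    clean = []
    for f in FRAMES:
        if _internal_stop_count(translate(iso2_dna, f)) > 0:
            continue
        if require_both and iso1_dna is not None:
            if _internal_stop_count(translate(iso1_dna, f)) > 0:
                continue
        clean.append(f)
    return clean[0] if len(clean) == 1 else None


def predict_frame(
    event: SpliceEvent,
    genome: Genome,
    known_proteins: list[str],
    min_match_len: int = 7,
    fallback_require_both: bool = False,
) -> FramePrediction:
    """Run the full frame-prediction cascade for one event."""
    shared = first_5prime_exon(event)
    if shared is None:
        logger.warning("%s: isoforms share no 5' exon; frame X", event.event_id)
        return FramePrediction(
            event.event_id, UNKNOWN, UNKNOWN, UNKNOWN, UNKNOWN, "unresolved"
        )
    exon_dna = extract_exon_dna(genome, shared).dna
    orf_frame = orf_method(exon_dna)
    pep_frame, counts = peptide_match_method(exon_dna, known_proteins, min_match_len)
    frame, resolved_by = combine_methods(orf_frame, pep_frame)
    fallback = None
    if resolved_by == "unresolved":
        fallback = fallback_full_isoform(
            isoform_dna(genome, event.iso2_exons),
            isoform_dna(genome, event.iso1_exons),
            require_both=fallback_require_both,
        )
        if fallback is not None:
            frame, resolved_by = fallback, "fallback"
    return FramePrediction(
        event_id=event.event_id,
        frame=_label(frame),
        orf_method_frame=_label(orf_frame),
        peptide_method_frame=_label(pep_frame),
        fallback_frame=_label(fallback),
        resolved_by=resolved_by,
        match_counts=counts,
    )


def frames_table(predictions: list[FramePrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [p.event_id for p in predictions],
            "frame": [p.frame for p in predictions],
            "orf_method_frame": [p.orf_method_frame for p in predictions],
            "peptide_method_frame": [p.peptide_method_frame for p in predictions],
            "fallback_frame": [p.fallback_frame for p in predictions],
            "resolved_by": [p.resolved_by for p in predictions],
            "match_f1": [p.match_counts[1] for p in predictions],
            "match_f2": [p.match_counts[2] for p in predictions],
            "match_f3": [p.match_counts[3] for p in predictions],
        }
    )


def agreement_matrix(predictions: list[FramePrediction]) -> pd.DataFrame:
    """ORF-method x peptide-method contingency table (frames 1/2/3/X)."""
    labels = ["1", "2", "3", UNKNOWN]
    df = pd.DataFrame(
        0, index=pd.Index(labels, name="orf_method"),
        columns=pd.Index(labels, name="peptide_method"),
    )
    for p in predictions:
        df.loc[p.orf_method_frame, p.peptide_method_frame] += 1
    return df
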