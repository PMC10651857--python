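"""Event, transcript-context and protein-domain figures.

Every figure is driven by an intermediate coordinate table that is exposed
for testing; rendering only draws what the table says.  Three views are
produced per event: a zoomed-in view of the two isoforms annotated with
protein changes (light blue exons translate identically in both isoforms,
light green exons carry altered peptide, red lines mark first stop codons)
next to a per-sample PSI jitter panel; a zoomed-out view aligning the event
with the best-matching annotated transcript; and a collapsed-exon view
aligned with protein domains, whose amino-acid coordinates are converted to
transcript nucleotides using the 5'UTR offset (distance from transcription
start to translation start).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .model import (
    DomainRecord,
    GeneModel,
    GenomicInterval,
    SpliceEvent,
    Transcript,
)
from .protein import ProteinDiff

logger = logging.getLogger(__name__)

SAME_COLOR = "lightblue"
DIFF_COLOR = "lightgreen"
STOP_COLOR = "red"

_QUALITY_RANK = {"both_exons_exact": 3, "one_exon_exact": 2, "overlap_only": 1,
                 "none": 0}


@dataclass(frozen=True)
class TranscriptMatch:
    event_id: str
    transcript_id: str | None
    match_quality: str  # both_exons_exact | one_exon_exact | overlap_only | none


@dataclass(frozen=True)
class CollapsedDomain:
    """Domain span on the collapsed (intron-free) transcript, 1-based nt."""

    accession: str
    name: str
    nt_start: int
    nt_end: int


def match_transcript(event: SpliceEvent, gene_model: GeneModel) -> TranscriptMatch:
    """Pick the annotated transcript that best fits the event flanks.

    Transcripts are ranked by how well the event's first and last exons
    match annotated exon boundaries: both exact > one exact > any coordinate
    overlap > none.  Ties go to the longer transcript, then the
    lexicographically smaller ID.
    """
    first, last = event.iso2_exons[0], event.iso2_exons[-1]
    best: tuple[int, int, str] | None = None
    best_tx: Transcript | None = None
    best_quality = "none"
    for tx in gene_model.transcripts:
        boundaries = {(e.start, e.end) for e in tx.exons}
        exact = sum(
            1 for e in (first, last) if (e.start, e.end) in boundaries
        )
        if exact == 2:
            quality = "both_exons_exact"
        elif exact == 1:
            quality = "one_exon_exact"
        elif any(e.overlaps(x) for e in (first, last) for x in tx.exons):
            quality = "overlap_only"
        else:
            quality = "none"
        key = (_QUALITY_RANK[quality], tx.length, tx.transcript_id)
        # higher rank, then longer transcript, then smaller ID wins
        if best is None or (key[0], key[1], _NegStr(key[2])) > (
            best[0], best[1], _NegStr(best[2])
        ):
            best, best_tx, best_quality = key, tx, quality
    if best_tx is None or best_quality == "none":
        return TranscriptMatch(event.event_id, None, "none")
    return TranscriptMatch(event.event_id, best_tx.transcript_id, best_quality)


class _NegStr(str):
    """Orders strings descending so that smaller IDs win in a max compare."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def collapse_domains(domains: list[DomainRecord]) -> list[DomainRecord]:
    """Merge overlapping records of the same domain by interval union.

    Different member databases predict slightly different boundaries for the
    same domain; records sharing an accession (falling back to name) are
    merged so each domain is drawn once.
    """
    groups: dict[str, list[DomainRecord]] = {}
    for d in domains:
        groups.setdefault(d.accession or d.name, []).append(d)
    merged: list[DomainRecord] = []
    for key, recs in groups.items():
        recs.sort(key=lambda d: d.aa_start)
        current = recs[0]
        for d in recs[1:]:
            if d.aa_start <= current.aa_end + 1:
                current = DomainRecord(
                    current.gene, current.accession, current.name,
                    current.aa_start, max(current.aa_end, d.aa_end),
                    current.source_db,
                )
            else:
                merged.append(current)
                current = d
        merged.append(current)
    return sorted(merged, key=lambda d: (d.aa_start, d.accession))


def domain_to_collapsed_coords(
    domains: list[DomainRecord],
    cds_start_offset: int,
    transcript_exons: list[GenomicInterval],
) -> list[CollapsedDomain]:
    """Convert amino-acid domain spans to collapsed-transcript nucleotides.

    nt_start = offset + 3*(aa_start - 1) + 1 and nt_end = offset + 3*aa_end
    on the intron-free transcript; spans beyond the transcript length are
    clipped with a warning.
    """
    tx_len = sum(len(e) for e in transcript_exons)
    out = []
    for d in collapse_domains(domains):
        nt_start = cds_start_offset + 3 * (d.aa_start - 1) + 1
        nt_end = cds_start_offset + 3 * d.aa_end
        if nt_start > tx_len:
            logger.warning("domain %s entirely past transcript end; skipped",
                           d.accession)
            continue
        if nt_end > tx_len:
            logger.warning("domain %s clipped at transcript end", d.accession)
            nt_end = tx_len
        out.append(CollapsedDomain(d.accession, d.name, nt_start, nt_end))
    return out


def collapsed_exon_coords(
    transcript_exons: list[GenomicInterval],
) -> pd.DataFrame:
    """Collapsed (intron-free) start/end of each exon, in transcription order."""
    rows, pos = [], 0
    for i, e in enumerate(transcript_exons, start=1):
        rows.append(
            {"exon_index": i, "genomic_start": e.start, "genomic_end": e.end,
             "nt_start": pos + 1, "nt_end": pos + len(e)}
        )
        pos += len(e)
    return pd.DataFrame(rows)


def _exon_residue_span(
    exons: list[GenomicInterval], exon_index: int, frame: int
) -> tuple[int, int]:
    """1-based residue range whose codons overlap the given exon."""
    upstream = sum(len(e) for e in exons[:exon_index])
    a = upstream + 1  # first transcript nt of the exon, 1-based
    b = upstream + len(exons[exon_index])
    first = max(1, (a - 1 - (frame - 1)) // 3 + 1) if a > frame - 1 else 1
    last = (b - 1 - (frame - 1)) // 3 + 1 if b >= frame - 1 + 3 else 0
    return first, last


def event_figure_data(
    event: SpliceEvent, diff: ProteinDiff | None
) -> pd.DataFrame:
    """Exon boxes for the zoomed-in figure with protein-change colors.

    An exon is "same" (light blue) iff every residue its bases contribute to
    lies in the shared prefix or shared suffix of the two peptides;
    otherwise it is light green.  Without a protein diff (frame X) all exons
    are uncolored.
    """
    rows = []
    for isoform, exons in ((1, event.iso1_exons), (2, event.iso2_exons)):
        aa = (diff.aa_iso1 if isoform == 1 else diff.aa_iso2) if diff else ""
        prefix_end = len(diff.same_start_aa) if diff else 0
        suffix_start = len(aa) - len(diff.same_end_aa) + 1 if diff else 0
        for i, exon in enumerate(exons):
            color = "none"
            if diff is not None:
                r1, r2 = _exon_residue_span(exons, i, diff.frame)
                if r2 < r1:  # exon too short to own a codon
                    color = SAME_COLOR
                elif r2 <= prefix_end or r1 >= suffix_start:
                    color = SAME_COLOR
                else:
                    color = DIFF_COLOR
            rows.append(
                {"isoform": isoform, "exon_index": i + 1, "start": exon.start,
                 "end": exon.end, "color": color}
            )
    df = pd.DataFrame(rows)
    stops = []
    if diff is not None:
        for isoform, pos in ((1, diff.stop_genomic_iso1), (2, diff.stop_genomic_iso2)):
            if pos is not None:
                stops.append({"isoform": isoform, "stop_genomic": pos})
    df.attrs["stops"] = pd.DataFrame(stops, columns=["isoform", "stop_genomic"])
    df.attrs["frameshift"] = bool(diff.frameshift) if diff else False
    return df


def domain_figure_data(
    event: SpliceEvent,
    transcript: Transcript,
    domains: list[DomainRecord],
) -> tuple[pd.DataFrame, list[CollapsedDomain]]:
    """Coordinate tables for the collapsed exon/domain alignment figure."""
    exons = collapsed_exon_coords(transcript.exons)
    event_spans = {(e.start, e.end) for e in event.iso2_exons + event.iso1_exons}
    exons["in_event"] = [
        (gs, ge) in event_spans
        for gs, ge in zip(exons["genomic_start"], exons["genomic_end"])
    ]
    collapsed = domain_to_collapsed_coords(
        domains, transcript.cds_start_offset, transcript.exons
    )
    return exons, collapsed


def _draw_exon_track(ax, exons, y, color_by=None, height=0.3):
    for _, row in exons.iterrows():
        color = row[color_by] if color_by else "steelblue"
        if color == "none":
            color = "lightgray"
        ax.add_patch(
            plt.Rectangle((row["start"], y - height / 2),
                          row["end"] - row["start"] + 1, height,
                          facecolor=color, edgecolor="black", linewidth=0.6)
        )


def render_event_figure(
    event: SpliceEvent,
    stats_row: dict | pd.Series | None,
    diff: ProteinDiff | None,
    psi: pd.DataFrame | None,
    out_path: str | Path,
) -> pd.DataFrame:
    """Zoomed-in event view plus PSI jitter panel; returns the data table."""
    data = event_figure_data(event, diff)
    fig, (ax, axp) = plt.subplots(
        1, 2, figsize=(9, 2.8), gridspec_kw={"width_ratios": [3, 1]}
    )
    for isoform, y in ((1, 1.0), (2, 0.0)):
        sub = data[data["isoform"] == isoform].rename(
            columns={"start": "start", "end": "end"}
        )
        _draw_exon_track(ax, sub, y, color_by="color")
        if len(sub) > 1:
            for a, b in zip(sub.itertuples(), list(sub.itertuples())[1:]):
                lo, hi = sorted([min(a.end, b.end), max(a.start, b.start)])
                ax.plot([lo, hi], [y, y], color="black", linewidth=0.8, zorder=0)
    for _, s in data.attrs["stops"].iterrows():
        y = 1.0 if s["isoform"] == 1 else 0.0
        ax.plot([s["stop_genomic"]] * 2, [y - 0.25, y + 0.25],
                color=STOP_COLOR, linewidth=1.6)
    lo = min(data["start"]) ; hi = max(data["end"])
    pad = max(10, (hi - lo) // 20)
    ax.set_xlim(lo - pad, hi + pad)
    ax.set_ylim(-0.6, 1.6)
    ax.set_yticks([1.0, 0.0])
    ax.set_yticklabels(["isoform 1", "isoform 2"])
    title = f"{event.gene}  {event.event_id}  {event.chrom}({event.strand})"
    if stats_row is not None and "p_adj" in dict(stats_row):
        title += f"  adj p={dict(stats_row)['p_adj']:.2g}"
    ax.set_title(title, fontsize=9)

    if psi is not None and len(psi):
        rng = np.random.default_rng(0)
        for i, (group, sub) in enumerate(sorted(psi.groupby("group"))):
            x = i + rng.uniform(-0.15, 0.15, len(sub))
            axp.plot(x, sub["psi"], "o", markersize=3, alpha=0.7)
        axp.set_xticks(range(psi["group"].nunique()))
        axp.set_xticklabels(sorted(psi["group"].unique()), fontsize=8)
        axp.set_ylim(-0.05, 1.05)
        axp.set_ylabel("PSI (isoform 2)", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return data


def render_transcript_figure(
    event: SpliceEvent,
    match: TranscriptMatch,
    gene_model: GeneModel,
    out_path: str | Path,
) -> pd.DataFrame | None:
    """Zoomed-out view of the event against the best-matching transcript."""
    if match.transcript_id is None:
        logger.warning("%s: no matching transcript; figure skipped",
                       event.event_id)
        return None
    tx = next(t for t in gene_model.transcripts
              if t.transcript_id == match.transcript_id)
    tx_rows = pd.DataFrame(
        {"start": [e.start for e in tx.exons], "end": [e.end for e in tx.exons]}
    )
    ev_rows = pd.DataFrame(
        {"start": [e.start for e in event.iso2_exons],
         "end": [e.end for e in event.iso2_exons]}
    )
    fig, ax = plt.subplots(figsize=(9, 2))
    _draw_exon_track(ax, tx_rows, 0.0)
    ev_rows["color"] = DIFF_COLOR
    _draw_exon_track(ax, ev_rows, 1.0, color_by="color")
    lo = min(tx_rows["start"].min(), ev_rows["start"].min())
    hi = max(tx_rows["end"].max(), ev_rows["end"].max())
    ax.plot([lo, hi], [0, 0], color="black", linewidth=0.6, zorder=0)
    ax.set_xlim(lo - 50, hi + 50)
    ax.set_ylim(-0.6, 1.6)
    ax.set_yticks([1.0, 0.0])
    ax.set_yticklabels(["event", match.transcript_id])
    ax.set_title(f"{event.gene} ({match.match_quality})", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return tx_rows


def render_domain_figure(
    event: SpliceEvent,
    transcript: Transcript,
    domains: list[DomainRecord],
    out_path: str | Path,
) -> tuple[pd.DataFrame, list[CollapsedDomain]]:
    """Collapsed exons aligned with protein-domain bars."""
    exons, collapsed = domain_figure_data(event, transcript, domains)
    if not collapsed:
        logger.info("%s: no domains to draw; exon track only", event.event_id)
    fig, ax = plt.subplots(figsize=(9, 2.2))
    for _, row in exons.iterrows():
        ax.add_patch(
            plt.Rectangle((row["nt_start"], 0.85),
                          row["nt_end"] - row["nt_start"] + 1, 0.3,
                          facecolor=DIFF_COLOR if row["in_event"] else "lightgray",
                          edgecolor="black", linewidth=0.6)
        )
    for i, dom in enumerate(collapsed):
        y = 0.35 - 0.18 * (i % 2)
        ax.add_patch(
            plt.Rectangle((dom.nt_start, y), dom.nt_end - dom.nt_start + 1, 0.12,
                          facecolor="mediumpurple", edgecolor="black",
                          linewidth=0.5)
        )
        ax.text(dom.nt_start, y - 0.08, dom.name, fontsize=6, va="top")
    total = exons["nt_end"].max() if len(exons) else 1
    ax.set_xlim(0, total * 1.02)
    ax.set_ylim(-0.3, 1.4)
    ax.set_yticks([])
    ax.set_title(f"{event.gene} {transcript.transcript_id} collapsed exons "
                 "and domains", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return exons, collapsed
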