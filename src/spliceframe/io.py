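"""Readers and writers for the interchange formats.

All tables are plain TSV.  Coordinates are 1-based inclusive (Ensembl
convention); conversion to 0-based half-open happens only at FASTA
extraction.

events.tsv      event_id, gene, event_type, chrom, strand,
                iso1_exons ("100-150;300-350"), iso2_exons,
                novel_iso1, novel_iso2
counts.tsv      event_id, sample_id, group, reads_iso1, reads_iso2
annotation.tsv  gene, biotype, transcript_id, chrom, strand,
                exons ("start-end;..."), cds_start_offset
domains.tsv     gene, accession, name, aa_start, aa_end, source_db
proteins.fa     FASTA; the owning gene is parsed from the description with a
                configurable regex (default ``gene=(\\S+)``)
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    DomainRecord,
    GeneModel,
    GenomicInterval,
    SpliceEvent,
    SpliceframeError,
    Transcript,
    compute_psi,
    normalize_isoforms,
)

_EVENT_COLUMNS = [
    "event_id",
    "gene",
    "event_type",
    "chrom",
    "strand",
    "iso1_exons",
    "iso2_exons",
]

RESULTS_COLUMNS = [
    "event_id",
    "genomic_name",
    "gene",
    "event_type",
    "chrom",
    "strand",
    "n_valid_case",
    "n_valid_control",
    "mean_psi_case",
    "mean_psi_control",
    "delta_psi",
    "p_value",
    "p_adj",
    "frame",
    "frame_method",
    "aa_iso1",
    "aa_iso2",
    "same_start_aa",
    "diff_aa_iso1",
    "diff_aa_iso2",
    "same_end_aa",
    "stop_in_iso1",
    "stop_in_iso2",
    "frameshift",
]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpliceframeError(f"{what}: missing required column(s) {missing}")


def parse_exon_blocks(spec: str, chrom: str, strand: str) -> list[GenomicInterval]:
    """Parse ``"100-150;300-350"`` into a list of intervals."""
    exons = []
    for block in str(spec).split(";"):
        block = block.strip()
        if not block:
            continue
        m = re.fullmatch(r"(\d+)-(\d+)", block)
        if not m:
            raise SpliceframeError(f"malformed exon block {block!r}")
        exons.append(GenomicInterval(chrom, int(m.group(1)), int(m.group(2)), strand))
    if not exons:
        raise SpliceframeError(f"empty exon list {spec!r}")
    return exons


def format_exon_blocks(exons: list[GenomicInterval]) -> str:
    return ";".join(f"{e.start}-{e.end}" for e in exons)


def _as_bool(value) -> bool:
    return str(value).strip().lower() in ("1", "true", "yes")


def read_event_table(path: str | Path) -> list[SpliceEvent]:
    """Read and normalize the event-level table.

    Every row becomes a :class:`SpliceEvent` with canonical isoform order.
    Malformed coordinates are fatal and name the offending row/event.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _EVENT_COLUMNS, f"event table {path}")
    events = []
    for idx, row in df.iterrows():
        try:
            event = SpliceEvent(
                event_id=row["event_id"],
                gene=row["gene"],
                event_type=row["event_type"],
                chrom=row["chrom"],
                strand=row["strand"],
                iso1_exons=parse_exon_blocks(
                    row["iso1_exons"], row["chrom"], row["strand"]
                ),
                iso2_exons=parse_exon_blocks(
                    row["iso2_exons"], row["chrom"], row["strand"]
                ),
                novel_iso1=_as_bool(row.get("novel_iso1", False)),
                novel_iso2=_as_bool(row.get("novel_iso2", False)),
            )
        except SpliceframeError as err:
            raise SpliceframeError(
                f"event table row {idx + 1} ({row['event_id']}): {err}"
            ) from err
        events.append(normalize_isoforms(event))
    return events


def write_event_table(events: list[SpliceEvent], path: str | Path) -> None:
    rows = [
        {
            "event_id": e.event_id,
            "gene": e.gene,
            "event_type": e.event_type,
            "chrom": e.chrom,
            "strand": e.strand,
            "iso1_exons": format_exon_blocks(e.iso1_exons),
            "iso2_exons": format_exon_blocks(e.iso2_exons),
            "novel_iso1": e.novel_iso1,
            "novel_iso2": e.novel_iso2,
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts_table(
    path: str | Path,
    events: list[SpliceEvent] | None = None,
    min_coverage: int = 10,
) -> pd.DataFrame:
    """Read per-sample isoform read counts and attach PSI.

    When ``events`` is given, counts of events whose isoform labels were
    swapped during normalization are swapped too, so reads_iso2 always refers
    to the canonical isoform 2.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df,
        ["event_id", "sample_id", "group", "reads_iso1", "reads_iso2"],
        f"counts table {path}",
    )
    if (df["reads_iso1"] < 0).any() or (df["reads_iso2"] < 0).any():
        raise SpliceframeError(f"counts table {path}: negative read counts")
    if events is not None:
        swapped = {e.event_id for e in events if e.swapped}
        if swapped:
            mask = df["event_id"].isin(swapped)
            df.loc[mask, ["reads_iso1", "reads_iso2"]] = df.loc[
                mask, ["reads_iso2", "reads_iso1"]
            ].to_numpy()
    df["psi"] = add_psi(df, min_coverage)
    return df


def add_psi(counts: pd.DataFrame, min_coverage: int = 10) -> pd.Series:
    """Vectorized PSI with the missingness rule of :func:`compute_psi`."""
    total = counts["reads_iso1"] + counts["reads_iso2"]
    psi = counts["reads_iso2"] / total.where(total > 0)
    return psi.where(total >= min_coverage, np.nan)


def read_annotation_table(path: str | Path) -> dict[str, GeneModel]:
    """Read the simplified one-row-per-transcript annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(
        df,
        ["gene", "biotype", "transcript_id", "chrom", "strand", "exons",
         "cds_start_offset"],
        f"annotation {path}",
    )
    genes: dict[str, GeneModel] = {}
    for _, row in df.iterrows():
        model = genes.setdefault(row["gene"], GeneModel(row["gene"], row["biotype"]))
        model.transcripts.append(
            Transcript(
                transcript_id=row["transcript_id"],
                exons=parse_exon_blocks(row["exons"], row["chrom"], row["strand"]),
                cds_start_offset=int(row["cds_start_offset"]),
            )
        )
    return genes


def read_annotation_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Read gene models from a GTF file.

    Uses exon and CDS features grouped by transcript; the 5'UTR offset is the
    number of exonic nucleotides upstream of the first CDS base.  Biotype is
    taken from the ``gene_biotype``/``gene_type`` attribute when present.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", disable_infer_genes=True,
        disable_infer_transcripts=True, keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    for tx in db.features_of_type("transcript"):
        gene = tx.attributes.get("gene_name", tx.attributes.get("gene_id", ["?"]))[0]
        biotype = tx.attributes.get(
            "gene_biotype", tx.attributes.get("gene_type", ["protein_coding"])
        )[0]
        exons = [
            GenomicInterval(f.seqid, f.start, f.end, f.strand)
            for f in db.children(tx, featuretype="exon", order_by="start")
        ]
        if not exons:
            continue
        strand = exons[0].strand
        exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
        cds = sorted(
            db.children(tx, featuretype="CDS"),
            key=lambda f: f.start,
            reverse=(strand == "-"),
        )
        offset = 0
        if cds:
            cds_first = cds[0].end if strand == "-" else cds[0].start
            for e in exons:
                if e.start <= cds_first <= e.end:
                    offset += (
                        e.end - cds_first if strand == "-" else cds_first - e.start
                    )
                    break
                offset += len(e)
        model = genes.setdefault(gene, GeneModel(gene, biotype))
        model.transcripts.append(Transcript(tx.id, exons, offset))
    return genes


def read_protein_fasta(
    path: str | Path, gene_pattern: str = r"gene=(\S+)"
) -> dict[str, list[str]]:
    """Known protein sequences per gene.

    The gene identifier is extracted from each record description by
    ``gene_pattern``; records without a match fall back to the record ID.
    """
    pat = re.compile(gene_pattern)
    proteins: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pat.search(rec.description)
        gene = m.group(1) if m else rec.id
        proteins.setdefault(gene, []).append(str(rec.seq).upper())
    return proteins


def read_domain_table(path: str | Path) -> list[DomainRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"aa_start": int, "aa_end": int})
    _require_columns(
        df, ["gene", "accession", "name", "aa_start", "aa_end"], f"domains {path}"
    )
    return [
        DomainRecord(
            gene=row["gene"],
            accession=row["accession"],
            name=row["name"],
            aa_start=int(row["aa_start"]),
            aa_end=int(row["aa_end"]),
            source_db=str(row.get("source_db", "")),
        )
        for _, row in df.iterrows()
    ]


def write_results_table(
    events: list[SpliceEvent],
    stats: pd.DataFrame,
    frames: pd.DataFrame | None,
    diffs: pd.DataFrame | None,
    path: str | Path,
) -> pd.DataFrame:
    """Assemble and write the per-event results table.

    ``stats`` must cover every event; frame and protein-diff tables may cover
    a subset (untranslated events get frame "X" and empty protein columns).
    Raises when the stats table contains IDs with no matching event.
    """
    by_id = {e.event_id: e for e in events}
    orphans = sorted(set(stats["event_id"]) - set(by_id))
    if orphans:
        raise SpliceframeError(f"stats rows with no matching event: {orphans}")

    base = pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "genomic_name": [e.genomic_name for e in events],
            "gene": [e.gene for e in events],
            "event_type": [e.event_type for e in events],
            "chrom": [e.chrom for e in events],
            "strand": [e.strand for e in events],
        }
    )
    keep = [
        "event_id", "n_valid_case", "n_valid_control", "mean_psi_case",
        "mean_psi_control", "delta_psi", "p_value", "p_adj",
    ]
    out = base.merge(stats[keep], on="event_id", how="inner")
    if frames is not None and len(frames):
        out = out.merge(
            frames[["event_id", "frame", "resolved_by"]].rename(
                columns={"resolved_by": "frame_method"}
            ),
            on="event_id",
            how="left",
        )
    else:
        out["frame"] = np.nan
        out["frame_method"] = np.nan
    out["frame"] = out["frame"].fillna("X")
    out["frame_method"] = out["frame_method"].fillna("untested")
    diff_cols = [
        "aa_iso1", "aa_iso2", "same_start_aa", "diff_aa_iso1", "diff_aa_iso2",
        "same_end_aa", "stop_in_iso1", "stop_in_iso2", "frameshift",
    ]
    if diffs is not None and len(diffs):
        out = out.merge(diffs[["event_id"] + diff_cols], on="event_id", how="left")
    else:
        for c in diff_cols:
            out[c] = np.nan
    out = out[RESULTS_COLUMNS]
    out.to_csv(path, sep="\t", index=False)
    return out


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"frame": str})
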