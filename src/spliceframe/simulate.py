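"""Deterministic synthetic data: a toy genome with planted splicing events.

The generator builds every input the pipeline consumes — genome FASTA, gene
annotation, event and counts tables, known proteins, protein domains — plus
a truth table recording each planted quantity, so every stage can be tested
end-to-end without external data.

Genes are built from designed codon blocks rather than uniform random DNA so
that reading frames are unambiguous *by construction*:

* SAFE codons carry T only at codon position 1, which makes any
  concatenation of them stop-free in all three reading frames (a stop codon
  must begin with its T, i.e. coincide with a designed codon, and stops are
  excluded from the set).
* the POISON block ``TTAAATGAC`` translates in-frame to LND but plants a
  TAA in the +1 frame and a TGA in the +2 frame, so an exon containing it
  has exactly one open reading frame.
* novel segments (retained introns, splice-site extensions, mutually
  exclusive intronic exons) use a T-free {C,G} alphabet and therefore never
  introduce stops — except where a truncating TAA is planted explicitly at
  a known in-frame position.

Each planted event is tagged with the method expected to resolve its frame
(both methods, ORF only, peptide only, or the full-isoform fallback), and
the generator verifies its own constructions with plain string operations
(Biopython translation + substring search) independent of the analysis
code.  Per-sample isoform counts are drawn from the same two-group
beta-binomial model the test assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import EVENT_TYPES

STOPS = {"TAA", "TAG", "TGA"}
SAFE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACG"
    for c in "ACG"
    if a + b + c not in STOPS
)
POISON = "TTAAATGAC"  # L-N-D in frame; TAA at +1, TGA at +2

_MODES = ("both", "peptide", "orf", "fallback")


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic cohort.

    Defaults mirror a realistic bulk RNA-seq case/control design: 14 case
    and 13 control samples, event coverage 100-300 reads, planted
    differential events at PSI 0.3 vs 0.7, overdispersion 0.05, and half of
    the events null.
    """

    seed: int = 0
    events_per_type: int = 10
    n_case: int = 14
    n_control: int = 13
    coverage_range: tuple[int, int] = (100, 300)
    psi_case: float = 0.7
    psi_control: float = 0.3
    null_psi_range: tuple[float, float] = (0.35, 0.65)
    phi: float = 0.05
    fraction_null: float = 0.5
    min_coverage: int = 10
    case_label: str = "case"
    control_label: str = "control"
    include_filter_cases: bool = True


@dataclass
class _Piece:
    name: str
    seq: str
    t_start: int = 0  # transcript-space offset within the gene, 0-based

    @property
    def t_end(self) -> int:
        return self.t_start + len(self.seq)


@dataclass
class _PlantedGene:
    gene: str
    strand: str
    pieces: dict[str, _Piece]
    length: int
    cds: str
    utr5: int
    chrom: str = ""
    g0: int = 0  # 0-based genomic offset of the gene block

    def interval(self, t_start: int, t_end: int) -> tuple[int, int]:
        """Transcript span -> 1-based inclusive genomic (start, end)."""
        if self.strand == "+":
            return self.g0 + t_start + 1, self.g0 + t_end
        return self.g0 + (self.length - t_end) + 1, self.g0 + (self.length - t_start)


@dataclass
class FixtureResult:
    out_dir: Path
    paths: dict[str, Path]
    truth: pd.DataFrame
    spec: FixtureSpec


def _rand_seq(rng, n: int, alphabet: str = "CG") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _translate(dna: str, frame: int) -> str:
    sub = dna[frame - 1 :]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate()) if sub else ""


def _build_gene(rng, gene: str, strand: str, true_frame: int, mode: str,
                event_type: str, variant: int) -> _PlantedGene:
    """Construct one gene hosting one event."""
    pad = {1: 0, 2: 2, 3: 1}[true_frame]  # CDS phase of the event's first exon

    def codons(n):
        return "".join(rng.choice(SAFE_CODONS, size=n))

    e1_cds = 21 + pad
    l2 = 36 + 3 * int(rng.integers(0, 3))
    # middle-exon length sets the frameshift status of skip-type events
    l3 = 42 + variant % 3
    l4 = 45
    l5 = 36
    # E6 absorbs the phase remainder so the full CDS ends on a codon boundary
    e6_cds = 24 + (-(e1_cds + l2 + l3 + l4 + l5 + 24)) % 3

    n_cds = e1_cds + l2 + l3 + l4 + l5 + e6_cds
    n_codons = -(-n_cds // 3)
    cds = "ATG" + codons(n_codons)
    cds = cds[: n_cds - 3] + "TAA"

    def poison_at(cds, exon_cds_start):
        j = -(-(exon_cds_start + 3) // 3)  # first codon fully inside the exon
        return cds[: 3 * j] + POISON + cds[3 * (j + 3) :]

    if mode in ("both", "orf"):
        cds = poison_at(cds, e1_cds)  # inside E2, near its start
    elif mode == "fallback":
        # the ambiguity-breaking stops must sit in an exon present in
        # isoform 2 but outside the shared first exon
        if event_type == "mutex_exons":
            cds = poison_at(cds, e1_cds + l2 + l3)  # E4
        else:
            cds = poison_at(cds, e1_cds + l2)  # E3
    # mode == "peptide": no poison anywhere; all frames of E2 stay open

    cuts = np.cumsum([e1_cds, l2, l3, l4, l5])
    exon_cds = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]

    utr5 = int(rng.integers(6, 18))
    utr3 = int(rng.integers(6, 15))
    exon_seqs = [
        _rand_seq(rng, utr5) + exon_cds[0],
        *exon_cds[1:5],
        exon_cds[5] + _rand_seq(rng, utr3),
    ]
    intron_lens = [int(rng.integers(30, 80)) for _ in range(5)]
    if event_type == "mutex_exons":
        # I3 must host the mutually exclusive intronic exon plus flanks
        intron_lens[2] = int(rng.integers(80, 110))
    # the intron after the event's first exon must keep codon phase for
    # retention events resolved via the fallback (no frameshift allowed there)
    if event_type == "intron_retention":
        want = variant % 3 if mode != "fallback" else 0
        intron_lens[1] += (want - intron_lens[1]) % 3
    intron_seqs = [_rand_seq(rng, n) for n in intron_lens]

    names = ["E1", "I1", "E2", "I2", "E3", "I3", "E4", "I4", "E5", "I5", "E6"]
    seqs = [
        exon_seqs[0], intron_seqs[0], exon_seqs[1], intron_seqs[1],
        exon_seqs[2], intron_seqs[2], exon_seqs[3], intron_seqs[3],
        exon_seqs[4], intron_seqs[4], exon_seqs[5],
    ]
    pieces, pos = {}, 0
    for name, seq in zip(names, seqs):
        pieces[name] = _Piece(name, seq, pos)
        pos += len(seq)
    return _PlantedGene(gene, strand, pieces, pos, cds, utr5)


def _plant_stop_inframe(seq: str, iso2_offset_of_seq: int, true_frame: int,
                        at: int = 9) -> tuple[str, int]:
    """Overwrite a TAA at the first in-frame codon start at/after ``at``.

    ``iso2_offset_of_seq`` is the transcript offset of ``seq`` within the
    assembled isoform-2 DNA.  Returns the edited sequence and the offset of
    the stop within it.
    """
    phase0 = (true_frame - 1)  # isoform offset where codons start
    q = at
    while (iso2_offset_of_seq + q - phase0) % 3 != 0:
        q += 1
    if q + 3 > len(seq):
        raise ValueError("segment too short to plant a stop codon")
    return seq[:q] + "TAA" + seq[q + 3 :], q


def _edit_piece(piece: _Piece, offset: int, sub: str) -> None:
    piece.seq = piece.seq[:offset] + sub + piece.seq[offset + len(sub) :]


def _event_structure(rng, g: _PlantedGene, event_type: str, mode: str,
                     true_frame: int, variant: int):
    """Exon spans (transcript space) of both isoforms.

    Returns (iso1 spans, iso2 spans, novel1, novel2); spans are (t_start,
    t_end, seq) in transcription order.  Edits to novel segments (the
    truncating in-frame TAA of odd variants, the phase-protecting leading C
    where a shared exon's partial codon is completed by the novel segment,
    and the mutually exclusive intronic exon itself) are written back into
    the gene's pieces so the emitted genome matches the event sequences.
    """
    P = g.pieces
    truncating = mode != "fallback" and variant % 2 == 1

    def span(piece):
        return (piece.t_start, piece.t_end, piece.seq)

    if event_type in ("exon_skip", "mult_exon_skip"):
        kept = ["E2", "E4"] if event_type == "exon_skip" else ["E2", "E5"]
        full = (
            ["E2", "E3", "E4"] if event_type == "exon_skip"
            else ["E2", "E3", "E4", "E5"]
        )
        return ([span(P[n]) for n in kept], [span(P[n]) for n in full],
                True, False)

    if event_type == "intron_retention":
        e2, i2, e3 = P["E2"], P["I2"], P["E3"]
        # a G completing E2's trailing partial codon could form TAG
        _edit_piece(i2, 0, "C")
        if truncating:
            seq, _ = _plant_stop_inframe(i2.seq, len(e2.seq), true_frame)
            i2.seq = seq
        merged = (e2.t_start, e3.t_end, e2.seq + i2.seq + e3.seq)
        return ([span(e2), span(e3)], [merged], False, True)

    if event_type == "alt_5prime":
        e2, i2, e3 = P["E2"], P["I2"], P["E3"]
        # a multiple-of-3 extension keeps downstream exons in phase, which
        # the fallback needs to see a clean true frame on the full isoform
        m = 12 if mode == "fallback" else 12 + (variant % 3)
        _edit_piece(i2, 0, "C")
        if truncating:
            ext, _ = _plant_stop_inframe(i2.seq[:m], len(e2.seq), true_frame,
                                         at=3)
            _edit_piece(i2, 0, ext)
        extended = (e2.t_start, e2.t_end + m, e2.seq + i2.seq[:m])
        return ([span(e2), span(e3)], [extended, span(e3)], False, True)

    if event_type == "alt_3prime":
        e2, i2, e3 = P["E2"], P["I2"], P["E3"]
        m = 12 if mode == "fallback" else 12 + (variant % 3)
        off = len(i2.seq) - m
        _edit_piece(i2, off, "C")
        if truncating:
            ext, _ = _plant_stop_inframe(i2.seq[off:], len(e2.seq), true_frame,
                                         at=3)
            _edit_piece(i2, off, ext)
        extended = (e3.t_start - m, e3.t_end, i2.seq[off:] + e3.seq)
        return ([span(e2), span(e3)], [span(e2), extended], False, True)

    if event_type == "mutex_exons":
        e2, i3, e4 = P["E2"], P["I3"], P["E4"]
        l3 = len(P["E3"].seq)
        if mode == "fallback":
            # keep E4 (which carries the poison) in phase on both isoforms
            alt_len = 42 + (l3 % 3)
        else:
            # varies relative to E3's length, so some mutex events frameshift
            alt_len = 42 + ((2 * variant) % 3)
        off = 15
        _edit_piece(i3, off, "C" + _rand_seq(rng, alt_len - 1))
        alt = (i3.t_start + off, i3.t_start + off + alt_len,
               i3.seq[off : off + alt_len])
        iso_canonical = [span(e2), span(P["E3"]), span(e4)]
        iso_alt = [span(e2), alt, span(e4)]
        # isoform 1 carries the exclusive exon with the smaller genomic start
        if g.strand == "+":
            return (iso_canonical, iso_alt, False, True)
        return (iso_alt, iso_canonical, True, False)

    raise ValueError(event_type)


def _iso_dna(spans) -> str:
    return "".join(s[2] for s in spans)


def _genomic_exons(g: _PlantedGene, spans) -> list[tuple[int, int]]:
    return [g.interval(s, e) for s, e, _ in spans]


def _stop_genomic(g: _PlantedGene, spans, frame: int, aa: str) -> int | None:
    idx = aa.find("*")
    if idx < 0:
        return None
    offset = (frame - 1) + 3 * idx
    for (t_s, t_e, seq), (g_s, g_e) in zip(spans, _genomic_exons(g, spans)):
        if offset < len(seq):
            return g_s + offset if g.strand == "+" else g_e - offset
        offset -= len(seq)
    return None


def _verify_event(g: _PlantedGene, spans1, spans2, true_frame: int, mode: str,
                  protein: str | None, event_id: str) -> None:
    """Self-check with plain string operations; raises on design failure."""
    e2 = min((spans1[0], spans2[0]), key=lambda s: s[1] - s[0])[2]
    peps = {f: _translate(e2, f) for f in (1, 2, 3)}
    if "*" in peps[true_frame]:
        raise AssertionError(f"{event_id}: stop in true frame of first exon")
    open_frames = [f for f, p in peps.items() if p and "*" not in p]
    if mode in ("both", "orf") and open_frames != [true_frame]:
        raise AssertionError(f"{event_id}: ORF ambiguity {open_frames}")
    if mode in ("peptide", "fallback") and len(open_frames) != 3:
        raise AssertionError(f"{event_id}: expected all frames open")
    if protein is not None:
        for f, p in peps.items():
            q = p.split("*")[0]
            hit = len(q) >= 7 and q in protein
            if f == true_frame and not hit:
                raise AssertionError(f"{event_id}: true peptide not in protein")
            if f != true_frame and hit:
                raise AssertionError(f"{event_id}: off-frame peptide matches")
    if mode == "fallback":
        dna2 = _iso_dna(spans2)
        clean = []
        for f in (1, 2, 3):
            p = _translate(dna2, f)
            stops = p.count("*") - (1 if p.endswith("*") else 0)
            if stops == 0:
                clean.append(f)
        if clean != [true_frame]:
            raise AssertionError(f"{event_id}: fallback ambiguity {clean}")


def simulate_event_counts(
    rng: np.random.Generator,
    psi_case: float,
    psi_control: float,
    phi: float,
    n_case: int,
    n_control: int,
    coverage_range: tuple[int, int],
) -> pd.DataFrame:
    """Beta-binomial isoform-2 counts for one event (y = reads_iso2)."""
    rows = []
    for group, psi, n_samp in (
        ("case", psi_case, n_case), ("control", psi_control, n_control)
    ):
        n = rng.integers(coverage_range[0], coverage_range[1] + 1, size=n_samp)
        if phi > 0:
            a = psi * (1 - phi) / phi
            b = (1 - psi) * (1 - phi) / phi
            p = rng.beta(a, b, size=n_samp)
        else:
            p = np.full(n_samp, psi)
        y = rng.binomial(n, p)
        for i in range(n_samp):
            rows.append((group, i, int(n[i] - y[i]), int(y[i])))
    return pd.DataFrame(rows, columns=["group", "idx", "reads_iso1", "reads_iso2"])


def generate_null_panel(
    n_events: int,
    phi: float = 0.05,
    n_case: int = 10,
    n_control: int = 10,
    coverage_range: tuple[int, int] = (20, 300),
    psi_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
) -> pd.DataFrame:
    """Counts table of independent null events (equal PSI in both groups)."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_events):
        psi = float(rng.uniform(*psi_range))
        df = simulate_event_counts(
            rng, psi, psi, phi, n_case, n_control, coverage_range
        )
        df["event_id"] = f"null_{i:05d}"
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["sample_id"] = out["group"] + "_" + out["idx"].astype(str)
    return out[["event_id", "sample_id", "group", "reads_iso1", "reads_iso2"]]


def _write_fasta(path: Path, records: list[tuple[str, str]], width: int = 60):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureResult:
    """Emit all six pipeline inputs plus truth.tsv into ``out_dir``."""
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    planned = []
    i = 0
    for etype in EVENT_TYPES:
        for k in range(spec.events_per_type):
            planned.append({"event_type": etype, "kind": "event", "idx": i,
                            "variant": k})
            i += 1
    if spec.include_filter_cases:
        for kind in ("filtered_coding", "filtered_missing", "filtered_sd"):
            planned.append({"event_type": "exon_skip", "kind": kind, "idx": i,
                            "variant": 0})
            i += 1

    chrom_seqs: dict[str, list[str]] = {}
    chrom_pos: dict[str, int] = {}
    events_rows, counts_rows, truth_rows = [], [], []
    annot_rows, protein_records, domain_rows = [], [], []

    for plan in planned:
        idx, variant = plan["idx"], plan["variant"]
        etype, kind = plan["event_type"], plan["kind"]
        gene = f"GENE{idx:03d}"
        event_id = f"{etype}.{idx}"
        strand = "-" if idx % 3 == 0 else "+"
        true_frame = (idx % 3) + 1
        mode = _MODES[variant % len(_MODES)] if kind == "event" else "both"
        # spread fraction_null null events evenly down the variant list
        # (Bresenham-style, so fraction 0.5 alternates differential/null)
        fn = spec.fraction_null
        is_null = kind != "event" or (
            math.floor((variant + 1) * fn) > math.floor(variant * fn)
        )

        g = _build_gene(rng, gene, strand, true_frame, mode, etype, variant)
        spans1, spans2, novel1, novel2 = _event_structure(
            rng, g, etype, mode, true_frame, variant
        )

        chrom = f"chr{idx % 4 + 1}"
        if chrom not in chrom_seqs:
            chrom_seqs[chrom] = []
            chrom_pos[chrom] = 0
        filler = _rand_seq(rng, int(rng.integers(80, 200)), "ACGT")
        chrom_seqs[chrom].append(filler)
        g.chrom = chrom
        g.g0 = chrom_pos[chrom] + len(filler)
        gene_seq = "".join(p.seq for p in g.pieces.values())
        if strand == "-":
            gene_seq = str(Seq(gene_seq).reverse_complement())
        chrom_seqs[chrom].append(gene_seq)
        chrom_pos[chrom] = g.g0 + g.length

        protein = str(Seq(g.cds).translate()).rstrip("*")
        has_protein = mode in ("both", "peptide") or kind != "event"
        if has_protein:
            protein_records.append((f"P_{gene} gene={gene}", protein))
        _verify_event(g, spans1, spans2, true_frame, mode,
                      protein if has_protein else None, event_id)

        aa1 = _translate(_iso_dna(spans1), true_frame)
        aa2 = _translate(_iso_dna(spans2), true_frame)
        frameshift = (len(_iso_dna(spans1)) - len(_iso_dna(spans2))) % 3 != 0
        stop_g1 = _stop_genomic(g, spans1, true_frame, aa1)
        stop_g2 = _stop_genomic(g, spans2, true_frame, aa2)

        exons1 = _genomic_exons(g, spans1)
        exons2 = _genomic_exons(g, spans2)

        def fmt(exs):
            # transcription order: ascending on '+', descending on '-'
            return ";".join(
                f"{s}-{e}" for s, e in sorted(exs, reverse=(strand == "-"))
            )
        # exercise the reader's normalization on part of the swappable types
        emit_swapped = (
            kind == "event"
            and etype in ("exon_skip", "mult_exon_skip", "intron_retention")
            and variant % 4 == 2
        )
        a_exons, b_exons = (exons2, exons1) if emit_swapped else (exons1, exons2)
        a_novel, b_novel = (novel2, novel1) if emit_swapped else (novel1, novel2)
        events_rows.append({
            "event_id": event_id, "gene": gene, "event_type": etype,
            "chrom": chrom, "strand": strand,
            "iso1_exons": fmt(a_exons), "iso2_exons": fmt(b_exons),
            "novel_iso1": a_novel, "novel_iso2": b_novel,
        })

        biotype = "lncRNA" if kind == "filtered_coding" else "protein_coding"
        tx_exons = [
            g.interval(g.pieces[n].t_start, g.pieces[n].t_end)
            for n in ("E1", "E2", "E3", "E4", "E5", "E6")
        ]
        annot_rows.append({
            "gene": gene, "biotype": biotype, "transcript_id": f"T_{gene}",
            "chrom": chrom, "strand": strand, "exons": fmt(tx_exons),
            "cds_start_offset": g.utr5,
        })
        if kind == "event" and variant % 3 == 0 and has_protein:
            la = len(protein)
            domain_rows += [
                {"gene": gene, "accession": f"IPR{idx:05d}",
                 "name": "domain_a", "aa_start": 3, "aa_end": min(20, la),
                 "source_db": "db1"},
                {"gene": gene, "accession": f"IPR{idx:05d}",
                 "name": "domain_a", "aa_start": 12, "aa_end": min(28, la),
                 "source_db": "db2"},
                {"gene": gene, "accession": f"IPR{idx:05d}X",
                 "name": "domain_b", "aa_start": min(35, la - 4),
                 "aa_end": min(50, la), "source_db": "db1"},
            ]

        # per-sample counts
        if kind == "filtered_missing":
            cov = (3, 8)
            psi_c = psi_h = 0.5
        elif kind == "filtered_sd":
            cov = spec.coverage_range
            psi_c = psi_h = 0.5
        elif is_null:
            psi_c = psi_h = float(rng.uniform(*spec.null_psi_range))
            cov = spec.coverage_range
        else:
            psi_c, psi_h = spec.psi_case, spec.psi_control
            cov = spec.coverage_range
        counts = simulate_event_counts(
            rng, psi_c, psi_h, spec.phi, spec.n_case, spec.n_control, cov
        )
        if kind == "filtered_sd":  # constant PSI: zero variability
            n_tot = counts["reads_iso1"] + counts["reads_iso2"]
            n_tot = (n_tot // 2) * 2
            counts["reads_iso2"] = n_tot // 2
            counts["reads_iso1"] = n_tot - counts["reads_iso2"]
        for _, c in counts.iterrows():
            grp = spec.case_label if c["group"] == "case" else spec.control_label
            r1, r2 = int(c["reads_iso1"]), int(c["reads_iso2"])
            if emit_swapped:
                r1, r2 = r2, r1
            counts_rows.append({
                "event_id": event_id,
                "sample_id": f"{grp}_{int(c['idx']):02d}",
                "group": grp, "reads_iso1": r1, "reads_iso2": r2,
            })

        truth_rows.append({
            "event_id": event_id, "gene": gene, "event_type": etype,
            "strand": strand, "kind": kind, "resolve_mode": mode,
            "emitted_swapped": emit_swapped,
            "expected_pass_filters": kind == "event",
            "expected_significant": kind == "event" and not is_null,
            "true_frame": true_frame,
            "aa_iso1": aa1, "aa_iso2": aa2, "frameshift": frameshift,
            "stop_pos_iso1": aa1.find("*") + 1 if "*" in aa1 else "",
            "stop_pos_iso2": aa2.find("*") + 1 if "*" in aa2 else "",
            "stop_genomic_iso1": stop_g1 if stop_g1 is not None else "",
            "stop_genomic_iso2": stop_g2 if stop_g2 is not None else "",
            "psi_case": psi_c, "psi_control": psi_h,
        })

    paths = {
        "genome": out_dir / "genome.fa",
        "annotation": out_dir / "annotation.tsv",
        "events": out_dir / "events.tsv",
        "counts": out_dir / "counts.tsv",
        "proteins": out_dir / "proteins.fa",
        "domains": out_dir / "domains.tsv",
        "truth": out_dir / "truth.tsv",
    }
    _write_fasta(
        paths["genome"],
        [(c, "".join(parts)) for c, parts in sorted(chrom_seqs.items())],
    )
    _write_fasta(paths["proteins"], protein_records)
    pd.DataFrame(events_rows).to_csv(paths["events"], sep="\t", index=False)
    pd.DataFrame(counts_rows).to_csv(paths["counts"], sep="\t", index=False)
    pd.DataFrame(annot_rows).to_csv(paths["annotation"], sep="\t", index=False)
    pd.DataFrame(domain_rows).to_csv(paths["domains"], sep="\t", index=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return FixtureResult(out_dir=out_dir, paths=paths, truth=truth, spec=spec)
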