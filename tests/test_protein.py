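"""Isoform translation, four-segment peptide diff, frameshift and mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spliceframe.model import GenomicInterval, SpliceEvent, SpliceframeError
from spliceframe.protein import (
    detect_frameshift,
    diff_isoforms,
    map_aa_to_genomic,
    protein_diff,
    translate_isoforms,
)
from spliceframe.seqtools import Genome


def iv(start, end, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


def event(iso1, iso2, strand="+", etype="exon_skip"):
    return SpliceEvent("e", "G", etype, "chr1", strand, iso1, iso2)


@pytest.fixture()
def genome_factory(tmp_path):
    def make(seq, name="chr1"):
        p = tmp_path / f"{name}.fa"
        p.write_text(f">{name}\n{seq}\n")
        return Genome(p)

    return make


class TestTranslateIsoforms:
    def test_example_pair(self, genome_factory):
        g = genome_factory("ATGAAACCTGGGTAA")
        ev = event([iv(1, 9)], [iv(1, 15)], etype="intron_retention")
        aa1, aa2 = translate_isoforms(ev, 1, g)
        assert aa1 == "MKP"
        assert aa2 == "MKPG*"  # retained intron read through the stop

    def test_refuses_unknown_frame(self, genome_factory):
        g = genome_factory("ATGAAA")
        ev = event([iv(1, 6)], [iv(1, 6)])
        with pytest.raises(SpliceframeError):
            translate_isoforms(ev, "X", g)

    def test_identical_isoforms_identical_peptides(self, genome_factory):
        g = genome_factory("ATGAAATTTGGG")
        ev = event([iv(1, 12)], [iv(1, 12)])
        aa1, aa2 = translate_isoforms(ev, 2, g)
        assert aa1 == aa2


class TestDiffIsoforms:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("MKP", "MKGT*", ("MK", "P", "GT*", "")),
            ("ABCD", "ABCD", ("ABCD", "", "", "")),
            ("AB", "CB", ("", "A", "C", "B")),
            ("MKWR", "MKR", ("MK", "W", "", "R")),
            ("", "XYZ", ("", "", "XYZ", "")),
        ],
    )
    def test_segment_decomposition(self, a, b, expected):
        assert diff_isoforms(a, b) == expected

    @given(st.text(alphabet="ACDEFG*", max_size=30),
           st.text(alphabet="ACDEFG*", max_size=30))
    @settings(derandomize=True, max_examples=1000)
    def test_reconstruction_property(self, a, b):
        prefix, d1, d2, suffix = diff_isoforms(a, b)
        assert prefix + d1 + suffix == a
        assert prefix + d2 + suffix == b

    @given(st.text(alphabet="ACDEFG", max_size=20),
           st.text(alphabet="ACDEFG", max_size=20))
    @settings(derandomize=True, max_examples=300)
    def test_symmetric_under_swap(self, a, b):
        p1, d1, d2, s1 = diff_isoforms(a, b)
        p2, e1, e2, s2 = diff_isoforms(b, a)
        assert (p1, s1) == (p2, s2) and (d1, d2) == (e2, e1)


class TestFrameshift:
    def test_skipped_exon_length_mod_three(self):
        base = [iv(1, 30), iv(100, 130)]
        with_4nt = [iv(1, 30), iv(50, 53), iv(100, 130)]
        assert detect_frameshift(event(base, with_4nt)) is True
        with_99nt = [iv(1, 30), iv(50, 148), iv(200, 230)]
        base99 = [iv(1, 30), iv(200, 230)]
        assert detect_frameshift(event(base99, with_99nt)) is False

    def test_mutex_differing_exclusive_lengths(self):
        iso1 = [iv(1, 30), iv(50, 109), iv(200, 230)]   # 60 nt middle
        iso2 = [iv(1, 30), iv(120, 180), iv(200, 230)]  # 61 nt middle
        ev = event(iso1, iso2, etype="mutex_exons")
        assert detect_frameshift(ev) is True


class TestMapAaToGenomic:
    def test_single_exon_plus_strand(self):
        ev = event([iv(100, 150)], [iv(100, 150)])
        assert map_aa_to_genomic(ev, 1, 2, 1) == 103
        assert map_aa_to_genomic(ev, 3, 1, 1) == 102

    def test_minus_strand_first_residue_at_exon_end(self):
        ev = event([iv(100, 150, "-")], [iv(100, 150, "-")], strand="-")
        assert map_aa_to_genomic(ev, 1, 1, 1) == 150
        assert map_aa_to_genomic(ev, 1, 2, 1) == 147

    def test_junction_spanning_codon_maps_to_upstream_exon(self):
        # exon1 = 4 nt, so residue 2's codon starts at exon1's last base
        ev = event([iv(100, 103), iv(200, 210)], [iv(100, 103), iv(200, 210)])
        assert map_aa_to_genomic(ev, 1, 2, 1) == 103

    def test_residue_beyond_peptide_fatal(self):
        ev = event([iv(100, 105)], [iv(100, 105)])
        with pytest.raises(SpliceframeError):
            map_aa_to_genomic(ev, 1, 3, 1)

    def test_agrees_with_per_base_walk_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 5))
            pos, exons = 1, []
            for _ in range(n_exons):
                pos += int(rng.integers(5, 40))
                length = int(rng.integers(3, 60))
                exons.append(iv(pos, pos + length - 1, strand))
                pos += length
            ev = event(list(exons), list(exons), strand=strand)
            # oracle: enumerate every base's genomic coordinate in
            # transcription order, then index the codon start directly
            walk = []
            for e in ev.iso1_exons:
                rng_bases = range(e.start, e.end + 1)
                walk.extend(reversed(rng_bases) if strand == "-" else rng_bases)
            frame = int(rng.integers(1, 4))
            n_res = (len(walk) - (frame - 1)) // 3
            if n_res < 1:
                continue
            residue = int(rng.integers(1, n_res + 1))
            expected = walk[(frame - 1) + 3 * (residue - 1)]
            assert map_aa_to_genomic(ev, frame, residue, 1) == expected


class TestProteinDiffEndToEnd:
    def test_truncating_stop_mapped_into_novel_segment(self, pipeline_full,
                                                       fixture_full):
        truth = fixture_full.truth.set_index("event_id")
        diffs = pipeline_full["diffs"].set_index("event_id")
        planted = truth[(truth.kind == "event")
                        & (truth.stop_genomic_iso2 != "")]
        for event_id, row in planted.iterrows():
            got = diffs.loc[event_id, "stop_genomic_iso2"]
            assert int(got) == int(row["stop_genomic_iso2"])

    def test_frameshift_extends_diff_to_peptide_ends(self, pipeline_full):
        diffs = pipeline_full["diffs"]
        shifted = diffs[diffs["frameshift"]]
        assert len(shifted) > 0
        for _, row in shifted.iterrows():
            # after a frameshift the tails differ except for short
            # coincidental suffixes (the novel {C,G} segments re-use a small
            # residue alphabet, so 1-3 residue coincidences do occur)
            assert len(row["same_end_aa"]) <= 4
            assert len(row["diff_aa_iso2"]) > len(row["same_end_aa"])
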