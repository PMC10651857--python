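"""Reading-frame prediction: the two methods, their combination, fallback."""

import numpy as np
import pytest
from Bio.Seq import Seq

from spliceframe.frames import (
    combine_methods,
    fallback_full_isoform,
    first_5prime_exon,
    orf_method,
    peptide_match_method,
)
from spliceframe.model import GenomicInterval, SpliceEvent


def iv(start, end, strand="+"):
    return GenomicInterval("chr1", start, end, strand)


def event(etype, strand, iso1, iso2):
    return SpliceEvent("e", "G", etype, "chr1", strand, iso1, iso2)


class TestFirstSharedExon:
    def test_plus_strand_lowest_start(self):
        ev = event("exon_skip", "+",
                   [iv(100, 150), iv(300, 350)],
                   [iv(100, 150), iv(200, 250), iv(300, 350)])
        assert first_5prime_exon(ev) == iv(100, 150)

    def test_minus_strand_highest_coordinates(self):
        ev = event("exon_skip", "-",
                   [iv(100, 150, "-"), iv(300, 350, "-")],
                   [iv(100, 150, "-"), iv(200, 250, "-"), iv(300, 350, "-")])
        assert first_5prime_exon(ev) == iv(300, 350, "-")

    def test_intron_retention_shared_prefix(self):
        ev = event("intron_retention", "+",
                   [iv(100, 150), iv(200, 250)], [iv(100, 250)])
        assert first_5prime_exon(ev) == iv(100, 150)

    def test_alt_5prime_shared_segment_before_the_moving_donor(self):
        ev = event("alt_5prime", "+",
                   [iv(100, 150), iv(300, 350)],
                   [iv(100, 170), iv(300, 350)])
        assert first_5prime_exon(ev) == iv(100, 150)

    def test_no_shared_segment_unresolvable(self):
        ev = event("mutex_exons", "+",
                   [iv(100, 150), iv(400, 450)],
                   [iv(110, 150), iv(400, 450)])
        assert first_5prime_exon(ev) is None


def orf_oracle(dna):
    open_frames = [
        f for f in (1, 2, 3)
        if len(dna) - (f - 1) >= 3
        and "*" not in Seq(dna[f - 1 :][: (len(dna) - f + 1) // 3 * 3]).translate()
    ]
    return open_frames[0] if len(open_frames) == 1 else None


def peptide_oracle(dna, proteins, min_len=7):
    hits = {}
    for f in (1, 2, 3):
        pep = str(
            Seq(dna[f - 1 :][: (len(dna) - f + 1) // 3 * 3]).translate()
        ).split("*")[0]
        hits[f] = (
            0 if len(pep) < min_len
            else sum(pep in prot for prot in proteins)
        )
    frames = [f for f in (1, 2, 3) if hits[f] > 0]
    return (frames[0] if len(frames) == 1 else None), hits


class TestOrfMethod:
    @pytest.mark.parametrize(
        "dna, expected",
        [
            ("TAAATAAGG", 3),   # frames 1/2 hit stops; frame 3 reads NK
            ("ATGGCC", None),   # every frame open
            ("TAATAGTAA", None),  # frames 2 and 3 both open
            ("AT", None),       # shorter than a codon
        ],
    )
    def test_single_open_frame_rule(self, dna, expected):
        assert orf_method(dna) == expected

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        rng = np.random.default_rng(13)
        for _ in range(500):
            dna = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(3, 90))))
            assert orf_method(dna) == orf_oracle(dna)


class TestPeptideMethod:
    def test_unique_matching_frame(self):
        dna = "GGATTTGCAGCTAGCTCAGAC"
        pep = str(Seq(dna).translate())
        frame, counts = peptide_match_method(dna, ["MK" + pep + "SW"])
        assert frame == 1 and counts[1] == 1 and counts[2] == counts[3] == 0

    def test_ambiguous_when_two_frames_match(self):
        dna = "GGATTTGCAGCTAGCTCAGACAAA"
        p1 = str(Seq(dna).translate()).split("*")[0]
        p2 = str(Seq(dna[1:22]).translate()).split("*")[0]
        frame, _ = peptide_match_method(dna, [p1 + "W", "M" + p2])
        assert frame is None

    def test_empty_protein_set(self):
        frame, counts = peptide_match_method("ATGGCAGCTGCTGCAGCAGCT", [])
        assert frame is None and sum(counts.values()) == 0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            dna = "".join(rng.choice(list("ACGT"),
                                     size=int(rng.integers(12, 70))))
            proteins = []
            for _ in range(int(rng.integers(1, 4))):
                if rng.random() < 0.5:
                    # sometimes embed a real frame's peptide
                    f = int(rng.integers(1, 4))
                    pep = str(Seq(
                        dna[f - 1 :][: (len(dna) - f + 1) // 3 * 3]
                    ).translate()).split("*")[0]
                    proteins.append("M" + pep + "W")
                else:
                    proteins.append(
                        "".join(rng.choice(aas, size=int(rng.integers(8, 40))))
                    )
            got_frame, got_counts = peptide_match_method(dna, proteins)
            want_frame, want_counts = peptide_oracle(dna, proteins)
            assert got_frame == (want_frame if want_frame else None) or \
                got_frame == want_frame
            assert got_counts == want_counts

    def test_raising_min_match_len_never_creates_a_call(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            dna = "".join(rng.choice(list("ACGT"), size=45))
            pep = str(Seq(dna).translate()).split("*")[0]
            proteins = [pep + "KKK"] if pep else ["MKWVLL"]
            calls = []
            for mml in (5, 7, 10, 14):
                frame, _ = peptide_match_method(dna, proteins, mml)
                calls.append(frame)
            # once the call disappears with growing threshold it stays gone
            seen_none = False
            for c in calls:
                if c is None:
                    seen_none = True
                elif seen_none:
                    pytest.fail("a longer threshold revived a frame call")


class TestCombineAndFallback:
    @pytest.mark.parametrize(
        "orf, pep, frame, how",
        [
            (2, 2, 2, "both_agree"),
            (None, 3, 3, "peptide_only"),
            (1, None, 1, "orf_only"),
            (None, None, None, "unresolved"),
            (1, 3, None, "conflict"),
        ],
    )
    def test_combination_table(self, orf, pep, frame, how):
        assert combine_methods(orf, pep) == (frame, how)

    def test_fallback_unique_clean_frame(self):
        # stops in frames 1 and 2 only (terminal stop in frame 1 excluded)
        dna = "TTAAATGACGGC"  # poison block + codon
        assert fallback_full_isoform(dna) == 1

    def test_fallback_ambiguous_when_several_frames_clean(self):
        assert fallback_full_isoform("GCAGCCGCTGCA") is None

    def test_fallback_all_frames_dirty(self):
        # internal stops in every frame: *INN / K*IT / NK*P
        dna = "TAAATAAATAACCC"
        assert fallback_full_isoform(dna) is None

    def test_terminal_stop_does_not_count(self):
        dna = "TTAAATGACGGCTAA"  # clean frame 1 ending in TAA
        assert fallback_full_isoform(dna) == 1

    def test_require_both_isoforms(self):
        iso2 = "TTAAATGACGGC"
        dirty_iso1 = "TAAGGG"  # stop in frame 1
        assert fallback_full_isoform(iso2, dirty_iso1, require_both=True) is None
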