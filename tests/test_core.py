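"""Coordinate parsing, shift classification, seed extraction, repertoires."""

import pytest
from hypothesis import given, settings, strategies as st

from isorewire.core import (
    CoordinateParseError,
    GenomicSpan,
    IsomirRecord,
    MirnaLocus,
    classify_shift,
    dedup_multicopy,
    enumerate_seed_variants,
    extract_seed,
    parse_isomir_coordinate,
    position_frequency_matrix,
)

RNA22 = "UGAGGUAGUAGGUUGUAUAGUU"


class TestCoordinateParsing:
    def test_printed_dialect(self):
        span = parse_isomir_coordinate("hg38:chr22:46112751-46112773:+")
        assert (span.assembly, span.chromosome, span.start, span.end, span.strand) == (
            "hg38", "chr22", 46112751, 46112773, "+")
        assert span.length == 23

    def test_single_base_span(self):
        assert parse_isomir_coordinate("hg38:chr1:100-100:-").length == 1

    @pytest.mark.parametrize("text", [
        "hg38:chr1:200-100:+",      # start > end
        "hg38:chr1:100-200:*",      # unknown strand
        "chr1:100-200:+",           # missing assembly
        "hg38:chr1:abc-200:+",      # non-numeric
        "garbage",
    ])
    def test_malformed_rejected(self, text):
        with pytest.raises(CoordinateParseError):
            parse_isomir_coordinate(text)

    def test_unicode_minus_strand_accepted(self):
        assert parse_isomir_coordinate("hg38:chr22:10-20:−").strand == "-"

    @given(st.integers(1, 10**8), st.integers(0, 500), st.sampled_from("+-"))
    @settings(max_examples=50, deadline=None)
    def test_parse_format_roundtrip(self, start, span_len, strand):
        span = GenomicSpan("hg38", "chrX", start, start + span_len, strand)
        assert parse_isomir_coordinate(span.format()) == span


class TestClassifyShift:
    annotated = GenomicSpan("hg38", "chr9", 52, 73, "+")

    @pytest.mark.parametrize("start,end,o5,o3", [
        (53, 74, +1, +1),
        (52, 71, 0, -2),
        (52, 73, 0, 0),
        (50, 75, -2, +2),
    ])
    def test_plus_strand_offsets(self, start, end, o5, o3):
        iso = GenomicSpan("hg38", "chr9", start, end, "+")
        shift = classify_shift(iso, self.annotated)
        assert (shift.offset5, shift.offset3) == (o5, o3)

    def test_minus_strand_genomic_end_is_five_prime(self):
        ann = GenomicSpan("hg38", "chr9", 52, 73, "-")
        iso = GenomicSpan("hg38", "chr9", 51, 72, "-")  # 5' trimmed by 1, 3' extended by 1
        shift = classify_shift(iso, ann)
        assert (shift.offset5, shift.offset3) == (+1, +1)

    def test_cross_chromosome_and_strand_rejected(self):
        with pytest.raises(ValueError):
            classify_shift(GenomicSpan("hg38", "chr1", 52, 73, "+"), self.annotated)
        with pytest.raises(ValueError):
            classify_shift(GenomicSpan("hg38", "chr9", 52, 73, "-"), self.annotated)

    @given(st.integers(100, 200), st.integers(100, 200), st.integers(0, 30),
           st.integers(0, 30), st.sampled_from("+-"))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, s1, s2, l1, l2, strand):
        a = GenomicSpan("hg38", "chr1", s1, s1 + l1, strand)
        b = GenomicSpan("hg38", "chr1", s2, s2 + l2, strand)
        fwd, rev = classify_shift(a, b), classify_shift(b, a)
        assert fwd.offset5 == -rev.offset5 and fwd.offset3 == -rev.offset3
        ident = classify_shift(a, a)
        assert (ident.offset5, ident.offset3) == (0, 0)


class TestExtractSeed:
    def test_positions_2_to_8(self):
        assert extract_seed(RNA22) == "GAGGUAG"
        assert extract_seed(RNA22) == RNA22[1:8]

    def test_dna_normalized(self):
        assert extract_seed("TGAGGTAGTAGGTTGTATAGTT") == "GAGGUAG"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            extract_seed("GAGGUAG")  # 7 nt: no position 2-8 window past position 1


def _locus_and_records():
    pre = "G" * 10 + RNA22 + "C" * 30
    ann = GenomicSpan("hg38", "chr9", 111, 132, "+")  # pre starts at 101
    locus = MirnaLocus(locus_id="let-7a", family="let-7", pre_mirna_sequence=pre,
                       mature_5p=ann, annotated_mature_sequences={"5p": RNA22})
    def rec(o5, o3, locus_id="let-7a"):
        seq = pre[10 + o5: 32 + o3]
        span = GenomicSpan("hg38", "chr9", 111 + o5, 132 + o3, "+")
        return IsomirRecord(isomir_id=f"i({o5:+d},{o3:+d})", locus_id=locus_id, arm="5p",
                            span=span, sequence=seq, counts={})
    return locus, rec


class TestEnumerateSeedVariants:
    def test_canonical_only(self):
        locus, rec = _locus_and_records()
        enum = enumerate_seed_variants([rec(0, 0)], locus)
        (v,) = enum.variants
        assert v.shift == 0 and v.is_annotated and v.label == "let-7-5p+0"

    def test_offsets_grouped_and_labelled(self):
        locus, rec = _locus_and_records()
        enum = enumerate_seed_variants([rec(0, 0), rec(1, 0), rec(-2, 1), rec(0, 2)], locus)
        labels = {v.label: v for v in enum.variants}
        assert set(labels) == {"let-7-5p+0", "let-7-5p+1", "let-7-5p-2"}
        # the 3'-only record shares the annotated variant
        assert set(labels["let-7-5p+0"].isomir_ids) == {"i(+0,+0)", "i(+0,+2)"}
        assert not enum.excluded

    def test_beyond_window_excluded(self):
        locus, rec = _locus_and_records()
        enum = enumerate_seed_variants([rec(0, 0), rec(6, 0)], locus)
        assert len(enum.variants) == 1
        assert [r.isomir_id for r in enum.excluded] == ["i(+6,+0)"]

    def test_variant_plus_excluded_counts_conserved(self):
        locus, rec = _locus_and_records()
        records = [rec(o5, o3) for o5 in (-5, -2, 0, 1, 6) for o3 in (0, 1)]
        enum = enumerate_seed_variants(records, locus)
        distinct_within = {(extract_seed(r.sequence), r.span.start - 111)
                           for r in records if abs(r.span.start - 111) <= 5}
        assert len(enum.variants) == len(distinct_within)
        assert len(enum.excluded) == sum(1 for r in records if abs(r.span.start - 111) > 5)


class TestDedupMulticopy:
    def _multi(self):
        locus, rec = _locus_and_records()
        a = rec(0, 0, locus_id="let-7a-1")
        b = rec(0, 0, locus_id="let-7a-2")
        c = rec(0, 0, locus_id="let-7a-3")
        d = rec(1, 0, locus_id="let-7a-1")
        return a, b, c, d

    def test_collapse_keeps_lexicographic_first(self):
        a, b, c, d = self._multi()
        kept, dropped = dedup_multicopy([b, a, c, d])
        assert {r.locus_id for r in kept if r.sequence == a.sequence} == {"let-7a-1"}
        assert len(dropped) == 2
        assert d in kept  # distinct sequence untouched

    def test_drop_all_mode(self):
        a, b, c, d = self._multi()
        kept, dropped = dedup_multicopy([a, b, c, d], mode="drop_all")
        assert kept == [d] and len(dropped) == 3

    def test_all_distinct_identity(self):
        locus, rec = _locus_and_records()
        records = [rec(0, 0), rec(1, 1)]
        kept, dropped = dedup_multicopy(records)
        assert kept == records and dropped == []


class TestPositionFrequencyMatrix:
    def test_uniform_and_ragged(self):
        pfm = position_frequency_matrix(["AAAA", "AAAA"])
        assert all(col == {"A": 1.0} for col in pfm.freq)
        pfm = position_frequency_matrix(["AU", "AA", "A"])
        assert pfm.freq[1] == {"A": 0.5, "U": 0.5}  # only the 2 long sequences count

    def test_column_sums_are_one(self):
        import numpy as np
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGU"), 22)) for _ in range(100)]
        pfm = position_frequency_matrix(seqs)
        assert pfm.length == 22
        for col in pfm.freq:
            assert abs(sum(col.values()) - 1.0) < 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            position_frequency_matrix([])
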