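"""Junction extraction, motif/strand/context calls and filter emulation."""

import re

import numpy as np
import pytest

from cldn5kit.junction_audit import (
    FilterThresholds,
    SpliceJunction,
    annotation_context,
    audit_report,
    extract_junctions,
    junction_motif,
    load_annotation,
    load_genome,
    star_like_filter,
    strand_from_flags,
    junction_table,
)
from cldn5kit.synthetic_data import gen_spliced_reads

from conftest import write_sam

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_walk_oracle(pos1, cigar):
    """Per-base reference walk: junctions as (start, end, overhang).

    Independent of the implementation: consumes the CIGAR string one
    operation at a time, advancing a 1-based reference cursor for
    M/=/X/D/N and counting aligned bases between skips.
    """
    cursor = pos1
    segments = [0]
    skips = []
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "N":
            skips.append((cursor, cursor + n - 1))
            segments.append(0)
            cursor += n
        elif op in "M=X":
            segments[-1] += n
            cursor += n
        elif op == "D":
            cursor += n
        # I, S, H, P consume no reference
    return [
        (s, e, min(segments[i], segments[i + 1]))
        for i, (s, e) in enumerate(skips)
    ]


def random_cigar(rng, read_length=60):
    """A plausible random spliced CIGAR consuming read_length query bases."""
    parts = []
    remaining = read_length
    if rng.random() < 0.3:
        c = int(rng.integers(1, 6))
        parts.append(f"{c}S")
        remaining -= c
    n_blocks = int(rng.integers(1, 4))
    for b in range(n_blocks):
        m = int(rng.integers(1, max(2, remaining - (n_blocks - b - 1)))) \
            if b < n_blocks - 1 else remaining
        parts.append(f"{m}M")
        remaining -= m
        if b < n_blocks - 1:
            r = rng.random()
            if r < 0.5:
                parts.append(f"{int(rng.integers(20, 500))}N")
            elif r < 0.75:
                parts.append(f"{int(rng.integers(1, 5))}D")
            else:
                ins = min(int(rng.integers(1, 4)), remaining - 1)
                if ins > 0:
                    parts.append(f"{ins}I")
                    remaining -= ins
    if remaining > 0:
        parts.append(f"{remaining}M")
    return "".join(parts)


class TestExtractJunctions:
    def test_single_skip_coordinates_and_overhang(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [("r1", 0, 11, 60, "10M50N10M")])
        js = extract_junctions(sam)
        assert set(js) == {("chrT", 21, 70)}
        j = js[("chrT", 21, 70)]
        assert j.read_support == 1 and j.max_overhang == 10

    def test_read_without_skip_yields_nothing(self, tmp_path):
        sam = write_sam(tmp_path / "b.sam", [("r1", 0, 5, 60, "20M")])
        assert extract_junctions(sam) == {}

    def test_mapq_filter_splits_unique_support(self, tmp_path):
        sam = write_sam(tmp_path / "c.sam", [
            ("r1", 0, 11, 60, "10M50N10M"),
            ("r2", 0, 11, 3, "10M50N10M"),
        ])
        j = extract_junctions(sam, min_mapq=10)[("chrT", 21, 70)]
        assert j.read_support == 2 and j.unique_support == 1

    def test_nh_tag_marks_multimappers(self, tmp_path):
        sam = write_sam(tmp_path / "d.sam", [
            ("r1", 0, 11, 60, "10M50N10M", ["NH:i:3"]),
            ("r2", 0, 11, 60, "10M50N10M", ["NH:i:1"]),
        ])
        j = extract_junctions(sam)[("chrT", 21, 70)]
        assert j.read_support == 2 and j.unique_support == 1

    def test_insertions_and_clips_do_not_consume_reference(self, tmp_path):
        # 5S10M2I3M50N10M starting at 1-based 101:
        # aligned blocks consume 10+3=13 ref bases -> intron starts at 114
        sam = write_sam(tmp_path / "e.sam", [("r1", 0, 101, 60, "5S10M2I3M50N10M")])
        js = extract_junctions(sam)
        assert set(js) == {("chrT", 114, 163)}
        assert js[("chrT", 114, 163)].max_overhang == 10  # min(13, 10)

    def test_equals_per_base_oracle_on_randomized_cigars(self, tmp_path):
        rng = np.random.default_rng(42)
        records = []
        expected = {}
        for i in range(300):
            pos1 = int(rng.integers(1, 5000))
            cig = random_cigar(rng)
            records.append((f"r{i}", 0, pos1, 60, cig))
            for s, e, o in cigar_walk_oracle(pos1, cig):
                if o >= 1:
                    key = ("chrT", s, e)
                    sup, mo = expected.get(key, (0, 0))
                    expected[key] = (sup + 1, max(mo, o))
        sam = write_sam(tmp_path / "rand.sam", records)
        js = extract_junctions(sam)
        assert set(js) == set(expected)
        for key, (sup, mo) in expected.items():
            assert js[key].read_support == sup
            assert js[key].max_overhang == mo

    def test_result_invariant_to_record_order(self, tmp_path):
        rng = np.random.default_rng(1)
        records = [(f"r{i}", 0, int(rng.integers(1, 1000)), 60, random_cigar(rng))
                   for i in range(50)]
        sam1 = write_sam(tmp_path / "o1.sam", records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        sam2 = write_sam(tmp_path / "o2.sam", shuffled)
        js1, js2 = extract_junctions(sam1), extract_junctions(sam2)
        assert set(js1) == set(js2)
        for k in js1:
            assert (js1[k].read_support, js1[k].max_overhang) == (
                js2[k].read_support, js2[k].max_overhang)


def _junction(start, end, strand="unknown", **kw):
    return SpliceJunction(chrom="chrT", intron_start=start, intron_end=end,
                          strand=strand, **kw)


class TestJunctionMotif:
    def test_plus_strand_canonical(self):
        genome = {"chrT": "AAAAGTCCCCAGAAAA"}  # intron 5..12: GT...AG
        call = junction_motif(_junction(5, 12, "+"), genome)
        assert (call.donor, call.acceptor, call.motif_class) == ("GT", "AG", "GT-AG")

    def test_plus_strand_gc_donor_semi_canonical(self):
        genome = {"chrT": "AAAAGCCCCCAGAAAA"}
        call = junction_motif(_junction(5, 12, "+"), genome)
        assert call.motif_class == "GC-AG"
        assert call.donor == "GC" and call.acceptor == "AG"

    def test_minus_strand_reads_reverse_complement(self):
        # plus-strand intron shows CT...AC => GT-AG on the minus strand
        genome = {"chrT": "AAAACTCCCCACAAAA"}
        call = junction_motif(_junction(5, 12, "-"), genome)
        assert (call.donor, call.acceptor, call.motif_class) == ("GT", "AG", "GT-AG")

    def test_unknown_strand_picks_the_canonical_orientation(self):
        genome = {"chrT": "AAAACTCCCCACAAAA"}  # only '-' yields GT-AG
        call = junction_motif(_junction(5, 12, "unknown"), genome)
        assert call.motif_class == "GT-AG" and call.strand_used == "-"

    def test_unknown_strand_tie_is_flagged_noncanonical(self):
        # GT...AC reads GT-AC on '+' (noncanonical) and GT-AC on '-' too;
        # build a palindromic GT...AC intron: revcomp(GT...AC) = GT...AC
        genome = {"chrT": "AAAAGTCCGGACAAAA"}
        call = junction_motif(_junction(5, 12, "unknown"), genome)
        assert call.motif_class == "noncanonical"
        assert not call.ambiguous  # neither orientation is canonical here

    def test_interval_outside_reference_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            junction_motif(_junction(5, 200, "+"), {"chrT": "A" * 20})

    def test_revcomp_genome_and_strand_flip_invariance(self):
        rng = np.random.default_rng(0)
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            L = len(seq)
            s, e = 11, 30
            for strand in ("+", "-"):
                fwd = junction_motif(_junction(s, e, strand), {"chrT": seq})
                rc = seq.translate(comp)[::-1]
                flipped = junction_motif(
                    _junction(L - e + 1, L - s + 1, "-" if strand == "+" else "+"),
                    {"chrT": rc})
                assert fwd.motif_class == flipped.motif_class
                assert (fwd.donor, fwd.acceptor) == (flipped.donor, flipped.acceptor)


class TestStrandFromFlags:
    def test_forward_pairs_rf_library_give_minus_strand(self):
        records = [(f"p{i}", f) for i in range(10) for f in (99, 147)]
        call = strand_from_flags(records, "RF")
        assert call.strand == "-"
        assert call.support_fraction == 1.0
        assert call.orientation_counts == {"+": 10, "-": 0}

    def test_same_records_fr_library_give_plus_strand(self):
        records = [(f"p{i}", f) for i in range(10) for f in (99, 147)]
        assert strand_from_flags(records, "FR").strand == "+"

    def test_unstranded_library_is_always_unknown(self):
        records = [(f"p{i}", 99) for i in range(50)]
        assert strand_from_flags(records, "unstranded").strand == "unknown"

    def test_reverse_pairs(self):
        records = [(f"p{i}", f) for i in range(4) for f in (83, 163)]
        call = strand_from_flags(records, "FR")
        assert call.strand == "-" and call.orientation_counts == {"+": 0, "-": 4}

    def test_orientation_counts_sum_to_informative_pairs(self):
        records = [("a", 99), ("a", 147), ("b", 83), ("b", 163),
                   ("c", 77), ("d", 99), ("e", 4)]  # c unpaired flags, e odd
        call = strand_from_flags(records, "FR")
        assert sum(call.orientation_counts.values()) == call.n_informative == 3
        assert call.n_uninformative == 2
        assert call.flag_counts[99] == 2

    def test_bad_library_type_rejected(self):
        with pytest.raises(ValueError):
            strand_from_flags([], "ff")


class TestAnnotationContext:
    @pytest.fixture
    def annotation(self, tmp_path):
        gff = tmp_path / "ann.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chrT\tt\tgene\t100\t2000\t.\t-\t.\tID=g1\n"
            "chrT\tt\tmRNA\t100\t2000\t.\t-\t.\tID=t1;Parent=g1\n"
            "chrT\tt\texon\t100\t800\t.\t-\t.\tID=e1;Parent=t1\n"
            "chrT\tt\texon\t1200\t2000\t.\t-\t.\tID=e2;Parent=t1\n"
        )
        return load_annotation(gff)

    def test_intra_exonic(self, annotation):
        assert annotation_context(_junction(300, 500), annotation) == "intra-exonic"

    def test_annotated_intron_exact_match(self, annotation):
        assert annotation_context(_junction(801, 1199), annotation) == "annotated-intron"

    def test_exon_spanning(self, annotation):
        assert annotation_context(_junction(700, 1300), annotation) == "exon-spanning"

    def test_intergenic(self, annotation):
        assert annotation_context(_junction(5000, 5100), annotation) == "intergenic"


class TestStarLikeFilter:
    def test_low_support_short_overhang_gc_junction_fails(self):
        j = _junction(100, 200, motif_class="GC-AG", unique_support=3, max_overhang=8)
        v = star_like_filter(j)
        assert v.verdict == "fail"
        assert any("overhang 8 below 12" in r for r in v.reasons)

    def test_strong_canonical_junction_passes(self):
        j = _junction(100, 200, motif_class="GT-AG", unique_support=100, max_overhang=50)
        assert star_like_filter(j).verdict == "pass"

    def test_noncanonical_boundaries_are_inclusive(self):
        j = _junction(100, 200, motif_class="noncanonical",
                      unique_support=3, max_overhang=30)
        assert star_like_filter(j).verdict == "pass"
        j2 = _junction(100, 200, motif_class="noncanonical",
                       unique_support=2, max_overhang=30)
        v = star_like_filter(j2)
        assert v.verdict == "fail" and "unique support 2 below 3" in v.reasons[0]

    def test_custom_thresholds(self):
        strict = FilterThresholds(
            overhang_min={"GT-AG": 20, "GC-AG": 20, "AT-AC": 20, "noncanonical": 40},
            count_min={"GT-AG": 5, "GC-AG": 5, "AT-AC": 5, "noncanonical": 10},
        )
        j = _junction(1, 50, motif_class="GT-AG", unique_support=4, max_overhang=25)
        v = star_like_filter(j, strict)
        assert v.verdict == "fail" and len(v.reasons) == 1


class TestAuditReport:
    def test_end_to_end_on_planted_truth(self, tmp_path):
        paths = gen_spliced_reads(tmp_path, seed=3, n_pairs=40,
                                  junction_fraction=0.5, library_type="RF",
                                  gene_strand="-")
        report = audit_report(paths["sam"], paths["fasta"], paths["gff3"],
                              library_type="RF")
        assert len(report) == 1
        entry = report[0]
        assert (entry["intron_start"], entry["intron_end"]) == (2001, 2500)
        assert entry["motif"]["motif_class"] == "GC-AG"
        assert entry["annotation_context"] == "intra-exonic"
        assert entry["strand_specificity"]["strand"] == "-" == entry["gene_strand"]
        assert entry["alignment_inspection"]["unique_support"] == 20
        assert entry["overall_verdict"] == "genuine-candidate"

    def test_no_spliced_reads_empty_report(self, tmp_path):
        paths = gen_spliced_reads(tmp_path, seed=3, n_pairs=20, junction_fraction=0.0)
        assert audit_report(paths["sam"], paths["fasta"], paths["gff3"]) == []

    def test_antisense_contamination_lowers_support_fraction(self, tmp_path):
        paths = gen_spliced_reads(tmp_path, seed=5, n_pairs=100,
                                  junction_fraction=0.5, library_type="RF",
                                  contamination_fraction=0.4)
        report = audit_report(paths["sam"], paths["fasta"], paths["gff3"],
                              library_type="RF")
        frac = report[0]["strand_specificity"]["support_fraction"]
        assert 0.5 <= frac < 0.9  # mixed support, not overwhelming

    def test_junction_table_coordinate_conventions(self, tmp_path):
        sam = write_sam(tmp_path / "t.sam", [("r1", 0, 11, 60, "10M50N10M")])
        table = junction_table(extract_junctions(sam))
        row = table.iloc[0]
        assert (row.intron_start, row.intron_end) == (21, 70)
        assert (row.bed_start, row.bed_end) == (20, 70)
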