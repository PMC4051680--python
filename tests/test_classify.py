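import numpy as np
import pandas as pd
import pytest

import _oracles
from conftest import make_gene, make_model, make_segment
from plastidtx.classify import (
    BLAST6_COLUMNS,
    build_catalog,
    classify_mappings,
    classify_segment,
    read_blast_hits,
    subtype_tally,
)
from plastidtx.errors import ParseError, UnclassifiableSegmentError


class TestPrintedExemplars:
    """Spot checks against rows of the printed ncRNA catalog whose partner
    genes are present in the printed gene table."""

    def test_span_antisense_b3b(self, printed_model):
        seg = make_segment(200, 1495, "+")
        assert classify_segment(seg, printed_model) == ("B3B", ("psbA",))

    def test_intergenic_a1(self, printed_model):
        seg = make_segment(50468, 50658, "-")
        subtype, partners = classify_segment(seg, printed_model)
        assert subtype == "A1"
        assert set(partners) == {"ndhC", "trnV-UAC"}

    def test_two_gene_antisense_b4_reports_outermost(self, printed_model):
        # the segment also fully covers psbF between psbL and psbE
        seg = make_segment(63555, 64076, "+")
        assert classify_segment(seg, printed_model) == ("B4", ("psbL", "psbE"))

    def test_intergenic_a2(self, printed_model):
        seg = make_segment(13547, 13720, "+")
        subtype, partners = classify_segment(seg, printed_model)
        assert subtype == "A2" and set(partners) == {"atpH", "atpI"}

    def test_intergenic_a3(self, printed_model):
        seg = make_segment(28478, 28711, "-")
        subtype, partners = classify_segment(seg, printed_model)
        assert subtype == "A3" and set(partners) == {"petN", "psbM"}

    def test_bilateral_a4_requires_opposite_overlap(self, printed_model):
        fwd = make_segment(44037, 44246, "+")
        rev = make_segment(43994, 44309, "-")
        subtype, _ = classify_segment(fwd, printed_model, opposite_segments=[rev])
        assert subtype == "A4"
        subtype, _ = classify_segment(rev, printed_model, opposite_segments=[fwd])
        assert subtype == "A4"
        # without the opposite partner the same region is plain intergenic
        subtype, _ = classify_segment(fwd, printed_model)
        assert subtype == "A3"


class TestStructuralRules:
    def _host(self, strand="+"):
        return make_model([make_gene("G", 1000, 1600, strand)])

    def test_b1_covers_five_prime_only(self):
        model = self._host("+")
        seg = make_segment(900, 1200, "-")
        assert classify_segment(seg, model) == ("B1", ("G",))
        # the same window against a minus-strand host covers its 3' end
        model = self._host("-")
        seg = make_segment(900, 1200, "+")
        assert classify_segment(seg, model) == ("B2", ("G",))

    def test_b2_covers_three_prime_only(self):
        model = self._host("+")
        seg = make_segment(1400, 1800, "-")
        assert classify_segment(seg, model) == ("B2", ("G",))

    def test_b3a_strictly_inside(self):
        seg = make_segment(1100, 1400, "-")
        assert classify_segment(seg, self._host()) == ("B3A", ("G",))

    def test_b3b_contains_gene(self):
        seg = make_segment(900, 1700, "-")
        assert classify_segment(seg, self._host()) == ("B3B", ("G",))

    def test_b5_intron_wins_over_b3a(self):
        model = make_model(
            [make_gene("G", 1000, 2000, "+", exons=((1000, 1200), (1800, 2000)))]
        )
        seg = make_segment(1300, 1700, "-")
        assert classify_segment(seg, model) == ("B5", ("G",))

    def test_same_strand_overlap_is_sense_transcript(self):
        with pytest.raises(UnclassifiableSegmentError, match="same-strand"):
            classify_segment(make_segment(1100, 1400, "+"), self._host("+"))

    def test_too_close_intergenic_rejected(self):
        model = make_model(
            [make_gene("L", 100, 400, "+"), make_gene("R", 700, 1000, "+")]
        )
        with pytest.raises(UnclassifiableSegmentError, match="closer than"):
            classify_segment(make_segment(450, 560, "+"), model)


class TestCatalog:
    def test_empty_input_empty_catalog(self, printed_model):
        records, rejects = build_catalog([], [], printed_model)
        assert records == [] and rejects == []

    def test_ids_follow_genome_order(self, printed_model):
        segs_plus = [make_segment(63555, 64076, "+")]
        segs_minus = [make_segment(50468, 50658, "-")]
        records, _ = build_catalog(segs_plus, segs_minus, printed_model)
        assert [r.id for r in records] == ["nc1", "nc2"]
        assert records[0].start == 50468  # genome order, not input order

    def test_oracle_equivalence_on_random_fixtures(self):
        """The interval classifier agrees with a per-position enumeration
        oracle on randomized gene models and segments."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(100):
            genes = []
            cursor = 200
            for i in range(rng.integers(3, 7)):
                length = int(rng.integers(150, 500))
                gap = int(rng.integers(0, 400))
                strand = "+" if rng.random() < 0.5 else "-"
                start = cursor + gap
                exons = ()
                if length > 360 and rng.random() < 0.3:
                    exons = ((start, start + 99), (start + length - 100, start + length - 1))
                genes.append(
                    make_gene(f"g{i}", start, start + length - 1, strand, exons=exons)
                )
                cursor = start + length
            model = make_model(genes, genome_length=cursor + 1000)
            for _ in range(5):
                s = int(rng.integers(100, cursor))
                e = s + int(rng.integers(100, 400))
                seg = make_segment(s, e, "+" if rng.random() < 0.5 else "-")
                expected = _oracles.classify_by_positions(seg, model)
                try:
                    got = classify_segment(seg, model)
                except UnclassifiableSegmentError:
                    got = None
                assert got == expected, (seg, [(g.start, g.end, g.strand) for g in genes])
                checked += 1
        assert checked == 500


class TestMappingClasses:
    def _df(self, pairs):
        rows = [
            [q, s, 95.0, 100, 1, 0, 1, 100, 1, 100, e, 180.0]
            for q, s, e in pairs
        ]
        return pd.DataFrame(rows, columns=BLAST6_COLUMNS)

    def test_one_to_n(self):
        maps = classify_mappings(
            self._df([("nc99", "ndhF-5p-1", 1e-12), ("nc99", "ndhF-5p-2", 2e-23)])
        )
        assert [m.mapping_class for m in maps] == ["1:n"]

    def test_n_to_n(self):
        maps = classify_mappings(
            self._df(
                [("nc92", "trnL-ndhBint", 4e-90), ("nc92", "ndhB-3p", 3e-44),
                 ("nc93", "ndhB-3p", 1e-110)]
            )
        )
        assert [m.mapping_class for m in maps] == ["n:n"]
        assert maps[0].component_queries == ("nc92", "nc93")

    def test_one_to_one_and_evalue_filter(self):
        assert [m.mapping_class for m in classify_mappings(self._df([("q", "s", 1e-10)]))] == ["1:1"]
        assert classify_mappings(self._df([("q", "s", 1e-3)])) == []

    def test_invariant_to_row_order(self):
        pairs = [("q1", "s1", 1e-9), ("q2", "s1", 1e-8), ("q2", "s2", 1e-7),
                 ("q3", "s3", 1e-12)]
        fwd = classify_mappings(self._df(pairs))
        rev = classify_mappings(self._df(list(reversed(pairs))))
        assert fwd == rev

    def test_malformed_hits_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t95.0\t100\n")
        with pytest.raises(ParseError):
            read_blast_hits(p)


class TestPrintedCatalogTallies:
    def test_printed_subtype_column_is_internally_consistent(self, printed_catalog):
        tally = subtype_tally(printed_catalog)
        assert tally == {
            "A1": 1, "A2": 4, "A3": 9, "A4": 4,
            "B1": 9, "B2": 9, "B3A": 72, "B3B": 6, "B4": 11, "B5": 11,
        }
        assert sum(tally.values()) == 136
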