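import numpy as np
import pytest
from scipy import stats

from conftest import make_gene, make_model
from plastidtx.associations import (
    Transcript,
    link_downstream,
    modification_expression_anova,
    rank_insertion_sites,
    sat_compare,
)
from plastidtx.classify import NcRNARecord
from plastidtx.errors import DegenerateGroupingError
from plastidtx.modification import MotifOccurrence
from plastidtx.segments import Polycistron


def _rec(i, subtype, partner, start=1, end=200, strand="+"):
    return NcRNARecord(id=f"nc{i}", subtype=subtype, partner_genes=(partner,),
                       start=start, end=end, strand=strand)


class TestSatCompare:
    def test_planted_offset_detected(self):
        rng = np.random.default_rng(0)
        ab = {}
        catalog = []
        for i in range(40):
            ab[f"gA{i}"] = rng.normal(7.0, 1.0)
            catalog.append(_rec(i, "B3A", f"gA{i}"))
        for i in range(27):
            ab[f"gB{i}"] = rng.normal(5.0, 1.0)
        comp, breakdown = sat_compare(catalog, ab)
        assert comp.significant and comp.p_value < 1e-6
        assert comp.group_sizes == (40, 27)
        assert breakdown["coding"]  # all partners are coding-antisense here

    def test_all_genes_with_asrna_is_degenerate(self):
        ab = {"g0": 5.0, "g1": 6.0}
        catalog = [_rec(0, "B3A", "g0"), _rec(1, "B2", "g1")]
        with pytest.raises(DegenerateGroupingError):
            sat_compare(catalog, ab)

    def test_invariant_to_common_shift_and_order(self):
        rng = np.random.default_rng(1)
        ab = {f"g{i}": rng.normal(5, 1) for i in range(30)}
        catalog = [_rec(i, "B1", f"g{i}") for i in range(12)]
        p1 = sat_compare(catalog, ab)[0].p_value
        shifted = {k: v + 11.5 for k, v in ab.items()}
        p2 = sat_compare(list(reversed(catalog)), shifted)[0].p_value
        assert p1 == pytest.approx(p2)

    def test_intergenic_records_do_not_mark_genes(self):
        ab = {"g0": 5.0, "g1": 6.0, "g2": 4.0}
        catalog = [
            NcRNARecord(id="nc1", subtype="A1", partner_genes=("g0", "g1"),
                        start=1, end=200, strand="+"),
            _rec(2, "B3A", "g2"),
        ]
        comp, _ = sat_compare(catalog, ab)
        assert comp.group_sizes == (1, 2)  # only g2 counts as asRNA-bearing


class TestLinkDownstream:
    def test_plus_strand_distance_window(self):
        occ = MotifOccurrence("M", 1000, 1010, "+")
        inside = Transcript("a", 1211, 1400, "+", "ncRNA")     # gap 200
        too_close = Transcript("b", 1050, 1200, "+", "ncRNA")  # gap 39
        links = link_downstream([occ], [inside, too_close], 100, 500)
        assert [(l.transcript.id, l.distance) for l in links] == [("a", 200)]

    def test_minus_strand_distance(self):
        occ = MotifOccurrence("M", 2000, 2010, "-")
        t = Transcript("a", 1600, 1800, "-", "ncRNA")  # 5' start at 1800
        links = link_downstream([occ], [t], 100, 500)
        assert [(l.transcript.id, l.distance) for l in links] == [("a", 199)]

    def test_opposite_strand_never_linked(self):
        occ = MotifOccurrence("M", 1000, 1010, "+")
        t = Transcript("a", 1211, 1400, "-", "ncRNA")
        assert link_downstream([occ], [t], 100, 500) == []

    def test_matches_exhaustive_pair_scan(self):
        rng = np.random.default_rng(3)
        occs = [
            MotifOccurrence("M", int(s), int(s) + 10, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(100, 5000, size=15)
        ]
        trs = [
            Transcript(f"t{i}", int(s), int(s) + 150, "+" if rng.random() < 0.5 else "-",
                       "ncRNA")
            for i, s in enumerate(rng.integers(100, 5000, size=25))
        ]
        got = {(l.occurrence.start, l.transcript.id) for l in
               link_downstream(occs, trs, 100, 500)}
        expected = set()
        for o in occs:
            for t in trs:
                if t.strand != o.strand:
                    continue
                five = t.start if t.strand == "+" else t.end
                gap = (
                    len(range(o.end + 1, five)) if o.strand == "+"
                    else len(range(five + 1, o.start))
                )
                if t.strand == "+" and five <= o.end:
                    continue
                if t.strand == "-" and five >= o.start:
                    continue
                if 100 <= gap <= 500:
                    expected.add((o.start, t.id))
        assert got == expected


def _links(n_mod, n_unmod, rng, effect=0.0):
    links, ab = [], {}
    occ_i = 0
    for modified, n in ((True, n_mod), (False, n_unmod)):
        for _ in range(n):
            occ_i += 1
            occ = MotifOccurrence("M", occ_i * 1000, occ_i * 1000 + 10, "+",
                                  modified=modified)
            t = Transcript(f"t{occ_i}", occ_i * 1000 + 211, occ_i * 1000 + 400,
                           "+", "ncRNA")
            ab[t.id] = rng.normal(5.0 + (effect if modified else 0.0), 1.0)
            links.extend(link_downstream([occ], [t], 100, 500))
    return links, ab


class TestModificationAnova:
    def test_equal_groups_give_f_zero(self):
        links, _ = _links(3, 3, np.random.default_rng(0))
        # identical value sets in both groups: equal means, nonzero spread
        ab = {f"t{i}": v for i, v in zip(range(1, 7), [4.0, 5.0, 6.0] * 2)}
        res = modification_expression_anova(links, ab)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(4)
        links, ab = _links(8, 9, rng, effect=1.0)
        res = modification_expression_anova(links, ab)
        mod = [ab[l.transcript.id] for l in links if l.motif_modified]
        unmod = [ab[l.transcript.id] for l in links if not l.motif_modified]
        t = stats.ttest_ind(mod, unmod, equal_var=True).statistic
        assert res.statistic == pytest.approx(t**2)

    def test_degenerate_grouping(self):
        links, ab = _links(5, 1, np.random.default_rng(5))
        with pytest.raises(DegenerateGroupingError):
            modification_expression_anova(links, ab)


class TestInsertionSites:
    def test_min_flank_scoring_and_position_tie_break(self):
        genes = [
            make_gene("A", 100, 400, "+"),
            make_gene("B", 600, 900, "+"),
            make_gene("C", 1100, 1400, "+"),
        ]
        model = make_model(genes)
        pc = Polycistron(id=1, strand="+", start=100, end=1400,
                         member_gene_names=("A", "B", "C"))
        sites = rank_insertion_sites([pc], model, {"A": 10.0, "B": 2.0, "C": 10.0})
        assert [s.score for s in sites] == [2.0, 2.0]
        assert sites[0].gap_start < sites[1].gap_start  # tie broken by position

    def test_overlapping_adjacent_genes_yield_no_candidate(self):
        genes = [make_gene("A", 100, 500, "+"), make_gene("B", 480, 900, "+")]
        model = make_model(genes)
        pc = Polycistron(id=1, strand="+", start=100, end=900,
                         member_gene_names=("A", "B"))
        assert rank_insertion_sites([pc], model, {"A": 5.0, "B": 5.0}) == []

    def test_small_gaps_filtered(self):
        genes = [make_gene("A", 100, 400, "+"), make_gene("B", 410, 700, "+")]
        model = make_model(genes)
        pc = Polycistron(id=1, strand="+", start=100, end=700,
                         member_gene_names=("A", "B"))
        assert rank_insertion_sites([pc], model, {"A": 5.0, "B": 5.0}, min_gap=20) == []
        assert len(rank_insertion_sites([pc], model, {"A": 5.0, "B": 5.0}, min_gap=5)) == 1
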