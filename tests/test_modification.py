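import numpy as np
import pytest

import _oracles
from plastidtx.errors import PlastidtxError
from plastidtx.modification import (
    KineticsRow,
    ModificationCall,
    MotifOccurrence,
    annotate_occurrences,
    call_modifications,
    iupac_match,
    read_kinetics,
    reverse_complement_motif,
    scan_motif,
    summarize_motif,
)
from plastidtx.simulate import simulate_kinetics


class TestIupacMatch:
    @pytest.mark.parametrize(
        "window,motif,expected",
        [
            ("TATAGGGATCA", "TATANNNATNA", True),
            ("ATCAGTGAA", "WNYANTGAW", True),
            ("TATAGGGATCG", "TATANNNATNA", False),
        ],
    )
    def test_degenerate_table(self, window, motif, expected):
        assert iupac_match(window, motif) is expected

    def test_non_iupac_character_rejected(self):
        with pytest.raises(ValueError):
            iupac_match("ACGT", "ACXT")

    def test_motif_reverse_complement(self):
        assert reverse_complement_motif("WNYANTGAW") == "WTCANTRNW"


class TestScanMotif:
    def test_minus_strand_occurrence(self):
        # "TGATCCCTATA" is the reverse complement of "TATAGGGATCA"
        occs = scan_motif("TGATCCCTATA", "TATANNNATNA")
        assert [(o.start, o.end, o.strand) for o in occs] == [(1, 11, "-")]

    def test_sequence_shorter_than_motif(self):
        assert scan_motif("ACGT", "TATANNNATNA") == []

    def test_overlapping_matches_all_reported(self):
        occs = scan_motif("CAAAC", "AA")
        plus = [(o.start, o.end) for o in occs if o.strand == "+"]
        assert plus == [(2, 3), (3, 4)]
        # "AA" on the minus strand means "TT" forward, absent here
        assert all(o.strand == "+" for o in occs)

    def test_matches_all_window_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            for motif in ("WNYANTGAW", "TATANNNATNA", "RYN"):
                got = {(o.start, o.end, o.strand) for o in scan_motif(seq, motif)}
                assert got == _oracles.scan_windows(seq, motif)

    def test_strand_symmetry_under_reverse_complement(self):
        rng = np.random.default_rng(6)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            rc = "".join(comp[b] for b in reversed(seq))
            fwd = scan_motif(seq, "WNYANTGAW")
            rev = scan_motif(rc, "WNYANTGAW")
            assert len(fwd) == len(rev)
            assert sum(o.strand == "+" for o in fwd) == sum(
                o.strand == "-" for o in rev
            )


def _row(position, ipds, control, strand="+"):
    return KineticsRow(position=position, strand=strand,
                       case_ipds=tuple(ipds), control_mean=control)


class TestCallModifications:
    def test_null_position_never_significant(self):
        calls, _ = call_modifications([_row(1, [0.8] * 20, 0.8)])
        assert calls[0].ipd_ratio == pytest.approx(1.0)
        assert calls[0].p_value == pytest.approx(1.0)
        assert not calls[0].significant

    def test_strong_slowdown_called(self):
        rng = np.random.default_rng(0)
        ipds = np.exp(rng.normal(np.log(5.0), 0.05, size=50))
        calls, _ = call_modifications([_row(10, ipds, 1.0)])
        c = calls[0]
        assert c.ipd_ratio == pytest.approx(5.0, rel=0.05)
        assert c.significant and c.p_value < 1e-10
        # sign-flip permutation agrees: every log deviation is positive,
        # so no sign assignment reaches the observed mean
        d = np.log(ipds) - np.log(1.0)
        flips = rng.choice([-1.0, 1.0], size=(2000, len(d)))
        perm_means = (flips * d).mean(axis=1)
        assert (perm_means >= d.mean()).mean() < 0.001

    def test_low_coverage_skipped_not_called(self):
        calls, skipped = call_modifications(
            [_row(1, [1.0] * 5, 1.0), _row(2, [1.0] * 20, 1.0)], min_coverage=10
        )
        assert [c.position for c in calls] == [2]
        assert [r.position for r in skipped] == [1]

    def test_fdr_flag_is_more_conservative(self):
        rng = np.random.default_rng(1)
        rows = [
            _row(i, np.exp(rng.normal(0.0, 0.6, size=30)), 1.0)
            for i in range(1, 301)
        ]
        raw, _ = call_modifications(rows, alpha=0.05)
        adj, _ = call_modifications(rows, alpha=0.05, fdr=True)
        assert sum(c.significant for c in adj) <= sum(c.significant for c in raw)


class TestKineticsIO:
    def test_per_observation_round_trip(self, tmp_path):
        import pandas as pd

        rows = [_row(5, [1.0, 1.2, 0.9], 1.1), _row(7, [2.0, 2.2], 1.0, strand="-")]
        recs = [
            {"position": r.position, "strand": r.strand, "ipd": ipd,
             "control_mean": r.control_mean}
            for r in rows for ipd in r.case_ipds
        ]
        path = tmp_path / "k.csv"
        pd.DataFrame(recs).to_csv(path, index=False)
        loaded = read_kinetics(path)
        assert [(r.position, r.strand, r.coverage) for r in loaded] == [
            (5, "+", 3), (7, "-", 2)
        ]

    def test_aggregated_layout_preserves_location(self, tmp_path):
        import pandas as pd

        pd.DataFrame(
            [{"position": 3, "strand": "+", "case_mean": 3.0, "case_sd": 0.3,
              "coverage": 40, "control_mean": 1.0}]
        ).to_csv(tmp_path / "k.csv", index=False)
        loaded = read_kinetics(tmp_path / "k.csv")
        calls, _ = call_modifications(loaded)
        assert calls[0].ipd_ratio == pytest.approx(3.0, rel=0.05)
        assert calls[0].significant


def _occ(start, end, strand="+", motif_id="M"):
    return MotifOccurrence(motif_id, start, end, strand)


def _call(position, strand="+", ratio=2.0, p=1e-4, coverage=50, significant=True):
    return ModificationCall(position=position, strand=strand, ipd_ratio=ratio,
                            p_value=p, coverage=coverage, significant=significant)


class TestMotifSummary:
    def test_no_significant_calls(self):
        occs = [_occ(10, 20), _occ(100, 110)]
        s = summarize_motif(occs, [], "M", "TATANNNATNA")
        assert (s.total, s.modified, s.fraction) == (2, 0, 0.0)
        assert s.modal_offset is None

    def test_offsets_are_strand_oriented(self):
        occs = annotate_occurrences(
            [_occ(10, 20, "+"), _occ(50, 60, "-")],
            [_call(13, "+"), _call(57, "-")],
        )
        assert occs[0].modified_offsets == (3,)
        assert occs[1].modified_offsets == (3,)  # 60 - 57, counted from the 5' end

    def test_modal_offset_tie_breaks_small(self):
        occs = [_occ(10, 20), _occ(30, 40)]
        calls = [_call(12), _call(35)]  # offsets 2 and 5, one vote each
        s = summarize_motif(occs, calls, "M", "TATANNNATNA")
        assert s.modal_offset == 2
        assert s.modal_offset_from_end == 2 - 10

    def test_call_on_wrong_strand_does_not_modify(self):
        occs = annotate_occurrences([_occ(10, 20, "+")], [_call(13, "-")])
        assert not occs[0].modified

    def test_absent_motif_is_an_error(self):
        with pytest.raises(PlastidtxError, match="absent"):
            summarize_motif([], [], "M", "TATA")

    def test_means_average_over_significant_calls_in_modified_occurrences(self):
        occs = [_occ(10, 20), _occ(30, 40), _occ(50, 60)]
        calls = [_call(12, ratio=2.0, coverage=40), _call(33, ratio=4.0, coverage=80),
                 _call(55, significant=False, ratio=9.0)]
        s = summarize_motif(occs, calls, "M", "TATANNNATNA")
        assert s.modified == 2
        assert s.mean_ipd_ratio == pytest.approx(3.0)
        assert s.mean_coverage == pytest.approx(60.0)


class TestSimulatedKinetics:
    def test_planted_ratio_recovered(self):
        rng = np.random.default_rng(9)
        rows = simulate_kinetics(
            [(i, "+") for i in range(1, 201)], [True] * 200, rng,
            coverage=50, mod_ipd_ratio=3.0,
        )
        calls, _ = call_modifications(rows)
        mean_ratio = np.mean([c.ipd_ratio for c in calls])
        assert mean_ratio == pytest.approx(3.0, rel=0.1)
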