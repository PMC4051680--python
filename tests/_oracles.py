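"""Independent brute-force oracles used by the test suite.

These re-derive results through per-position enumeration and exhaustive
window checks, deliberately avoiding the interval arithmetic and regex
machinery of the package under test.
"""

from __future__ import annotations

# independent copy of the degenerate-nucleotide table
_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def segment_runs(depth, c_min, l_min):
    """Run-length segment detection by explicit position walking."""
    runs = []
    start = None
    for i, d in enumerate(depth, start=1):
        if d >= c_min and start is None:
            start = i
        elif d < c_min and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(depth)))
    return [(s, e) for s, e in runs if e - s + 1 >= l_min]


def overlap_positions(a_start, a_end, b_start, b_end):
    """Overlap size by counting shared positions."""
    return len(set(range(a_start, a_end + 1)) & set(range(b_start, b_end + 1)))


def scan_windows(seq, motif):
    """All-window IUPAC scan of both strands; returns {(start,end,strand)}."""
    seq = seq.upper()
    L = len(motif)
    rc = "".join(_COMP[b] for b in reversed(seq))
    n = len(seq)
    hits = set()
    for i in range(n - L + 1):
        if all(seq[i + j] in _IUPAC[motif[j]] for j in range(L)):
            hits.add((i + 1, i + L, "+"))
        if all(rc[i + j] in _IUPAC[motif[j]] for j in range(L)):
            # positions i..i+L-1 on the reverse complement map back to
            # forward-axis n-i-L+1 .. n-i (1-based)
            hits.add((n - i - L + 1, n - i, "-"))
    return hits


def classify_by_positions(seg, model, opposite_segments=(), min_dist=100):
    """Position-set re-derivation of the ncRNA subtype rules.

    Returns (subtype, partners) or None when the segment is unclassifiable.
    """
    pos = set(range(seg.start, seg.end + 1))

    def gene_pos(g):
        return set(range(g.start, g.end + 1))

    if any(g.strand == seg.strand and pos & gene_pos(g) for g in model.genes):
        return None
    opp = sorted(
        (g for g in model.genes if g.strand != seg.strand and pos & gene_pos(g)),
        key=lambda g: (g.start, g.end),
    )
    if opp:
        for g in opp:
            for i_start, i_end in g.introns:
                if pos <= set(range(i_start, i_end + 1)):
                    return "B5", (g.name,)
        if len(opp) >= 2:
            return "B4", (opp[0].name, opp[-1].name)
        g = opp[0]
        gp = gene_pos(g)
        if gp <= pos:
            return "B3B", (g.name,)
        five = g.start if g.strand == "+" else g.end
        three = g.end if g.strand == "+" else g.start
        if five in pos and three not in pos:
            return "B1", (g.name,)
        if three in pos and five not in pos:
            return "B2", (g.name,)
        if pos <= gp:
            return "B3A", (g.name,)
        return None

    lefts = [g for g in model.genes if g.end < seg.start]
    rights = [g for g in model.genes if g.start > seg.end]
    if not lefts or not rights:
        return None
    left = max(lefts, key=lambda g: g.end)
    right = min(rights, key=lambda g: g.start)
    gap_left = len(set(range(left.end + 1, seg.start)))
    gap_right = len(set(range(seg.end + 1, right.start)))
    if gap_left < min_dist or gap_right < min_dist:
        return None
    partners = (left.name, right.name)
    for other in opposite_segments:
        other_pos = set(range(other.start, other.end + 1))
        if pos & other_pos and not any(other_pos & gene_pos(g) for g in model.genes):
            return "A4", partners
    if left.strand == seg.strand and right.strand == seg.strand:
        return "A1", partners
    if left.strand == right.strand:
        return "A2", partners
    return "A3", partners
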