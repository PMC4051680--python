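"""ncRNA subtype classification and cross-species mapping classes.

Transcribed segments that do not correspond to an annotated same-strand
gene are either intergenic (subtypes A1-A4) or antisense (B1-B5):

* A1 - intergenic, both flanking genes on the segment's strand
* A2 - intergenic, flanking genes agree with each other but oppose the segment
* A3 - intergenic, flanking genes on opposite strands
* A4 - bilateral: two overlapping intergenic segments, one per strand
* B1 - antisense, covers the partner gene's 5' boundary only
* B2 - antisense, covers the partner gene's 3' boundary only
* B3A - antisense, strictly inside the partner gene's span
* B3B - antisense, contains the partner gene's entire span
* B4 - antisense, spans two or more adjacent genes (outermost two reported)
* B5 - antisense, entirely within one intron of the partner gene

The structural B rules are evaluated most-specific-first
(B5 > B4 > B3B > B1/B2 > B3A) so that overlap ambiguity resolves
deterministically.  A-subtype semantics follow the exemplars of the study
this package re-implements and are configurable via ``min_intergenic_dist``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import ParseError, UnclassifiableSegmentError
from .model import GeneModel, Strand, feature_length, opposite
from .segments import TranscribedSegment

SUBTYPES = ("A1", "A2", "A3", "A4", "B1", "B2", "B3A", "B3B", "B4", "B5")
ANTISENSE_SUBTYPES = ("B1", "B2", "B3A", "B3B", "B4", "B5")


@dataclass(frozen=True)
class NcRNARecord:
    id: str
    subtype: str
    partner_genes: tuple[str, ...]
    start: int
    end: int
    strand: Strand
    log_abundance: Optional[float] = None
    partner_log_abundance: Optional[float] = None
    log_ratio: Optional[float] = None

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")

    @property
    def length(self) -> int:
        return feature_length(self.start, self.end)

    @property
    def is_antisense(self) -> bool:
        return self.subtype in ANTISENSE_SUBTYPES


def _overlaps(seg, start: int, end: int) -> bool:
    return seg.start <= end and start <= seg.end


def classify_segment(
    seg: TranscribedSegment,
    model: GeneModel,
    opposite_segments: Sequence[TranscribedSegment] = (),
    min_intergenic_dist: int = 100,
) -> tuple[str, tuple[str, ...]]:
    """Classify one segment; returns ``(subtype, partner gene names)``.

    ``opposite_segments`` are the segments detected on the other strand;
    they are needed only to recognise bilateral (A4) transcripts.  Raises
    :class:`UnclassifiableSegmentError` with a reason otherwise.
    """
    same = model.overlapping(seg.start, seg.end, strand=seg.strand)
    if same:
        raise UnclassifiableSegmentError(
            f"overlaps same-strand gene(s) {','.join(g.name for g in same)}: "
            "treated as (part of) the sense transcript"
        )
    opp = sorted(
        model.overlapping(seg.start, seg.end, strand=opposite(seg.strand)),
        key=lambda g: (g.start, g.end),
    )
    if opp:
        # B5: entirely within one intron
        for g in opp:
            for (is_, ie) in g.introns:
                if is_ <= seg.start and seg.end <= ie:
                    return "B5", (g.name,)
        if len(opp) >= 2:
            return "B4", (opp[0].name, opp[-1].name)
        g = opp[0]
        if seg.start <= g.start and g.end <= seg.end:
            return "B3B", (g.name,)
        covers_5 = seg.start <= g.five_prime <= seg.end
        covers_3 = seg.start <= g.three_prime <= seg.end
        if covers_5 and not covers_3:
            return "B1", (g.name,)
        if covers_3 and not covers_5:
            return "B2", (g.name,)
        if g.start <= seg.start and seg.end <= g.end:
            return "B3A", (g.name,)
        raise UnclassifiableSegmentError("antisense overlap fits no B rule")

    # intergenic path
    left, right = model.flanking(seg.start, seg.end)
    if left is None or right is None:
        raise UnclassifiableSegmentError("no flanking transcript on one side")
    dist_left = seg.start - left.end - 1
    dist_right = right.start - seg.end - 1
    if dist_left < min_intergenic_dist or dist_right < min_intergenic_dist:
        raise UnclassifiableSegmentError(
            f"closer than {min_intergenic_dist} bp to a flanking transcript"
        )
    partners = (left.name, right.name)
    for other in opposite_segments:
        if _overlaps(other, seg.start, seg.end) and not model.overlapping(
            other.start, other.end
        ):
            return "A4", partners
    if left.strand == seg.strand and right.strand == seg.strand:
        return "A1", partners
    if left.strand == right.strand:
        return "A2", partners
    return "A3", partners


@dataclass(frozen=True)
class RejectedSegment:
    segment: TranscribedSegment
    reason: str


def build_catalog(
    segments_plus: Sequence[TranscribedSegment],
    segments_minus: Sequence[TranscribedSegment],
    model: GeneModel,
    min_intergenic_dist: int = 100,
    prefix: str = "nc",
) -> tuple[list[NcRNARecord], list[RejectedSegment]]:
    """Classify all segments into an ncRNA catalog.

    Ids are assigned in genome order.  Segments that cannot be classified
    (sense transcripts, boundary cases) are reported alongside, never
    silently dropped.
    """
    by_strand = {"+": segments_plus, "-": segments_minus}
    ordered = sorted(
        list(segments_plus) + list(segments_minus),
        key=lambda s: (s.start, s.end, s.strand),
    )
    records: list[NcRNARecord] = []
    rejects: list[RejectedSegment] = []
    n = 0
    for seg in ordered:
        try:
            subtype, partners = classify_segment(
                seg,
                model,
                opposite_segments=by_strand[opposite(seg.strand)],
                min_intergenic_dist=min_intergenic_dist,
            )
        except UnclassifiableSegmentError as exc:
            rejects.append(RejectedSegment(seg, exc.reason))
            continue
        n += 1
        records.append(
            NcRNARecord(
                id=f"{prefix}{n}",
                subtype=subtype,
                partner_genes=partners,
                start=seg.start,
                end=seg.end,
                strand=seg.strand,
            )
        )
    return records, rejects


def subtype_tally(records: Iterable[NcRNARecord]) -> dict[str, int]:
    tally = {s: 0 for s in SUBTYPES}
    for r in records:
        tally[r.subtype] += 1
    return tally


# ---------------------------------------------------------------------------
# cross-species homology mapping classes
# ---------------------------------------------------------------------------

BLAST6_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class MappingClass:
    component_queries: tuple[str, ...]
    component_subjects: tuple[str, ...]

    @property
    def mapping_class(self) -> str:
        nq, ns = len(self.component_queries), len(self.component_subjects)
        if nq == 1 and ns == 1:
            return "1:1"
        if nq == 1:
            return "1:n"
        if ns == 1:
            return "n:1"
        return "n:n"


def read_blast_hits(path: str | Path) -> pd.DataFrame:
    """Read 12-column tabular alignment hits (BLAST outfmt 6)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] != 12 or df["evalue"].isna().any():
        bad = int(df.index[df["evalue"].isna()][0]) + 1 if df["evalue"].isna().any() else "?"
        raise ParseError(f"{path}: malformed hit row {bad}")
    return df


def classify_mappings(
    hits: pd.DataFrame | str | Path, e_max: float = 1e-5
) -> list[MappingClass]:
    """Group E-value-filtered query/subject pairs into bipartite components.

    Hits with E >= ``e_max`` are discarded; the remaining deduplicated
    pairs form a bipartite graph whose connected components determine the
    mapping class (1:1, 1:n, n:1, n:n).  The result is invariant to hit
    row order.
    """
    if not isinstance(hits, pd.DataFrame):
        hits = read_blast_hits(hits)
    kept = hits[hits["evalue"] < e_max]
    graph = nx.Graph()
    for q, s in {(str(q), str(s)) for q, s in zip(kept["query"], kept["subject"])}:
        graph.add_edge(("q", q), ("s", s))
    out = []
    for comp in nx.connected_components(graph):
        queries = tuple(sorted(n for side, n in comp if side == "q"))
        subjects = tuple(sorted(n for side, n in comp if side == "s"))
        out.append(MappingClass(queries, subjects))
    out.sort(key=lambda m: (m.component_queries, m.component_subjects))
    return out
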