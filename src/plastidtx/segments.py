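"""Strand-specific transcribed-segment detection and polycistron calling.

A transcribed segment is a maximal run of positions whose read depth is at
least ``c_min`` (default 1 — ncRNAs are lowly expressed, so no higher
cutoff is imposed).  Polycistronic units are continuous transcripts that
cover two or more annotated genes on one strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ParseError
from .model import GeneModel, Strand, feature_length

@dataclass
class StrandCoverage:
    """Dense per-position read depth over [1, genome_length] for one strand."""

    strand: Strand
    depth: np.ndarray  # index 0 holds position 1

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValueError("negative depth")

    @property
    def genome_length(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class TranscribedSegment:
    start: int
    end: int
    strand: Strand
    mean_depth: float
    total_depth: float
    read_count: Optional[int] = None

    @property
    def length(self) -> int:
        return feature_length(self.start, self.end)


@dataclass(frozen=True)
class Polycistron:
    id: int
    strand: Strand
    start: int
    end: int
    member_gene_names: tuple[str, ...]

    @property
    def n_members(self) -> int:
        return len(self.member_gene_names)


def _read_bedgraph(path: str | Path, genome_length: int) -> np.ndarray:
    """Parse a bedGraph file (0-based, half-open) into dense 1-based depth."""
    depth = np.zeros(genome_length, dtype=float)
    seen = np.zeros(genome_length, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            try:
                start0, end0, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if value < 0:
                raise ParseError(f"{path}: line {lineno}: negative depth {value}")
            if start0 < 0 or end0 > genome_length or start0 >= end0:
                raise ParseError(
                    f"{path}: line {lineno}: interval [{start0},{end0}) outside "
                    f"genome of length {genome_length}"
                )
            if seen[start0:end0].any():
                raise ParseError(
                    f"{path}: line {lineno}: overlapping bedGraph intervals"
                )
            seen[start0:end0] = True
            depth[start0:end0] = value
    return depth


def load_coverage(
    plus_path: str | Path, minus_path: str | Path, genome_length: int
) -> tuple[StrandCoverage, StrandCoverage]:
    """Read one bedGraph per strand into dense per-position depth arrays."""
    return (
        StrandCoverage("+", _read_bedgraph(plus_path, genome_length)),
        StrandCoverage("-", _read_bedgraph(minus_path, genome_length)),
    )


def write_bedgraph(cov: StrandCoverage, path: str | Path, chrom: str = "genome") -> None:
    """Write dense depth back to bedGraph (runs of constant non-zero depth)."""
    d = cov.depth
    with open(path, "w") as fh:
        boundaries = np.flatnonzero(np.diff(d) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(d)]))
        for s, e in zip(starts, ends):
            if d[s] != 0:
                v = d[s]
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def detect_segments(
    cov: StrandCoverage, c_min: float = 1, l_min: int = 1
) -> list[TranscribedSegment]:
    """Maximal runs of depth >= c_min, filtered to length >= l_min.

    Segments are returned sorted by start; ``mean_depth`` is the arithmetic
    mean of the depth over the run.
    """
    if c_min < 1 or l_min < 1:
        raise ValueError("c_min and l_min must be >= 1")
    mask = cov.depth >= c_min
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    out: list[TranscribedSegment] = []
    for s0, e0 in zip(edges[::2], edges[1::2]):  # 0-based half-open runs
        if e0 - s0 < l_min:
            continue
        run = cov.depth[s0:e0]
        out.append(
            TranscribedSegment(
                start=s0 + 1,
                end=e0,
                strand=cov.strand,
                mean_depth=float(run.mean()),
                total_depth=float(run.sum()),
            )
        )
    return out


def merge_segments(
    segments: Sequence[TranscribedSegment], max_gap: int = 0
) -> list[TranscribedSegment]:
    """Merge same-strand segments separated by at most ``max_gap`` bases."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[TranscribedSegment] = []
    for seg in sorted(segments, key=lambda s: (s.start, s.end)):
        if out and seg.strand == out[-1].strand and seg.start - out[-1].end - 1 <= max_gap:
            prev = out[-1]
            total = prev.total_depth + seg.total_depth
            end = max(prev.end, seg.end)
            out[-1] = TranscribedSegment(
                start=prev.start,
                end=end,
                strand=prev.strand,
                mean_depth=total / feature_length(prev.start, end),
                total_depth=total,
            )
        else:
            out.append(seg)
    return out


def call_polycistrons(
    segments: Sequence[TranscribedSegment],
    model: GeneModel,
    max_gap: int = 0,
    member_overlap_frac: float = 0.5,
    same_strand_members: bool = True,
) -> list[Polycistron]:
    """Call polycistronic units from continuous transcripts.

    Per strand, segments separated by at most ``max_gap`` are merged; a
    merged transcript that covers at least ``member_overlap_frac`` of each
    of two or more genes yields one unit.  Member names are deduplicated
    (inverted-repeat copies count once); unit ids are assigned in genome
    order starting at 1.
    """
    units: list[tuple[int, str, tuple[str, ...]]] = []
    for strand in ("+", "-"):
        strand_segs = [s for s in segments if s.strand == strand]
        for merged in merge_segments(strand_segs, max_gap=max_gap):
            members: list[str] = []
            genes = model.overlapping(
                merged.start, merged.end, strand=strand if same_strand_members else None
            )
            for g in sorted(genes, key=lambda g: (g.start, g.end)):
                overlap = min(merged.end, g.end) - max(merged.start, g.start) + 1
                if overlap >= member_overlap_frac * g.length:
                    if g.name not in members:
                        members.append(g.name)
            if len(members) >= 2:
                units.append((merged.start, merged.end, strand, tuple(members)))
    units.sort(key=lambda u: (u[0], u[1], u[2]))
    return [
        Polycistron(id=i, strand=strand, start=start, end=end, member_gene_names=names)
        for i, (start, end, strand, names) in enumerate(units, start=1)
    ]
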