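"""Genome/annotation data model, interval algebra and annotation IO.

Coordinates are 1-based inclusive throughout the package, matching the
conventions of organellar genome tables.  bedGraph input (0-based,
half-open) is converted at the reader boundary in :mod:`plastidtx.segments`.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError

Strand = Literal["+", "-"]

GENE_CLASSES = ("protein", "tRNA", "rRNA", "pseudogene")

_VALID_BASES = set("ACGTN")


def opposite(strand: Strand) -> Strand:
    return "-" if strand == "+" else "+"


@dataclass(frozen=True)
class GenomeSequence:
    """A (typically circular) genome sequence.

    The sequence is normalised to upper case; only A/C/G/T/N are accepted.
    Intervals never wrap around the origin anywhere in the package.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"genome contains non-IUPAC-core characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"({start},{end}) outside genome [1,{self.length}]")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class Gene:
    id: str
    name: str
    gene_class: str
    strand: Strand
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    polycistron_label: Optional[int] = None
    log_abundance: Optional[float] = None

    def __post_init__(self):
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r} for {self.id}")
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start > end")
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        ex = tuple(sorted(self.exons))
        prev_end = None
        for s, e in ex:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"gene {self.id}: exon ({s},{e}) outside span")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"gene {self.id}: overlapping exons")
            prev_end = e
        object.__setattr__(self, "exons", ex)

    @property
    def length(self) -> int:
        return feature_length(self.start, self.end)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, 1-based inclusive."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class GeneModel:
    """An annotated gene set over one genome."""

    genes: list[Gene]
    genome_length: int
    total_mapped_reads: Optional[int] = None

    def __post_init__(self):
        ids = [g.id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("gene ids are not unique")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.strand))

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def by_name(self, name: str) -> list[Gene]:
        return [g for g in self.genes if g.name == name]

    @property
    def unique_names(self) -> list[str]:
        """Gene names deduplicated (inverted-repeat copies share a name)."""
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.name, None)
        return list(seen)

    def overlapping(
        self, start: int, end: int, strand: Optional[Strand] = None
    ) -> list[Gene]:
        out = []
        for g in self.genes:
            if strand is not None and g.strand != strand:
                continue
            if g.start <= end and start <= g.end:
                out.append(g)
        return out

    def flanking(self, start: int, end: int) -> tuple[Optional[Gene], Optional[Gene]]:
        """Nearest non-overlapping genes to the left and right, any strand."""
        left = None
        right = None
        for g in self.genes:
            if g.end < start and (left is None or g.end > left.end):
                left = g
            if g.start > end and (right is None or g.start < right.start):
                right = g
        return left, right


@dataclass(frozen=True)
class IntervalRelation:
    overlap_bp: int
    a_contains_b: bool
    b_contains_a: bool
    signed_distance: int
    same_strand: bool


def feature_length(start: int, end: int) -> int:
    """Inclusive length end - start + 1."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return end - start + 1


def interval_relation(
    a: tuple[int, int, Strand], b: tuple[int, int, Strand]
) -> IntervalRelation:
    """Strand-aware relation between two 1-based inclusive intervals.

    ``signed_distance`` is 0 when the intervals overlap, otherwise the number
    of bases strictly between them, positive when ``b`` lies downstream of
    ``a`` on ``a``'s strand.
    """
    (a_start, a_end, a_strand) = a
    (b_start, b_end, b_strand) = b
    if a_start > a_end or b_start > b_end:
        raise ValueError("interval with start > end")
    overlap = max(0, min(a_end, b_end) - max(a_start, b_start) + 1)
    if overlap > 0:
        signed = 0
    elif b_start > a_end:
        gap = b_start - a_end - 1
        signed = gap if a_strand == "+" else -gap
    else:
        gap = a_start - b_end - 1
        signed = -gap if a_strand == "+" else gap
    return IntervalRelation(
        overlap_bp=overlap,
        a_contains_b=a_start <= b_start and b_end <= a_end,
        b_contains_a=b_start <= a_start and a_end <= b_end,
        signed_distance=signed,
        same_strand=a_strand == b_strand,
    )


# ---------------------------------------------------------------------------
# annotation IO (GFF3)
# ---------------------------------------------------------------------------

_CLASS_FROM_TYPE = {
    "gene": None,  # class read from attributes
    "tRNA_gene": "tRNA",
    "rRNA_gene": "rRNA",
    "pseudogene": "pseudogene",
}


def _validate_gff_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError(f"{path}: malformed GFF3 line {lineno} (expected 9 columns)")


def load_annotation(path: str | Path) -> GeneModel:
    """Read a GFF3 annotation into a :class:`GeneModel`.

    Gene class is taken from the ``gene_class`` (or ``gene_biotype``)
    attribute of ``gene`` features; exon structure from child ``exon``
    features.  A ``##sequence-region`` pragma, when present, sets the genome
    length; otherwise the maximum feature end is used.
    """
    path = Path(path)
    _validate_gff_lines(path)
    genome_length = 0
    has_features = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    genome_length = int(parts[3])
            elif line.strip() and not line.startswith("#"):
                has_features = True
    if not has_features:
        return GeneModel(genes=[], genome_length=genome_length)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:  # pragma: no cover - gffutils wraps many errors
        raise ParseError(f"{path}: {exc}") from exc

    genes: list[Gene] = []
    for feat in db.features_of_type("gene"):
        attrs = feat.attributes
        cls = (attrs.get("gene_class") or attrs.get("gene_biotype") or [None])[0]
        if cls is None or cls not in GENE_CLASSES:
            raise ParseError(
                f"{path}: gene {feat.id}: unknown or missing gene class {cls!r} "
                f"(expected one of {GENE_CLASSES})"
            )
        exons = tuple(
            (e.start, e.end) for e in db.children(feat, featuretype="exon", order_by="start")
        )
        label = attrs.get("polycistron")
        genes.append(
            Gene(
                id=feat.id,
                name=(attrs.get("Name") or [feat.id])[0],
                gene_class=cls,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                exons=exons,
                polycistron_label=int(label[0]) if label else None,
            )
        )
    if not genome_length:
        genome_length = max((g.end for g in genes), default=0)
    return GeneModel(genes=genes, genome_length=genome_length)


def write_annotation(model: GeneModel, path: str | Path, seqid: str = "genome") -> None:
    """Write a :class:`GeneModel` back to GFF3 (deterministic row order)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {model.genome_length}\n")
        for g in model.genes:  # already sorted by (start, end, strand)
            attrs = [f"ID={g.id}", f"Name={g.name}", f"gene_class={g.gene_class}"]
            if g.polycistron_label is not None:
                attrs.append(f"polycistron={g.polycistron_label}")
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "plastidtx",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    "\t".join(
                        [
                            seqid,
                            "plastidtx",
                            "exon",
                            str(s),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            f"ID={g.id}.exon{i};Parent={g.id}",
                        ]
                    )
                    + "\n"
                )


def read_genome(path: str | Path) -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return GenomeSequence(name=rec.id, sequence=str(rec.seq))


def write_genome(genome: GenomeSequence, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")
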