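"""Association analyses: asRNA vs cRNA abundance, motif modification vs
downstream ncRNA expression, and insertion-site ranking.

All comparisons operate on log2 abundances and are invariant to a common
additive shift.  The two-sample comparison uses Welch's t by default
(pooled-variance Student's t behind a flag); the two-group modification
contrast uses a one-way ANOVA, whose F equals the squared pooled t for two
groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateGroupingError
from .classify import NcRNARecord
from .modification import MotifOccurrence
from .model import GeneModel, Strand
from .segments import Polycistron

# Fig-4-style grouping of antisense subtypes by where they sit on the gene
ASRNA_POSITION_CLASS = {
    "B1": "5prime",
    "B2": "3prime",
    "B3A": "coding",
    "B3B": "coding",
    "B5": "intron",
}


@dataclass(frozen=True)
class GroupComparison:
    test: str
    group_labels: tuple[str, ...]
    group_sizes: tuple[int, ...]
    group_means: tuple[float, ...]
    statistic: float
    df: tuple[float, ...]
    p_value: float
    alpha: float
    significant: bool


def sat_compare(
    catalog: Sequence[NcRNARecord],
    gene_abundances: Mapping[str, float],
    alpha: float = 0.05,
    equal_var: bool = False,
    gene_filter: Optional[Iterable[str]] = None,
) -> tuple[GroupComparison, dict[str, list[float]]]:
    """Compare cRNA abundance with vs without an overlapping asRNA.

    ``gene_abundances`` maps gene name to log abundance (typically the
    protein-coding genes).  A gene counts as asRNA-bearing when it is a
    partner of any antisense catalog record.  Returns the Welch (default)
    two-sample comparison plus a per-position-class breakdown
    (5prime / 3prime / coding / intron) of the asRNA-bearing genes.
    """
    names = set(gene_filter) if gene_filter is not None else set(gene_abundances)
    as_partners: dict[str, set[str]] = {}
    for rec in catalog:
        if rec.is_antisense:
            for p in rec.partner_genes:
                as_partners.setdefault(p, set()).add(rec.subtype)
    with_as = [gene_abundances[n] for n in sorted(names) if n in as_partners]
    without = [gene_abundances[n] for n in sorted(names) if n not in as_partners]
    if not with_as or not without:
        raise DegenerateGroupingError(
            "degenerate grouping: every gene falls in one asRNA class"
        )
    res = stats.ttest_ind(with_as, without, equal_var=equal_var)
    comparison = GroupComparison(
        test="student_t" if equal_var else "welch_t",
        group_labels=("with_asRNA", "without_asRNA"),
        group_sizes=(len(with_as), len(without)),
        group_means=(float(np.mean(with_as)), float(np.mean(without))),
        statistic=float(res.statistic),
        df=(float(res.df),),
        p_value=float(res.pvalue),
        alpha=alpha,
        significant=bool(res.pvalue < alpha),
    )
    breakdown: dict[str, list[float]] = {}
    for name in sorted(names):
        for subtype in as_partners.get(name, ()):
            cls = ASRNA_POSITION_CLASS.get(subtype)
            if cls is not None:
                breakdown.setdefault(cls, []).append(gene_abundances[name])
    return comparison, breakdown


@dataclass(frozen=True)
class Transcript:
    """A minimal stranded transcript for downstream-linking."""

    id: str
    start: int
    end: int
    strand: Strand
    kind: str  # protein | tRNA | rRNA | ncRNA

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class DownstreamLink:
    occurrence: MotifOccurrence
    transcript: Transcript
    distance: int
    motif_modified: bool


def link_downstream(
    occurrences: Sequence[MotifOccurrence],
    transcripts: Sequence[Transcript],
    d_min: int = 100,
    d_max: int = 500,
) -> list[DownstreamLink]:
    """Link each motif occurrence to the same-strand transcripts whose 5'
    start lies downstream at a gap of ``d_min``..``d_max`` bases.

    The distance is the number of bases strictly between the motif's
    downstream end and the transcript's 5' start.
    """
    if d_min >= d_max:
        raise ValueError("d_min must be < d_max")
    links = []
    for occ in occurrences:
        for t in transcripts:
            if t.strand != occ.strand:
                continue
            if occ.strand == "+":
                distance = t.five_prime - occ.end - 1
            else:
                distance = occ.start - t.five_prime - 1
            if d_min <= distance <= d_max:
                links.append(
                    DownstreamLink(
                        occurrence=occ,
                        transcript=t,
                        distance=distance,
                        motif_modified=occ.modified,
                    )
                )
    return links


def modification_expression_anova(
    links: Sequence[DownstreamLink],
    abundances: Mapping[str, float],
    alpha: float = 0.01,
) -> GroupComparison:
    """One-way ANOVA of downstream transcript log abundance grouped by
    whether the upstream motif is significantly modified."""
    groups: dict[bool, list[float]] = {True: [], False: []}
    for link in links:
        if link.transcript.id in abundances:
            groups[link.motif_modified].append(abundances[link.transcript.id])
    if len(groups[True]) < 2 or len(groups[False]) < 2:
        raise DegenerateGroupingError(
            "degenerate grouping: need >= 2 links per modification group"
        )
    modified, unmodified = groups[True], groups[False]
    res = stats.f_oneway(modified, unmodified)
    n = len(modified) + len(unmodified)
    return GroupComparison(
        test="anova",
        group_labels=("modified", "unmodified"),
        group_sizes=(len(modified), len(unmodified)),
        group_means=(float(np.mean(modified)), float(np.mean(unmodified))),
        statistic=float(res.statistic),
        df=(1.0, float(n - 2)),
        p_value=float(res.pvalue),
        alpha=alpha,
        significant=bool(res.pvalue < alpha),
    )


@dataclass(frozen=True)
class InsertionCandidate:
    polycistron_id: int
    flank_genes: tuple[str, str]
    gap_start: int
    gap_end: int
    score: float

    @property
    def gap_length(self) -> int:
        return self.gap_end - self.gap_start + 1


def rank_insertion_sites(
    polycistrons: Sequence[Polycistron],
    model: GeneModel,
    gene_abundances: Mapping[str, float],
    min_gap: int = 20,
    score: str = "min",
) -> list[InsertionCandidate]:
    """Rank intergenic gaps inside polycistrons as foreign-gene insertion sites.

    A good site disrupts no endogenous gene (it lies in a within-unit
    intergenic gap of at least ``min_gap`` bases) and sits in a highly
    expressed unit; the score is the minimum (conservative, default) or
    mean of the two flanking genes' log abundances.  Candidates are sorted
    by descending score, ties broken by genome position; the ranking is
    deterministic for fixed input.
    """
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    if score not in ("min", "mean"):
        raise ValueError("score must be 'min' or 'mean'")
    candidates = []
    for pc in polycistrons:
        members = []
        for name in pc.member_gene_names:
            copies = [
                g
                for g in model.by_name(name)
                if g.start <= pc.end and pc.start <= g.end
            ]
            members.extend(copies)
        members.sort(key=lambda g: (g.start, g.end))
        for left, right in zip(members, members[1:]):
            gap_start, gap_end = left.end + 1, right.start - 1
            if gap_end - gap_start + 1 < min_gap:
                continue
            la = gene_abundances.get(left.name)
            ra = gene_abundances.get(right.name)
            if la is None or ra is None:
                continue
            value = min(la, ra) if score == "min" else (la + ra) / 2
            candidates.append(
                InsertionCandidate(
                    polycistron_id=pc.id,
                    flank_genes=(left.name, right.name),
                    gap_start=gap_start,
                    gap_end=gap_end,
                    score=value,
                )
            )
    candidates.sort(key=lambda c: (-c.score, c.gap_start))
    return candidates


def plot_group_boxes(groups: Mapping[str, Sequence[float]], path, title: str = ""):
    """Box plot of log abundances per group (optional figure output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.5 + len(groups), 4))
    labels = list(groups)
    ax.boxplot([groups[k] for k in labels], tick_labels=labels)
    ax.set_ylabel("log2 abundance")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
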