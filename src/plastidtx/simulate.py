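"""Synthetic plastid-genome bundles with known ground truth.

The generator lays out a compact circular-genome annotation as a sequence
of non-overlapping "cassettes": polycistrons (runs of co-transcribed
genes), one cassette per planted ncRNA subtype, standalone genes (a subset
carrying an antisense partner), and modification-motif sites each followed
by a downstream ncRNA.  Per-transcript abundances are log-normal in RPM;
planted effects (asRNA presence on cRNA abundance, motif modification on
downstream ncRNA abundance) are additive on the log2 scale.  Strand-specific
coverage, IPD kinetics, qPCR Ct values and homology hits are all derived
from the same truth manifest, which is emitted alongside for
parameter-recovery tests.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``config.seed``; a fixed seed yields byte-identical output bundles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import SUBTYPES
from .errors import PlacementError
from .model import Gene, GeneModel, GenomeSequence, write_annotation, write_genome
from .modification import (
    IUPAC,
    KineticsRow,
    MotifOccurrence,
    reverse_complement_motif,
    scan_motif,
)
from .segments import StrandCoverage, write_bedgraph

_MARGIN = 120     # clearance inside a cassette (room for B1/B3B overhangs)
_SPACING = 200    # zero-coverage gap between cassettes


def _default_planted() -> dict[str, int]:
    return {s: 1 for s in SUBTYPES}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions
    the analyses assume (see docs/methods.md for rationale)."""

    genome_length: Optional[int] = None  # None -> auto-sized to the layout
    n_polycistrons: int = 2
    genes_per_polycistron: int = 3
    n_single_genes: int = 8
    n_asrna_genes: int = 4  # of the single genes, how many carry an asRNA
    planted_ncrnas: dict[str, int] = field(default_factory=_default_planted)
    # abundance law: per-transcript log2 RPM ~ Normal(mean, sd)
    abundance_mean: float = 5.0
    abundance_sd: float = 1.0
    asrna_effect: float = 2.0        # log2 boost of cRNA when an asRNA is planted
    mod_expression_effect: float = 1.5  # log2 boost of ncRNA downstream of a modified motif
    depth_model: str = "poisson"     # poisson | nb | exact
    nb_dispersion: float = 10.0
    read_length: int = 100
    total_mapped_reads: int = 1_000_000
    motif_strings: tuple[str, ...] = ("TATANNNATNA", "WNYANTGAW")
    n_motif_occurrences: int = 6     # planted occurrences of motif_strings[0]
    fraction_modified: float = 0.5
    mod_ipd_ratio: float = 3.0
    ipd_noise: float = 0.6           # sd of log IPD per observation
    kinetics_coverage: int = 50
    control_ipd_mean: float = 1.0
    control_ipd_sd: float = 0.2      # positional control-IPD variation (log scale)
    n_background_kinetics: int = 200
    n_qpcr_pairs: int = 8
    qpcr_efficiency: float = 1.0
    ct_noise: float = 0.25
    ct_intercept: float = 38.0
    with_sequence: bool = True
    with_kinetics: bool = True
    with_qpcr: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.fraction_modified <= 1:
            raise ValueError("fraction_modified must be in [0,1]")
        if self.n_asrna_genes > self.n_single_genes:
            raise ValueError("n_asrna_genes exceeds n_single_genes")
        if any(v < 0 for v in self.planted_ncrnas.values()):
            raise ValueError("planted ncRNA counts must be >= 0")
        unknown = set(self.planted_ncrnas) - set(SUBTYPES)
        if unknown:
            raise ValueError(f"unknown ncRNA subtypes {sorted(unknown)}")
        if self.depth_model not in ("poisson", "nb", "exact"):
            raise ValueError("depth_model must be poisson | nb | exact")


@dataclass
class PlannedTranscript:
    id: str
    start: int
    end: int
    strand: str
    kind: str  # gene | polycistron | ncrna
    log2_rpm: float = 0.0
    subtype: Optional[str] = None
    partners: tuple[str, ...] = ()
    motif_index: Optional[int] = None  # for motif-downstream ncRNAs

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    genome: Optional[GenomeSequence]
    model: GeneModel
    coverage_plus: StrandCoverage
    coverage_minus: StrandCoverage
    kinetics: list[KineticsRow]
    qpcr: pd.DataFrame
    hits: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.genome is not None:
            write_genome(self.genome, outdir / "genome.fasta")
        write_annotation(self.model, outdir / "annotation.gff3")
        write_bedgraph(self.coverage_plus, outdir / "coverage_plus.bedgraph")
        write_bedgraph(self.coverage_minus, outdir / "coverage_minus.bedgraph")
        if self.kinetics:
            recs = []
            for row in self.kinetics:
                for ipd in row.case_ipds:
                    recs.append(
                        {
                            "position": row.position,
                            "strand": row.strand,
                            "ipd": round(ipd, 6),
                            "control_mean": round(row.control_mean, 6),
                        }
                    )
            pd.DataFrame(recs).to_csv(outdir / "kinetics.csv", index=False)
        if len(self.qpcr):
            self.qpcr.to_csv(outdir / "qpcr.csv", index=False)
        if len(self.hits):
            self.hits.to_csv(outdir / "hits.tsv", sep="\t", index=False, header=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


class _Layout:
    """Cursor-based left-to-right placement; cassettes never overlap."""

    def __init__(self):
        self.cursor = _SPACING
        self.genes: list[Gene] = []
        self.transcripts: list[PlannedTranscript] = []
        self.ncrnas: list[PlannedTranscript] = []
        self.polycistrons: list[dict] = []
        self._gene_n = 0
        self._nc_n = 0

    def _gene_id(self) -> str:
        self._gene_n += 1
        return f"g{self._gene_n}"

    def _nc_id(self) -> str:
        self._nc_n += 1
        return f"snc{self._nc_n}"

    def add_gene(self, start, end, strand, gene_class="protein", exons=(), label=None):
        gid = self._gene_id()
        gene = Gene(
            id=gid, name=gid, gene_class=gene_class, strand=strand,
            start=start, end=end, exons=tuple(exons), polycistron_label=label,
        )
        self.genes.append(gene)
        return gene

    def add_transcript(self, start, end, strand, kind, **kw) -> PlannedTranscript:
        if kind == "ncrna":
            t = PlannedTranscript(self._nc_id(), start, end, strand, kind, **kw)
            self.ncrnas.append(t)
        else:
            t = PlannedTranscript(f"t{len(self.transcripts)+1}", start, end, strand, kind, **kw)
        self.transcripts.append(t)
        return t

    def advance(self, extent_end: int):
        self.cursor = extent_end + _MARGIN + _SPACING


def _other(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _instantiate_motif(
    motif: str, all_motifs: Sequence[str], rng: np.random.Generator, tries: int = 500
) -> str:
    """Draw a concrete (non-degenerate) instantiation of an IUPAC motif that
    contains no internal occurrence of any configured motif other than
    itself at offset 0 on the plus strand.  Such nested matches could not
    be screened out of the background later because every base of the
    planted site is protected."""
    for _ in range(tries):
        concrete = "".join(rng.choice(list(IUPAC[code])) for code in motif)
        ok = True
        for m in all_motifs:
            for occ in scan_motif(concrete, m):
                is_self = (
                    m == motif and occ.strand == "+" and occ.start == 1
                    and occ.end == len(concrete)
                )
                if not is_self:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return concrete
    raise PlacementError(
        f"could not instantiate motif {motif} free of nested motif matches"
    )


def _build_layout(cfg: SimulationConfig, rng: np.random.Generator):
    lay = _Layout()
    strand_cycle = ["+", "-"]

    # --- polycistron cassettes -------------------------------------------
    gene_len, intra_gap = 300, 50
    for i in range(cfg.n_polycistrons):
        s = strand_cycle[i % 2]
        start = lay.cursor + _MARGIN
        pos = start
        members = []
        for _ in range(cfg.genes_per_polycistron):
            g = lay.add_gene(pos, pos + gene_len - 1, s, label=i + 1)
            members.append(g.name)
            pos = g.end + intra_gap + 1
        extent_end = lay.genes[-1].end
        lay.add_transcript(start, extent_end, s, "polycistron")
        lay.polycistrons.append(
            {"label": i + 1, "strand": s, "start": start, "end": extent_end,
             "members": members}
        )
        lay.advance(extent_end)

    # --- one cassette per planted ncRNA subtype --------------------------
    order = [s for s in SUBTYPES for _ in range(cfg.planted_ncrnas.get(s, 0))]
    for i, subtype in enumerate(order):
        s = strand_cycle[i % 2]
        t = _other(s)
        c = lay.cursor
        if subtype in ("B1", "B2", "B3A", "B3B"):
            gs, ge = c + _MARGIN, c + _MARGIN + 399
            g = lay.add_gene(gs, ge, s)
            lay.add_transcript(gs, ge, s, "gene")
            if subtype == "B1":
                span = (gs - 100, gs + 200) if s == "+" else (ge - 200, ge + 100)
            elif subtype == "B2":
                span = (ge - 200, ge + 100) if s == "+" else (gs - 100, gs + 200)
            elif subtype == "B3A":
                span = (gs + 100, gs + 300)
            else:  # B3B
                span = (gs - 80, ge + 80)
            lay.add_transcript(*span, t, "ncrna", subtype=subtype, partners=(g.name,))
            lay.advance(max(ge, span[1]))
        elif subtype == "B5":
            gs, ge = c + _MARGIN, c + _MARGIN + 699
            exons = ((gs, gs + 149), (gs + 500, ge))
            g = lay.add_gene(gs, ge, s, exons=exons)
            lay.add_transcript(gs, ge, s, "gene")
            lay.add_transcript(gs + 180, gs + 379, t, "ncrna", subtype="B5",
                               partners=(g.name,))
            lay.advance(ge)
        elif subtype == "B4":
            g1 = lay.add_gene(c + _MARGIN, c + _MARGIN + 249, s)
            g2 = lay.add_gene(g1.end + 81, g1.end + 330, s)
            lay.add_transcript(g1.start, g1.end, s, "gene")
            lay.add_transcript(g2.start, g2.end, s, "gene")
            lay.add_transcript(g1.start + 100, g2.end - 100, t, "ncrna",
                               subtype="B4", partners=(g1.name, g2.name))
            lay.advance(g2.end)
        else:  # A1-A4 intergenic cassettes
            if subtype == "A1":
                f1s = f2s = s
            elif subtype == "A2":
                f1s = f2s = t
            elif subtype == "A3":
                f1s, f2s = s, t
            else:  # A4: flank strands irrelevant
                f1s = f2s = "+"
            g1 = lay.add_gene(c + _MARGIN, c + _MARGIN + 249, f1s)
            g2 = lay.add_gene(g1.end + 491, g1.end + 740, f2s)
            lay.add_transcript(g1.start, g1.end, f1s, "gene")
            lay.add_transcript(g2.start, g2.end, f2s, "gene")
            if subtype == "A4":
                lay.add_transcript(g1.end + 121, g1.end + 320, "+", "ncrna",
                                   subtype="A4", partners=(g1.name, g2.name))
                lay.add_transcript(g1.end + 171, g1.end + 370, "-", "ncrna",
                                   subtype="A4", partners=(g1.name, g2.name))
            else:
                lay.add_transcript(g1.end + 121, g1.end + 320, s, "ncrna",
                                   subtype=subtype, partners=(g1.name, g2.name))
            lay.advance(g2.end)

    # --- standalone genes, a subset with an antisense partner ------------
    asrna_hosts: list[str] = []
    for i in range(cfg.n_single_genes):
        s = strand_cycle[i % 2]
        gs = lay.cursor + _MARGIN
        g = lay.add_gene(gs, gs + 249, s)
        lay.add_transcript(gs, gs + 249, s, "gene")
        if i < cfg.n_asrna_genes:
            lay.add_transcript(gs + 60, gs + 209, _other(s), "ncrna",
                               subtype="B3A", partners=(g.name,))
            asrna_hosts.append(g.name)
        lay.advance(g.end)

    # --- motif cassettes, each with a downstream same-strand ncRNA -------
    motif = cfg.motif_strings[0] if cfg.motif_strings else None
    if motif is None and cfg.n_motif_occurrences > 0:
        raise PlacementError("n_motif_occurrences > 0 but no motif_strings given")
    occurrences: list[dict] = []
    n_mod = int(round(cfg.fraction_modified * cfg.n_motif_occurrences))
    for i in range(cfg.n_motif_occurrences):
        s = strand_cycle[i % 2]
        L = len(motif)
        d = int(rng.integers(150, 451))
        modified = i < n_mod
        c = lay.cursor
        if s == "+":
            ms = c + _MARGIN
            me = ms + L - 1
            nc = lay.add_transcript(me + d + 1, me + d + 200, "+", "ncrna",
                                    subtype=None, motif_index=i)
            extent_end = nc.end
        else:
            nc_start = c + _MARGIN
            nc = lay.add_transcript(nc_start, nc_start + 199, "-", "ncrna",
                                    subtype=None, motif_index=i)
            ms = nc.end + d + 1
            me = ms + L - 1
            extent_end = me
        concrete = _instantiate_motif(motif, cfg.motif_strings, rng)
        occurrences.append(
            {"motif_id": "DMM1", "motif": motif, "start": ms, "end": me,
             "strand": s, "modified": bool(modified), "offsets": [3] if modified else [],
             "concrete": concrete, "downstream_ncrna": nc.id, "distance": d}
        )
        lay.advance(extent_end)

    required = lay.cursor + _SPACING
    if cfg.genome_length is None:
        genome_length = required
    elif cfg.genome_length < required:
        raise PlacementError(
            f"genome_length {cfg.genome_length} too small for the planted "
            f"layout (needs >= {required} bp)"
        )
    else:
        genome_length = cfg.genome_length
    return lay, occurrences, asrna_hosts, genome_length


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


def _assign_abundances(cfg, lay, occurrences, asrna_hosts, rng) -> None:
    asrna_set = set(asrna_hosts)
    modified_by_nc = {
        o["downstream_ncrna"]: o["modified"] for o in occurrences
    }
    for t in lay.transcripts:
        la = float(rng.normal(cfg.abundance_mean, cfg.abundance_sd))
        if t.kind == "gene":
            # gene name == transcript span owner; asRNA boost applies to hosts
            host = next(
                (g.name for g in lay.genes if g.start == t.start and g.end == t.end
                 and g.strand == t.strand),
                None,
            )
            if host in asrna_set:
                la += cfg.asrna_effect
        elif t.kind == "ncrna" and modified_by_nc.get(t.id, False):
            la += cfg.mod_expression_effect
        t.log2_rpm = la
    # polycistron units record their transcript's abundance (matched by extent)
    for pc in lay.polycistrons:
        for t in lay.transcripts:
            if t.kind == "polycistron" and t.start == pc["start"] and t.end == pc["end"]:
                pc["log2_rpm"] = t.log2_rpm


def _depth_arrays(cfg, lay, genome_length, rng):
    depth = {"+": np.zeros(genome_length), "-": np.zeros(genome_length)}
    for t in lay.transcripts:
        expected = 2.0 ** t.log2_rpm * cfg.total_mapped_reads / 1e6
        if cfg.depth_model == "exact":
            count = expected
        elif cfg.depth_model == "poisson":
            count = float(rng.poisson(expected))
        else:  # negative binomial with mean `expected`
            r = cfg.nb_dispersion
            count = float(rng.negative_binomial(r, r / (r + expected)))
        # uniform depth over the span; floored at 1 so every planted
        # transcript is detectable at the study's minimal-coverage-1 rule
        d = max(1.0, count * cfg.read_length / t.length)
        depth[t.strand][t.start - 1 : t.end] += d
    return depth


def _build_sequence(cfg, occurrences, genome_length, rng) -> str:
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=genome_length)
    planted_mask = np.zeros(genome_length, dtype=bool)
    for o in occurrences:
        s0, e0 = o["start"] - 1, o["end"]
        site = o["concrete"] if o["strand"] == "+" else reverse_complement_motif(
            o["concrete"]
        )
        # concrete instantiations contain no degenerate codes, so the
        # reverse complement is a plain sequence
        seq[s0:e0] = list(site)
        planted_mask[s0:e0] = True
    planted_keys = {(o["start"], o["end"], o["strand"]) for o in occurrences}
    text = "".join(seq)
    for _ in range(100):
        strays = []
        for motif in cfg.motif_strings:
            for occ in scan_motif(text, motif):
                if (occ.start, occ.end, occ.strand) not in planted_keys:
                    strays.append((occ, motif))
        if not strays:
            return text
        arr = np.array(list(text))
        for occ, motif in strays:
            pattern = motif if occ.strand == "+" else reverse_complement_motif(motif)
            for off, code in enumerate(pattern):
                pos0 = occ.start - 1 + off
                if code != "N" and not planted_mask[pos0]:
                    forbidden = set(IUPAC[code])
                    choices = [b for b in "ACGT" if b not in forbidden]
                    arr[pos0] = choices[int(rng.integers(len(choices)))]
                    break
        text = "".join(arr)
    raise PlacementError("could not screen background sequence free of stray motifs")


def simulate_kinetics(
    positions: Sequence[tuple[int, str]],
    modified: Sequence[bool],
    rng: np.random.Generator,
    coverage: int = 50,
    mod_ipd_ratio: float = 3.0,
    ipd_noise: float = 0.6,
    control_ipd_mean: float = 1.0,
    control_ipd_sd: float = 0.2,
) -> list[KineticsRow]:
    """Per-position IPD observations: log IPD ~ Normal(log(control x ratio),
    ipd_noise), with ratio = ``mod_ipd_ratio`` at modified positions and 1
    elsewhere.  The recorded control mean is the position's geometric-mean
    IPD under no modification, so the caller's test is exactly calibrated."""
    rows = []
    for (pos, strand), is_mod in zip(positions, modified):
        control = float(
            np.exp(rng.normal(math.log(control_ipd_mean), control_ipd_sd))
        )
        ratio = mod_ipd_ratio if is_mod else 1.0
        ipds = np.exp(rng.normal(math.log(control * ratio), ipd_noise, size=coverage))
        rows.append(
            KineticsRow(
                position=pos, strand=strand,
                case_ipds=tuple(float(x) for x in ipds),
                control_mean=control,
            )
        )
    return rows


def _build_kinetics(cfg, occurrences, genome_length, rng) -> list[KineticsRow]:
    positions: list[tuple[int, str]] = []
    modified: list[bool] = []
    for o in occurrences:
        mod_positions = set()
        for off in o["offsets"]:
            mod_positions.add(o["start"] + off if o["strand"] == "+" else o["end"] - off)
        for pos in range(o["start"], o["end"] + 1):
            positions.append((pos, o["strand"]))
            modified.append(pos in mod_positions)
    occupied = {p for p, _ in positions}
    n_bg = cfg.n_background_kinetics
    candidates = rng.choice(np.arange(1, genome_length + 1), size=3 * n_bg, replace=False)
    taken = 0
    for i, pos in enumerate(candidates):
        if taken >= n_bg:
            break
        if int(pos) in occupied:
            continue
        positions.append((int(pos), "+" if i % 2 == 0 else "-"))
        modified.append(False)
        taken += 1
    return simulate_kinetics(
        positions, modified, rng,
        coverage=cfg.kinetics_coverage,
        mod_ipd_ratio=cfg.mod_ipd_ratio,
        ipd_noise=cfg.ipd_noise,
        control_ipd_mean=cfg.control_ipd_mean,
        control_ipd_sd=cfg.control_ipd_sd,
    )


def _build_qpcr(cfg, lay, rng) -> tuple[pd.DataFrame, list[dict]]:
    pairs = []
    # map gene name -> its transcript abundance via matching extents
    name_ab: dict[str, float] = {}
    for g in lay.genes:
        for t in lay.transcripts:
            if t.kind == "gene" and (t.start, t.end, t.strand) == (g.start, g.end, g.strand):
                name_ab[g.name] = t.log2_rpm
    candidates = [
        nc for nc in lay.ncrnas
        if nc.subtype in ("B1", "B2", "B3A", "B3B", "B5") and nc.partners
        and nc.partners[0] in name_ab
    ]
    rows = []
    slope = 1.0 / math.log2(1.0 + cfg.qpcr_efficiency)
    for k, nc in enumerate(candidates[: cfg.n_qpcr_pairs]):
        gene = nc.partners[0]
        la_nc, la_c = nc.log2_rpm, name_ab[gene]
        pairs.append(
            {"pair_id": f"pair{k+1}", "ncrna": nc.id, "gene": gene,
             "true_log_ratio": la_nc - la_c}
        )
        for bio in range(1, 4):
            for tech in range(1, 4):
                ct_nc = cfg.ct_intercept - slope * la_nc + rng.normal(0, cfg.ct_noise)
                ct_c = cfg.ct_intercept - slope * la_c + rng.normal(0, cfg.ct_noise)
                rows.append(
                    {"pair_id": f"pair{k+1}", "biological_rep": bio,
                     "technical_rep": tech,
                     "ct_ncrna": round(min(max(ct_nc, 0.1), 40.0), 3),
                     "ct_crna": round(min(max(ct_c, 0.1), 40.0), 3),
                     "rnaseq_log_ratio": round(la_nc - la_c, 4)}
                )
    return pd.DataFrame(rows), pairs


def _build_hits(lay) -> tuple[pd.DataFrame, list[dict]]:
    """Synthetic cross-species hits realising one component of each
    mapping class, plus one hit that fails the E-value filter."""
    ncs = [nc.id for nc in lay.ncrnas]
    rows = []
    expected = []

    def hit(q, s, e):
        rows.append([q, s, 95.0, 150, 5, 0, 1, 150, 1, 150, e, 200.0])

    if len(ncs) >= 1:
        hit(ncs[0], "ref_a", 1e-20)
        expected.append({"queries": [ncs[0]], "subjects": ["ref_a"], "class": "1:1"})
    if len(ncs) >= 2:
        hit(ncs[1], "ref_b1", 1e-15)
        hit(ncs[1], "ref_b2", 1e-12)
        expected.append(
            {"queries": [ncs[1]], "subjects": ["ref_b1", "ref_b2"], "class": "1:n"}
        )
    if len(ncs) >= 4:
        hit(ncs[2], "ref_c", 1e-8)
        hit(ncs[3], "ref_c", 1e-9)
        expected.append(
            {"queries": sorted([ncs[2], ncs[3]]), "subjects": ["ref_c"], "class": "n:1"}
        )
    if len(ncs) >= 6:
        hit(ncs[4], "ref_d1", 1e-10)
        hit(ncs[4], "ref_d2", 1e-11)
        hit(ncs[5], "ref_d2", 1e-18)
        expected.append(
            {"queries": sorted([ncs[4], ncs[5]]),
             "subjects": ["ref_d1", "ref_d2"], "class": "n:n"}
        )
    if len(ncs) >= 7:
        hit(ncs[6], "ref_weak", 1e-3)  # filtered at the default 1e-5 cutoff
    return pd.DataFrame(rows), expected


def simulate(
    config: SimulationConfig | None = None, outdir: str | Path | None = None
) -> SimulatedBundle:
    """Generate a full synthetic bundle; optionally write it to ``outdir``."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    lay, occurrences, asrna_hosts, genome_length = _build_layout(cfg, rng)
    _assign_abundances(cfg, lay, occurrences, asrna_hosts, rng)
    depth = _depth_arrays(cfg, lay, genome_length, rng)

    genome = None
    if cfg.with_sequence:
        genome = GenomeSequence(
            name="synthetic", sequence=_build_sequence(cfg, occurrences, genome_length, rng)
        )
    kinetics = (
        _build_kinetics(cfg, occurrences, genome_length, rng) if cfg.with_kinetics else []
    )
    qpcr, qpcr_pairs = (
        _build_qpcr(cfg, lay, rng) if cfg.with_qpcr else (pd.DataFrame(), [])
    )
    hits, expected_mappings = _build_hits(lay)

    model = GeneModel(
        genes=list(lay.genes),
        genome_length=genome_length,
        total_mapped_reads=cfg.total_mapped_reads,
    )

    modified_positions = []
    for o in occurrences:
        for off in o["offsets"]:
            pos = o["start"] + off if o["strand"] == "+" else o["end"] - off
            modified_positions.append([pos, o["strand"]])

    truth = {
        "seed": cfg.seed,
        "genome_length": genome_length,
        "total_mapped_reads": cfg.total_mapped_reads,
        "genes": [
            {"id": g.id, "name": g.name, "class": g.gene_class, "strand": g.strand,
             "start": g.start, "end": g.end, "polycistron": g.polycistron_label}
            for g in lay.genes
        ],
        "polycistrons": lay.polycistrons,
        "transcripts": [
            {"id": t.id, "kind": t.kind, "start": t.start, "end": t.end,
             "strand": t.strand, "log2_rpm": t.log2_rpm, "subtype": t.subtype,
             "partners": list(t.partners), "motif_index": t.motif_index}
            for t in lay.transcripts
        ],
        "asrna_hosts": asrna_hosts,
        "motif_occurrences": [
            {k: o[k] for k in
             ("motif_id", "motif", "start", "end", "strand", "modified",
              "offsets", "downstream_ncrna", "distance")}
            for o in occurrences
        ],
        "modified_positions": modified_positions,
        "qpcr_pairs": qpcr_pairs,
        "expected_mappings": expected_mappings,
    }

    bundle = SimulatedBundle(
        config=cfg,
        genome=genome,
        model=model,
        coverage_plus=StrandCoverage("+", depth["+"]),
        coverage_minus=StrandCoverage("-", depth["-"]),
        kinetics=kinetics,
        qpcr=qpcr,
        hits=hits,
        truth=truth,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
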