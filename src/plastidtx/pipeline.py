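"""End-to-end orchestration: coverage -> segments -> polycistrons ->
ncRNA catalog -> quantification -> modification -> association statistics.

Every stage's output is persisted as TSV/CSV/BED/JSON in the output
directory so that individual CLI subcommands can be re-run on the
intermediates with identical results.  All randomness upstream (the
simulator) is seeded; the pipeline itself is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import classify as cls
from . import modification as mod
from . import expression as qt
from . import segments as seg
from .errors import ConfigError, StageError
from .model import GeneModel, load_annotation, read_genome

log = logging.getLogger("plastidtx")


@dataclass
class RunConfig:
    annotation_gff: str
    coverage_plus: str
    coverage_minus: str
    outdir: str
    genome_fasta: Optional[str] = None
    kinetics_csv: Optional[str] = None
    qpcr_csv: Optional[str] = None
    hits_tsv: Optional[str] = None
    c_min: float = 1
    l_min: int = 100
    max_gap: int = 0
    member_overlap_frac: float = 0.5
    min_intergenic_dist: int = 100
    eps: float = 1.0
    read_length: int = 100
    total_mapped_reads: int = 1_000_000
    alpha_expression: float = 0.05
    alpha_modification: float = 0.01
    min_mod_coverage: int = 10
    motifs: tuple[str, ...] = ("TATANNNATNA", "WNYANTGAW")
    d_min: int = 100
    d_max: int = 500
    min_gap: int = 20
    e_max: float = 1e-5
    plots: bool = False

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls_)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "motifs" in data:
            data["motifs"] = tuple(data["motifs"])
        try:
            return cls_(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        required = {
            "annotation_gff": self.annotation_gff,
            "coverage_plus": self.coverage_plus,
            "coverage_minus": self.coverage_minus,
        }
        optional = {
            "genome_fasta": self.genome_fasta,
            "kinetics_csv": self.kinetics_csv,
            "qpcr_csv": self.qpcr_csv,
            "hits_tsv": self.hits_tsv,
        }
        for name, path in required.items():
            if path is None or not Path(path).exists():
                raise ConfigError(f"{name}: missing input file {path!r}")
        for name, path in optional.items():
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{name}: file {path!r} does not exist")
        if self.c_min < 1 or self.l_min < 1 or self.max_gap < 0:
            raise ConfigError("c_min, l_min must be >= 1 and max_gap >= 0")
        if not 0 < self.member_overlap_frac <= 1:
            raise ConfigError("member_overlap_frac must be in (0, 1]")
        if self.d_min >= self.d_max:
            raise ConfigError("d_min must be < d_max")


def _write_segments(segments, path):
    pd.DataFrame(
        [
            {"start": s.start, "end": s.end, "strand": s.strand,
             "length": s.length, "mean_depth": round(s.mean_depth, 3)}
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


def _write_segments_bed(segments, path, chrom="genome"):
    with open(path, "w") as fh:
        for i, s in enumerate(
            sorted(segments, key=lambda x: (x.start, x.end, x.strand)), 1
        ):
            score = int(round(s.mean_depth * 100))
            fh.write(
                f"{chrom}\t{s.start-1}\t{s.end}\tseg{i}\t{score}\t{s.strand}\n"
            )


def _comparison_dict(c: assoc.GroupComparison) -> dict:
    return {
        "test": c.test,
        "groups": list(c.group_labels),
        "n": list(c.group_sizes),
        "means": [round(m, 4) for m in c.group_means],
        "statistic": round(c.statistic, 4),
        "df": list(c.df),
        "p": c.p_value,
        "alpha": c.alpha,
        "significant": c.significant,
    }


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s")
    )
    log.addHandler(handler)
    summary: dict = {"parameters": dataclasses.asdict(config)}
    try:
        # ------------------------------------------------------------ load
        stage = "load"
        log.info("stage %s", stage)
        model = load_annotation(config.annotation_gff)
        genome = read_genome(config.genome_fasta) if config.genome_fasta else None
        cov_plus, cov_minus = seg.load_coverage(
            config.coverage_plus, config.coverage_minus, model.genome_length
        )
        cov = {"+": cov_plus, "-": cov_minus}

        # -------------------------------------------------------- segments
        stage = "segments"
        log.info("stage %s", stage)
        segs_all = [
            s
            for c in (cov_plus, cov_minus)
            for s in seg.detect_segments(c, c_min=config.c_min, l_min=1)
        ]
        _write_segments(segs_all, out / "segments.tsv")
        _write_segments_bed(segs_all, out / "segments.bed")

        # ---------------------------------------------------- polycistrons
        stage = "polycistrons"
        log.info("stage %s", stage)
        polycistrons = seg.call_polycistrons(
            segs_all,
            model,
            max_gap=config.max_gap,
            member_overlap_frac=config.member_overlap_frac,
        )
        pd.DataFrame(
            [
                {"id": p.id, "strand": p.strand, "start": p.start, "end": p.end,
                 "n_members": p.n_members,
                 "members": ";".join(p.member_gene_names)}
                for p in polycistrons
            ]
        ).to_csv(out / "polycistrons.tsv", sep="\t", index=False)
        summary["n_polycistrons"] = len(polycistrons)
        summary["n_polycistron_genes"] = len(
            {n for p in polycistrons for n in p.member_gene_names}
        )

        # --------------------------------------------------------- catalog
        stage = "classify"
        log.info("stage %s", stage)
        candidates = {
            st: [s for s in segs_all if s.strand == st and s.length >= config.l_min]
            for st in "+-"
        }
        records, rejects = cls.build_catalog(
            candidates["+"], candidates["-"], model,
            min_intergenic_dist=config.min_intergenic_dist,
        )
        pd.DataFrame(
            [
                {"start": r.segment.start, "end": r.segment.end,
                 "strand": r.segment.strand, "reason": r.reason}
                for r in rejects
            ]
        ).to_csv(out / "rejected_segments.tsv", sep="\t", index=False)

        # -------------------------------------------------------- quantify
        stage = "quantify"
        log.info("stage %s", stage)
        total = config.total_mapped_reads
        gene_ab: dict[str, float] = {}
        gene_rows = []
        for name in model.unique_names:
            g = model.by_name(name)[0]  # primary copy
            est = qt.quantify(
                g.start, g.end, g.strand, cov[g.strand], total,
                eps=config.eps, read_length=config.read_length,
            )
            gene_ab[name] = est.log_abundance
            gene_rows.append(
                {"gene": name, "class": g.gene_class, "start": g.start,
                 "end": g.end, "strand": g.strand,
                 "rpm": round(est.rpm, 3),
                 "log_abundance": qt.round_half_up(est.log_abundance)}
            )
        pd.DataFrame(gene_rows).to_csv(out / "gene_abundances.tsv", sep="\t", index=False)

        quantified = []
        for r in records:
            est = qt.quantify(
                r.start, r.end, r.strand, cov[r.strand], total,
                eps=config.eps, read_length=config.read_length,
            )
            partner_las = [gene_ab[p] for p in r.partner_genes if p in gene_ab]
            partner_la = float(np.mean(partner_las)) if partner_las else None
            lr = (
                qt.log_ratio(est.log_abundance, partner_la)
                if partner_la is not None
                else None
            )
            quantified.append(
                cls.NcRNARecord(
                    id=r.id, subtype=r.subtype, partner_genes=r.partner_genes,
                    start=r.start, end=r.end, strand=r.strand,
                    log_abundance=est.log_abundance,
                    partner_log_abundance=partner_la,
                    log_ratio=lr,
                )
            )
        records = quantified
        pd.DataFrame(
            [
                {"id": r.id, "subtype": r.subtype,
                 "partners": ";".join(r.partner_genes),
                 "start": r.start, "end": r.end, "strand": r.strand,
                 "log_abundance": qt.round_half_up(r.log_abundance),
                 "partner_log_abundance":
                     None if r.partner_log_abundance is None
                     else qt.round_half_up(r.partner_log_abundance),
                 "log_ratio":
                     None if r.log_ratio is None else qt.round_half_up(r.log_ratio)}
                for r in records
            ]
        ).to_csv(out / "ncrna_catalog.tsv", sep="\t", index=False)
        with open(out / "ncrna_catalog.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for r in records:
                fh.write(
                    "\t".join(
                        ["genome", "plastidtx", "ncRNA", str(r.start), str(r.end),
                         ".", r.strand, ".",
                         f"ID={r.id};subtype={r.subtype};"
                         f"partners={','.join(r.partner_genes)}"]
                    ) + "\n"
                )
        summary["n_ncrna"] = len(records)
        summary["subtype_tally"] = cls.subtype_tally(records)

        # ---------------------------------------------------- modification
        stage = "modification"
        calls: list[mod.ModificationCall] = []
        occurrences_by_motif: dict[str, list[mod.MotifOccurrence]] = {}
        if config.kinetics_csv:
            log.info("stage %s", stage)
            rows = mod.read_kinetics(config.kinetics_csv)
            calls, skipped = mod.call_modifications(
                rows, alpha=config.alpha_modification,
                min_coverage=config.min_mod_coverage,
            )
            mod.write_calls(calls, out / "modifications.csv")
            summary["n_significant_mod_calls"] = sum(c.significant for c in calls)
            if skipped:
                log.info("%d kinetics positions below coverage minimum", len(skipped))
        if genome is not None:
            motif_summaries = []
            with open(out / "motif_occurrences.bed", "w") as fh:
                for idx, motif in enumerate(config.motifs, start=1):
                    motif_id = f"DMM{idx}"
                    occs = mod.scan_motif(genome, motif, motif_id=motif_id)
                    occs = mod.annotate_occurrences(occs, calls)
                    occurrences_by_motif[motif_id] = occs
                    for j, o in enumerate(occs, 1):
                        fh.write(
                            f"genome\t{o.start-1}\t{o.end}\t{motif_id}.{j}"
                            f"\t{int(o.modified)}\t{o.strand}\n"
                        )
                    if occs:
                        motif_summaries.append(
                            mod.summarize_motif(occs, calls, motif_id, motif)
                        )
            pd.DataFrame(
                [
                    {"motif_id": s.motif_id, "motif_sequence": s.motif_sequence,
                     "total": s.total, "modified": s.modified,
                     "fraction": s.fraction,
                     "mean_ipd_ratio":
                         None if s.mean_ipd_ratio is None
                         else qt.round_half_up(s.mean_ipd_ratio),
                     "mean_coverage":
                         None if s.mean_coverage is None
                         else qt.round_half_up(s.mean_coverage),
                     "modal_offset": s.modal_offset,
                     "modal_offset_from_end": s.modal_offset_from_end}
                    for s in motif_summaries
                ]
            ).to_csv(out / "motif_summary.tsv", sep="\t", index=False)
            summary["motif_fractions"] = {
                s.motif_id: s.fraction for s in motif_summaries
            }

        # ----------------------------------------------------- association
        stage = "associations"
        log.info("stage %s", stage)
        statistics: dict = {}
        protein = [
            n for n in model.unique_names
            if model.by_name(n)[0].gene_class == "protein"
        ]
        try:
            comparison, breakdown = assoc.sat_compare(
                records, gene_ab, alpha=config.alpha_expression,
                gene_filter=protein,
            )
            statistics["sat_compare"] = _comparison_dict(comparison)
            statistics["sat_breakdown_sizes"] = {k: len(v) for k, v in breakdown.items()}
            if config.plots:
                assoc.plot_group_boxes(
                    {
                        "with": [gene_ab[n] for n in protein
                                 if any(n in r.partner_genes for r in records
                                        if r.is_antisense)],
                        "without": [gene_ab[n] for n in protein
                                    if not any(n in r.partner_genes for r in records
                                               if r.is_antisense)],
                    },
                    out / "sat_compare.png",
                    title="cRNA abundance by asRNA presence",
                )
        except Exception as exc:
            statistics["sat_compare"] = {"error": str(exc)}

        dmm1 = occurrences_by_motif.get("DMM1", [])
        # downstream linking needs every noncoding transcript with an extent
        # and an abundance, including segments the subtype classifier could
        # not place (e.g. for lack of flanking-gene context)
        transcripts = []
        nc_ab: dict[str, float] = {}
        by_extent = {(r.start, r.end, r.strand): r for r in records}
        n_extra = 0
        for st in "+-":
            for s in candidates[st]:
                if model.overlapping(s.start, s.end, strand=st):
                    continue  # sense transcript
                rec = by_extent.get((s.start, s.end, st))
                if rec is not None:
                    tid, la = rec.id, rec.log_abundance
                else:
                    n_extra += 1
                    tid = f"nca{n_extra}"
                    la = qt.quantify(
                        s.start, s.end, st, cov[st], total,
                        eps=config.eps, read_length=config.read_length,
                    ).log_abundance
                transcripts.append(
                    assoc.Transcript(id=tid, start=s.start, end=s.end,
                                     strand=st, kind="ncRNA")
                )
                nc_ab[tid] = la
        links = assoc.link_downstream(
            dmm1, transcripts, d_min=config.d_min, d_max=config.d_max
        )
        statistics["n_downstream_links"] = len(links)
        if links:
            try:
                anova = assoc.modification_expression_anova(
                    links, nc_ab, alpha=config.alpha_modification
                )
                statistics["modification_anova"] = _comparison_dict(anova)
            except Exception as exc:
                statistics["modification_anova"] = {"error": str(exc)}

        sites = assoc.rank_insertion_sites(
            polycistrons, model, gene_ab, min_gap=config.min_gap
        )
        pd.DataFrame(
            [
                {"rank": i, "polycistron": c.polycistron_id,
                 "left": c.flank_genes[0], "right": c.flank_genes[1],
                 "gap_start": c.gap_start, "gap_end": c.gap_end,
                 "gap_length": c.gap_length, "score": qt.round_half_up(c.score)}
                for i, c in enumerate(sites, 1)
            ]
        ).to_csv(out / "insertion_sites.tsv", sep="\t", index=False)
        summary["n_insertion_sites"] = len(sites)

        # ------------------------------------------------------------ qPCR
        stage = "qpcr"
        if config.qpcr_csv:
            log.info("stage %s", stage)
            qdf = pd.read_csv(config.qpcr_csv)
            results = []
            for pair_id, grp in qdf.groupby("pair_id", sort=True):
                reps = []
                for bio, bgrp in grp.groupby("biological_rep", sort=True):
                    cts = tuple(
                        (float(r.ct_ncrna), float(r.ct_crna))
                        for r in bgrp.itertuples(index=False)
                    )
                    reps.append(
                        qt.QpcrReplicate(str(pair_id), int(bio), cts)
                    )
                if "rnaseq_log_ratio" not in grp.columns:
                    continue
                rnaseq_lr = float(grp["rnaseq_log_ratio"].iloc[0])
                try:
                    results.append(
                        qt.compare_pair(reps, rnaseq_lr, alpha=config.alpha_expression)
                    )
                except Exception as exc:
                    log.warning("pair %s: %s", pair_id, exc)
            pd.DataFrame(
                [
                    {"pair_id": r.pair_id,
                     "rnaseq_log_ratio": qt.round_half_up(r.rnaseq_log_ratio),
                     "qpcr_mean_log_ratio": qt.round_half_up(r.qpcr_mean_log_ratio),
                     "qpcr_sd": qt.round_half_up(r.qpcr_sd, 3),
                     "t": qt.round_half_up(r.t_statistic, 3), "df": r.df,
                     "p": r.p_value, "significant": r.significant}
                    for r in results
                ]
            ).to_csv(out / "qpcr_comparison.tsv", sep="\t", index=False)
            if results:
                concordant = sum(1 for r in results if not r.significant)
                statistics["qpcr"] = {
                    "n_pairs": len(results),
                    "n_concordant": concordant,
                    "fraction_concordant": round(concordant / len(results), 3),
                }

        # -------------------------------------------------------- mappings
        stage = "mappings"
        if config.hits_tsv:
            log.info("stage %s", stage)
            mappings = cls.classify_mappings(config.hits_tsv, e_max=config.e_max)
            pd.DataFrame(
                [
                    {"class": m.mapping_class,
                     "queries": ";".join(m.component_queries),
                     "subjects": ";".join(m.component_subjects)}
                    for m in mappings
                ]
            ).to_csv(out / "mappings.tsv", sep="\t", index=False)
            tally: dict[str, int] = {}
            for m in mappings:
                tally[m.mapping_class] = tally.get(m.mapping_class, 0) + 1
            statistics["mapping_classes"] = tally

        summary["statistics"] = statistics
        with open(out / "statistics.json", "w") as fh:
            json.dump(statistics, fh, indent=1, sort_keys=True)
            fh.write("\n")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
        return summary
    except ConfigError:
        raise
    except StageError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, str(exc)) from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def fixture_report() -> dict:
    """Tallies and re-derived quantities from the packaged printed tables."""
    from . import fixtures as fx

    records = fx.load_ncrna_records()
    tally = cls.subtype_tally(records)
    df = fx.load_ncrna_table()
    recomputed = df["log_abundance"] - df["partner_log_abundance"]
    max_dev = float((recomputed - df["printed_log_ratio"]).abs().max())
    _, n_units, n_members = fx.fixture_polycistron_calls()
    return {
        "n_ncrna": len(records),
        "n_antisense": sum(r.is_antisense for r in records),
        "n_intergenic": sum(not r.is_antisense for r in records),
        "subtype_tally": tally,
        "max_length": max(r.length for r in records),
        "min_length": min(r.length for r in records),
        "max_log_ratio_deviation": round(max_dev, 4),
        "n_polycistrons": n_units,
        "n_polycistron_genes": n_members,
    }
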