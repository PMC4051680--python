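"""Loaders for the packaged reference tables.

Three tab-separated tables transcribed from a published chloroplast study
ship with the package: the quantified gene/polycistron table, the ncRNA
catalog, and the DNA-modification motif summary.  They serve as realistic,
fully-worked inputs for tests, the ``report`` CLI subcommand and the
acceptance checks.
"""

from __future__ import annotations

from collections import Counter
from importlib import resources
from io import StringIO

import pandas as pd

from .classify import NcRNARecord
from .model import Gene, GeneModel

_STRAND = {"P": "+", "N": "-"}


def _read(name: str) -> pd.DataFrame:
    text = resources.files("plastidtx.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t")


def load_gene_table(harmonize_polycistron_strands: bool = False) -> GeneModel:
    """Build a :class:`GeneModel` from the packaged gene table.

    Inverted-repeat duplicate copies are separate records sharing a name.
    Polycistron labels are carried only by the primary copies, as printed.

    When ``harmonize_polycistron_strands`` is true, every labeled gene is
    reassigned to the majority strand of its polycistron.  A continuous
    transcript lies on a single strand, so members of one unit must share
    it; the printed table violates this for exactly one unit (two tRNAs in
    the ndhJ/ndhK/ndhC unit carry the opposite strand letter), which this
    option repairs.
    """
    df = _read("table1_genes.tsv")
    genes: list[Gene] = []
    for row in df.itertuples(index=False):
        name = str(row.name)
        if name.startswith("trn"):
            cls = "tRNA"
        elif name.startswith("rrn"):
            cls = "rRNA"
        else:
            cls = "protein"
        label = None if pd.isna(row.polycistron) else int(row.polycistron)
        ab = None if pd.isna(row.log_abundance) else float(row.log_abundance)
        genes.append(
            Gene(
                id=str(row.id),
                name=name,
                gene_class=cls,
                strand=_STRAND[row.strand],
                start=int(row.start),
                end=int(row.end),
                polycistron_label=label,
                log_abundance=ab,
            )
        )
    if harmonize_polycistron_strands:
        by_label: dict[int, list[Gene]] = {}
        for g in genes:
            if g.polycistron_label is not None:
                by_label.setdefault(g.polycistron_label, []).append(g)
        majority = {
            label: Counter(g.strand for g in members).most_common(1)[0][0]
            for label, members in by_label.items()
        }
        genes = [
            g
            if g.polycistron_label is None or g.strand == majority[g.polycistron_label]
            else Gene(
                id=g.id,
                name=g.name,
                gene_class=g.gene_class,
                strand=majority[g.polycistron_label],
                start=g.start,
                end=g.end,
                polycistron_label=g.polycistron_label,
                log_abundance=g.log_abundance,
            )
            for g in genes
        ]
    genome_length = int(df["end"].max())
    return GeneModel(genes=genes, genome_length=genome_length)


def load_gene_abundances() -> dict[str, float]:
    """Arbitrary log abundance per gene name (primary copies)."""
    df = _read("table1_genes.tsv")
    out: dict[str, float] = {}
    for row in df.itertuples(index=False):
        if not pd.isna(row.log_abundance) and str(row.name) not in out:
            out[str(row.name)] = float(row.log_abundance)
    return out


def load_ncrna_table() -> pd.DataFrame:
    """The packaged ncRNA catalog as a DataFrame (strand recoded to +/-)."""
    df = _read("table2_ncrna.tsv")
    df["strand"] = df["strand"].map(_STRAND)
    return df


def load_ncrna_records() -> list[NcRNARecord]:
    records = []
    for row in load_ncrna_table().itertuples(index=False):
        records.append(
            NcRNARecord(
                id=str(row.id),
                subtype=str(row.subtype),
                partner_genes=tuple(str(row.partners).split(";")),
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                log_abundance=float(row.log_abundance),
                partner_log_abundance=float(row.partner_log_abundance),
                log_ratio=float(row.log_abundance) - float(row.partner_log_abundance),
            )
        )
    return records


def load_motif_table() -> pd.DataFrame:
    return _read("table4_motifs.tsv")


def fixture_polycistron_calls(max_gap: int = 0):
    """Re-call polycistrons from the packaged gene table.

    Synthesizes depth-1 strand-specific coverage across each labeled unit's
    genomic extent (the continuous transcript the unit was called from),
    runs segment detection and polycistron calling, and returns
    ``(polycistrons, n_units, n_unique_member_names)``.
    """
    import numpy as np

    from .segments import StrandCoverage, call_polycistrons, detect_segments

    model = load_gene_table(harmonize_polycistron_strands=True)
    depth = {
        "+": np.zeros(model.genome_length),
        "-": np.zeros(model.genome_length),
    }
    groups: dict[int, list] = {}
    for g in model.genes:
        if g.polycistron_label is not None:
            groups.setdefault(g.polycistron_label, []).append(g)
    for members in groups.values():
        strand = members[0].strand  # single-stranded after harmonization
        start = min(g.start for g in members)
        end = max(g.end for g in members)
        depth[strand][start - 1 : end] = 1.0
    segments = detect_segments(StrandCoverage("+", depth["+"])) + detect_segments(
        StrandCoverage("-", depth["-"])
    )
    polycistrons = call_polycistrons(segments, model, max_gap=max_gap)
    unique = {name for pc in polycistrons for name in pc.member_gene_names}
    return polycistrons, len(polycistrons), len(unique)
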