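"""Transcript abundance (RPM), log ratios and the RNA-Seq vs qPCR comparison.

Abundance is reads per million mapped reads (RPM); the arbitrary log
abundance is log2(RPM + eps) with eps defaulting to 1 so that an
unexpressed region scores 0.  All downstream comparisons use differences
of log abundances, which are invariant to the shared base and offset.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError
from .model import Strand, feature_length
from .segments import StrandCoverage


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Table-style rounding (half away from zero), e.g. 0.365 -> 0.37."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class AbundanceEstimate:
    start: int
    end: int
    strand: Strand
    read_count: float
    rpm: float
    log_abundance: float


def rpm_from_count(read_count: float, total_mapped: int) -> float:
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    return read_count * 1e6 / total_mapped


def log_abundance_from_rpm(rpm: float, eps: float = 1.0) -> float:
    return math.log2(rpm + eps)


def quantify(
    start: int,
    end: int,
    strand: Strand,
    source,
    total_mapped: int,
    eps: float = 1.0,
    read_length: int = 100,
) -> AbundanceEstimate:
    """Abundance of a stranded region from reads or dense coverage.

    ``source`` is either a sequence of ``(start, end, strand)`` read
    intervals (a read counts once if it overlaps the region on the matching
    strand) or a :class:`StrandCoverage`, in which case the read count is
    estimated as total depth in the region divided by the read length.
    """
    if start > end:
        raise ValueError("region start > end")
    if isinstance(source, StrandCoverage):
        if source.strand != strand:
            raise ValueError("coverage strand does not match region strand")
        if end > source.genome_length:
            raise ValueError("region outside genome")
        count = float(source.depth[start - 1 : end].sum()) / read_length
    else:
        count = 0
        for r_start, r_end, r_strand in source:
            if r_strand == strand and r_start <= end and start <= r_end:
                count += 1
    rpm = rpm_from_count(count, total_mapped)
    return AbundanceEstimate(
        start=start,
        end=end,
        strand=strand,
        read_count=count,
        rpm=rpm,
        log_abundance=log_abundance_from_rpm(rpm, eps),
    )


def log_ratio(la_nc: float, la_c: float) -> float:
    """Log ratio of two transcripts' abundances = difference of log abundances."""
    if not (math.isfinite(la_nc) and math.isfinite(la_c)):
        raise ValueError("log abundances must be finite")
    return la_nc - la_c


def qpcr_log_ratio(ct_nc: float, ct_c: float, max_cycles: float = 40.0) -> float:
    """(max - Ct) difference: [(40-ct) for ncRNA] - [(40-ct) for cRNA]."""
    for ct in (ct_nc, ct_c):
        if not 0 < ct <= max_cycles:
            raise ValueError(f"Ct {ct} outside (0, {max_cycles}]")
    return (max_cycles - ct_nc) - (max_cycles - ct_c)


def one_sample_t(values: Sequence[float], mu0: float) -> tuple[float, int, float]:
    """Two-sided one-sample t test; returns (t, df, p)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise DegenerateSampleError("degenerate sample: n < 2")
    if np.std(x, ddof=1) == 0:
        raise DegenerateSampleError("degenerate sample: zero variance")
    res = stats.ttest_1samp(x, popmean=mu0)
    return float(res.statistic), len(x) - 1, float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires n >= 3 and nonzero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateSampleError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateSampleError("degenerate sample: zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class QpcrReplicate:
    """One biological replicate: three technical (Ct_ncRNA, Ct_cRNA) pairs."""

    pair_id: str
    biological_rep: int
    technical_cts: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.technical_cts) != 3:
            raise ValueError("expected exactly 3 technical replicates")

    @property
    def mean_log_ratio(self) -> float:
        return float(np.mean([qpcr_log_ratio(nc, c) for nc, c in self.technical_cts]))

    @property
    def sd_log_ratio(self) -> float:
        return float(
            np.std([qpcr_log_ratio(nc, c) for nc, c in self.technical_cts], ddof=1)
        )


@dataclass(frozen=True)
class ComparisonResult:
    pair_id: str
    rnaseq_log_ratio: float
    qpcr_mean_log_ratio: float
    qpcr_sd: float
    t_statistic: float
    df: int
    p_value: float
    significant: bool


def compare_pair(
    replicates: Sequence[QpcrReplicate], rnaseq_lr: float, alpha: float = 0.05
) -> ComparisonResult:
    """One-sample t test of the biological-replicate mean qPCR log ratios
    against the RNA-Seq log ratio for the same ncRNA/cRNA pair."""
    if len(replicates) != 3:
        raise ValueError("expected exactly 3 biological replicates")
    means = [r.mean_log_ratio for r in replicates]
    t, df, p = one_sample_t(means, rnaseq_lr)
    return ComparisonResult(
        pair_id=replicates[0].pair_id,
        rnaseq_log_ratio=rnaseq_lr,
        qpcr_mean_log_ratio=float(np.mean(means)),
        qpcr_sd=float(np.std(means, ddof=1)),
        t_statistic=t,
        df=df,
        p_value=p,
        significant=p < alpha,
    )
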