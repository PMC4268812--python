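"""Assembly summary statistics and table-shaped region reports.

N50 uses the half-sum rule: sort piece lengths descending; N50 is the length
at which the cumulative sum first reaches half the total.  Contigs are the
gap-free pieces of scaffolds, split at runs of at least ``min_gap_run`` N
bases (default 1).  Genome coverage percentages are relative to an assumed
genome size and printed to one decimal with half-up rounding.

Region summaries report the integer floor of total/count as the mean length
(the rule consistent with published region tables) and the population
standard deviation of lengths rounded to an integer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from .intervals import IntervalSet
from .kmers import CoverageProfile
from .seqio import SequenceSet


def n50(lengths) -> int:
    """Length at which the descending cumulative sum first reaches half the total."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if len(arr) == 0:
        return 0
    half = arr.sum()  # compare 2*cum >= total to stay in integers
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(2 * cum, half, side="left"))
    return int(arr[idx])


def split_contigs(seq: str, min_gap_run: int = 1) -> list[int]:
    """Lengths of gap-free contig pieces of one scaffold."""
    return [len(p) for p in re.split("N{%d,}" % min_gap_run, seq) if p]


def round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"),
                                           rounding=ROUND_HALF_UP))


@dataclass
class AssemblyStats:
    total_span: int
    total_bases: int
    n_scaffolds: int
    scaffold_n50: int
    max_scaffold: int
    n_contigs: int          # contigs longer than min_contig
    contig_n50: int
    max_contig: int
    span_coverage_pct: float
    bases_coverage_pct: float


def assembly_stats(assembly: SequenceSet, assumed_size: int,
                   min_gap_run: int = 1, min_contig: int = 1000) -> AssemblyStats:
    """Scaffold/contig statistics and genome coverage against an assumed size."""
    if assumed_size <= 0:
        raise ValueError("assumed genome size must be positive")
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    scaf_lens = [len(s) for s in assembly.values()]
    contigs: list[int] = []
    for s in assembly.values():
        contigs.extend(split_contigs(s, min_gap_run))
    big = [c for c in contigs if c > min_contig]
    span = assembly.total_span
    bases = assembly.total_bases
    return AssemblyStats(
        total_span=span,
        total_bases=bases,
        n_scaffolds=len(scaf_lens),
        scaffold_n50=n50(scaf_lens),
        max_scaffold=max(scaf_lens),
        n_contigs=len(big),
        contig_n50=n50(big) if big else 0,
        max_contig=max(contigs) if contigs else 0,
        span_coverage_pct=round_half_up(100 * span / assumed_size),
        bases_coverage_pct=round_half_up(100 * bases / assumed_size),
    )


@dataclass
class RegionSummary:
    total_bp: int
    regions: int
    mean_length: int        # floor(total/count)
    sd_length: int          # population sd, rounded to integer
    max_length: int
    mean_kmer_coverage: float | None = None


def region_summary(regions: IntervalSet,
                   profiles: dict[str, CoverageProfile] | None = None
                   ) -> RegionSummary:
    """Total bp / count / floor-mean / sd / max (and mean k-mer coverage)."""
    total = regions.total_bp()
    count = regions.count()
    if count == 0:
        return RegionSummary(0, 0, 0, 0, 0, None)
    lens = regions.lengths().astype(float)
    mean_cov = None
    if profiles is not None:
        cov_sum = 0.0
        n_pos = 0
        for name, arr in regions.items():
            prof = profiles[name]
            for s, e in arr:
                e2 = min(e, len(prof.values))
                if e2 > s:
                    cov_sum += float(prof.values[s:e2].sum())
                    n_pos += e2 - s
        mean_cov = cov_sum / n_pos if n_pos else 0.0
    return RegionSummary(
        total_bp=total,
        regions=count,
        mean_length=total // count,
        sd_length=int(round_half_up(float(lens.std(ddof=0)), 0)),
        max_length=int(lens.max()),
        mean_kmer_coverage=mean_cov,
    )


__all__ = ["AssemblyStats", "RegionSummary", "assembly_stats",
           "region_summary", "n50", "split_contigs", "round_half_up"]
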