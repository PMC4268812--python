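"""Per-base Venn classification of a genome trio and genome-specific calling.

Given whole-genome alignments among three genomes, every base of each
genome is classified into one of four sectors relative to the two partner
genomes: specific (aligned to neither), shared with exactly one partner
(two sectors), or core (aligned to both).  Across the trio these project
onto the seven sectors of a three-way Venn diagram
(``A``/``B``/``C``/``AB``/``AC``/``BC``/``ABC``).

Specific *regions* worth reporting are then refined with k-mer coverage:
at least ``min_length`` bp with no alignments to the other genomes, mean
self k-mer coverage within the single-copy band, and mean coverage below
the cross cutoff in both partner read sets — which removes unassembled
high-copy repeats and leaves genuinely novel sequence.  Genic specific
regions additionally intersect an annotated gene span by a minimum overlap,
keeping flanking promoter/regulatory bases of the region intact.

Unaligned-set inputs use the repeat-inclusive (pre one-to-one filter)
alignments, so copy-number differences do not masquerade as novel sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import AnnotationSet, Gene, IntervalSet, min_overlap_filter
from .kmers import CoverageProfile, mean_region_coverage

SECTOR_ORDER = ("ABC", "AB", "AC", "BC", "A", "B", "C")


@dataclass(frozen=True)
class SpecificRegionCriteria:
    """Filter for reportable genome-specific regions.

    ``self_cov_range`` is inclusive at both ends; ``cross_cov_max`` is a
    strict upper bound ("average below" the cutoff).
    """

    min_length: int = 100
    self_cov_range: tuple[float, float] = (10.0, 100.0)
    cross_cov_max: float = 10.0

    def __post_init__(self):
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.self_cov_range[0] > self.self_cov_range[1]:
            raise ValueError("self coverage range bounds out of order")


@dataclass
class SectorLabeling:
    """Four-sector partition of one focal genome.

    ``specific``: aligned to neither partner; ``shared_1`` / ``shared_2``:
    aligned only to ``others[0]`` / ``others[1]``; ``core``: aligned to both.
    ``sector_name`` translates these into three-way Venn labels.
    """

    genome: str
    others: tuple[str, str]
    lengths: dict[str, int]
    specific: IntervalSet
    shared_1: IntervalSet
    shared_2: IntervalSet
    core: IntervalSet

    def sector_name(self, part: str) -> str:
        if part == "specific":
            return self.genome
        if part == "core":
            return "".join(sorted(self.genome + self.others[0] + self.others[1]))
        other = self.others[0] if part == "shared_1" else self.others[1]
        return "".join(sorted(self.genome + other))

    def parts(self) -> dict[str, IntervalSet]:
        return {"specific": self.specific, "shared_1": self.shared_1,
                "shared_2": self.shared_2, "core": self.core}

    def by_sector(self) -> dict[str, IntervalSet]:
        return {self.sector_name(p): s for p, s in self.parts().items()}

    def verify_partition(self) -> None:
        total = sum(s.total_bp() for s in self.parts().values())
        glen = sum(self.lengths.values())
        if total != glen:
            raise AssertionError(
                f"sectors cover {total} bp of a {glen} bp genome")
        union = self.specific.union(self.shared_1).union(self.shared_2).union(self.core)
        if union.total_bp() != glen:
            raise AssertionError("sector interval sets overlap")


def classify_bases(genome_lengths: Mapping[str, int],
                   unaligned_1: IntervalSet, unaligned_2: IntervalSet,
                   genome: str, others: tuple[str, str]) -> SectorLabeling:
    """Classify every base of the focal genome from its two unaligned sets.

    ``unaligned_i`` is the set of focal-genome bases with no alignment to
    partner ``others[i-1]`` (repeat-inclusive alignments).  Specific bases
    are unaligned to both; core bases aligned to both; the pairwise sectors
    follow by set algebra.  The four sectors partition the genome exactly.
    """
    lengths = dict(genome_lengths)
    for uset in (unaligned_1, unaligned_2):
        for name, arr in uset.items():
            if name not in lengths:
                raise ValueError(f"unaligned interval on unknown sequence {name!r}")
            if len(arr) and arr[-1, 1] > lengths[name]:
                raise ValueError(f"interval beyond bounds of {name!r}")
    specific = unaligned_1.intersect(unaligned_2)
    core = unaligned_1.union(unaligned_2).complement(lengths)
    shared_1 = unaligned_2.subtract(unaligned_1)   # aligned to 1 only
    shared_2 = unaligned_1.subtract(unaligned_2)   # aligned to 2 only
    lab = SectorLabeling(genome=genome, others=tuple(others), lengths=lengths,
                         specific=specific, shared_1=shared_1,
                         shared_2=shared_2, core=core)
    lab.verify_partition()
    return lab


# ---------------------------------------------------------------------------
# gene sector assignment
# ---------------------------------------------------------------------------

def _sharedness_rank(sector: str) -> int:
    return len(sector)


def assign_gene_sector(gene: Gene, labeling: SectorLabeling,
                       order: Sequence[str] = ("A", "B", "C")
                       ) -> tuple[str, dict[str, int]]:
    """Majority-rule sector of one gene from its exonic base overlap.

    Exonic bp per sector are summed across all transcripts (exons shared by
    several transcripts count once per transcript), and the gene goes to the
    sector with the most bases.  Ties resolve toward the more-shared sector
    (core over pairwise over specific), then by the supplied genome order.
    Returns ``(sector, per-sector exonic bp)``.
    """
    support = {labeling.sector_name(p): 0 for p in labeling.parts()}
    sectors = labeling.by_sector()
    total = 0
    for t in gene.transcripts:
        for s, e in t.exons:
            exon = IntervalSet({gene.seqid: [(s, e)]})
            total += e - s
            for name, sec_set in sectors.items():
                support[name] += exon.intersect(sec_set).total_bp()
    if total == 0:
        raise ValueError(f"gene {gene.id} has no exonic bases")

    def tie_key(name: str) -> tuple:
        # larger support first, then more shared, then genome precedence order
        prec = [order.index(g) for g in name if g in order]
        return (-support[name], -_sharedness_rank(name), prec)

    best = min(support, key=tie_key)
    return best, support


def assign_all_genes(annotation: AnnotationSet, labeling: SectorLabeling,
                     order: Sequence[str] = ("A", "B", "C")
                     ) -> dict[str, str]:
    out = {}
    for gene in annotation:
        if not any(t.exons for t in gene.transcripts):
            continue
        out[gene.id], _ = assign_gene_sector(gene, labeling, order)
    return out


# ---------------------------------------------------------------------------
# venn summary
# ---------------------------------------------------------------------------

@dataclass
class VennSector:
    sector: str
    reporting_genome: str
    bp: int
    exonic_bp: int
    gene_count: int


def venn_summary(labelings: Mapping[str, SectorLabeling],
                 annotations: Mapping[str, AnnotationSet],
                 assignments: Mapping[str, Mapping[str, str]],
                 order: Sequence[str] = ("A", "B", "C")) -> list[VennSector]:
    """Seven-sector table of (bp, exonic bp, gene count).

    Each shared sector is measurable from every member genome; values are
    reported from the first member in ``order`` (genome precedence), the
    convention used for the published Venn diagrams.
    """
    rows = []
    for sector in SECTOR_ORDER:
        rep = next(g for g in order if g in sector)
        lab = labelings[rep]
        sec_set = lab.by_sector()[sector]
        exonic = sec_set.intersect(annotations[rep].exon_union()).total_bp()
        count = sum(1 for g, s in assignments[rep].items() if s == sector)
        rows.append(VennSector(sector=sector, reporting_genome=rep,
                               bp=sec_set.total_bp(), exonic_bp=exonic,
                               gene_count=count))
    return rows


# ---------------------------------------------------------------------------
# specific region calling
# ---------------------------------------------------------------------------

def call_specific_regions(labeling: SectorLabeling,
                          self_profiles: Mapping[str, CoverageProfile],
                          other_profiles: Sequence[Mapping[str, CoverageProfile]],
                          criteria: SpecificRegionCriteria = SpecificRegionCriteria(),
                          ) -> IntervalSet:
    """Non-repetitive genome-specific regions of the focal genome.

    Keeps maximal runs of the specific label that are at least ``min_length``
    bp, have mean self k-mer coverage inside the inclusive single-copy band,
    and mean coverage strictly below ``cross_cov_max`` in both partner read
    samples.  Coverage is averaged over k-mer start positions of the whole
    region.
    """
    if len(other_profiles) != 2:
        raise ValueError("expected exactly two partner profile sets")
    for i, prof in enumerate((self_profiles, *other_profiles)):
        missing = [n for n in labeling.lengths if n not in prof]
        if missing:
            who = "self" if i == 0 else f"partner {labeling.others[i - 1]}"
            raise ValueError(f"missing coverage profile for {missing[0]!r} ({who})")
    lo, hi = criteria.self_cov_range
    out_raw: dict[str, list[tuple[int, int]]] = {}
    for name, arr in labeling.specific.items():
        for s, e in arr:
            if e - s < criteria.min_length:
                continue
            try:
                self_cov = mean_region_coverage(self_profiles[name], (s, e))
            except ValueError:     # region entirely in the profile-less tail
                continue
            if not (lo <= self_cov <= hi):
                continue
            if any(mean_region_coverage(prof[name], (s, e)) >= criteria.cross_cov_max
                   for prof in other_profiles):
                continue
            out_raw.setdefault(name, []).append((int(s), int(e)))
    return IntervalSet(out_raw)


def call_genic_specific_regions(specific_regions: IntervalSet,
                                annotation: AnnotationSet,
                                min_overlap: int = 100) -> IntervalSet:
    """Specific regions intersecting an annotated gene span by >= min_overlap bp.

    Kept regions are retained whole, so flanking promoter and regulatory
    bases stay attached to the genic call.
    """
    return min_overlap_filter(specific_regions, annotation, min_bp=min_overlap)


# ---------------------------------------------------------------------------
# spacing statistics
# ---------------------------------------------------------------------------

@dataclass
class SpacingStats:
    n_regions: int
    n_gaps: int
    mean_gap: float
    sd_gap: float
    dispersion: float    # sd/mean; ~1 under exponential (Poisson) spacing


def spacing_stats(regions: IntervalSet) -> SpacingStats:
    """Spacing of regions along their sequences via midpoint-to-midpoint gaps.

    Gaps are pooled across sequences; the sd/mean dispersion diagnostic is
    ~1 when regions are dropped uniformly at random (exponential spacing).
    Requires at least three regions overall.
    """
    n_regions = regions.count()
    if n_regions < 3:
        raise ValueError(f"insufficient regions for spacing statistics ({n_regions} < 3)")
    gaps = []
    for _name, arr in regions.items():
        mid = (arr[:, 0] + arr[:, 1]) // 2
        if len(mid) > 1:
            gaps.append(np.diff(np.sort(mid)))
    if not gaps:
        raise ValueError("regions are spread one per sequence; no gaps to measure")
    g = np.concatenate(gaps).astype(float)
    mean = float(g.mean())
    sd = float(g.std(ddof=1)) if len(g) > 1 else 0.0
    return SpacingStats(n_regions=n_regions, n_gaps=len(g), mean_gap=mean,
                        sd_gap=sd, dispersion=sd / mean if mean else float("nan"))


__all__ = [
    "SECTOR_ORDER", "SectorLabeling", "SpecificRegionCriteria", "VennSector",
    "SpacingStats", "classify_bases", "assign_gene_sector", "assign_all_genes",
    "venn_summary", "call_specific_regions", "call_genic_specific_regions",
    "spacing_stats",
]
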