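"""Exact set arithmetic on genomic intervals and annotation-aware overlap.

This module re-implements the interval operations the pipeline needs
(merge, subtract, intersect, union, complement, summary statistics, and
annotation-category overlap) with exact base-set semantics.  All internal
coordinates are 0-based half-open; GFF3 (1-based inclusive) is converted on
read and write.

An :class:`IntervalSet` stores, per sequence name, an ``(n, 2)`` integer
array of sorted, non-overlapping, non-adjacent ``[start, end)`` rows.
Touching intervals merge during normalization: the semantics are base sets,
not records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

Interval = tuple[int, int]


def _normalize_array(arr: np.ndarray) -> np.ndarray:
    """Sort and coalesce overlapping or touching [start, end) rows."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.asarray(arr, dtype=np.int64)
    if np.any(arr[:, 0] >= arr[:, 1]):
        bad = arr[arr[:, 0] >= arr[:, 1]][0]
        raise ValueError(f"empty or inverted interval [{bad[0]}, {bad[1]})")
    if np.any(arr[:, 0] < 0):
        raise ValueError("negative interval start")
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    # new run starts where start > running max of previous ends
    run_end = np.maximum.accumulate(arr[:, 1])
    new_run = np.empty(len(arr), dtype=bool)
    new_run[0] = True
    new_run[1:] = arr[1:, 0] > run_end[:-1]
    run_id = np.cumsum(new_run) - 1
    starts = arr[new_run, 0]
    ends = np.maximum.reduceat(arr[:, 1], np.flatnonzero(new_run))
    out = np.stack([starts, ends], axis=1)
    assert len(out) == run_id[-1] + 1
    return out


class IntervalSet:
    """Per-sequence sorted disjoint intervals with base-set semantics."""

    def __init__(self, data: Mapping[str, Iterable[Interval]] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if data:
            for name, ivs in data.items():
                arr = np.array(list(ivs), dtype=np.int64).reshape(-1, 2)
                arr = _normalize_array(arr)
                if len(arr):
                    self._data[name] = arr

    # -- basic container protocol ------------------------------------------
    def __getitem__(self, name: str) -> np.ndarray:
        return self._data.get(name, np.empty((0, 2), dtype=np.int64))

    def __contains__(self, name: str) -> bool:
        return name in self._data

    def sequences(self) -> list[str]:
        return sorted(self._data)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in sorted(self._data):
            yield name, self._data[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.sequences() != other.sequences():
            return False
        return all(np.array_equal(self[n], other[n]) for n in self.sequences())

    def __repr__(self) -> str:
        return f"IntervalSet({{{', '.join(f'{n!r}: {len(a)} ivs' for n, a in self.items())}}})"

    # -- summary statistics -------------------------------------------------
    def total_bp(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def count(self) -> int:
        return sum(len(a) for a in self._data.values())

    def max_len(self) -> int:
        lens = self.lengths()
        return int(lens.max()) if len(lens) else 0

    def lengths(self) -> np.ndarray:
        if not self._data:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([a[:, 1] - a[:, 0] for a in self._data.values()])

    # -- set algebra ---------------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for name in set(self._data) | set(other._data):
            arr = np.concatenate([self[name], other[name]])
            arr = _normalize_array(arr)
            if len(arr):
                out._data[name] = arr
        return out

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for name in set(self._data) & set(other._data):
            arr = _pairwise_intersect(self[name], other[name])
            if len(arr):
                out._data[name] = arr
        return out

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet()
        for name, a in self._data.items():
            b = other[name]
            if len(b) == 0:
                out._data[name] = a.copy()
                continue
            arr = _pairwise_subtract(a, b)
            if len(arr):
                out._data[name] = arr
        return out

    def complement(self, lengths: Mapping[str, int]) -> "IntervalSet":
        """Complement within ``[0, length)`` of every named sequence."""
        out = IntervalSet()
        for name, length in lengths.items():
            a = self[name]
            if len(a) and a[-1, 1] > length:
                raise ValueError(f"interval beyond sequence bounds on {name!r}")
            bounds = np.concatenate([[0], a.ravel(), [length]])
            pieces = bounds.reshape(-1, 2)
            pieces = pieces[pieces[:, 0] < pieces[:, 1]]
            if len(pieces):
                out._data[name] = pieces.astype(np.int64)
        return out

    # -- per-interval queries -----------------------------------------------
    def overlap_bp_per_interval(self, other: "IntervalSet") -> dict[str, np.ndarray]:
        """For each interval of self, bp of overlap with ``other``."""
        result = {}
        for name, a in self._data.items():
            b = other[name]
            out = np.zeros(len(a), dtype=np.int64)
            if len(b):
                # prefix sums of b lengths for range queries
                bl = b[:, 1] - b[:, 0]
                cum = np.concatenate([[0], np.cumsum(bl)])
                lo = np.searchsorted(b[:, 1], a[:, 0], side="right")
                hi = np.searchsorted(b[:, 0], a[:, 1], side="left")
                for i, (s, e) in enumerate(a):
                    if lo[i] >= hi[i]:
                        continue
                    full = cum[hi[i]] - cum[lo[i]]
                    # clip partial overlap at both ends
                    full -= max(0, s - b[lo[i], 0])
                    full -= max(0, b[hi[i] - 1, 1] - e)
                    out[i] = full
            result[name] = out
        return result

    # -- I/O ------------------------------------------------------------------
    @classmethod
    def from_bed(cls, path: str | Path) -> "IntervalSet":
        raw: dict[str, list[Interval]] = {}
        for name, start, end, _label in iter_bed(path):
            raw.setdefault(name, []).append((start, end))
        return cls(raw)

    def to_bed(self, path: str | Path, label: str | None = None) -> None:
        with open(path, "w") as fh:
            for name, arr in self.items():
                for s, e in arr:
                    if label is None:
                        fh.write(f"{name}\t{s}\t{e}\n")
                    else:
                        fh.write(f"{name}\t{s}\t{e}\t{label}\t0\t+\n")


def iter_bed(path: str | Path) -> Iterator[tuple[str, int, int, str | None]]:
    """Yield (seq, start, end, name-or-None) from BED3/BED6 text."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else None
            yield parts[0], int(parts[1]), int(parts[2]), name


def _pairwise_intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _pairwise_subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        jj = j
        while jj < len(b) and b[jj, 0] < e:
            if b[jj, 0] > cur:
                out.append((cur, b[jj, 0]))
            cur = max(cur, b[jj, 1])
            jj += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def normalize(raw: Mapping[str, Iterable[Interval]]) -> IntervalSet:
    """Normalize raw per-sequence intervals: sort + merge overlap/adjacency."""
    return IntervalSet(raw)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    id: str
    exons: list[Interval] = field(default_factory=list)       # 0-based half-open
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    span: Interval = (0, 0)


@dataclass
class Gene:
    id: str
    seqid: str
    start: int     # 0-based half-open span
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


class AnnotationSet:
    """Gene models (gene -> mRNA -> exon/CDS/UTR) for one assembly."""

    def __init__(self, genes: list[Gene]):
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def gene_spans(self) -> IntervalSet:
        raw: dict[str, list[Interval]] = {}
        for g in self.genes:
            raw.setdefault(g.seqid, []).append((g.start, g.end))
        return IntervalSet(raw)

    def exon_union(self) -> IntervalSet:
        raw: dict[str, list[Interval]] = {}
        for g in self.genes:
            for t in g.transcripts:
                raw.setdefault(g.seqid, []).extend(t.exons)
        return IntervalSet(raw)

    def category_sets(self, exclusive: bool = True) -> dict[str, IntervalSet]:
        """Annotation categories as interval sets.

        With ``exclusive=True`` categories are disjointified by precedence
        CDS > 5' UTR > 3' UTR > non-coding exon > remaining mRNA, so the
        reported bp form a partition of the annotated span.
        """
        def collect(attr: str) -> IntervalSet:
            raw: dict[str, list[Interval]] = {}
            for g in self.genes:
                for t in g.transcripts:
                    raw.setdefault(g.seqid, []).extend(getattr(t, attr))
            return IntervalSet(raw)

        cds = collect("cds")
        utr5 = collect("utr5")
        utr3 = collect("utr3")
        exon = collect("exons")
        mrna_raw: dict[str, list[Interval]] = {}
        for g in self.genes:
            for t in g.transcripts:
                mrna_raw.setdefault(g.seqid, []).append(t.span)
        mrna = IntervalSet(mrna_raw)
        if not exclusive:
            return {"cds": cds, "utr5": utr5, "utr3": utr3,
                    "noncoding_exon": exon, "mrna": mrna}
        noncoding = exon.subtract(cds).subtract(utr5).subtract(utr3)
        utr3x = utr3.subtract(cds).subtract(utr5)
        utr5x = utr5.subtract(cds)
        mrna_other = mrna.subtract(exon)
        return {"cds": cds, "utr5": utr5x, "utr3": utr3x,
                "noncoding_exon": noncoding, "mrna": mrna_other}

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationSet":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
        genes = []
        for g in db.features_of_type("gene", order_by=("seqid", "start")):
            gene = Gene(id=g.id, seqid=g.seqid, start=g.start - 1, end=g.end,
                        strand=g.strand)
            for t in db.children(g, featuretype="mRNA", order_by="start"):
                tr = Transcript(id=t.id, span=(t.start - 1, t.end))
                for f in db.children(t, order_by="start"):
                    iv = (f.start - 1, f.end)
                    if f.featuretype == "exon":
                        tr.exons.append(iv)
                    elif f.featuretype == "CDS":
                        tr.cds.append(iv)
                    elif f.featuretype == "five_prime_UTR":
                        tr.utr5.append(iv)
                    elif f.featuretype == "three_prime_UTR":
                        tr.utr3.append(iv)
                gene.transcripts.append(tr)
            genes.append(gene)
        return cls(genes)


def annotate_overlap(regions: IntervalSet, annotation: AnnotationSet,
                     exclusive: bool = True) -> dict[str, int]:
    """bp of ``regions`` falling into each annotation category.

    With exclusive categories the values are mutually exclusive and sum to at
    most ``regions.total_bp()``.
    """
    cats = annotation.category_sets(exclusive=exclusive)
    return {name: regions.intersect(cset).total_bp() for name, cset in cats.items()}


def min_overlap_filter(regions: IntervalSet, annotation: AnnotationSet,
                       min_bp: int = 100) -> IntervalSet:
    """Keep regions whose overlap with the union of gene spans is >= min_bp.

    Kept regions are retained whole (flanking bases included).
    """
    spans = annotation.gene_spans()
    per_iv = regions.overlap_bp_per_interval(spans)
    out = IntervalSet()
    for name, arr in regions.items():
        keep = arr[per_iv[name] >= min_bp]
        if len(keep):
            out._data[name] = keep.copy()
    return out


__all__ = [
    "IntervalSet", "normalize", "iter_bed",
    "AnnotationSet", "Gene", "Transcript",
    "annotate_overlap", "min_overlap_filter",
]
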