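"""Synthetic genome trios with known pan-genome ground truth.

The simulator emulates three diverged genomes of one species that share a
common core: ancestral segments are generated for each of the seven Venn
sectors (``ABC`` core, pairwise ``AB``/``AC``/``BC``, and genome-specific
``A``/``B``/``C``), high-copy repeat families are inserted into them, gene
models are planted, each genome receives the segments of the sectors it
belongs to in an independently shuffled order (so shared content is
relocated between genomes), and per-genome substitutions and small indels
are applied to shared copies.  Shotgun reads are drawn uniformly at a
configurable depth with per-base substitution errors.

Ground truth (:class:`TrioTruth`) records the post-mutation coordinates of
every sector segment, planted repeat copy, variant, and gene, so downstream
classification can be scored exactly.

A note on segment junctions: a maximal exact match between two genomes that
covers a shared segment would, with probability ~1/4 per boundary, extend a
few bases into the neighboring segment by chance.  When that neighbor is
absent from the partner genome this blurs the planted sector boundaries.
The simulator therefore assigns the first/last base of every segment that is
absent from some genome via a small constraint solver so that such chance
extensions are impossible, making per-base sector truth exactly recoverable
at zero mutation rate.  This touches at most two bases per segment and does
not alter segment lengths or labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import IntervalSet
from .seqio import SequenceSet, decode, encode, random_dna, revcomp, write_fastq

SECTORS = ("ABC", "AB", "AC", "BC", "A", "B", "C")
GENOMES = ("A", "B", "C")


@dataclass
class SimConfig:
    """Study conditions for one simulated trio.

    ``core_length`` is split into ``core_segments`` shared segments unless an
    explicit ``ABC`` list is given in ``sector_segment_lengths``.  Rates are
    per bp per genome copy (so two genomes diverge at ~2x ``snp_rate``).
    ``repeat_family_specs`` is a list of ``(unit_length, copies_per_genome)``;
    ``repeat_in_specific`` of those copies are placed inside genome-specific
    segments (the rest inside core segments, at the same position in every
    genome carrying them).
    """

    seed: int = 0
    core_length: int = 1_000_000
    core_segments: int = 20
    sector_segment_lengths: dict[str, list[int]] | None = None
    snp_rate: float = 0.005
    small_indel_rate: float = 0.0005
    repeat_family_specs: list[tuple[int, int]] = field(
        default_factory=lambda: [(400, 50)])
    repeat_in_specific: int = 0
    gene_density: float = 1.0          # genes per 10 kbp
    gene_length_range: tuple[int, int] = (600, 3000)
    boundary_genes: int = 0            # extra genes planted across sector junctions
    read_depth: float = 50.0
    read_length: int = 100
    read_error_rate: float = 0.0
    min_segment_length: int = 100

    def __post_init__(self):
        if self.core_length <= 0 or self.read_length <= 0:
            raise ValueError("lengths must be positive")
        for rate in (self.snp_rate, self.small_indel_rate, self.read_error_rate):
            if not (0 <= rate < 1):
                raise ValueError("rates must lie in [0, 1)")
        if self.read_depth <= 0:
            raise ValueError("read depth must be positive")
        for sector, lens in (self.sector_segment_lengths or {}).items():
            if sector not in SECTORS:
                raise ValueError(f"unknown sector {sector!r}")
            if any(l < self.min_segment_length for l in lens):
                raise ValueError(
                    f"segment lengths must be >= {self.min_segment_length} bp")

    #: default sector plan: ten 0.5-5 kbp specific segments per genome and a
    #: few pairwise-shared blocks, alongside the split core
    DEFAULT_SECTORS = {
        "A": [500, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000],
        "B": [600, 1100, 1600, 2100, 2600, 3100, 3600, 4100, 4600, 4900],
        "C": [700, 1200, 1700, 2200, 2700, 3200, 3700, 4200, 4700, 4800],
        "AB": [2000, 1500], "AC": [1800], "BC": [2500],
    }

    def segment_lengths(self) -> dict[str, list[int]]:
        given = self.DEFAULT_SECTORS if self.sector_segment_lengths is None \
            else self.sector_segment_lengths
        lens = {s: list(given.get(s, [])) for s in SECTORS}
        if not lens["ABC"]:
            n = max(1, self.core_segments)
            base = self.core_length // n
            lens["ABC"] = [base] * (n - 1) + [self.core_length - base * (n - 1)]
        return lens

    def to_dict(self) -> dict:
        d = asdict(self)
        d["repeat_family_specs"] = [list(t) for t in self.repeat_family_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "repeat_family_specs" in d:
            d["repeat_family_specs"] = [tuple(t) for t in d["repeat_family_specs"]]
        if "gene_length_range" in d:
            d["gene_length_range"] = tuple(d["gene_length_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GenePlacement:
    gene_id: str
    seqid: str
    start: int
    end: int
    sector: str
    strand: str


@dataclass
class TrioTruth:
    """Planted ground truth in post-mutation assembled coordinates."""

    sector_intervals: dict[str, list[tuple[str, int, int, str]]]
    repeat_intervals: dict[str, list[tuple[str, int, int, str]]]
    variants: dict[str, list[tuple[str, int, str, int]]]
    gene_placements: dict[str, list[GenePlacement]]

    def sector_set(self, genome: str, sectors: str | Sequence[str]) -> IntervalSet:
        if isinstance(sectors, str):
            sectors = (sectors,)
        raw: dict[str, list[tuple[int, int]]] = {}
        for seqid, s, e, lab in self.sector_intervals[genome]:
            if lab in sectors:
                raw.setdefault(seqid, []).append((s, e))
        return IntervalSet(raw)

    def sector_totals(self, genome: str) -> dict[str, int]:
        out = {s: 0 for s in SECTORS}
        for _seqid, s, e, lab in self.sector_intervals[genome]:
            out[lab] += e - s
        return out

    def repeat_set(self, genome: str) -> IntervalSet:
        raw: dict[str, list[tuple[int, int]]] = {}
        for seqid, s, e, _fam in self.repeat_intervals[genome]:
            raw.setdefault(seqid, []).append((s, e))
        return IntervalSet(raw)

    def write_bed(self, genome: str, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seqid, s, e, lab in self.sector_intervals[genome]:
                fh.write(f"{seqid}\t{s}\t{e}\t{lab}\t0\t+\n")


# ---------------------------------------------------------------------------
# internal segment bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _Segment:
    sid: int
    sector: str                       # membership, e.g. "AB"
    seq: np.ndarray                   # ancestral codes (uint8), post repeat insertion
    repeats: list[tuple[int, int, str]] = field(default_factory=list)  # local ivs
    genes: list[tuple[str, int, int, str]] = field(default_factory=list)  # id, s, e, strand


def _mutate(rng: np.random.Generator, seq: np.ndarray, snp_rate: float,
            indel_rate: float) -> tuple[np.ndarray, list[tuple[int, str, int]],
                                        np.ndarray, np.ndarray]:
    """Apply substitutions then 1-5 bp indels to one segment copy.

    Returns (mutated codes, variants in mutated-local coords,
    map_starts, map_offsets) where ancestral coordinate ``x`` maps to
    ``x + offset`` for the greatest ``map_starts[i] <= x``.
    """
    seq = seq.copy()
    variants: list[tuple[int, str, int]] = []
    if snp_rate > 0:
        hits = np.flatnonzero(rng.random(len(seq)) < snp_rate)
        if len(hits):
            seq[hits] = (seq[hits] + rng.integers(1, 4, size=len(hits))) % 4
    map_starts = [0]
    map_offsets = [0]
    if indel_rate > 0:
        pos = np.sort(np.flatnonzero(rng.random(len(seq)) < indel_rate))
        # keep indels off the forced boundary bases and non-overlapping
        pos = pos[(pos > 5) & (pos < len(seq) - 10)]
        pieces = []
        cur = 0
        offset = 0
        last = -10
        for p in pos:
            if p - last < 6:
                continue
            last = p
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5:  # deletion of ancestral bases [p, p+size)
                pieces.append(seq[cur:p])
                cur = p + size
                offset -= size
                map_starts.append(p + size)
                map_offsets.append(offset)
                variants.append((p + offset + size, "del", size))
            else:  # insertion after ancestral base p
                pieces.append(seq[cur:p])
                pieces.append(rng.integers(0, 4, size=size, dtype=np.uint8))
                cur = p
                variants.append((p + offset, "ins", size))
                offset += size
                map_starts.append(p)
                map_offsets.append(offset)
        pieces.append(seq[cur:])
        seq = np.concatenate(pieces) if len(pieces) > 1 else pieces[0]
    if snp_rate > 0:
        ms = np.array(map_starts)
        mo = np.array(map_offsets)
        for h in hits:
            idx = np.searchsorted(ms, h, side="right") - 1
            variants.append((int(h + mo[idx]), "snp", 1))
    variants.sort()
    return seq, variants, np.array(map_starts), np.array(map_offsets)


def _map_coord(x: int, map_starts: np.ndarray, map_offsets: np.ndarray) -> int:
    idx = int(np.searchsorted(map_starts, x, side="right")) - 1
    return int(x + map_offsets[idx])


def _enforce_junctions(rng: np.random.Generator, segments: dict[int, _Segment],
                       orders: dict[str, list[int]]) -> None:
    """Assign boundary bases so shared-segment matches stop exactly at junctions.

    For every ordered genome pair (G, H) and segment X in G absent from H
    whose neighbor P is shared with H, the first base of X must differ from
    the first base of P's successor in H (and symmetrically for last bases).
    Solved by iterated repair; each inequality clique has size <= 3 over a
    4-letter alphabet, so this converges in a few sweeps.
    """
    succ = {g: {} for g in GENOMES}
    pred = {g: {} for g in GENOMES}
    for g, order in orders.items():
        for a, b in zip(order, order[1:]):
            succ[g][a] = b
            pred[g][b] = a

    fb_cons: set[tuple[int, int]] = set()
    lb_cons: set[tuple[int, int]] = set()
    for g in GENOMES:
        for h in GENOMES:
            if h == g:
                continue
            for x in orders[g]:
                if h in segments[x].sector:
                    continue  # x present in h: no constraint
                p = pred[g].get(x)
                if p is not None and h in segments[p].sector and p in succ[h]:
                    y = succ[h][p]
                    fb_cons.add((min(x, y), max(x, y)))
                q = succ[g].get(x)
                if q is not None and h in segments[q].sector and q in pred[h]:
                    w = pred[h][q]
                    lb_cons.add((min(x, w), max(x, w)))

    for cons, pos in ((fb_cons, 0), (lb_cons, -1)):
        neighbors: dict[int, set[int]] = {}
        for a, b in cons:
            neighbors.setdefault(a, set()).add(b)
            neighbors.setdefault(b, set()).add(a)
        converged = False
        for _ in range(100):
            dirty = False
            for a in sorted(neighbors):
                taken = {int(segments[b].seq[pos]) for b in neighbors[a]}
                if int(segments[a].seq[pos]) in taken:
                    choices = [c for c in range(4) if c not in taken]
                    segments[a].seq[pos] = int(rng.choice(choices)) if choices \
                        else int(rng.integers(0, 4))
                    dirty = True
            if not dirty:
                converged = True
                break
        if not converged:
            raise RuntimeError("junction constraint solving did not converge")


def _place_genes(rng: np.random.Generator, seg: _Segment, density: float,
                 length_range: tuple[int, int]) -> None:
    n = int(rng.poisson(density * len(seg.seq) / 10_000))
    blocked = IntervalSet({"s": [(s, e) for s, e, _ in seg.repeats]} if seg.repeats else {})
    placed: list[tuple[int, int]] = []
    for i in range(n):
        lo, hi = length_range
        glen = int(rng.integers(lo, hi + 1))
        if glen + 20 >= len(seg.seq):
            continue
        for _attempt in range(20):
            start = int(rng.integers(10, len(seg.seq) - glen - 10))
            iv = IntervalSet({"s": [(start, start + glen)]})
            if iv.intersect(blocked).total_bp() == 0 and all(
                    not (start < pe and ps < start + glen) for ps, pe in placed):
                strand = "+" if rng.random() < 0.5 else "-"
                seg.genes.append(
                    (f"seg{seg.sid}.g{i}", start, start + glen, strand))
                placed.append((start, start + glen))
                break


def _gene_model(gene_id: str, seqid: str, start: int, end: int, strand: str,
                rng: np.random.Generator) -> list[str]:
    """GFF3 lines (1-based inclusive) for a simple gene -> mRNA -> exon/CDS model."""
    glen = end - start
    n_exons = int(rng.integers(1, 4)) if glen >= 400 else 1
    # split the span into exons separated by introns
    cuts = np.sort(rng.choice(np.arange(50, glen - 50), size=2 * (n_exons - 1),
                              replace=False)) if n_exons > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[0], cuts, [glen]])
    exons = [(start + int(bounds[2 * i]), start + int(bounds[2 * i + 1]))
             for i in range(n_exons)]
    exons = [(s, e) for s, e in exons if e - s >= 30]
    lines = [
        f"{seqid}\t.\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gene_id}",
        f"{seqid}\t.\tmRNA\t{start + 1}\t{end}\t.\t{strand}\t.\t"
        f"ID={gene_id}.t1;Parent={gene_id}",
    ]
    for j, (s, e) in enumerate(exons):
        lines.append(f"{seqid}\t.\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                     f"ID={gene_id}.t1.e{j};Parent={gene_id}.t1")
    # CDS: exon union trimmed by 50 bp UTRs at both gene ends
    utr5 = (start, min(start + 50, end))
    utr3 = (max(end - 50, start), end)
    for j, (s, e) in enumerate(exons):
        cs, ce = max(s, utr5[1]), min(e, utr3[0])
        if cs < ce:
            lines.append(f"{seqid}\t.\tCDS\t{cs + 1}\t{ce}\t.\t{strand}\t0\t"
                         f"ID={gene_id}.t1.c{j};Parent={gene_id}.t1")
    first_s, first_e = exons[0]
    if first_s < utr5[1]:
        lines.append(f"{seqid}\t.\tfive_prime_UTR\t{first_s + 1}\t{min(first_e, utr5[1])}"
                     f"\t.\t{strand}\t.\tID={gene_id}.t1.u5;Parent={gene_id}.t1")
    last_s, last_e = exons[-1]
    if last_e > utr3[0]:
        lines.append(f"{seqid}\t.\tthree_prime_UTR\t{max(last_s, utr3[0]) + 1}\t{last_e}"
                     f"\t.\t{strand}\t.\tID={gene_id}.t1.u3;Parent={gene_id}.t1")
    return lines


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def simulate_trio(config: SimConfig) -> tuple[dict[str, SequenceSet],
                                              dict[str, list[str]],
                                              TrioTruth]:
    """Simulate three genomes, their GFF3 annotations, and ground truth.

    Returns ``(genomes, annotations, truth)`` where ``genomes`` maps genome
    name to a single-scaffold :class:`SequenceSet` (scaffold named
    ``{genome}_chr1``) and ``annotations`` maps genome name to GFF3 lines.
    """
    rng = np.random.default_rng(config.seed)
    seg_lengths = config.segment_lengths()

    # ancestral segments
    segments: dict[int, _Segment] = {}
    sid = 0
    for sector in SECTORS:
        for length in seg_lengths[sector]:
            segments[sid] = _Segment(sid, sector, encode(random_dna(rng, length)))
            sid += 1

    genome_len = {g: sum(len(s.seq) for s in segments.values() if g in s.sector)
                  for g in GENOMES}
    total_repeat = sum(ul * cn for ul, cn in config.repeat_family_specs)
    if any(total_repeat >= genome_len[g] for g in GENOMES):
        raise ValueError("total repeat content exceeds genome length")

    # repeat insertion: shared copies into core segments, the rest into
    # genome-specific segments (same unit sequence everywhere)
    core_ids = [s.sid for s in segments.values() if s.sector == "ABC"]
    for fam_idx, (unit_len, copies) in enumerate(config.repeat_family_specs):
        fam = f"rep{fam_idx}"
        unit = rng.integers(0, 4, size=unit_len, dtype=np.uint8)
        n_specific = min(config.repeat_in_specific, copies)
        for _ in range(copies - n_specific):
            seg = segments[int(rng.choice(core_ids))]
            pos = int(rng.integers(10, len(seg.seq) - 10))
            _insert_repeat(seg, pos, unit, fam)
        for g in GENOMES:
            spec_ids = [s.sid for s in segments.values() if s.sector == g]
            for _ in range(n_specific):
                if not spec_ids:
                    break
                seg = segments[int(rng.choice(spec_ids))]
                pos = int(rng.integers(10, len(seg.seq) - 10))
                _insert_repeat(seg, pos, unit, fam)

    # gene placement on ancestral segments (entirely within one segment)
    for seg in segments.values():
        _place_genes(rng, seg, config.gene_density, config.gene_length_range)

    # per-genome segment order: seeded random shuffle
    orders: dict[str, list[int]] = {}
    for g in GENOMES:
        ids = [s.sid for s in segments.values() if g in s.sector]
        rng.shuffle(ids)
        orders[g] = ids

    _enforce_junctions(rng, segments, orders)

    genomes: dict[str, SequenceSet] = {}
    annotations: dict[str, list[str]] = {}
    truth = TrioTruth(sector_intervals={}, repeat_intervals={}, variants={},
                      gene_placements={})
    for g in GENOMES:
        seqid = f"{g}_chr1"
        parts: list[np.ndarray] = []
        sect_ivs, rep_ivs, var_list, gene_list = [], [], [], []
        gff = ["##gff-version 3"]
        offset = 0
        for sid_ in orders[g]:
            seg = segments[sid_]
            mutate = len(seg.sector) > 1  # shared copies diverge per genome
            if mutate and (config.snp_rate > 0 or config.small_indel_rate > 0):
                mseq, variants, ms, mo = _mutate(
                    rng, seg.seq, config.snp_rate, config.small_indel_rate)
            else:
                mseq, variants = seg.seq, []
                ms = np.array([0]); mo = np.array([0])
            parts.append(mseq)
            sect_ivs.append((seqid, offset, offset + len(mseq), seg.sector))
            for s, e, fam in seg.repeats:
                rep_ivs.append((seqid, offset + _map_coord(s, ms, mo),
                                offset + _map_coord(e, ms, mo), fam))
            for p, typ, size in variants:
                var_list.append((seqid, offset + p, typ, size))
            for gid, s, e, strand in seg.genes:
                gs = offset + _map_coord(s, ms, mo)
                ge = offset + _map_coord(e, ms, mo)
                if ge - gs < 60:
                    continue
                full_id = f"{g}.{gid}"
                gene_list.append(GenePlacement(full_id, seqid, gs, ge,
                                               seg.sector, strand))
                gff.extend(_gene_model(full_id, seqid, gs, ge, strand, rng))
            offset += len(mseq)
        seq = decode(np.concatenate(parts))
        # optional boundary-spanning genes to exercise the majority rule
        for b in range(config.boundary_genes):
            junctions = [e for _sq, _s, e, _l in sect_ivs[:-1]]
            if not junctions:
                break
            j = int(rng.choice(junctions))
            gs, ge = max(0, j - 1800), min(len(seq), j + 200)
            full_id = f"{g}.bnd{b}"
            gene_list.append(GenePlacement(full_id, seqid, gs, ge, "boundary", "+"))
            gff.extend(_gene_model(full_id, seqid, gs, ge, "+", rng))
        genomes[g] = SequenceSet({seqid: seq})
        annotations[g] = gff
        truth.sector_intervals[g] = sect_ivs
        truth.repeat_intervals[g] = rep_ivs
        truth.variants[g] = sorted(var_list)
        truth.gene_placements[g] = gene_list
    return genomes, annotations, truth


def _insert_repeat(seg: _Segment, pos: int, unit: np.ndarray, fam: str) -> None:
    shift = len(unit)
    seg.seq = np.concatenate([seg.seq[:pos], unit, seg.seq[pos:]])
    seg.repeats = [(s + shift, e + shift, f) if s >= pos else (s, e, f)
                   for s, e, f in seg.repeats]
    seg.genes = [(gid, s + shift, e + shift, st) if s >= pos else (gid, s, e, st)
                 for gid, s, e, st in seg.genes]
    seg.repeats.append((pos, pos + shift, fam))
    seg.repeats.sort(key=lambda t: t[0])


def simulate_reads(genome: SequenceSet, config: SimConfig,
                   seed: int | None = None,
                   name_prefix: str = "read") -> list[tuple[str, str]]:
    """Uniform single-end shotgun reads at ``config.read_depth`` fold coverage.

    Read count is ``round(depth * genome_span / read_length)``; start
    positions are uniform over windows fully inside a scaffold, strand is
    uniform, and substitution errors are applied per base at
    ``config.read_error_rate``.
    """
    if config.read_depth <= 0:
        raise ValueError("read depth must be positive")
    rl = config.read_length
    names = list(genome)
    lengths = np.array([len(genome[n]) for n in names])
    if rl > lengths.min():
        raise ValueError("read length exceeds shortest scaffold")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_reads = int(round(config.read_depth * lengths.sum() / rl))
    windows = lengths - rl + 1
    probs = windows / windows.sum()
    scaf_idx = rng.choice(len(names), size=n_reads, p=probs)
    encoded = [encode(genome[n]) for n in names]
    reads: list[tuple[str, str]] = []
    batch = 200_000
    ridx = 0
    for lo in range(0, n_reads, batch):
        hi = min(lo + batch, n_reads)
        idxs = scaf_idx[lo:hi]
        offs = (rng.random(hi - lo) * windows[idxs]).astype(np.int64)
        strands = rng.random(hi - lo) < 0.5
        err = None
        if config.read_error_rate > 0:
            err = rng.random((hi - lo, rl)) < config.read_error_rate
            err_shift = rng.integers(1, 4, size=(hi - lo, rl), dtype=np.uint8)
        for i in range(hi - lo):
            codes = encoded[idxs[i]][offs[i]: offs[i] + rl]
            if err is not None and err[i].any():
                codes = codes.copy()
                mask = err[i] & (codes < 4)
                codes[mask] = (codes[mask] + err_shift[i][mask]) % 4
            seq = decode(codes)
            if strands[i]:
                seq = revcomp(seq)
            reads.append((f"{name_prefix}.{ridx}", seq))
            ridx += 1
    return reads


def write_fixture(directory: str | Path,
                  genomes: dict[str, SequenceSet],
                  annotations: dict[str, list[str]],
                  truth: TrioTruth,
                  config: SimConfig,
                  reads: dict[str, list[tuple[str, str]]] | None = None,
                  ) -> dict[str, Path]:
    """Write FASTA/GFF3/BED(+FASTQ) fixture files plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for g, seqs in genomes.items():
        p = directory / f"{g}.fa"
        seqs.to_fasta(p)
        paths[f"fasta_{g}"] = p
        p = directory / f"{g}.gff3"
        p.write_text("\n".join(annotations[g]) + "\n")
        paths[f"gff_{g}"] = p
        p = directory / f"{g}.truth.bed"
        truth.write_bed(g, p)
        paths[f"truth_{g}"] = p
        if reads and g in reads:
            p = directory / f"{g}.reads.fq"
            write_fastq(reads[g], p)
            paths[f"reads_{g}"] = p
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps(
        {"config": config.to_dict(), "seed": config.seed,
         "files": {k: p.name for k, p in paths.items()}}, indent=2) + "\n")
    paths["manifest"] = manifest
    return paths


__all__ = ["SimConfig", "TrioTruth", "GenePlacement", "SECTORS", "GENOMES",
           "simulate_trio", "simulate_reads", "write_fixture"]
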