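"""Anchor-based whole-genome alignment of two assemblies.

The aligner follows the classic MUM pipeline: find maximal exact matches
that are unique in the reference (both strands), cluster them along
diagonals, close the gaps between clustered anchors with banded unit-cost
global alignment, optionally select the best one-to-one set of blocks by
length x identity weight, and summarize the remaining differences as
substitutions, small indels (<= 5 bp), larger indels, inversions,
relocations, and translocations.

Defaults mirror sensitive settings of the nucmer family: minimum anchor 30,
minimum cluster 65, diagonal band factor 5, maximum anchor gap 90 bp.
N runs in scaffolds match nothing and therefore break anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .intervals import IntervalSet
from .seqio import SequenceSet, encode, revcomp


@dataclass(frozen=True)
class AlignerConfig:
    min_match: int = 30            # minimum anchor (maximal exact match) length
    min_cluster: int = 65          # minimum summed anchor length per cluster
    diag_band: int = 5             # max diagonal drift factor for chaining / band
    max_gap: int = 90              # max gap between chained anchors (bp)
    small_indel_cutoff: int = 5    # boundary between small and large indels (bp)
    relocation_gap: int = 10_000   # in-order gap beyond which blocks are relocated
    end_min_identity: float = 0.65
    unique_in: str = "ref"         # "ref" (MUM-in-reference) or "both"

    def __post_init__(self):
        if min(self.min_match, self.min_cluster, self.diag_band,
               self.max_gap, self.small_indel_cutoff, self.relocation_gap) <= 0:
            raise ValueError("all aligner parameters must be positive")
        if self.small_indel_cutoff >= self.relocation_gap:
            raise ValueError("small_indel_cutoff must be < relocation_gap")
        if self.min_match > 32:
            raise ValueError("min_match above 32 is not supported (2-bit seeds)")


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match, unique in the reference.

    ``qry_start`` is on the query's forward strand; ``qs`` is the match start
    in strand space (coordinates of the reverse complement for '-' anchors),
    which is what diagonal clustering operates on.
    """

    ref_name: str
    ref_start: int
    qry_name: str
    qry_start: int
    length: int
    strand: str
    qs: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length

    @property
    def qe(self) -> int:
        return self.qs + self.length


@dataclass
class AlignmentBlock:
    ref_name: str
    ref_start: int
    ref_end: int
    qry_name: str
    qry_start: int       # forward strand of the query
    qry_end: int
    strand: str
    matches: int
    columns: int
    substitutions: int
    small_indel_events: int
    large_indels: list[tuple[int, str]] = field(default_factory=list)

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def weight(self) -> float:
        return self.ref_span * self.identity


@dataclass
class DiffSummary:
    unaligned_ref_fraction: float
    unaligned_qry_fraction: float
    avg_identity: float
    snps_small_indels: int
    large_indel_events: int
    inversions: int
    relocations: int
    translocations: int


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def _concat_codes(seqs: SequenceSet) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Concatenate scaffolds with single-N separators; return codes, names, offsets."""
    names = list(seqs)
    parts = []
    offsets = []
    pos = 0
    sep = np.array([4], dtype=np.uint8)
    for i, n in enumerate(names):
        offsets.append(pos)
        c = encode(seqs[n])
        parts.append(c)
        pos += len(c)
        if i != len(names) - 1:
            parts.append(sep)
            pos += 1
    return np.concatenate(parts) if parts else np.empty(0, np.uint8), names, np.array(offsets)


def _seed_codes(codes: np.ndarray, s: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward 2-bit codes and validity for every s-window (no canonicalization)."""
    n = len(codes) - s + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    bad = (codes >= 4).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[s:] - cum[:-s]) == 0
    safe = np.where(codes >= 4, 0, codes).astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(s):
        out = (out << np.uint64(2)) | safe[j : j + n]
    return out, valid


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-query [lo, hi) index ranges; returns (source row, flat index)."""
    lens = hi - lo
    keep = lens > 0
    lo, lens = lo[keep], lens[keep]
    rows = np.flatnonzero(keep)
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    row_rep = np.repeat(rows, lens)
    cml = np.cumsum(lens)
    flat = np.arange(total) - np.repeat(cml - lens, lens) + np.repeat(lo, lens)
    return row_rep, flat


def _match_runs(q_codes: np.ndarray, q_valid: np.ndarray,
                ref_sorted: np.ndarray, ref_sorted_pos: np.ndarray,
                s: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All maximal exact matches >= s between query windows and the indexed ref.

    Returns (ref_start, q_start, length) arrays; matches are maximal because
    a run of diagonal-consecutive seed hits is bounded by a mismatching (or
    invalid) flanking window.
    """
    qpos_all = np.flatnonzero(q_valid)
    if len(qpos_all) == 0 or len(ref_sorted) == 0:
        return (np.empty(0, np.int64),) * 3
    qc = q_codes[qpos_all]
    lo = np.searchsorted(ref_sorted, qc, side="left")
    hi = np.searchsorted(ref_sorted, qc, side="right")
    rows, flat = _expand_ranges(lo, hi)
    if len(rows) == 0:
        return (np.empty(0, np.int64),) * 3
    qpos = qpos_all[rows].astype(np.int64)
    rpos = ref_sorted_pos[flat].astype(np.int64)
    diag = rpos - qpos
    order = np.lexsort((qpos, diag))
    qpos, rpos, diag = qpos[order], rpos[order], diag[order]
    new_run = np.empty(len(qpos), dtype=bool)
    new_run[0] = True
    new_run[1:] = (diag[1:] != diag[:-1]) | (qpos[1:] != qpos[:-1] + 1)
    starts = np.flatnonzero(new_run)
    ends = np.concatenate([starts[1:], [len(qpos)]])
    length = (qpos[ends - 1] - qpos[starts]) + s
    return rpos[starts], qpos[starts], length


class ReferenceIndex:
    """Sorted seed index plus self-repeat intervals for one reference assembly.

    Build once per reference and reuse across queries; repeat intervals are
    forward-strand ref-vs-ref maximal matches (off the identity diagonal) and
    drive the anchor uniqueness screen.
    """

    def __init__(self, ref: SequenceSet, config: AlignerConfig):
        self.config = config
        self.ref = ref
        s = config.min_match
        self.s = s
        self.codes, self.names, self.offsets = _concat_codes(ref)
        seed, valid = _seed_codes(self.codes, s)
        pos = np.flatnonzero(valid)
        order = np.argsort(seed[pos], kind="stable")
        self.sorted_codes = seed[pos][order]
        self.sorted_pos = pos[order]
        # self matches for the uniqueness screen
        r, q, ln = _match_runs(seed, valid, self.sorted_codes, self.sorted_pos, s)
        off_diag = r != q
        ivs = np.concatenate([
            np.stack([r[off_diag], r[off_diag] + ln[off_diag]], axis=1),
            np.stack([q[off_diag], q[off_diag] + ln[off_diag]], axis=1),
        ]) if off_diag.any() else np.empty((0, 2), dtype=np.int64)
        if len(ivs):
            ivs = ivs[np.argsort(ivs[:, 0], kind="stable")]
            self._rep_starts = ivs[:, 0]
            self._rep_maxend = np.maximum.accumulate(ivs[:, 1])
        else:
            self._rep_starts = np.empty(0, np.int64)
            self._rep_maxend = np.empty(0, np.int64)

    def non_unique(self, starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """True where ref[start:start+length] occurs more than once (forward)."""
        if len(self._rep_starts) == 0:
            return np.zeros(len(starts), dtype=bool)
        idx = np.searchsorted(self._rep_starts, starts, side="right") - 1
        out = np.zeros(len(starts), dtype=bool)
        ok = idx >= 0
        out[ok] = self._rep_maxend[idx[ok]] >= (starts[ok] + lengths[ok])
        return out

    def locate(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global concat positions to (scaffold index, local position)."""
        idx = np.searchsorted(self.offsets, gpos, side="right") - 1
        return idx, gpos - self.offsets[idx]


def find_anchors(ref: SequenceSet, qry: SequenceSet,
                 config: AlignerConfig = AlignerConfig(),
                 index: ReferenceIndex | None = None) -> list[Anchor]:
    """All maximal exact matches >= min_match, unique in the reference, both strands.

    With ``config.unique_in == "both"`` matches must additionally be unique in
    the query (full MUM mode).
    """
    if index is None:
        index = ReferenceIndex(ref, config)
    s = config.min_match
    qry_index = ReferenceIndex(qry, config) if config.unique_in == "both" else None
    anchors: list[Anchor] = []
    for qname in qry:
        qseq = qry[qname]
        qlen = len(qseq)
        for strand in "+-":
            sseq = qseq if strand == "+" else revcomp(qseq)
            codes, valid = _seed_codes(encode(sseq), s)
            r, q, ln = _match_runs(codes, valid, index.sorted_codes,
                                   index.sorted_pos, s)
            if len(r) == 0:
                continue
            keep = ~index.non_unique(r, ln)
            if qry_index is not None and keep.any():
                qf = q if strand == "+" else qlen - (q + ln)
                qoff = qry_index.offsets[list(qry).index(qname)]
                keep &= ~qry_index.non_unique(qf + qoff, ln)
            r, q, ln = r[keep], q[keep], ln[keep]
            sidx, rloc = index.locate(r)
            for i in range(len(r)):
                qs = int(q[i])
                length = int(ln[i])
                qf = qs if strand == "+" else qlen - (qs + length)
                anchors.append(Anchor(
                    ref_name=index.names[int(sidx[i])], ref_start=int(rloc[i]),
                    qry_name=qname, qry_start=qf, length=length,
                    strand=strand, qs=qs))
    anchors.sort(key=lambda a: (a.ref_name, a.qry_name, a.strand, a.ref_start, a.qs))
    return anchors


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def cluster_anchors(anchors: Sequence[Anchor],
                    config: AlignerConfig = AlignerConfig()) -> list[list[Anchor]]:
    """Chain anchors of one (ref seq, qry seq, strand) triple into clusters.

    Two anchors chain when both coordinate gaps are <= max_gap and the
    diagonal drift is <= diag_band x the gap; clusters whose summed anchor
    length falls below min_cluster are discarded.
    """
    if not anchors:
        return []
    key = {(a.ref_name, a.qry_name, a.strand) for a in anchors}
    if len(key) != 1:
        raise ValueError("cluster_anchors expects a single (ref, qry, strand) group")
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].ref_start, anchors[i].qs))
    parent = list(range(len(anchors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    window = 60
    for oi, i in enumerate(order):
        a = anchors[i]
        for j in order[max(0, oi - window): oi]:
            b = anchors[j]
            gap_r = a.ref_start - b.ref_end
            gap_q = a.qs - b.qe
            if gap_r > config.max_gap or gap_q > config.max_gap:
                continue
            tol = min(a.length, b.length) - 1
            if gap_r < -tol or gap_q < -tol:
                continue
            gap = max(gap_r, gap_q, 1)
            if abs(gap_r - gap_q) <= config.diag_band * gap:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict[int, list[Anchor]] = {}
    for i in order:
        groups.setdefault(find(i), []).append(anchors[i])
    clusters = [sorted(g, key=lambda a: (a.ref_start, a.qs))
                for g in groups.values()
                if sum(a.length for a in g) >= config.min_cluster]
    clusters.sort(key=lambda c: (c[0].ref_start, c[0].qs))
    return clusters


# ---------------------------------------------------------------------------
# extension
# ---------------------------------------------------------------------------

def _cigar_stats(cigar: str) -> tuple[int, int, list[tuple[int, str]]]:
    """(matches, substitutions, indel events) from an extended edlib CIGAR."""
    matches = subs = 0
    events: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            matches += n
        elif ch == "X":
            subs += n
        elif ch == "I":   # extra bases in the query
            events.append((n, "qry"))
        elif ch == "D":   # bases missing from the query
            events.append((n, "ref"))
    return matches, subs, events


def _close_gap(rgap: str, qgap: str, config: AlignerConfig
               ) -> tuple[int, int, list[tuple[int, str]], int] | None:
    """Align one inter-anchor gap; None signals band overflow (split block)."""
    if not rgap and not qgap:
        return 0, 0, [], 0
    if not rgap:
        return 0, 0, [(len(qgap), "qry")], len(qgap)
    if not qgap:
        return 0, 0, [(len(rgap), "ref")], len(rgap)
    lim = max(abs(len(rgap) - len(qgap)) + config.diag_band,
              int(0.35 * max(len(rgap), len(qgap))), 5)
    res = edlib.align(qgap, rgap, mode="NW", task="path", k=lim)
    if res["editDistance"] < 0:
        return None
    matches, subs, events = _cigar_stats(res["cigar"])
    columns = matches + subs + sum(n for n, _ in events)
    return matches, subs, events, columns


def _extend_end(ref_str: str, qry_str: str, rpos: int, qpos: int, step: int,
                min_identity: float) -> tuple[int, int, int]:
    """Greedy end extension; returns (extension length, matches, substitutions).

    Walks outward one base at a time while the identity of the extension stays
    at or above ``min_identity`` (evaluated after every added base), then trims
    trailing mismatches.  A leading mismatch therefore stops extension at once.
    """
    length = matches = 0
    best_len = best_matches = 0
    r, q = rpos, qpos
    while 0 <= r < len(ref_str) and 0 <= q < len(qry_str):
        hit = ref_str[r] == qry_str[q] and ref_str[r] != "N"
        length += 1
        if hit:
            matches += 1
            best_len, best_matches = length, matches
        if matches / length < min_identity:
            break
        r += step
        q += step
    return best_len, best_matches, best_len - best_matches


def extend_cluster(cluster: Sequence[Anchor], ref: SequenceSet, qry: SequenceSet,
                   config: AlignerConfig = AlignerConfig(),
                   qry_strand_seq: str | None = None) -> list[AlignmentBlock]:
    """Close inter-anchor gaps with unit-cost banded alignment and extend ends.

    Returns one block normally; a band overflow in some gap splits the cluster
    there and yields multiple blocks.
    """
    if not cluster:
        raise ValueError("empty cluster")
    a0 = cluster[0]
    ref_str = ref[a0.ref_name]
    if qry_strand_seq is None:
        qseq = qry[a0.qry_name]
        qry_strand_seq = qseq if a0.strand == "+" else revcomp(qseq)
    qlen_full = len(qry_strand_seq)

    # enforce consistent, non-overlapping anchor order in both coordinates
    chain: list[list[int]] = []   # [ref_start, qs, length]
    for a in sorted(cluster, key=lambda a: (a.ref_start, a.qs)):
        rs, qs, ln = a.ref_start, a.qs, a.length
        if chain:
            pr, pq, pl = chain[-1]
            trim = max(pr + pl - rs, pq + pl - qs, 0)
            if trim >= ln:
                continue
            rs += trim
            qs += trim
            ln -= trim
            if qs < pq + pl:
                continue
        chain.append([rs, qs, ln])

    blocks: list[AlignmentBlock] = []
    cur: dict | None = None
    for rs, qs, ln in chain:
        if cur is None:
            cur = dict(rstart=rs, qstart=qs, rend=rs + ln, qend=qs + ln,
                       matches=ln, columns=ln, subs=0, events=[])
            continue
        gap = _close_gap(ref_str[cur["rend"]: rs], qry_strand_seq[cur["qend"]: qs],
                         config)
        if gap is None:  # band overflow: split here
            blocks.append(_finalize(cur, a0, ref_str, qry_strand_seq,
                                    qlen_full, config))
            cur = dict(rstart=rs, qstart=qs, rend=rs + ln, qend=qs + ln,
                       matches=ln, columns=ln, subs=0, events=[])
            continue
        m, s, ev, cols = gap
        cur["matches"] += m + ln
        cur["subs"] += s
        cur["events"].extend(ev)
        cur["columns"] += cols + ln
        cur["rend"] = rs + ln
        cur["qend"] = qs + ln
    if cur is not None:
        blocks.append(_finalize(cur, a0, ref_str, qry_strand_seq, qlen_full, config))
    return blocks


def _finalize(cur: dict, a0: Anchor, ref_str: str, qry_strand_seq: str,
              qlen_full: int, config: AlignerConfig) -> AlignmentBlock:
    # end extension outward from both block ends
    ext, m, s = _extend_end(ref_str, qry_strand_seq, cur["rstart"] - 1,
                            cur["qstart"] - 1, -1, config.end_min_identity)
    cur["rstart"] -= ext
    cur["qstart"] -= ext
    cur["matches"] += m
    cur["subs"] += s
    cur["columns"] += ext
    ext, m, s = _extend_end(ref_str, qry_strand_seq, cur["rend"], cur["qend"],
                            +1, config.end_min_identity)
    cur["rend"] += ext
    cur["qend"] += ext
    cur["matches"] += m
    cur["subs"] += s
    cur["columns"] += ext
    small = sum(1 for n, _ in cur["events"] if n <= config.small_indel_cutoff)
    large = [(n, side) for n, side in cur["events"] if n > config.small_indel_cutoff]
    if a0.strand == "+":
        q0, q1 = cur["qstart"], cur["qend"]
    else:
        q0, q1 = qlen_full - cur["qend"], qlen_full - cur["qstart"]
    return AlignmentBlock(
        ref_name=a0.ref_name, ref_start=cur["rstart"], ref_end=cur["rend"],
        qry_name=a0.qry_name, qry_start=q0, qry_end=q1, strand=a0.strand,
        matches=cur["matches"], columns=cur["columns"],
        substitutions=cur["subs"], small_indel_events=small, large_indels=large)


# ---------------------------------------------------------------------------
# one-to-one filtering
# ---------------------------------------------------------------------------

def filter_one_to_one(blocks: Sequence[AlignmentBlock],
                      exact_limit: int = 30,
                      overlap_tol: int = 10) -> list[AlignmentBlock]:
    """Best mutually consistent subset of blocks, weight = ref length x identity.

    Blocks conflict when they overlap by more than ``overlap_tol`` bp in
    reference or in query coordinates (the tolerance absorbs the few-bp
    chance extension at block ends); residual small overlaps among the
    selected blocks are trimmed afterwards, so the returned blocks never
    overlap.  Each connected component of the conflict graph is solved
    exactly by branch-and-bound up to ``exact_limit`` blocks; larger
    (repeat-induced) components fall back to greedy selection by
    descending weight.
    """
    n = len(blocks)
    adj: list[set[int]] = [set() for _ in range(n)]
    for side in ("ref", "qry"):
        name_of = (lambda b: b.ref_name) if side == "ref" else (lambda b: b.qry_name)
        start_of = (lambda b: b.ref_start) if side == "ref" else (lambda b: b.qry_start)
        end_of = (lambda b: b.ref_end) if side == "ref" else (lambda b: b.qry_end)
        order = sorted(range(n), key=lambda i: (name_of(blocks[i]), start_of(blocks[i])))
        for ii in range(n):
            for jj in range(ii + 1, n):
                i, j = order[ii], order[jj]
                if name_of(blocks[i]) != name_of(blocks[j]):
                    break
                if start_of(blocks[j]) >= end_of(blocks[i]):
                    break
                ov = min(end_of(blocks[i]), end_of(blocks[j])) - start_of(blocks[j])
                if ov > overlap_tol:
                    adj[i].add(j)
                    adj[j].add(i)

    seen = [False] * n
    keep: list[int] = []
    for start in range(n):
        if seen[start]:
            continue
        comp = []
        stack = [start]
        seen[start] = True
        while stack:
            x = stack.pop()
            comp.append(x)
            for y in adj[x]:
                if not seen[y]:
                    seen[y] = True
                    stack.append(y)
        if len(comp) == 1:
            keep.append(comp[0])
        elif len(comp) <= exact_limit:
            keep.extend(_mwis_exact(comp, blocks, adj))
        else:
            keep.extend(_mwis_greedy(comp, blocks, adj))
    keep.sort(key=lambda i: (blocks[i].ref_name, blocks[i].ref_start))
    return _trim_overlaps([_copy_block(blocks[i]) for i in keep])


def _copy_block(b: AlignmentBlock) -> AlignmentBlock:
    from dataclasses import replace
    return replace(b, large_indels=list(b.large_indels))


def _trim_overlaps(blocks: list[AlignmentBlock], max_rounds: int = 4
                   ) -> list[AlignmentBlock]:
    """Trim residual sub-tolerance overlaps so kept blocks never overlap."""
    def shrink(b: AlignmentBlock, d: int, at_start: bool, side: str) -> bool:
        if d <= 0:
            return False
        if b.ref_span <= d or (b.qry_end - b.qry_start) <= d:
            blocks.remove(b)
            return True
        fwd = b.strand == "+"
        if side == "ref":
            if at_start:
                b.ref_start += d
                if fwd:
                    b.qry_start += d
                else:
                    b.qry_end -= d
            else:
                b.ref_end -= d
                if fwd:
                    b.qry_end -= d
                else:
                    b.qry_start += d
        else:
            if at_start:
                b.qry_start += d
                if fwd:
                    b.ref_start += d
                else:
                    b.ref_end -= d
            else:
                b.qry_end -= d
                if fwd:
                    b.ref_end -= d
                else:
                    b.ref_start += d
        b.columns = max(b.columns - d, 1)
        b.matches = min(b.matches, b.columns)
        return True

    for _ in range(max_rounds):
        dirty = False
        for side in ("ref", "qry"):
            start_of = (lambda b: b.ref_start) if side == "ref" else (lambda b: b.qry_start)
            end_of = (lambda b: b.ref_end) if side == "ref" else (lambda b: b.qry_end)
            name_of = (lambda b: b.ref_name) if side == "ref" else (lambda b: b.qry_name)
            blocks.sort(key=lambda b: (name_of(b), start_of(b)))
            prev: AlignmentBlock | None = None
            for b in list(blocks):
                if prev is not None and name_of(b) == name_of(prev) \
                        and start_of(b) < end_of(prev):
                    ov = min(end_of(prev), end_of(b)) - start_of(b)
                    low = b if b.weight <= prev.weight else prev
                    dirty |= shrink(low, ov, at_start=(low is b), side=side)
                    if low in blocks and low is prev and b in blocks:
                        prev = b
                    elif b in blocks:
                        prev = b
                    continue
                prev = b
        if not dirty:
            break
    blocks.sort(key=lambda b: (b.ref_name, b.ref_start))
    return blocks


def _mwis_exact(comp: list[int], blocks: Sequence[AlignmentBlock],
                adj: list[set[int]]) -> list[int]:
    comp = sorted(comp, key=lambda i: -blocks[i].weight)
    weights = [blocks[i].weight for i in comp]
    suffix = np.concatenate([np.cumsum(weights[::-1])[::-1], [0.0]])
    best: tuple[float, list[int]] = (-1.0, [])

    def rec(pos: int, chosen: list[int], banned: set[int], total: float):
        nonlocal best
        if total > best[0]:
            best = (total, list(chosen))
        if pos == len(comp) or total + suffix[pos] <= best[0]:
            return
        i = comp[pos]
        if i not in banned:
            newly = adj[i] - banned
            chosen.append(i)
            rec(pos + 1, chosen, banned | newly, total + blocks[i].weight)
            chosen.pop()
        rec(pos + 1, chosen, banned, total)

    rec(0, [], set(), 0.0)
    return best[1]


def _mwis_greedy(comp: list[int], blocks: Sequence[AlignmentBlock],
                 adj: list[set[int]]) -> list[int]:
    chosen: list[int] = []
    banned: set[int] = set()
    for i in sorted(comp, key=lambda i: (-blocks[i].weight, i)):
        if i not in banned:
            chosen.append(i)
            banned |= adj[i]
    return chosen


# ---------------------------------------------------------------------------
# summaries and unaligned regions
# ---------------------------------------------------------------------------

def blocks_interval_set(blocks: Iterable[AlignmentBlock], side: str = "ref") -> IntervalSet:
    raw: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        if side == "ref":
            raw.setdefault(b.ref_name, []).append((b.ref_start, b.ref_end))
        else:
            raw.setdefault(b.qry_name, []).append((b.qry_start, b.qry_end))
    return IntervalSet(raw)


def unaligned_regions(target: SequenceSet, blocks_all: Iterable[AlignmentBlock],
                      side: str = "ref") -> IntervalSet:
    """Per-sequence complement of the union of aligned intervals.

    Pass the pre-filter (repeat-inclusive) block set when hunting novel
    sequence, so that copy-number differences are not mistaken for it.
    """
    aligned = blocks_interval_set(blocks_all, side=side)
    return aligned.complement(target.lengths())


def summarize_diff(blocks: Sequence[AlignmentBlock], ref: SequenceSet,
                   qry: SequenceSet,
                   config: AlignerConfig = AlignerConfig()) -> DiffSummary:
    """Summarize one-to-one blocks as dnadiff-style difference counts."""
    if not blocks:
        return DiffSummary(1.0, 1.0, 0.0, 0, 0, 0, 0, 0)
    aligned_ref = blocks_interval_set(blocks, "ref").total_bp()
    aligned_qry = blocks_interval_set(blocks, "qry").total_bp()
    total_cols = sum(b.columns for b in blocks)
    avg_identity = sum(b.matches for b in blocks) / total_cols
    snps_small = sum(b.substitutions + b.small_indel_events for b in blocks)
    large = sum(len(b.large_indels) for b in blocks)
    inversions = relocations = translocations = 0
    ordered = sorted(blocks, key=lambda b: (b.qry_name, b.qry_start))
    for a, b in zip(ordered, ordered[1:]):
        if a.qry_name != b.qry_name:
            continue
        if a.strand != b.strand:
            inversions += 1
        elif a.ref_name != b.ref_name:
            translocations += 1
        else:
            if a.strand == "+":
                gap = b.ref_start - a.ref_end
                in_order = b.ref_start >= a.ref_start
            else:
                gap = a.ref_start - b.ref_end
                in_order = b.ref_end <= a.ref_end
            if not in_order or gap > config.relocation_gap:
                relocations += 1
    return DiffSummary(
        unaligned_ref_fraction=1 - aligned_ref / ref.total_span,
        unaligned_qry_fraction=1 - aligned_qry / qry.total_span,
        avg_identity=avg_identity,
        snps_small_indels=snps_small,
        large_indel_events=large,
        inversions=inversions,
        relocations=relocations,
        translocations=translocations)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    anchors: list[Anchor]
    blocks_all: list[AlignmentBlock]
    blocks: list[AlignmentBlock]        # one-to-one filtered
    summary: DiffSummary

    def unaligned(self, target: SequenceSet, side: str = "ref") -> IntervalSet:
        return unaligned_regions(target, self.blocks_all, side=side)


def align_genomes(ref: SequenceSet, qry: SequenceSet,
                  config: AlignerConfig = AlignerConfig(),
                  index: ReferenceIndex | None = None) -> AlignmentResult:
    """Full anchoring -> clustering -> extension -> one-to-one -> summary run."""
    anchors = find_anchors(ref, qry, config, index=index)
    groups: dict[tuple[str, str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.ref_name, a.qry_name, a.strand), []).append(a)
    blocks_all: list[AlignmentBlock] = []
    rc_cache: dict[str, str] = {}
    for (_rn, qn, strand), group in sorted(groups.items()):
        if strand == "-":
            if qn not in rc_cache:
                rc_cache[qn] = revcomp(qry[qn])
            strand_seq = rc_cache[qn]
        else:
            strand_seq = qry[qn]
        for cluster in cluster_anchors(group, config):
            blocks_all.extend(extend_cluster(cluster, ref, qry, config,
                                             qry_strand_seq=strand_seq))
    blocks = filter_one_to_one(blocks_all)
    summary = summarize_diff(blocks, ref, qry, config)
    return AlignmentResult(anchors, blocks_all, blocks, summary)


def write_blocks_tsv(blocks: Iterable[AlignmentBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("ref\trstart\trend\tqry\tqstart\tqend\tstrand\tidentity\t"
                 "substitutions\tsmall_indels\tlarge_indels\n")
        for b in blocks:
            large = ",".join(f"{n}{side[0]}" for n, side in b.large_indels)
            fh.write(f"{b.ref_name}\t{b.ref_start}\t{b.ref_end}\t{b.qry_name}\t"
                     f"{b.qry_start}\t{b.qry_end}\t{b.strand}\t{b.identity:.6f}\t"
                     f"{b.substitutions}\t{b.small_indel_events}\t{large}\n")


__all__ = [
    "AlignerConfig", "Anchor", "AlignmentBlock", "DiffSummary", "ReferenceIndex",
    "AlignmentResult", "find_anchors", "cluster_anchors", "extend_cluster",
    "filter_one_to_one", "summarize_diff", "unaligned_regions",
    "blocks_interval_set", "align_genomes", "write_blocks_tsv",
]
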