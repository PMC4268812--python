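"""Canonical k-mer counting, coverage profiling, and presence/absence calls.

Reads are counted as canonical k-mers (lexicographic minimum of each window
and its reverse complement; default k = 21) so counting is independent of
read strand.  Per-position coverage profiles along an assembly then act as a
repeat- and variant-robust proxy for copy number x sequencing depth: single
copy sequence sits near the read-depth mode, high-copy repeats orders of
magnitude above it, and absent sequence at zero.  Substitutions relative to
the reads appear as abrupt runs of exactly k zero-coverage windows.

k is capped at 31 so a 2-bit packed k-mer fits a 64-bit integer, and must be
odd so no k-mer equals its own reverse complement (canonical form unique).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seqio import encode, decode

DEFAULT_K = 21


class NoSignalError(ValueError):
    """Raised when a k-mer histogram has no mass above the error cutoff."""


@dataclass(frozen=True)
class KmerThresholds:
    """Operating points for repeat classification and presence calling.

    ``error_cutoff``: counts below this are treated as sequencing errors when
    locating the histogram mode.  ``repeat_threshold``: mean fold coverage
    strictly above this marks a region repetitive.  ``presence_self_min`` /
    ``presence_cross_max``: per-position coverage bounds used when calling a
    locus present or absent from a read sample.  ``present_frac`` /
    ``absent_frac``: fraction of (non-repetitive) positions at or above
    ``presence_self_min`` required for a present / allowed for an absent call.
    """

    error_cutoff: int = 10
    repeat_threshold: float = 100.0
    presence_self_min: float = 10.0
    presence_cross_max: float = 10.0
    present_frac: float = 0.8
    absent_frac: float = 0.2

    def __post_init__(self):
        if self.error_cutoff < 1:
            raise ValueError("error_cutoff must be >= 1")
        if self.repeat_threshold <= self.presence_self_min:
            raise ValueError("repeat_threshold must exceed presence_self_min")


# ---------------------------------------------------------------------------
# encoding helpers
# ---------------------------------------------------------------------------

def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical codes and validity mask for every k-window of ``codes``.

    Returns ``(canon, valid)`` of length ``len(codes) - k + 1``; windows
    containing non-ACGT are flagged invalid (their code is meaningless).
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    is_bad = (codes >= 4).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(is_bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    safe = np.where(codes >= 4, 0, codes).astype(np.uint64)
    comp = (3 - safe).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : j + n]
        rev |= comp[j : j + n] << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon, valid


def kmer_to_code(kmer: str) -> int:
    c = encode(kmer)
    if np.any(c >= 4):
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    code = 0
    for b in c:
        code = (code << 2) | int(b)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = np.empty(k, dtype=np.uint8)
    for i in range(k - 1, -1, -1):
        out[i] = code & 3
        code >>= 2
    return decode(out)


def canonical(kmer: str) -> str:
    from .seqio import revcomp
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


# ---------------------------------------------------------------------------
# KmerDB
# ---------------------------------------------------------------------------

class KmerDB:
    """Multiplicity table of canonical k-mers, keyed by 2-bit packed code.

    Stored as a sorted uint64 key array with parallel int64 counts, which
    keeps lookups a vectorized binary search.
    """

    def __init__(self, k: int, keys: np.ndarray, counts: np.ndarray):
        _check_k(k)
        self.k = k
        self.keys = np.asarray(keys, dtype=np.uint64)
        self.counts = np.asarray(counts, dtype=np.int64)
        if len(self.keys) != len(self.counts):
            raise ValueError("keys and counts length mismatch")
        if np.any(self.counts < 1):
            raise ValueError("all counts must be >= 1")

    def __len__(self) -> int:
        return len(self.keys)

    def total_mass(self) -> int:
        """Total counted windows (sum of all counts)."""
        return int(self.counts.sum())

    def get(self, kmer: str) -> int:
        code = kmer_to_code(canonical(kmer))
        i = np.searchsorted(self.keys, np.uint64(code))
        if i < len(self.keys) and self.keys[i] == code:
            return int(self.counts[i])
        return 0

    def lookup_codes(self, codes: np.ndarray) -> np.ndarray:
        """Counts for an array of canonical codes (0 where absent)."""
        idx = np.searchsorted(self.keys, codes)
        idx = np.minimum(idx, max(len(self.keys) - 1, 0))
        out = np.zeros(len(codes), dtype=np.int64)
        if len(self.keys):
            hit = self.keys[idx] == codes
            out[hit] = self.counts[idx[hit]]
        return out

    def histogram(self) -> dict[int, int]:
        mult, freq = np.unique(self.counts, return_counts=True)
        return {int(m): int(f) for m, f in zip(mult, freq)}

    # -- persistence: sorted TSV dump (k-mer string, count) ------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for key, cnt in zip(self.keys, self.counts):
                fh.write(f"{code_to_kmer(int(key), self.k)}\t{cnt}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerDB":
        keys, counts = [], []
        k = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if line.startswith("#k="):
                        k = int(line[3:].strip())
                    continue
                kmer, cnt = line.split("\t")
                if k is None:
                    k = len(kmer)
                keys.append(kmer_to_code(kmer))
                counts.append(int(cnt))
        if k is None:
            raise ValueError(f"empty k-mer dump {path}")
        order = np.argsort(np.array(keys, dtype=np.uint64))
        return cls(k,
                   np.array(keys, dtype=np.uint64)[order],
                   np.array(counts, dtype=np.int64)[order])


def _check_k(k: int) -> None:
    if not (1 <= k <= 31):
        raise ValueError("k must be in [1, 31] (2-bit packed 64-bit codes)")
    if k % 2 == 0:
        raise ValueError("k must be odd so canonical form is unique")


def count_kmers(reads: Iterable[str], k: int = DEFAULT_K,
                chunk_bases: int = 8_000_000) -> KmerDB:
    """Count canonical k-mers over every read window, skipping non-ACGT windows.

    Reads are concatenated in chunks with ``N`` separators so windows never
    span two reads; each chunk is counted with a sort-based unique pass and
    partial tables are merged at the end.  An empty read set yields an empty
    table.
    """
    _check_k(k)
    part_keys: list[np.ndarray] = []
    part_counts: list[np.ndarray] = []
    buf: list[str] = []
    size = 0

    def flush():
        nonlocal buf, size
        if not buf:
            return
        codes = encode("N".join(buf))
        canon, valid = _window_codes(codes, k)
        canon = canon[valid]
        if len(canon):
            keys, counts = np.unique(canon, return_counts=True)
            part_keys.append(keys)
            part_counts.append(counts.astype(np.int64))
        buf, size = [], 0

    for read in reads:
        buf.append(read)
        size += len(read)
        if size >= chunk_bases:
            flush()
    flush()

    if not part_keys:
        return KmerDB(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    while len(part_keys) > 1:
        merged_k, merged_c = [], []
        for i in range(0, len(part_keys), 2):
            if i + 1 == len(part_keys):
                merged_k.append(part_keys[i])
                merged_c.append(part_counts[i])
                continue
            keys = np.concatenate([part_keys[i], part_keys[i + 1]])
            counts = np.concatenate([part_counts[i], part_counts[i + 1]])
            order = np.argsort(keys, kind="stable")
            keys, counts = keys[order], counts[order]
            new = np.empty(len(keys), dtype=bool)
            new[0] = True
            new[1:] = keys[1:] != keys[:-1]
            merged_k.append(keys[new])
            merged_c.append(np.add.reduceat(counts, np.flatnonzero(new)))
        part_keys, part_counts = merged_k, merged_c
    return KmerDB(k, part_keys[0], part_counts[0])


def count_kmers_from_files(paths: Sequence[str | Path], k: int = DEFAULT_K,
                           sample_reads: int | None = None,
                           seed: int = 0) -> KmerDB:
    """Count k-mers from FASTA/FASTQ files, optionally down-sampling reads.

    ``sample_reads`` keeps a seeded uniform subsample of that many reads
    (reservoir sampling over the stream).
    """
    from .seqio import iter_reads

    def stream() -> Iterator[str]:
        for p in paths:
            yield from iter_reads(p)

    if sample_reads is None:
        return count_kmers(stream(), k=k)
    rng = np.random.default_rng(seed)
    reservoir: list[str] = []
    for i, read in enumerate(stream()):
        if i < sample_reads:
            reservoir.append(read)
        else:
            j = int(rng.integers(0, i + 1))
            if j < sample_reads:
                reservoir[j] = read
    return count_kmers(reservoir, k=k)


# ---------------------------------------------------------------------------
# histogram / mode
# ---------------------------------------------------------------------------

def histogram(db: KmerDB) -> dict[int, int]:
    """Multiplicity -> number of distinct canonical k-mers with that count."""
    return db.histogram()


def estimate_mode(hist: dict[int, int], error_cutoff: int = 10) -> int:
    """Mode of the k-mer frequency distribution above the error cutoff.

    Returns the multiplicity with the largest number of distinct k-mers among
    multiplicities >= ``error_cutoff`` (ties break toward the smaller
    multiplicity).  This is the single-copy fold-coverage estimate of the
    read sample.
    """
    best_m, best_f = None, -1
    for m in sorted(hist):
        if m < error_cutoff:
            continue
        if hist[m] > best_f:
            best_m, best_f = m, hist[m]
    if best_m is None:
        raise NoSignalError(
            f"no k-mer multiplicity at or above error cutoff {error_cutoff}")
    return best_m


def expected_kmer_coverage(depth: float, read_length: int, k: int,
                           error_rate: float = 0.0) -> float:
    """Analytic expected k-mer coverage of single-copy sequence.

    depth x (1 - (k-1)/read_length) x (1 - error_rate)^k: each read of length
    R contributes R-k+1 windows, and an error anywhere in a window sends it
    off the true k-mer.
    """
    return depth * (1 - (k - 1) / read_length) * (1 - error_rate) ** k


# ---------------------------------------------------------------------------
# coverage profiles
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-position k-mer count along one sequence.

    ``values[i]`` is the count of the canonical k-mer starting at position
    ``i``; length is ``len(seq) - k + 1`` (empty when the sequence is shorter
    than k).  Windows containing N carry value 0.  The value is attributed to
    the window's start coordinate, so the final k-1 positions of the sequence
    carry no value.
    """

    name: str
    k: int
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def to_bedgraph(self, fh, merge_runs: bool = True) -> None:
        """Write as BedGraph (0-based half-open), coalescing equal-value runs."""
        v = self.values
        if len(v) == 0:
            return
        if merge_runs:
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
        else:
            starts = np.arange(len(v))
            ends = starts + 1
        for s, e in zip(starts, ends):
            fh.write(f"{self.name}\t{s}\t{e}\t{v[s]}\n")


def coverage_profile(name: str, seq: str, db: KmerDB) -> CoverageProfile:
    """k-mer coverage of ``seq`` under ``db``: value at i = count of window [i, i+k)."""
    codes = encode(seq)
    canon, valid = _window_codes(codes, db.k)
    values = np.zeros(len(canon), dtype=np.int64)
    if valid.any():
        values[valid] = db.lookup_codes(canon[valid])
    return CoverageProfile(name=name, k=db.k, values=values)


def profile_sequence_set(seqs, db: KmerDB) -> dict[str, CoverageProfile]:
    return {name: coverage_profile(name, seq, db) for name, seq in seqs.items()}


def mean_region_coverage(profile: CoverageProfile, interval: tuple[int, int]) -> float:
    """Arithmetic mean of profile values with start positions in [start, end).

    The interval is clipped to the profile span (the last k-1 positions of the
    sequence carry no value); an interval empty after clipping is rejected.
    Zeros count toward the mean.
    """
    start, end = interval
    if start >= end:
        raise ValueError(f"empty interval [{start}, {end})")
    start = max(start, 0)
    end = min(end, len(profile.values))
    if start >= end:
        raise ValueError(
            f"interval [{start}, {end}) has no profile positions (span {len(profile.values)})")
    return float(profile.values[start:end].mean())


def classify_repetitive(mean_cov: float, thresholds: KmerThresholds = KmerThresholds()) -> str:
    """'repetitive' iff mean coverage strictly exceeds the repeat threshold."""
    if mean_cov < 0:
        raise ValueError("mean coverage must be >= 0")
    return "repetitive" if mean_cov > thresholds.repeat_threshold else "unique"


@dataclass
class PresenceCall:
    call: str                 # present / absent / ambiguous
    covered_fraction: float   # fraction of unmasked positions >= presence_self_min
    masked_fraction: float    # fraction of positions masked as repetitive
    mode_estimate: float | None = None


def call_presence(profile: CoverageProfile | np.ndarray,
                  mode_estimate: float | None = None,
                  thresholds: KmerThresholds = KmerThresholds()) -> PresenceCall:
    """Call a locus present/absent from the k-mer coverage of one read sample.

    Positions with coverage strictly above the repeat threshold are masked as
    repetitive (isolated high-copy k-mers inside an otherwise absent locus,
    e.g. dispersed repeats, do not rescue a presence call).  Among the
    remaining positions, the locus is 'present' when the fraction with
    coverage >= ``presence_self_min`` reaches ``present_frac``, 'absent' when
    it is at most ``absent_frac``, else 'ambiguous'.  ``mode_estimate`` is
    recorded for reference alongside the call.
    """
    values = profile.values if isinstance(profile, CoverageProfile) else np.asarray(profile)
    if len(values) == 0:
        raise ValueError("locus shorter than k: no profile positions")
    repeat_mask = values > thresholds.repeat_threshold
    unmasked = values[~repeat_mask]
    masked_frac = float(repeat_mask.mean())
    if len(unmasked) == 0:
        return PresenceCall("ambiguous", 0.0, masked_frac, mode_estimate)
    frac = float((unmasked >= thresholds.presence_self_min).mean())
    if frac >= thresholds.present_frac:
        call = "present"
    elif frac <= thresholds.absent_frac:
        call = "absent"
    else:
        call = "ambiguous"
    return PresenceCall(call, frac, masked_frac, mode_estimate)


__all__ = [
    "DEFAULT_K", "KmerDB", "KmerThresholds", "CoverageProfile", "PresenceCall",
    "NoSignalError", "count_kmers", "count_kmers_from_files", "histogram",
    "estimate_mode", "expected_kmer_coverage", "coverage_profile",
    "profile_sequence_set", "mean_region_coverage", "classify_repetitive",
    "call_presence", "canonical", "kmer_to_code", "code_to_kmer",
]
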