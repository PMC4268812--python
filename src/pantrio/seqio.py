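"""Sequence containers and FASTA/FASTQ input/output.

Assemblies are held as a :class:`SequenceSet`, an ordered mapping of scaffold
name to an upper-case ``A/C/G/T/N`` string.  Numeric 2-bit encodings used by
the k-mer and alignment machinery live here so every module agrees on the
same ``A=0, C=1, G=2, T=3, N=4`` convention.
"""

from __future__ import annotations

import gzip
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lower case

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes: A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


class SequenceSet(OrderedDict):
    """Named scaffolds of one assembly: ordered ``{name: sequence}``.

    Sequences are plain upper-case strings over ``ACGTN``.
    """

    @property
    def total_span(self) -> int:
        return sum(len(s) for s in self.values())

    @property
    def total_bases(self) -> int:
        """Non-N bases."""
        return sum(len(s) - s.count("N") for s in self.values())

    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceSet":
        out = cls()
        with _maybe_gzip(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                out[rec.id] = str(rec.seq).upper()
        return out

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield read sequences (upper case) from FASTA or FASTQ, gzip allowed."""
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with _maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield str(rec.seq).upper()


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: int = 35) -> None:
    """Write ``(name, sequence)`` pairs as FASTQ with a constant Phred+33 quality."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qchar * len(seq)}\n")


def write_fasta_records(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random ACGT string."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


__all__ = [
    "SequenceSet",
    "revcomp",
    "encode",
    "decode",
    "iter_reads",
    "write_fastq",
    "write_fasta_records",
    "random_dna",
]
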