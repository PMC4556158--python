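"""Canonical tetranucleotide frequency (TNF) signatures of assembled contigs.

Every 4-mer is collapsed onto the lexicographically smaller of itself and its
reverse complement, which partitions the 256 tetramers into 136 canonical
classes (16 palindromes plus 120 collapsed pairs).  Frequencies over these
classes are strand-invariant, which is required because assembled contigs have
arbitrary orientation.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "N_TNF_CLASSES",
    "ContigRecord",
    "TNFVector",
    "FastaFormatError",
    "read_fasta",
    "reverse_complement",
    "tnf_vector",
    "tnf_matrix",
    "tnf_distance",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _build_tables() -> tuple[np.ndarray, np.ndarray, int]:
    """ASCII->base-code table and 256-entry kmer-code -> canonical class table."""
    ascii_code = np.full(256, 4, dtype=np.uint8)  # 4 marks "not ACGT"
    for i, ch in enumerate("ACGT"):
        ascii_code[ord(ch)] = i
        ascii_code[ord(ch.lower())] = i

    codes = np.arange(256)
    digits = [(codes >> sh) & 3 for sh in (6, 4, 2, 0)]
    # reverse complement: complement each base (3 - b) and reverse digit order
    rc = ((3 - digits[3]) << 6) | ((3 - digits[2]) << 4) | ((3 - digits[1]) << 2) | (3 - digits[0])
    canonical = np.minimum(codes, rc)
    classes, class_of = np.unique(canonical, return_inverse=True)
    return ascii_code, class_of.astype(np.int64), len(classes)


_ASCII_CODE, _CANON_CLASS, N_TNF_CLASSES = _build_tables()
assert N_TNF_CLASSES == 136


@dataclass(frozen=True)
class ContigRecord:
    """One assembled sequence: unique id, upper-case sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TNFVector:
    """Normalized canonical 4-mer frequencies and the number of counted windows.

    ``values`` sums to 1 when ``valid_kmers >= 1``; a vector with
    ``valid_kmers == 0`` is unusable and must not enter distance computations.
    """

    values: np.ndarray
    valid_kmers: int


class FastaFormatError(ValueError):
    """Raised for empty or malformed FASTA input."""


_ALLOWED = set("ACGTN")


def _clean_sequence(raw: str) -> str:
    seq = raw.upper()
    if set(seq) <= _ALLOWED:
        return seq
    return "".join(ch if ch in _ALLOWED else "N" for ch in seq)


def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read contigs from a plain or gzip FASTA file.

    Record ids are the header token up to the first whitespace; sequences are
    upper-cased with any character outside {A,C,G,T} mapped to N.  Raises
    ``FileNotFoundError`` for a missing path and :class:`FastaFormatError`
    for an empty file or content before the first header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[ContigRecord] = []
    header: str | None = None
    chunks: list[str] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(ContigRecord(header, _clean_sequence("".join(chunks))))
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before any FASTA header at line {lineno}"
                    )
                chunks.append(line)
    if header is not None:
        records.append(ContigRecord(header, _clean_sequence("".join(chunks))))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
    return records


def tnf_vector(seq: str) -> TNFVector:
    """Canonical tetranucleotide frequency vector of one sequence.

    Slides a 4-base window with step 1; windows containing N (or any
    non-ACGT character) are skipped.  Returns an all-zero vector with
    ``valid_kmers == 0`` when no window is countable.
    """
    codes = _ASCII_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size < 4:
        return TNFVector(np.zeros(N_TNF_CLASSES), 0)
    c0 = codes[:-3].astype(np.int64)
    c1 = codes[1:-2].astype(np.int64)
    c2 = codes[2:-1].astype(np.int64)
    c3 = codes[3:].astype(np.int64)
    ok = (c0 < 4) & (c1 < 4) & (c2 < 4) & (c3 < 4)
    n_valid = int(ok.sum())
    if n_valid == 0:
        return TNFVector(np.zeros(N_TNF_CLASSES), 0)
    kmer = (c0[ok] << 6) | (c1[ok] << 4) | (c2[ok] << 2) | c3[ok]
    counts = np.bincount(_CANON_CLASS[kmer], minlength=N_TNF_CLASSES)
    return TNFVector(counts / n_valid, n_valid)


def tnf_matrix(sequences: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Stack :func:`tnf_vector` over sequences -> (n, 136) matrix, valid counts."""
    mat = np.zeros((len(sequences), N_TNF_CLASSES))
    counts = np.zeros(len(sequences), dtype=np.int64)
    for i, seq in enumerate(sequences):
        v = tnf_vector(seq)
        mat[i] = v.values
        counts[i] = v.valid_kmers
    return mat, counts


def tnf_distance(a: TNFVector, b: TNFVector) -> float:
    """Euclidean distance between two usable TNF vectors."""
    if a.valid_kmers < 1 or b.valid_kmers < 1:
        raise ValueError("cannot compute TNF distance for a vector with no valid 4-mers")
    return float(np.linalg.norm(a.values - b.values))
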