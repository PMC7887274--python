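"""Ungapped read mapping, duplicate removal, and pileup construction.

The mapper is a deliberate desk-scale design: exact 16-mer seeding at every
read offset against a hashed reference, candidate placements scored by
Hamming distance on both strands, ties broken toward the lowest reference
start and then the plus strand.  The simulator emits no indels and the
variant caller skips them, so gapped alignment is intentionally absent;
real-data users ingest an external SAM instead (see :mod:`sedapop.io`).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .io import FastqRead
from .simulate import revcomp

__all__ = [
    "AlignedRead", "PileupColumn", "map_reads",
    "remove_exact_duplicates", "remove_coordinate_duplicates",
    "build_pileup", "mean_coverage",
]

_SEED_K = 16
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclasses.dataclass(frozen=True)
class AlignedRead:
    """A mapped fragment; ``sequence`` is stored in reference orientation."""

    name: str
    sequence: str
    qual: np.ndarray           # Phred values, same length as sequence
    ref_start: int
    strand: str                # "+" or "-"
    sample_id: str = ""
    n_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.sequence):
            raise ValueError("quality length != sequence length")

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.sequence)

    def read_oriented(self) -> tuple[str, np.ndarray]:
        """Sequence and qualities in sequencing (read) orientation."""
        if self.strand == "-":
            return revcomp(self.sequence), self.qual[::-1]
        return self.sequence, self.qual


@dataclasses.dataclass
class PileupColumn:
    ref_pos: int
    ref_base: str
    counts: dict[str, int]           # A/C/G/T
    mean_qual: dict[str, float]      # per observed base
    depth: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _ReferenceIndex:
    """Hashed exact k-mer index over a reference sequence."""

    def __init__(self, reference: str, k: int = _SEED_K):
        self.reference = reference.upper()
        self.k = k
        self.encoded = _encode(self.reference)
        self.index: dict[bytes, list[int]] = defaultdict(list)
        enc = self.reference.encode("ascii")
        for i in range(len(enc) - k + 1):
            self.index[enc[i:i + k]].append(i)

    def candidates(self, read: str) -> set[int]:
        enc = read.encode("ascii")
        k = self.k
        out: set[int] = set()
        for off in range(len(enc) - k + 1):
            for pos in self.index.get(enc[off:off + k], ()):
                start = pos - off
                if 0 <= start <= len(self.reference) - len(read):
                    out.add(start)
        return out


def _hamming(ref_enc: np.ndarray, start: int, read_enc: np.ndarray) -> int:
    return int(np.count_nonzero(ref_enc[start:start + len(read_enc)] != read_enc))


def map_reads(
    reads: Iterable[FastqRead],
    reference: str,
    max_mismatch_rate: float = 0.1,
    seed: int = 0,
    sample_id: str = "",
    index: "_ReferenceIndex | None" = None,
) -> list[AlignedRead]:
    """Place each read at its best ungapped position on ``reference``.

    Both orientations are tried; the placement minimising Hamming mismatches
    among the seeded candidates wins, ties resolved by lowest ``ref_start``
    then plus strand.  Reads whose best mismatch rate exceeds
    ``max_mismatch_rate`` are dropped.
    """
    if not reference:
        raise ValueError("reference is empty")
    idx = index if index is not None else _ReferenceIndex(reference)
    ref_enc = idx.encoded
    out: list[AlignedRead] = []
    for read in reads:
        seq_fwd = read.sequence.upper()
        if len(seq_fwd) < idx.k or len(seq_fwd) > len(reference):
            continue
        seq_rev = revcomp(seq_fwd)
        best: tuple[int, int, int] | None = None  # (mismatches, start, strand_rank)
        best_seq = ""
        for strand_rank, seq in ((0, seq_fwd), (1, seq_rev)):
            enc = _encode(seq)
            for start in idx.candidates(seq):
                mm = _hamming(ref_enc, start, enc)
                key = (mm, start, strand_rank)
                if best is None or key < best:
                    best = key
                    best_seq = seq
        if best is None:
            continue
        mm, start, strand_rank = best
        if mm > max_mismatch_rate * len(seq_fwd):
            continue
        qual = np.frombuffer(read.quality.encode("ascii"), dtype=np.uint8) - 33
        if strand_rank == 1:
            qual = qual[::-1]
        out.append(AlignedRead(
            name=read.name, sequence=best_seq, qual=qual,
            ref_start=start, strand="-" if strand_rank else "+",
            sample_id=sample_id, n_mismatches=mm,
        ))
    return out


def remove_exact_duplicates(
    reads: Sequence[AlignedRead], replicate_seed: int = 0,
) -> list[AlignedRead]:
    """Among reads with identical (orientation-normalised) sequence, keep one
    copy chosen uniformly at random; output preserves input order."""
    rng = np.random.default_rng(replicate_seed)
    groups: dict[str, list[int]] = defaultdict(list)
    for i, r in enumerate(reads):
        groups[r.read_oriented()[0]].append(i)
    keep: set[int] = set()
    for key in sorted(groups):   # sorted for seed-stable iteration
        members = groups[key]
        keep.add(members[int(rng.integers(0, len(members)))])
    return [r for i, r in enumerate(reads) if i in keep]


def remove_coordinate_duplicates(reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Among reads sharing (ref_start, strand, length), keep the copy with the
    highest mean base quality (first in input order on ties).  Deterministic."""
    best: dict[tuple[int, str, int], tuple[float, int]] = {}
    for i, r in enumerate(reads):
        key = (r.ref_start, r.strand, len(r.sequence))
        mq = float(np.mean(r.qual)) if len(r.qual) else 0.0
        if key not in best or mq > best[key][0]:
            best[key] = (mq, i)
    keep = {i for _, i in best.values()}
    return [r for i, r in enumerate(reads) if i in keep]


_BASES = "ACGT"


def build_pileup(reads: Sequence[AlignedRead], reference: str) -> list[PileupColumn]:
    """Tally per-position base counts and mean qualities from mapped reads."""
    ref = reference.upper()
    n = len(ref)
    counts = np.zeros((4, n), dtype=np.int64)
    qual_sums = np.zeros((4, n), dtype=np.float64)
    for r in reads:
        if r.ref_end > n:
            raise ValueError(f"read {r.name} overruns the reference end")
        enc = _encode(r.sequence)
        pos = np.arange(r.ref_start, r.ref_end)
        for bi, base in enumerate(_BASES):
            mask = enc == ord(base)
            if mask.any():
                np.add.at(counts[bi], pos[mask], 1)
                np.add.at(qual_sums[bi], pos[mask], r.qual[mask])
    depth = counts.sum(axis=0)
    columns: list[PileupColumn] = []
    for p in range(n):
        c = {b: int(counts[bi, p]) for bi, b in enumerate(_BASES)}
        mq = {b: (qual_sums[bi, p] / counts[bi, p])
              for bi, b in enumerate(_BASES) if counts[bi, p] > 0}
        columns.append(PileupColumn(p, ref[p], c, mq, int(depth[p])))
    return columns


def mean_coverage(pileup: Sequence[PileupColumn]) -> float:
    """Mean depth over all reference positions, zeros included."""
    if not pileup:
        return 0.0
    return sum(col.depth for col in pileup) / len(pileup)
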