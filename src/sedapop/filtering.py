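"""Post-merge read filtering: minimum length and DUST low-complexity removal.

The DUST variant used here is the windowed Morgulis-style triplet score:
within each 64-bp sliding window count every overlapping 3-mer, score the
window as sum(c*(c-1)/2) / (w-1) over the w triplet slots, and report the
maximum over windows.  Triplets containing N are skipped.  A homopolymer of
35 bp scores 33*32/2 / 32 = 16.5; a sequence with all-distinct 3-mers scores 0.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable

from .config import PipelineConfig
from .io import FastqRead

__all__ = ["FilterReport", "dust_score", "filter_reads"]

_DUST_WINDOW = 64


@dataclasses.dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_length_removed: int
    n_dust_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        assert self.n_input == (self.n_length_removed + self.n_dust_removed
                                + self.n_retained)

    def to_tsv(self) -> str:
        return "".join(
            f"{k}\t{getattr(self, k)}\n"
            for k in ("n_input", "n_length_removed", "n_dust_removed", "n_retained"))


def dust_score(seq: str) -> float:
    """Maximum windowed triplet-repetition score of ``seq``.

    Raises ``ValueError`` for sequences shorter than 3.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 3:
        raise ValueError(f"sequence shorter than 3 bp ({n})")
    triplets = [seq[i:i + 3] for i in range(n - 2)]
    valid = [t if "N" not in t else None for t in triplets]
    best = 0.0
    n_windows = max(1, n - _DUST_WINDOW + 1)
    for start in range(n_windows):
        window = valid[start:start + _DUST_WINDOW - 2]
        counts = Counter(t for t in window if t is not None)
        w = sum(counts.values())
        if w < 2:
            continue
        score = sum(c * (c - 1) // 2 for c in counts.values()) / (w - 1)
        best = max(best, score)
    return best


def filter_reads(
    reads: Iterable[FastqRead], cfg: PipelineConfig | None = None,
) -> tuple[list[FastqRead], FilterReport]:
    """Retain reads of at least ``min_read_length`` bp whose DUST score does
    not exceed ``dust_threshold`` (a read scoring exactly the threshold is
    kept).  Reads that are more than half N are removed as degenerate and
    counted with the low-complexity removals.  Input order is preserved.
    """
    cfg = cfg or PipelineConfig()
    retained: list[FastqRead] = []
    n_len = n_dust = n_in = 0
    for idx, read in enumerate(reads):
        n_in += 1
        seq = read.sequence
        if len(seq) != len(read.quality):
            raise ValueError(f"record {idx} ({read.name}): bad FASTQ record")
        if len(seq) < cfg.min_read_length:
            n_len += 1
            continue
        if seq.upper().count("N") * 2 > len(seq):
            n_dust += 1
            continue
        if dust_score(seq) > cfg.dust_threshold:
            n_dust += 1
            continue
        retained.append(read)
    return retained, FilterReport(n_in, n_len, n_dust, len(retained))
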