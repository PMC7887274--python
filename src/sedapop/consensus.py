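"""Iterative reference-guided composite consensus reconstruction.

A seed organellar genome is used to recruit reads; the majority base at each
covered position replaces the seed, and the loop repeats with the updated
consensus as mapping reference until the sequence stops changing (or a
safety iteration cap is hit).  Two consensus modes are supported: uncovered
sites take the seed base (``reference_fill``) or N (``no_fill``).  Coverage
gaps and low-coverage regions are reported, not filled — users may splice in
externally assembled patch sequences via :func:`splice_patches`.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .align import (PileupColumn, build_pileup, map_reads, mean_coverage,
                    remove_coordinate_duplicates)
from .config import PipelineConfig
from .io import FastqRead

__all__ = [
    "ConsensusResult", "majority_consensus", "iterate_consensus",
    "coverage_gaps", "splice_patches",
]

_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class ConsensusResult:
    sequence: str
    n_iterations: int
    edits_per_iteration: tuple[int, ...]
    gap_intervals: tuple[tuple[int, int], ...]     # depth == 0, half-open
    low_intervals: tuple[tuple[int, int], ...]     # 0 < depth < threshold
    mean_coverage: float
    converged: bool


def majority_consensus(
    pileup: Sequence[PileupColumn],
    seed_ref: str,
    mode: str = "reference_fill",
) -> str:
    """Majority-rule consensus over a pileup.

    Covered positions take the highest-count base; on a tie the seed base
    wins if it is among the tied leaders, otherwise the lexicographically
    smallest.  Uncovered positions take the seed base (``reference_fill``)
    or ``N`` (``no_fill``).
    """
    if mode not in ("reference_fill", "no_fill"):
        raise ValueError(f"unknown consensus mode: {mode}")
    if len(pileup) != len(seed_ref):
        raise ValueError("pileup length != seed reference length")
    out = []
    for col, seed_base in zip(pileup, seed_ref.upper()):
        if col.depth == 0:
            out.append(seed_base if mode == "reference_fill" else "N")
            continue
        top = max(col.counts.values())
        leaders = [b for b in _BASES if col.counts[b] == top]
        out.append(seed_base if seed_base in leaders else leaders[0])
    return "".join(out)


def iterate_consensus(
    reads: Iterable[FastqRead],
    seed_ref: str,
    cfg: PipelineConfig | None = None,
    max_iter: int = 10,
    low_cov_threshold: int = 5,
) -> ConsensusResult:
    """Map → deduplicate → pileup → majority consensus, repeated with the
    previous consensus as mapping reference until a fixed point.

    Returns a flagged (``converged=False``) result if ``max_iter`` passes
    without two successive consensus sequences agreeing, or if no reads map.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    cfg = cfg or PipelineConfig()
    reads = list(reads)
    current = seed_ref.upper()
    edits: list[int] = []
    converged = False
    pileup: Sequence[PileupColumn] = []
    for _ in range(max_iter):
        mapped = map_reads(reads, current, cfg.max_mismatch_rate)
        mapped = remove_coordinate_duplicates(mapped)
        pileup = build_pileup(mapped, current)
        nxt = majority_consensus(pileup, current, mode="reference_fill")
        n_edits = sum(a != b for a, b in zip(nxt, current))
        edits.append(n_edits)
        current = nxt
        if n_edits == 0:
            converged = True
            break
    gaps, lows = coverage_gaps(pileup, low_cov_threshold)
    return ConsensusResult(
        sequence=current,
        n_iterations=len(edits),
        edits_per_iteration=tuple(edits),
        gap_intervals=tuple(gaps),
        low_intervals=tuple(lows),
        mean_coverage=mean_coverage(pileup),
        converged=converged,
    )


def coverage_gaps(
    pileup: Sequence[PileupColumn], low_threshold: int,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Maximal half-open intervals of zero depth (gaps) and of depth strictly
    between zero and ``low_threshold`` (low coverage), sorted and disjoint."""

    def runs(predicate) -> list[tuple[int, int]]:
        out = []
        start = None
        for i, col in enumerate(pileup):
            if predicate(col.depth):
                if start is None:
                    start = i
            elif start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(pileup)))
        return out

    return runs(lambda d: d == 0), runs(lambda d: 0 < d < low_threshold)


def splice_patches(
    consensus: str,
    patches: Sequence[str],
    anchor_length: int = 20,
) -> str:
    """Incorporate externally assembled patch sequences by exact flank match.

    Each patch must carry ``anchor_length`` bp at both ends that occur
    exactly once in ``consensus``; the region between the anchors is replaced
    by the patch interior.  Raises ``ValueError`` for ambiguous or missing
    anchors.
    """
    out = consensus.upper()
    for patch in patches:
        patch = patch.upper()
        if len(patch) < 2 * anchor_length:
            raise ValueError("patch shorter than two anchors")
        left, right = patch[:anchor_length], patch[-anchor_length:]
        for anchor in (left, right):
            if out.count(anchor) != 1:
                raise ValueError(f"anchor {anchor!r} not unique in consensus")
        i = out.index(left)
        j = out.index(right) + anchor_length
        if j <= i:
            raise ValueError("patch anchors out of order on the consensus")
        out = out[:i] + patch + out[j:]
    return out
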