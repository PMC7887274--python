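"""Minimum haplotype counting from read-linked transversion variants.

Where two or more transversion-only variant sites fall within a short window
(35 bp by default — within reach of a single ancient-DNA fragment), every
read that fully covers the window phases the sites jointly.  The number of
distinct allele combinations that survive the support filters is a direct
lower bound on the number of haplotypes in the sample: a window showing k
phased combinations demonstrates at least k haplotypes, even when no single
site can distinguish them.

Windows are defined on sites pooled across samples; phasing and counting are
per sample.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np

from .align import AlignedRead
from .variants import VariantSite

__all__ = [
    "LinkedWindow", "HaplotypeSummary",
    "find_linked_windows", "phase_window", "filter_and_count",
    "summarize_haplotypes", "score_sample",
]


@dataclasses.dataclass(frozen=True)
class LinkedWindow:
    positions: tuple[int, ...]             # sorted, 0-based
    combos: dict[str, int]                 # allele string -> spanning reads
    n_spanning: int
    passing: tuple[str, ...] = ()
    count: int = 0

    @property
    def span(self) -> int:
        return self.positions[-1] - self.positions[0] + 1


@dataclasses.dataclass(frozen=True)
class HaplotypeSummary:
    per_sample_windows: dict[str, tuple[LinkedWindow, ...]]
    per_sample_mean: dict[str, float]
    estimate: int           # max passing-combo count over windows and samples


def find_linked_windows(
    sites: Sequence[VariantSite], window_span: int = 35,
) -> list[tuple[int, ...]]:
    """Greedy left-to-right chaining of sorted transversion sites.

    A site joins the open cluster while the total span (last − first + 1)
    stays within ``window_span``; clusters with at least two sites are
    returned.  Each site belongs to at most one cluster.
    """
    positions = sorted(s.pos for s in sites)
    if positions != [s.pos for s in sites]:
        sites = sorted(sites, key=lambda s: s.pos)
    clusters: list[tuple[int, ...]] = []
    current: list[int] = []
    for pos in positions:
        if current and pos - current[0] + 1 <= window_span:
            current.append(pos)
        else:
            if len(current) >= 2:
                clusters.append(tuple(current))
            current = [pos]
    if len(current) >= 2:
        clusters.append(tuple(current))
    return clusters


def phase_window(
    cluster: Sequence[int], reads: Sequence[AlignedRead],
) -> LinkedWindow:
    """Tally allele combinations among reads spanning every cluster position.

    A read contributes only if its aligned span covers all positions; its
    combination is the concatenation of its (uppercase) bases at those
    positions.  Combinations containing N are excluded.
    """
    positions = tuple(sorted(cluster))
    first, last = positions[0], positions[-1]
    combos: dict[str, int] = {}
    for r in reads:
        if r.ref_start > first or r.ref_end <= last:
            continue
        combo = "".join(r.sequence[p - r.ref_start] for p in positions).upper()
        if "N" in combo:
            continue
        combos[combo] = combos.get(combo, 0) + 1
    return LinkedWindow(positions, combos, sum(combos.values()))


def filter_and_count(
    win: LinkedWindow, min_reads: int = 3, min_fraction: float = 0.15,
) -> LinkedWindow:
    """Score a window: combinations with at least ``min_reads`` supporting
    reads AND at least ``min_fraction`` of spanning reads pass (both bounds
    inclusive — removal is strict ``<``); ``count`` is the number passing."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    if win.n_spanning == 0:
        return dataclasses.replace(win, passing=(), count=0)
    passing = tuple(sorted(
        c for c, n in win.combos.items()
        if n >= min_reads and n / win.n_spanning >= min_fraction))
    return dataclasses.replace(win, passing=passing, count=len(passing))


def score_sample(
    clusters: Sequence[Sequence[int]],
    reads: Sequence[AlignedRead],
    min_reads: int = 3,
    min_fraction: float = 0.15,
) -> list[LinkedWindow]:
    """Phase and score every cluster against one sample's read set."""
    return [filter_and_count(phase_window(c, reads), min_reads, min_fraction)
            for c in clusters]


def summarize_haplotypes(
    windows_per_sample: Mapping[str, Sequence[LinkedWindow]],
) -> HaplotypeSummary:
    """Per-sample mean window count (windows with spanning reads only) and
    the overall minimum-haplotype estimate: the maximum passing-combination
    count over all windows and samples."""
    if not windows_per_sample:
        raise ValueError("no windows supplied")
    per_sample = {s: tuple(ws) for s, ws in windows_per_sample.items()}
    means: dict[str, float] = {}
    estimate = 0
    any_scorable = False
    for sample, wins in per_sample.items():
        scorable = [w for w in wins if w.n_spanning > 0]
        if scorable:
            any_scorable = True
            means[sample] = float(np.mean([w.count for w in scorable]))
            estimate = max(estimate, max(w.count for w in scorable))
        else:
            means[sample] = float("nan")
    if not any_scorable:
        warnings.warn("no window has spanning reads; empty haplotype summary")
    return HaplotypeSummary(per_sample, means, estimate)


def windows_to_tsv(windows_per_sample: Mapping[str, Sequence[LinkedWindow]]) -> str:
    """Window table: sample, 1-based comma-joined positions, spanning reads,
    combo:count list, passing count."""
    lines = ["sample\tpositions\tn_spanning\tcombos\tcount"]
    for sample, wins in windows_per_sample.items():
        for w in wins:
            pos = ",".join(str(p + 1) for p in w.positions)
            combos = ";".join(f"{c}:{n}" for c, n in sorted(w.combos.items()))
            lines.append(f"{sample}\t{pos}\t{w.n_spanning}\t{combos}\t{w.count}")
    return "\n".join(lines) + "\n"
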