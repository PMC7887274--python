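"""Transversion-only variant calling and haplogroup consensus splitting.

Variant sites are called from a pileup against the reconstructed composite
organellar genome.  Site quality is the Phred-scaled exact binomial tail
probability that the minor-allele count arose from base-calling error at the
quality-implied rate.  Analyses are restricted to transversion-only sites
(purine↔pyrimidine at every allele pair) so that cytosine-deamination
artefacts (C→T, G→A) cannot masquerade as biological variation.

High-frequency variants are defined as the alleles present in the composite
genome itself — membership is by presence in the composite, not by
frequency — and the high/low allele sets are rendered into the two
haplogroup consensus sequences.  Allele proportions are estimated with
replicated random de-duplication to expose sampling variance.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .align import (AlignedRead, PileupColumn, build_pileup, mean_coverage,
                    remove_coordinate_duplicates, remove_exact_duplicates)
from .config import PipelineConfig
from .damage import filter_damaged
from .simulate import DamageModel, is_transversion

__all__ = [
    "VariantSite", "ProportionReport", "ReplicateResult",
    "call_variants", "transversions_only", "restrict_transversions",
    "split_high_low",
    "apply_variant_consensus", "allele_proportions", "damage_restricted_recall",
    "half_mean_coverage",
]

_MIN_ALLELE_COUNT = 2   # noise floor: singleton observations never form an allele
_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class VariantSite:
    pos: int                                  # 0-based
    composite_base: str
    alleles: tuple[tuple[str, int, float], ...]   # (base, count, proportion)
    qual: float                               # Phred-scaled
    depth: int
    is_transversion: bool
    rare_removed: tuple[str, ...] = ()        # alleles dropped by the rare floor

    @property
    def allele_bases(self) -> tuple[str, ...]:
        return tuple(b for b, _, _ in self.alleles)


@dataclasses.dataclass(frozen=True)
class ReplicateResult:
    replicate: int
    sites: tuple[VariantSite, ...]
    per_site_alt: dict[int, float]     # pos -> summed alternative proportion
    mean_alt: float


@dataclasses.dataclass(frozen=True)
class ProportionReport:
    replicates: tuple[ReplicateResult, ...]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def mean_alt_per_replicate(self) -> list[float]:
        return [r.mean_alt for r in self.replicates]


def _phred_binom_tail(k_minor: int, depth: int, err: float) -> float:
    """Phred score of P(X >= k_minor | Binomial(depth, err))."""
    sf = float(stats.binom.sf(k_minor - 1, depth, err))
    if sf <= 0:
        return 999.0
    return min(999.0, -10.0 * math.log10(sf))


def call_variants(
    pileup: Sequence[PileupColumn],
    composite_ref: str,
    min_qual: float = 30.0,
    min_cov: int = 1,
) -> list[VariantSite]:
    """Report sites where at least two alleles rise above the noise floor.

    An allele needs at least two supporting reads.  Site quality tests the
    second-largest allele count against the column's quality-implied error
    rate with an exact binomial tail; sites below ``min_qual`` or with depth
    below ``min_cov`` are excluded.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    out: list[VariantSite] = []
    for col, comp_base in zip(pileup, composite_ref.upper()):
        if col.depth < min_cov:
            continue
        observed = [(b, col.counts[b]) for b in _BASES
                    if col.counts[b] >= _MIN_ALLELE_COUNT]
        if len(observed) < 2:
            continue
        observed.sort(key=lambda bc: (-bc[1], bc[0]))
        err = sum(col.counts[b] * 10.0 ** (-col.mean_qual[b] / 10.0)
                  for b in _BASES if col.counts[b] > 0) / col.depth
        err = max(err, 1e-10)
        qual = _phred_binom_tail(observed[1][1], col.depth, err)
        if qual < min_qual:
            continue
        total = sum(c for _, c in observed)
        alleles = tuple((b, c, c / total) for b, c in observed)
        bases = [b for b, _ in observed]
        tv = all(is_transversion(a, b)
                 for i, a in enumerate(bases) for b in bases[i + 1:])
        out.append(VariantSite(col.ref_pos, comp_base, alleles, qual,
                               col.depth, tv))
    return out


def transversions_only(sites: Sequence[VariantSite]) -> list[VariantSite]:
    """Keep sites where every allele pair is a transversion (idempotent)."""
    return [s for s in sites if s.is_transversion]


def split_high_low(
    sites: Sequence[VariantSite],
    composite_ref: str,
) -> tuple[dict[int, str], dict[int, str], list[int]]:
    """Partition each site's alleles into high (present in the composite) and
    low (everything else) haplogroup choices.

    Returns ``(high, low, flagged)`` where ``high`` and ``low`` map position
    to the chosen consensus base (the low choice is the highest-proportion
    non-composite allele), and ``flagged`` lists degenerate sites whose
    alleles never include the composite base (all alleles go low).
    """
    comp = composite_ref.upper()
    high: dict[int, str] = {}
    low: dict[int, str] = {}
    flagged: list[int] = []
    for s in sites:
        if s.composite_base != comp[s.pos]:
            raise ValueError(f"site {s.pos}: composite_base disagrees with reference")
        bases = s.allele_bases
        if s.composite_base in bases:
            high[s.pos] = s.composite_base
            others = [(b, p) for b, _, p in s.alleles if b != s.composite_base]
            if others:
                low[s.pos] = max(others, key=lambda bp: bp[1])[0]
        else:
            flagged.append(s.pos)
            low[s.pos] = max(s.alleles, key=lambda a: a[2])[0]
    return high, low, flagged


def apply_variant_consensus(
    composite_ref: str, choices: Mapping[int, str],
) -> str:
    """Substitute the chosen allele at each site; length is preserved."""
    seq = list(composite_ref.upper())
    seen: set[int] = set()
    for pos, base in choices.items():
        if pos in seen:
            raise ValueError(f"duplicate position {pos}")
        if not 0 <= pos < len(seq):
            raise ValueError(f"position {pos} out of bounds")
        seen.add(pos)
        seq[pos] = base.upper()
    return "".join(seq)


def _apply_rare_floor(site: VariantSite, floor: float) -> VariantSite:
    """Drop alleles below the rare-allele floor (strict ``<``), renormalise
    the surviving proportions, and recompute the transversion flag.

    Renormalising matches reporting site proportions over the reference and
    alternative alleles only: noise alleles (including minor deamination
    artefacts) leave both the allele list and the denominator."""
    removed = tuple(b for b, _, p in site.alleles if p < floor)
    if not removed:
        return site
    survivors = [(b, c) for b, c, p in site.alleles if p >= floor]
    total = sum(c for _, c in survivors)
    kept = tuple((b, c, c / total) for b, c in survivors) if total else ()
    bases = [b for b, _, _ in kept]
    tv = len(bases) >= 2 and all(
        is_transversion(a, b)
        for i, a in enumerate(bases) for b in bases[i + 1:])
    return dataclasses.replace(site, alleles=kept, rare_removed=removed,
                               is_transversion=tv)


def restrict_transversions(
    sites: Sequence[VariantSite], rare_floor: float = 0.1,
) -> list[VariantSite]:
    """The analysis restriction the pipeline applies to called sites: remove
    rare alleles (noise, including minor deamination artefacts that would
    otherwise disguise a transversion site as multiallelic), then keep sites
    that remain variable and whose surviving allele pairs are all
    transversions."""
    floored = [_apply_rare_floor(s, rare_floor) for s in sites]
    return [s for s in floored if len(s.alleles) >= 2 and s.is_transversion]


def allele_proportions(
    reads_merged: Sequence[AlignedRead],
    composite_ref: str,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
) -> ProportionReport:
    """Replicated allele-proportion estimation against the composite genome.

    ``reads_merged`` is the merged result of mapping the sample separately
    against the high- and low-frequency haplogroup consensus sequences (to
    avoid reference bias); the same read therefore usually appears twice and
    the exact-sequence de-duplication collapses it.  Each replicate draws an
    independent de-duplication substream, removes coordinate duplicates,
    calls transversion-only variants, drops alleles below the rare-allele
    floor (strict ``<``; proportions are reported raw, removed alleles are
    flagged), and reports per-site and genome-wide mean alternative-allele
    proportions relative to the composite base.
    """
    cfg = cfg or PipelineConfig()
    if cfg.n_dedup_replicates < 1:
        raise ValueError("n_dedup_replicates must be >= 1")
    base_seed = cfg.rng_seed if seed is None else seed
    replicates: list[ReplicateResult] = []
    for rep in range(cfg.n_dedup_replicates):
        sub = np.random.SeedSequence((base_seed, 101, rep)).generate_state(1)[0]
        dd = remove_exact_duplicates(reads_merged, int(sub) % (2 ** 31))
        dd = remove_coordinate_duplicates(dd)
        pileup = build_pileup(dd, composite_ref)
        min_cov = half_mean_coverage(pileup, cfg.var_cov_fraction)
        sites = call_variants(pileup, composite_ref, cfg.var_min_qual, min_cov)
        sites = restrict_transversions(sites, cfg.rare_allele_floor)
        per_site: dict[int, float] = {}
        for s in sites:
            alt = sum(p for b, _, p in s.alleles if b != s.composite_base)
            if alt > 0:
                per_site[s.pos] = alt
        mean_alt = float(np.mean(list(per_site.values()))) if per_site else 0.0
        replicates.append(ReplicateResult(rep, tuple(sites), per_site, mean_alt))
    return ProportionReport(tuple(replicates))


def half_mean_coverage(
    pileup: Sequence[PileupColumn], fraction: float = 0.5,
) -> int:
    """Depth cutoff: ``fraction`` of the mean depth over all positions
    (zeros included), rounded down, floored at 1."""
    return max(1, int(mean_coverage(pileup) * fraction))


def damage_restricted_recall(
    sites: Sequence[VariantSite],
    reads: Sequence[AlignedRead],
    reference: str,
    cfg: PipelineConfig | None = None,
    dmg_params: DamageModel | None = None,
) -> float:
    """Fraction of ``sites`` re-called using only damage-bearing reads.

    Reads are filtered at the PMD-score threshold, then variants are
    re-called with the relaxed quality/coverage thresholds and the
    transversion restriction; recall is by position.
    """
    cfg = cfg or PipelineConfig()
    if not sites:
        warnings.warn("no original sites; recall undefined, returning 0")
        return 0.0
    damaged = filter_damaged(reads, reference, cfg.damage_score_threshold,
                             dmg_params)
    if not damaged:
        warnings.warn("no reads pass the damage filter; recall 0")
        return 0.0
    pileup = build_pileup(damaged, reference)
    recalled = call_variants(pileup, reference, cfg.dmg_var_min_qual,
                             cfg.dmg_var_min_cov)
    recalled = restrict_transversions(recalled, cfg.rare_allele_floor)
    original = {s.pos for s in sites}
    hit = original & {s.pos for s in recalled}
    return len(hit) / len(original)
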