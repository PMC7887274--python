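"""Synthetic ancient-DNA read simulator with full ground truth.

Emulates a sediment extract containing a small number of organellar
haplotypes at known mixture proportions: short fragments (35–160 bp),
elevated terminal cytosine deamination (C→T at the 5′ end, G→A at the 3′
end) decaying geometrically into the read, and a uniform sequencing-error
floor.  Every planted variant and every read's haplotype of origin are
recorded so downstream estimators can be scored against truth.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .io import FastqRead

__all__ = [
    "HaplotypeSet", "DamageModel", "FragmentModel",
    "make_haplotype_set", "simulate_reads",
    "revcomp", "is_transversion", "TRANSVERSION_PARTNERS", "TRANSITION_PARTNER",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
# purine <-> pyrimidine changes; immune to deamination artefacts
TRANSVERSION_PARTNERS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_transversion(a: str, b: str) -> bool:
    """True iff a↔b is a purine↔pyrimidine change."""
    return (a in PURINES) != (b in PURINES)


@dataclasses.dataclass(frozen=True)
class VariantTruth:
    pos: int                 # 0-based reference position
    ref_base: str
    hap_bases: tuple[str, ...]   # one base per haplotype
    is_transversion: bool


@dataclasses.dataclass(frozen=True)
class HaplotypeSet:
    """A reference plus co-occurring haplotypes at fixed proportions."""

    reference: str
    haplotypes: tuple[tuple[str, float], ...]   # (sequence, proportion)
    variant_truth: tuple[VariantTruth, ...]

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.haplotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype proportions sum to {total}, not 1")
        for seq, _ in self.haplotypes:
            if len(seq) != len(self.reference):
                raise ValueError("haplotype length differs from reference")
        for t in self.variant_truth:
            if all(b == t.ref_base for b in t.hap_bases):
                raise ValueError(f"truth site {t.pos} identical to reference")


@dataclasses.dataclass(frozen=True)
class DamageModel:
    """Post-mortem deamination plus a uniform sequencing-error floor.

    The probability of deamination at read-coordinate distance z from the
    relevant end is ``d * decay**z`` (z 0-based): C→T measured from the 5′
    end, G→A from the 3′ end, independently (double-stranded library
    behaviour).
    """

    d5: float = 0.3
    d3: float = 0.3
    decay: float = 0.5
    seq_error: float = 0.002

    def __post_init__(self) -> None:
        for k in ("d5", "d3", "seq_error"):
            v = getattr(self, k)
            if not 0 <= v <= 1:
                raise ValueError(f"{k} must be in [0,1], got {v}")
        if not 0 < self.decay < 1:
            raise ValueError(f"decay must be in (0,1), got {self.decay}")


@dataclasses.dataclass(frozen=True)
class FragmentModel:
    """Log-normal fragment lengths, rejection-truncated to [min, max].

    Defaults emulate well-preserved lake-sediment extracts (mean ≈ 65 bp);
    the more degraded of the study's two samples is emulated with a shorter
    mean (≈ 55 bp) via the ``mean_length`` knob.
    """

    mean_length: float = 65.0
    spread: float = 0.25      # sigma of log-length
    min_length: int = 35
    max_length: int = 160

    def __post_init__(self) -> None:
        if not self.min_length <= self.mean_length <= self.max_length:
            raise ValueError("mean_length outside [min_length, max_length]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mu = np.log(self.mean_length) - self.spread ** 2 / 2
        out = np.empty(n, dtype=np.int64)
        filled = 0
        while filled < n:
            draw = np.rint(rng.lognormal(mu, self.spread, size=2 * (n - filled)))
            ok = draw[(draw >= self.min_length) & (draw <= self.max_length)]
            take = min(len(ok), n - filled)
            out[filled:filled + take] = ok[:take]
            filled += take
        return out


@dataclasses.dataclass(frozen=True)
class TruthRead:
    """An error-free placement record for one simulated read."""

    name: str
    hap_index: int
    ref_start: int
    length: int
    strand: str
    sequence: str     # final (damaged+errored) sequence, reference orientation


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_haplotype_set(
    ref_length: int,
    n_haplotypes: int,
    n_transversion_sites: int = 0,
    n_transition_sites: int = 0,
    proportions: Sequence[float] | None = None,
    linked_pairs: Sequence[int] = (),
    seed: int = 0,
) -> HaplotypeSet:
    """Build a reference and ``n_haplotypes`` derived haplotypes.

    Parameters
    ----------
    linked_pairs : sequence of int
        For each entry ``gap``, a pair of transversion sites at distance
        ``gap`` is planted at which the haplotypes are pairwise
        distinguishable (all haplotypes show distinct 2-base combinations).
    """
    rng = np.random.default_rng(seed)
    if proportions is None:
        proportions = [1.0 / n_haplotypes] * n_haplotypes
    proportions = list(proportions)
    if len(proportions) != n_haplotypes:
        raise ValueError("proportions length must equal n_haplotypes")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {sum(proportions)}, not 1")
    if n_haplotypes > 4 and linked_pairs:
        raise ValueError("linked pairs can distinguish at most 4 haplotypes")

    reference = _random_sequence(rng, ref_length)
    margin = 5  # keep planted sites apart and off the ends

    # Reserve positions: linked pairs first, then scattered singles.
    used: set[int] = set()

    def reserve(pos: int, width: int = 1) -> bool:
        block = range(pos - margin, pos + width + margin)
        if pos < margin or pos + width + margin > ref_length:
            return False
        if any(p in used for p in block):
            return False
        used.update(range(pos, pos + width))
        return True

    pair_positions: list[tuple[int, int]] = []
    for gap in linked_pairs:
        if gap < 1:
            raise ValueError("linked pair gap must be >= 1")
        placed = False
        for _ in range(200):
            p = int(rng.integers(margin, ref_length - gap - margin))
            if reserve(p, gap + 1):
                pair_positions.append((p, p + gap))
                placed = True
                break
        if not placed:
            raise ValueError("could not place linked pair: reference too short")

    def scatter(n: int) -> list[int]:
        out = []
        for _ in range(n):
            for _ in range(500):
                p = int(rng.integers(margin, ref_length - margin))
                if reserve(p):
                    out.append(p)
                    break
            else:
                raise ValueError("could not place variant site: reference too short")
        return out

    tv_positions = scatter(n_transversion_sites)
    ts_positions = scatter(n_transition_sites)

    haps = [list(reference) for _ in range(n_haplotypes)]
    truth: list[VariantTruth] = []

    def plant(pos: int, alt_of, assignment: Sequence[int]) -> None:
        ref_base = reference[pos]
        alt = alt_of(ref_base)
        bases = tuple(alt if a else ref_base for a in assignment)
        for h, b in zip(haps, bases):
            h[pos] = b
        truth.append(VariantTruth(pos, ref_base, bases,
                                  is_transversion(ref_base, alt)))

    def tv_alt(ref_base: str) -> str:
        return rng.choice(list(TRANSVERSION_PARTNERS[ref_base]))

    def random_assignment() -> list[int]:
        # polymorphic within the mixture: neither all-reference nor all-alternative
        while True:
            a = list(rng.integers(0, 2, size=n_haplotypes))
            if any(a) and not all(a):
                return a

    if n_haplotypes >= 2:
        # Linked pairs: haplotype h gets the 2-bit pattern of h, so all
        # haplotypes are pairwise distinguishable within the pair.
        for p1, p2 in pair_positions:
            bits1 = [(h >> 1) & 1 for h in range(n_haplotypes)]
            bits2 = [h & 1 for h in range(n_haplotypes)]
            if not any(bits1):
                bits1 = bits2  # K=2: make the first site variable too
            plant(p1, tv_alt, bits1)
            plant(p2, tv_alt, bits2)
        for p in tv_positions:
            plant(p, tv_alt, random_assignment())
        for p in ts_positions:
            plant(p, lambda b: TRANSITION_PARTNER[b], random_assignment())

    truth.sort(key=lambda t: t.pos)
    return HaplotypeSet(
        reference=reference,
        haplotypes=tuple(("".join(h), p) for h, p in zip(haps, proportions)),
        variant_truth=tuple(truth),
    )


def _apply_damage(read: str, dmg: DamageModel, rng: np.random.Generator) -> str:
    """Deaminate in read coordinates: C→T from the 5′ end, G→A from the 3′ end."""
    if dmg.d5 == 0 and dmg.d3 == 0:
        return read
    bases = list(read)
    n = len(bases)
    u5 = rng.random(n)
    u3 = rng.random(n)
    for i in range(n):
        if bases[i] == "C" and u5[i] < dmg.d5 * dmg.decay ** i:
            bases[i] = "T"
        elif bases[i] == "G" and u3[i] < dmg.d3 * dmg.decay ** (n - 1 - i):
            bases[i] = "A"
    return "".join(bases)


def _apply_seq_error(read: str, p: float, rng: np.random.Generator) -> str:
    if p == 0:
        return read
    n = len(read)
    hits = np.nonzero(rng.random(n) < p)[0]
    if len(hits) == 0:
        return read
    bases = list(read)
    alphabet = "ACGT"
    for i in hits:
        choices = alphabet.replace(bases[i], "") if bases[i] in alphabet else alphabet
        bases[i] = choices[rng.integers(0, len(choices))]
    return "".join(bases)


def simulate_reads(
    hs: HaplotypeSet,
    coverage: float,
    frag: FragmentModel | None = None,
    dmg: DamageModel | None = None,
    seed: int = 0,
    name_prefix: str = "read",
) -> tuple[list[FastqRead], list[TruthRead]]:
    """Draw reads from the haplotype mixture to a target fold coverage.

    Each read picks a source haplotype with its mixture probability and a
    uniform start.  Deamination is applied in read coordinates (after
    reverse-complementing minus-strand fragments, matching the biological
    mechanism), then uniform sequencing error.  The FASTQ stores the read as
    sequenced; the truth record stores reference orientation and origin.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    frag = frag or FragmentModel()
    dmg = dmg or DamageModel()
    rng = np.random.default_rng(seed)
    ref_len = len(hs.reference)
    target_bases = coverage * ref_len

    qual_phred = 40 if dmg.seq_error == 0 else min(
        40, int(round(-10 * np.log10(dmg.seq_error))))
    qual_char = chr(qual_phred + 33)

    props = np.array([p for _, p in hs.haplotypes])
    n_guess = max(1, int(np.ceil(target_bases / frag.mean_length * 1.2)))
    lengths = frag.sample(rng, n_guess)
    # trim to the target base count
    keep = int(np.searchsorted(np.cumsum(lengths), target_bases) + 1)
    lengths = lengths[:min(keep, len(lengths))]
    n_reads = len(lengths)

    hap_idx = rng.choice(len(props), size=n_reads, p=props)
    strands = rng.random(n_reads) < 0.5  # True => minus

    fastq: list[FastqRead] = []
    truth: list[TruthRead] = []
    for i in range(n_reads):
        length = int(lengths[i])
        start = int(rng.integers(0, ref_len - length + 1))
        h = int(hap_idx[i])
        fragment = hs.haplotypes[h][0][start:start + length]
        minus = bool(strands[i])
        read0 = revcomp(fragment) if minus else fragment
        read1 = _apply_damage(read0, dmg, rng)
        read2 = _apply_seq_error(read1, dmg.seq_error, rng)
        name = f"{name_prefix}_{i}"
        fastq.append(FastqRead(name, read2, qual_char * length))
        truth.append(TruthRead(
            name=name, hap_index=h, ref_start=start, length=length,
            strand="-" if minus else "+",
            sequence=revcomp(read2) if minus else read2,
        ))
    return fastq, truth
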