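"""Ancient-DNA damage diagnostics.

Two tools live here: per-position deamination profiles (C→T by distance from
the 5′ end, G→A from the 3′ end) of a mapped read set, and a per-read
post-mortem-damage (PMD) score — the log-likelihood ratio of an ancient
(damage-elevated) versus modern substitution model — used to extract the
damage-bearing subset of reads.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .align import AlignedRead
from .simulate import DamageModel, revcomp

__all__ = ["DamageProfile", "damage_profile", "pmd_score", "filter_damaged"]

_MIN_ERROR = 1e-4   # floor on the quality-implied error rate


@dataclasses.dataclass(frozen=True)
class DamageProfile:
    """Deamination frequencies by distance from the read ends.

    ``ct5[z]`` is the fraction of read positions at 5′ distance ``z`` with
    reference C read as T, among positions with reference C; ``ga3`` is the
    3′-end G→A analogue.  Positions with no observations carry frequency NaN
    and ``n_obs`` 0.  ``length_hist[L]`` counts reads of length ``L``.
    """

    ct5: np.ndarray
    ga3: np.ndarray
    n_obs_ct5: np.ndarray
    n_obs_ga3: np.ndarray
    length_hist: dict[int, int]

    def to_tsv(self) -> str:
        lines = ["end\tposition\tfrequency\tn_obs"]
        for z in range(len(self.ct5)):
            f = "NA" if np.isnan(self.ct5[z]) else f"{self.ct5[z]:.6f}"
            lines.append(f"5p_CT\t{z}\t{f}\t{int(self.n_obs_ct5[z])}")
        for z in range(len(self.ga3)):
            f = "NA" if np.isnan(self.ga3[z]) else f"{self.ga3[z]:.6f}"
            lines.append(f"3p_GA\t{z}\t{f}\t{int(self.n_obs_ga3[z])}")
        return "\n".join(lines) + "\n"


def damage_profile(
    reads: Sequence[AlignedRead],
    reference: str,
    n_positions: int = 25,
    length_cap: int = 160,
) -> DamageProfile:
    """Compute deamination profiles over the first ``n_positions`` from each
    read end (capped at ``length_cap``), in read coordinates after strand
    normalisation."""
    n_positions = min(n_positions, length_cap)
    ref = reference.upper()
    ct = np.zeros(n_positions)
    ct_n = np.zeros(n_positions)
    ga = np.zeros(n_positions)
    ga_n = np.zeros(n_positions)
    length_hist: dict[int, int] = {}
    for r in reads:
        length = len(r.sequence)
        length_hist[length] = length_hist.get(length, 0) + 1
        ref_span = ref[r.ref_start:r.ref_end]
        read_seq, _ = r.read_oriented()
        ref_seq = revcomp(ref_span) if r.strand == "-" else ref_span
        for z in range(min(length, n_positions)):
            if ref_seq[z] == "C":
                ct_n[z] += 1
                if read_seq[z] == "T":
                    ct[z] += 1
            z3 = length - 1 - z
            if ref_seq[z3] == "G":
                ga_n[z] += 1
                if read_seq[z3] == "A":
                    ga[z] += 1
    with np.errstate(invalid="ignore"):
        ct5 = np.where(ct_n > 0, ct / np.maximum(ct_n, 1), np.nan)
        ga3 = np.where(ga_n > 0, ga / np.maximum(ga_n, 1), np.nan)
    return DamageProfile(ct5, ga3, ct_n, ga_n, length_hist)


def pmd_score(
    read: AlignedRead,
    reference: str,
    dmg_params: DamageModel | None = None,
) -> float:
    """Log-likelihood ratio (natural log) of ancient vs modern models.

    At read-coordinate distance z the ancient model deaminates with
    probability D(z) = d * decay**z (C→T from the 5′ end, G→A from the 3′
    end).  With quality-implied error rate eps, an observed deamination-type
    mismatch contributes log(D/eps), a matching C (or G) contributes
    log((1-D)/(1-eps)), and every other position contributes 0.
    """
    dmg = dmg_params or DamageModel()
    ref_span = reference.upper()[read.ref_start:read.ref_end]
    read_seq, quals = read.read_oriented()
    ref_seq = revcomp(ref_span) if read.strand == "-" else ref_span
    n = len(read_seq)
    score = 0.0
    for z in range(n):
        eps = max(10.0 ** (-float(quals[z]) / 10.0), _MIN_ERROR)
        rb, ob = ref_seq[z], read_seq[z]
        if rb == "C":
            d = dmg.d5 * dmg.decay ** z
            if ob == "T":
                score += np.log(max(d, _MIN_ERROR) / eps)
            elif ob == "C":
                score += np.log((1 - d) / (1 - eps))
        elif rb == "G":
            d = dmg.d3 * dmg.decay ** (n - 1 - z)
            if ob == "A":
                score += np.log(max(d, _MIN_ERROR) / eps)
            elif ob == "G":
                score += np.log((1 - d) / (1 - eps))
    return float(score)


def filter_damaged(
    reads: Sequence[AlignedRead],
    reference: str,
    threshold: float = 3.0,
    dmg_params: DamageModel | None = None,
) -> list[AlignedRead]:
    """Retain reads whose PMD score is at or above ``threshold``."""
    return [r for r in reads if pmd_score(r, reference, dmg_params) >= threshold]
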