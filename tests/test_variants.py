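import math

import numpy as np
import pytest

import sedapop as sp
from sedapop.align import PileupColumn
from sedapop.variants import (VariantSite, _apply_rare_floor,
                              damage_restricted_recall, half_mean_coverage)


def _col(pos, ref_base, qual=40, **counts):
    c = {b: counts.get(b, 0) for b in "ACGT"}
    mq = {b: float(qual) for b in "ACGT" if c[b] > 0}
    return PileupColumn(pos, ref_base, c, mq, sum(c.values()))


def binom_tail_oracle(k, n, p):
    """Exact upper-tail binomial probability by direct summation."""
    return sum(math.comb(n, i) * p ** i * (1 - p) ** (n - i)
               for i in range(k, n + 1))


def test_monomorphic_column_yields_no_site():
    assert sp.call_variants([_col(0, "C", C=50)], "C") == []


def test_biallelic_transversion_site_proportions():
    [site] = sp.call_variants([_col(0, "A", A=30, T=20)], "A")
    assert site.is_transversion
    props = {b: p for b, _, p in site.alleles}
    assert props == {"A": pytest.approx(0.6), "T": pytest.approx(0.4)}
    assert sum(props.values()) == pytest.approx(1.0)


def test_minor_allele_quality_is_binomial_tail():
    """C:48 T:2 at Q40: site quality equals the Phred-scaled exact binomial
    tail of seeing >=2 errors at the quality-implied rate."""
    col = _col(0, "C", qual=40, C=48, T=2)
    expected_p = binom_tail_oracle(2, 50, 1e-4)
    expected_qual = -10 * math.log10(expected_p)
    sites = sp.call_variants([col], "C", min_qual=0)
    assert sites and sites[0].qual == pytest.approx(expected_qual, rel=1e-6)
    # and the site is excluded exactly when min_qual exceeds that value
    assert sp.call_variants([col], "C", min_qual=expected_qual + 1) == []
    assert sp.call_variants([col], "C", min_qual=expected_qual - 1) != []


def test_depth_and_singleton_thresholds():
    assert sp.call_variants([_col(0, "A", A=30, T=20)], "A", min_cov=60) == []
    # singleton observations never form an allele
    assert sp.call_variants([_col(0, "A", A=49, T=1)], "A", min_qual=0) == []


def test_transversion_filter_examples():
    ct = sp.call_variants([_col(0, "C", C=30, T=20)], "C", min_qual=0)[0]
    ac = sp.call_variants([_col(0, "A", A=30, C=20)], "A", min_qual=0)[0]
    multi = sp.call_variants([_col(0, "A", A=20, C=15, T=15)], "A",
                             min_qual=0)[0]
    out = sp.transversions_only([ct, ac, multi])
    assert out == [ac]                      # C/T removed; A/C kept
    assert not multi.is_transversion        # A/C/T has the C/T transition pair
    assert sp.transversions_only(out) == out  # idempotent


def _site(pos, comp, alleles):
    total = sum(c for _, c in alleles)
    return VariantSite(pos, comp,
                       tuple((b, c, c / total) for b, c in alleles),
                       qual=99.0, depth=total, is_transversion=True)


def test_split_high_low_membership_by_composite_not_frequency():
    s_major = _site(5, "A", [("A", 60), ("T", 40)])
    s_minor = _site(9, "A", [("A", 40), ("T", 60)])
    high, low, flagged = sp.split_high_low([s_major, s_minor], "C" * 5 + "A" * 10)
    # the composite allele is high at both sites regardless of its frequency
    assert high == {5: "A", 9: "A"}
    assert low == {5: "T", 9: "T"}
    assert flagged == []


def test_split_high_low_degenerate_site_flagged():
    s = _site(2, "A", [("C", 30), ("T", 20)])
    high, low, flagged = sp.split_high_low([s], "GGAGG")
    assert flagged == [2]
    assert 2 not in high and low[2] == "C"


def test_split_high_low_partition():
    sites = [_site(i * 3, "A", [("A", 30), ("C", 20)]) for i in range(5)]
    high, low, _ = sp.split_high_low(sites, "A" * 15)
    for s in sites:
        assert {high[s.pos], low[s.pos]} == set(s.allele_bases)


def test_apply_variant_consensus():
    ref = "ACGTACGTAC"
    assert sp.apply_variant_consensus(ref, {}) == ref
    out = sp.apply_variant_consensus(ref, {0: "T", 5: "A", 9: "G"})
    assert sum(a != b for a, b in zip(out, ref)) == 3
    assert out[0] == "T" and out[5] == "A" and out[9] == "G"
    with pytest.raises(ValueError, match="out of bounds"):
        sp.apply_variant_consensus(ref, {10: "A"})


def test_high_low_pair_recovers_true_haplotypes(two_hap_run, two_hap_tv_sites):
    """At truth transversion sites with both alleles >= 0.15 and good
    coverage, the high/low consensus pair equals the two true haplotypes."""
    d = two_hap_run
    composite = d["composite"]
    high, low, _ = sp.split_high_low(two_hap_tv_sites, composite)
    high_seq = sp.apply_variant_consensus(composite, high)
    low_seq = sp.apply_variant_consensus(composite, low)
    hap_major = d["hs"].haplotypes[0][0]   # 0.6 proportion
    hap_minor = d["hs"].haplotypes[1][0]
    for t in d["hs"].variant_truth:
        if not t.is_transversion:
            continue
        assert {high_seq[t.pos], low_seq[t.pos]} == set(t.hap_bases)
        assert high_seq[t.pos] == composite[t.pos]


def test_rare_allele_floor_boundary():
    s = _site(0, "A", [("A", 91), ("T", 9)])     # alt proportion 0.09
    floored = _apply_rare_floor(s, 0.1)
    assert floored.allele_bases == ("A",)
    assert floored.rare_removed == ("T",)
    s2 = _site(0, "A", [("A", 90), ("T", 10)])   # exactly 0.1 is retained
    assert _apply_rare_floor(s2, 0.1).allele_bases == ("A", "T")


def test_single_haplotype_mean_alternative_zero(noiseless_single_hap):
    d = noiseless_single_hap
    report = sp.allele_proportions(d["mapped"], d["hs"].reference, seed=1)
    assert report.n_replicates == 5
    assert all(m == 0.0 for m in report.mean_alt_per_replicate)


def test_mixture_proportion_recovery(two_hap_run):
    """Each replicate's genome-wide mean alternative proportion recovers the
    0.4 minor mixture fraction within 0.05."""
    d = two_hap_run
    report = sp.allele_proportions(d["mapped"], d["composite"], seed=2)
    for m in report.mean_alt_per_replicate:
        assert abs(m - 0.40) < 0.05


def test_half_mean_coverage_convention():
    pile = [_col(i, "A", A=10) for i in range(50)] + \
           [_col(i + 50, "A") for i in range(50)]
    # mean depth 5.0 over all positions including zeros; half -> 2
    assert half_mean_coverage(pile, 0.5) == 2


def test_recall_zero_without_damaged_reads(noiseless_single_hap):
    d = noiseless_single_hap
    sites = [_site(10, "A", [("A", 30), ("C", 20)])]
    with pytest.warns(UserWarning):
        rec = damage_restricted_recall(sites, d["mapped"], d["hs"].reference)
    assert rec == 0.0


def test_damage_restricted_recall_on_damaged_mixture(two_hap_run,
                                                     two_hap_tv_sites):
    d = two_hap_run
    rec = damage_restricted_recall(two_hap_tv_sites, d["dedup"], d["composite"])
    assert rec >= 0.5
    # relaxing the damage threshold can only help recall
    cfg_loose = sp.PipelineConfig(damage_score_threshold=1e-9)
    rec_loose = damage_restricted_recall(two_hap_tv_sites, d["dedup"],
                                         d["composite"], cfg_loose)
    assert rec_loose >= rec


def test_called_sites_cover_planted_truth(two_hap_run, two_hap_tv_sites):
    """Transversion calling recovers >=95% of planted transversion truth
    sites (both alleles >= 0.15, coverage ~60x) with accurate proportions."""
    d = two_hap_run
    truth_tv = [t for t in d["hs"].variant_truth if t.is_transversion]
    called = {s.pos: s for s in two_hap_tv_sites}
    hit = [t for t in truth_tv if t.pos in called]
    assert len(hit) >= 0.95 * len(truth_tv)
    for t in hit:
        site = called[t.pos]
        minor_truth = sum(p for (_, p), b in
                          zip(d["hs"].haplotypes, t.hap_bases)
                          if b != d["composite"][t.pos])
        est = sum(p for b, _, p in site.alleles
                  if b != d["composite"][t.pos])
        assert abs(est - minor_truth) < 0.1
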