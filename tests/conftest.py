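"""Shared fixtures: small seeded synthetic datasets, built once per session."""

import numpy as np
import pytest

import sedapop as sp
from sedapop.variants import half_mean_coverage


@pytest.fixture(scope="session")
def two_hap_run():
    """A 0.6/0.4 two-haplotype mixture at 60x with default damage, mapped and
    coordinate-deduplicated, plus its composite consensus and pileup."""
    hs = sp.make_haplotype_set(
        4000, 2, n_transversion_sites=15, n_transition_sites=5,
        proportions=[0.6, 0.4], linked_pairs=[20], seed=5)
    fastq, truth = sp.simulate_reads(hs, 60, seed=6)
    mapped = sp.map_reads(fastq, hs.reference)
    dedup = sp.remove_coordinate_duplicates(mapped)
    pileup = sp.build_pileup(dedup, hs.reference)
    composite = sp.majority_consensus(pileup, hs.reference)
    return dict(hs=hs, fastq=fastq, truth=truth, mapped=mapped, dedup=dedup,
                pileup=pileup, composite=composite)


@pytest.fixture(scope="session")
def two_hap_tv_sites(two_hap_run):
    pileup = two_hap_run["pileup"]
    sites = sp.call_variants(pileup, two_hap_run["composite"], 30,
                             half_mean_coverage(pileup))
    return sp.restrict_transversions(sites)


@pytest.fixture(scope="session")
def noiseless_single_hap():
    """One haplotype, zero damage, zero sequencing error, 50x."""
    hs = sp.make_haplotype_set(3000, 1, seed=21)
    dmg = sp.DamageModel(d5=0.0, d3=0.0, decay=0.5, seq_error=0.0)
    fastq, truth = sp.simulate_reads(hs, 50, dmg=dmg, seed=22)
    mapped = sp.map_reads(fastq, hs.reference)
    return dict(hs=hs, fastq=fastq, truth=truth, mapped=mapped)


def make_read(seq, start, strand="+", qual=35, name="r", sample=""):
    """Convenience AlignedRead constructor for hand-built cases."""
    return sp.AlignedRead(
        name=name, sequence=seq,
        qual=np.full(len(seq), qual, dtype=np.uint8),
        ref_start=start, strand=strand, sample_id=sample)
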