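import numpy as np
import pytest

import sedapop as sp
from sedapop.io import FastqRead
from sedapop.simulate import revcomp
from conftest import make_read


def _fq(seq, name="r"):
    return FastqRead(name, seq, "I" * len(seq))


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_best(read, reference):
    """Exhaustive Hamming scan over every offset and strand."""
    best = None
    for strand_rank, seq in ((0, read), (1, revcomp(read))):
        for start in range(len(reference) - len(seq) + 1):
            mm = sum(a != b for a, b in zip(reference[start:start + len(seq)], seq))
            key = (mm, start, strand_rank)
            if best is None or key < best:
                best = key
    return best


def test_exact_substring_maps_at_origin():
    rng = np.random.default_rng(0)
    ref = _random_seq(rng, 500)
    read = ref[100:140]
    [aln] = sp.map_reads([_fq(read)], ref)
    assert (aln.ref_start, aln.strand, aln.n_mismatches) == (100, "+", 0)


def test_reverse_complement_maps_at_origin_minus():
    rng = np.random.default_rng(1)
    ref = _random_seq(rng, 500)
    [aln] = sp.map_reads([_fq(revcomp(ref[100:140]))], ref)
    assert (aln.ref_start, aln.strand, aln.n_mismatches) == (100, "-", 0)
    assert aln.sequence == ref[100:140]  # stored in reference orientation


def test_planted_mismatches_match_brute_force_scan():
    rng = np.random.default_rng(2)
    for trial in range(10):
        ref = _random_seq(rng, 400)
        start = int(rng.integers(0, 360))
        read = list(ref[start:start + 40])
        # keep a clean 16-mer so seeding can find the locus
        for p in rng.choice(12, size=2, replace=False):
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        read = "".join(read)
        if rng.random() < 0.5:
            read = revcomp(read)
        aligned = sp.map_reads([_fq(read)], ref)
        expected = brute_force_best(read, ref)
        assert aligned, f"trial {trial}: read unmapped"
        aln = aligned[0]
        got = (aln.n_mismatches, aln.ref_start, 0 if aln.strand == "+" else 1)
        assert got == expected


def test_high_divergence_read_dropped():
    rng = np.random.default_rng(3)
    ref = _random_seq(rng, 300)
    junk = _random_seq(rng, 40)
    assert sp.map_reads([_fq(junk)], ref, max_mismatch_rate=0.05) == []


def test_exact_duplicates_single_survivor():
    reads = [make_read("ACGT" * 10, 10, name="a"),
             make_read("ACGT" * 10, 10, name="b"),
             make_read("ACGT" * 10, 55, name="c")]
    out = sp.remove_exact_duplicates(reads, replicate_seed=0)
    assert len(out) == 1


def test_exact_duplicates_orientation_normalized():
    seq = "ACGTACGTACGTACGTACGA"
    reads = [make_read(seq, 10, "+", name="a"),
             make_read(seq, 10, "-", name="b")]
    # same reference-orientation sequence, opposite strands: read-oriented
    # sequences differ, so both survive
    assert len(sp.remove_exact_duplicates(reads, 0)) == 2
    # identical read-oriented copies collapse
    reads2 = [make_read(seq, 10, "+", name="a"),
              make_read(seq, 99, "+", name="b")]
    assert len(sp.remove_exact_duplicates(reads2, 0)) == 1


def test_exact_duplicates_no_op_on_distinct():
    rng = np.random.default_rng(4)
    reads = [make_read(_random_seq(rng, 30), i, name=f"r{i}") for i in range(20)]
    assert sp.remove_exact_duplicates(reads, 1) == reads


def test_exact_duplicate_choice_is_uniform():
    reads = [make_read("ACGTACGTACGTACGTACGT", 5, name="first"),
             make_read("ACGTACGTACGTACGTACGT", 90, name="second")]
    kept_first = sum(
        sp.remove_exact_duplicates(reads, seed)[0].name == "first"
        for seed in range(1000))
    assert abs(kept_first / 1000 - 0.5) < 0.05


def test_coordinate_duplicates_keep_highest_quality():
    a = make_read("A" * 40, 10, qual=30, name="low")
    b = make_read("C" * 40, 10, qual=35, name="high")
    out = sp.remove_coordinate_duplicates([a, b])
    assert [r.name for r in out] == ["high"]


def test_coordinate_duplicates_strand_in_key():
    a = make_read("A" * 40, 10, "+")
    b = make_read("A" * 40, 10, "-")
    assert len(sp.remove_coordinate_duplicates([a, b])) == 2


def test_coordinate_duplicates_count_equals_distinct_keys():
    rng = np.random.default_rng(5)
    reads = []
    for i in range(200):
        start = int(rng.integers(0, 20))
        strand = "+-"[rng.integers(0, 2)]
        length = int(rng.integers(30, 34))
        reads.append(make_read(_random_seq(rng, length), start, strand,
                               qual=int(rng.integers(20, 40)), name=f"r{i}"))
    keys = {(r.ref_start, r.strand, len(r.sequence)) for r in reads}
    assert len(sp.remove_coordinate_duplicates(reads)) == len(keys)


def test_coordinate_dedup_idempotent_and_shrinking():
    rng = np.random.default_rng(6)
    reads = [make_read(_random_seq(rng, 30), int(rng.integers(0, 10)),
                       name=f"r{i}") for i in range(50)]
    once = sp.remove_coordinate_duplicates(reads)
    assert len(once) <= len(reads)
    assert sp.remove_coordinate_duplicates(once) == once


def test_pileup_single_perfect_read():
    rng = np.random.default_rng(7)
    ref = _random_seq(rng, 200)
    read = make_read(ref[100:140], 100)
    pile = sp.build_pileup([read], ref)
    for p, col in enumerate(pile):
        if 100 <= p < 140:
            assert col.depth == 1 and col.counts[ref[p]] == 1
        else:
            assert col.depth == 0


def test_pileup_empty():
    assert all(col.depth == 0 for col in sp.build_pileup([], "ACGT" * 25))


def test_pileup_depth_matches_interval_stabbing_oracle():
    rng = np.random.default_rng(8)
    ref = _random_seq(rng, 300)
    reads = []
    for i in range(60):
        length = int(rng.integers(20, 60))
        start = int(rng.integers(0, 300 - length))
        reads.append(make_read(ref[start:start + length], start, name=f"r{i}"))
    pile = sp.build_pileup(reads, ref)
    for p in range(300):
        naive = sum(r.ref_start <= p < r.ref_end for r in reads)
        assert pile[p].depth == naive


def test_pileup_read_overrunning_reference_rejected():
    with pytest.raises(ValueError, match="overruns"):
        sp.build_pileup([make_read("ACGT" * 10, 90)], "A" * 100)


def test_noiseless_pileup_has_zero_nonreference_counts(noiseless_single_hap):
    d = noiseless_single_hap
    pile = sp.build_pileup(d["mapped"], d["hs"].reference)
    for col in pile:
        for base in "ACGT":
            if base != col.ref_base:
                assert col.counts[base] == 0


def test_sam_roundtrip_gives_identical_pileup(tmp_path, noiseless_single_hap):
    """External SAM ingestion and the internal mapper agree for identical
    placements."""
    d = noiseless_single_hap
    ref = d["hs"].reference
    path = tmp_path / "reads.sam"
    sp.write_sam(d["mapped"], "ref", len(ref), path)
    back = sp.read_sam(path)
    pile_a = sp.build_pileup(d["mapped"], ref)
    pile_b = sp.build_pileup(back, ref)
    for a, b in zip(pile_a, pile_b):
        assert a.counts == b.counts and a.depth == b.depth
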