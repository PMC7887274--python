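import numpy as np
import pytest

import sedapop as sp
from sedapop.metagenomics import HitRecord, TaxonomyTree


@pytest.fixture()
def toy_tree():
    # root(1) -> Eukaryota(2) -> genus G(3) -> species S1(4), S2(5)
    #         -> Bacteria(6) -> species B1(7)
    nodes = {
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Eukaryota"),
        3: (2, "genus", "G"),
        4: (3, "species", "S1"),
        5: (3, "species", "S2"),
        6: (1, "superkingdom", "Bacteria"),
        7: (6, "species", "B1"),
    }
    return TaxonomyTree(nodes, root=1)


def _hit(query, taxid, bitscore, identity=99.0, evalue=1e-20, cover=100.0):
    return HitRecord(query, f"subj{taxid}", identity, 50, evalue, bitscore,
                     taxid, cover)


def test_single_hit_assigns_species(toy_tree):
    out = sp.naive_lca({"q1": [_hit("q1", 4, 100)]}, toy_tree)
    assert out == {"q1": 4}


def test_top_percent_boundary_inclusive(toy_tree):
    # 91 >= 0.9 * 100 -> both vote, LCA is the genus
    out = sp.naive_lca({"q": [_hit("q", 4, 100), _hit("q", 5, 91)]}, toy_tree)
    assert out == {"q": 3}
    # 89 < 90 -> dropped, assignment stays at the best species
    out2 = sp.naive_lca({"q": [_hit("q", 4, 100), _hit("q", 5, 89)]}, toy_tree)
    assert out2 == {"q": 4}


def test_threshold_filters_drop_hits(toy_tree):
    bad = [
        _hit("q", 4, 20),                      # bitscore < 35
        _hit("q", 4, 100, evalue=1e-3),        # e-value too large
        _hit("q", 4, 100, identity=90.0),      # identity < 95
        _hit("q", 4, 100, cover=50.0),         # cover < 95
    ]
    assert sp.naive_lca({"q": bad}, toy_tree) == {}


def test_min_support_merges_weak_siblings_at_parent(toy_tree):
    cfg = sp.PipelineConfig(lca_min_support=20.0)  # 20% of assigned queries
    hits = {f"s1_{i}": [_hit(f"s1_{i}", 4, 100)] for i in range(8)}
    hits["lone_a"] = [_hit("lone_a", 5, 100)]                     # species S2
    hits["lone_b"] = [_hit("lone_b", 4, 100), _hit("lone_b", 5, 95)]  # genus
    out = sp.naive_lca(hits, toy_tree, cfg)
    # each alone is 10% (weak); S2 folds into the genus, where they pool to 20%
    assert out["lone_a"] == out["lone_b"] == 3
    assert all(out[q] == 4 for q in hits if not q.startswith("lone"))


def test_min_support_unrescuable_taxon_climbs_to_root(toy_tree):
    cfg = sp.PipelineConfig(lca_min_support=20.0)
    hits = {f"s1_{i}": [_hit(f"s1_{i}", 4, 100)] for i in range(9)}
    hits["lone"] = [_hit("lone", 7, 100)]   # no sibling support anywhere
    out = sp.naive_lca(hits, toy_tree, cfg)
    assert out["lone"] == 1


def test_assignment_is_ancestor_or_self_of_all_hits(toy_tree):
    rng = np.random.default_rng(0)
    taxa = [4, 5, 7]
    for trial in range(30):
        picks = rng.choice(taxa, size=rng.integers(1, 4))
        hits = [_hit("q", int(t), float(100 - rng.integers(0, 8)))
                for t in picks]
        out = sp.naive_lca({"q": hits}, toy_tree)
        best = max(h.bitscore for h in hits)
        voters = [h.taxon_id for h in hits if h.bitscore >= 0.9 * best]
        for t in voters:
            assert toy_tree.is_within(t, out["q"])


def test_competitive_filter_rules(toy_tree):
    reads = [
        ("better_ref", 80.0, [_hit("x", 7, 75)]),
        ("equal_same_genus", 80.0, [_hit("x", 4, 80)]),
        ("worse_other_family", 80.0, [_hit("x", 7, 85)]),
    ]
    out = sp.competitive_filter(reads, toy_tree, target_genus=3)
    assert out == ["better_ref", "equal_same_genus"]


def test_competitive_filter_root_target_never_shrinks(toy_tree):
    reads = [("a", 10.0, [_hit("a", 7, 85)]),
             ("b", 90.0, [_hit("b", 7, 85)])]
    narrow = sp.competitive_filter(reads, toy_tree, 3)
    root = sp.competitive_filter(reads, toy_tree, 1)
    assert set(narrow) <= set(root)
    assert set(root) == {"a", "b"}


def test_reads_per_mb():
    assert sp.reads_per_mb(1000, 1_000_000) == pytest.approx(1000.0)
    assert sp.reads_per_mb(0, 1_000_000) == 0.0
    assert sp.reads_per_mb(310_000, 33_330_000) == pytest.approx(9301, rel=1e-3)
    with pytest.raises(ValueError):
        sp.reads_per_mb(10, 0)


def test_summary_table_percentages():
    counts = {"Bacteria": 18852, "Nannochloropsis": 5913, "Total": 29488}
    df = sp.summary_table(counts, n_identified=29488, n_analysed=2_000_000)
    row = df.set_index("taxon")
    assert row.loc["Nannochloropsis", "I"] == 20.05
    assert row.loc["Bacteria", "I"] == 63.93
    assert row.loc["Total", "I"] == 100.0
    assert row.loc["Total", "A"] == 1.47
    assert list(df["N"]) == sorted(df["N"], reverse=True)


def test_summary_table_i_column_partitions():
    rng = np.random.default_rng(1)
    parts = rng.multinomial(10000, [0.5, 0.3, 0.15, 0.05])
    counts = {f"t{i}": int(n) for i, n in enumerate(parts)}
    df = sp.summary_table(counts, n_identified=10000, n_analysed=50000)
    assert abs(df["I"].sum() - 100.0) <= 0.05


def test_summary_table_validates_denominators():
    with pytest.raises(ValueError):
        sp.summary_table({"a": 5}, 0, 10)
    with pytest.raises(ValueError):
        sp.summary_table({"a": 50}, 10, 100)


def test_crosstab_disjoint_and_identical():
    unique, shared = sp.unique_mapping_crosstab({"g1": {"a"}, "g2": {"b"}})
    assert unique == {"g1": 1, "g2": 1}
    assert shared == {("g1", "g2"): 0}
    unique2, shared2 = sp.unique_mapping_crosstab(
        {"g1": {"a", "b"}, "g2": {"a", "b"}})
    assert unique2 == {"g1": 0, "g2": 0}
    assert shared2 == {("g1", "g2"): 2}


def test_crosstab_matches_set_algebra_oracle():
    rng = np.random.default_rng(2)
    ids = [f"r{i}" for i in range(1000)]
    sets = {g: {i for i in ids if rng.random() < p}
            for g, p in (("g1", 0.3), ("g2", 0.4), ("g3", 0.1))}
    unique, shared = sp.unique_mapping_crosstab(sets)
    for g in sets:
        others = set().union(*(sets[h] for h in sets if h != g))
        assert unique[g] == len(sets[g] - others)
    for (a, b), n in shared.items():
        assert n == len(sets[a] & sets[b])


def test_hits_table_and_taxonomy_roundtrip(tmp_path, toy_tree):
    hits = tmp_path / "hits.tsv"
    hits.write_text(
        "q1\tsubj4\t99.0\t50\t0\t0\t1\t50\t1\t50\t1e-20\t100\t4\n"
        "q1\tsubj5\t99.0\t50\t0\t0\t1\t50\t1\t50\t1e-20\t95\t5\n"
        "q2\tsubj7\t99.0\t50\t0\t0\t1\t50\t1\t50\t1e-20\t80\t7\n")
    tax = tmp_path / "tax.tsv"
    tax.write_text("\n".join(
        f"{t}\t{p}\t{r}\t{n}" for t, (p, r, n) in {
            1: (1, "no rank", "root"), 2: (1, "sk", "Eukaryota"),
            3: (2, "genus", "G"), 4: (3, "species", "S1"),
            5: (3, "species", "S2"), 6: (1, "sk", "Bacteria"),
            7: (6, "species", "B1")}.items()) + "\n")
    tree = sp.read_taxonomy(tax)
    table = sp.read_hits_table(hits)
    out = sp.naive_lca(table, tree)
    assert out == {"q1": 3, "q2": 7}   # q1: both hits within top 10% -> genus
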