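"""Naive-LCA assignment and a published-style metagenomic summary table.

Assigns queries from a small tabular hit set over a toy taxonomy, then
reproduces identified-sequence percentage arithmetic from category counts.
"""

import sedapop as sp
from sedapop.metagenomics import HitRecord, TaxonomyTree

nodes = {
    1: (1, "no rank", "root"),
    2: (1, "superkingdom", "Eukaryota"),
    3: (2, "genus", "Nannochloropsis"),
    4: (3, "species", "N. limnetica"),
    5: (3, "species", "N. granulata"),
}
tree = TaxonomyTree(nodes, root=1)


def hit(q, taxid, score):
    return HitRecord(q, f"s{taxid}", 99.0, 50, 1e-20, score, taxid)


hits = {
    "read1": [hit("read1", 4, 100)],                       # one clear species
    "read2": [hit("read2", 4, 100), hit("read2", 5, 95)],  # two close species
    "read3": [hit("read3", 4, 100), hit("read3", 5, 80)],  # second hit weak
}
for query, taxon in sp.naive_lca(hits, tree).items():
    print(f"{query} -> {tree.name(taxon)}")
# read2's hits are within 10% of each other, so it climbs to the genus;
# read3's weak second hit is outside the top-percent band and is ignored.

counts = {"Bacteria": 18852, "Nannochloropsis": 5913, "Total": 29488}
table = sp.summary_table(counts, n_identified=29488, n_analysed=2_000_000)
print()
print(table.to_string(index=False))
# I is the percentage of identified sequences, A the percentage of all
# sequences entering the metagenomic analysis.
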