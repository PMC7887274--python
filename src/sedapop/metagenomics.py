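"""Taxonomic assignment and metagenomic summary tables.

Implements naive lowest-common-ancestor (LCA) assignment over tabular
similarity-search hits (the standard 12-column tabular format plus a 13th
taxon-id column), the competitive reference-versus-database bitscore filter
used to weed out spurious mappings, per-megabase mapping-density
normalisation, summary tables of identified-sequence counts and
percentages, and unique/shared mapping cross-tabulation between reference
genomes.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import PipelineConfig

__all__ = [
    "TaxonomyTree", "HitRecord", "read_hits_table", "read_taxonomy",
    "naive_lca", "competitive_filter", "reads_per_mb", "summary_table",
    "unique_mapping_crosstab",
]


@dataclasses.dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    identity: float        # percent
    length: int
    evalue: float
    bitscore: float
    taxon_id: int
    query_cover: float = 100.0    # percent of query covered

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be in [0, 100]")


class TaxonomyTree:
    """Rooted taxonomy: taxon-id -> (parent, rank, name)."""

    def __init__(self, nodes: Mapping[int, tuple[int, str, str]], root: int):
        self.nodes = dict(nodes)
        self.root = root
        if root not in self.nodes:
            raise ValueError("root missing from node table")
        for tid in self.nodes:
            if tid != root and self._parent(tid) not in self.nodes:
                raise ValueError(f"taxon {tid}: parent not in tree")
            # cycle check via path-to-root
            self.path_to_root(tid)

    def _parent(self, tid: int) -> int:
        return self.nodes[tid][0]

    def path_to_root(self, tid: int) -> list[int]:
        if tid not in self.nodes:
            raise KeyError(f"unknown taxon-id {tid}")
        path = [tid]
        seen = {tid}
        while path[-1] != self.root:
            parent = self._parent(path[-1])
            if parent in seen:
                raise ValueError(f"taxonomy cycle involving taxon {parent}")
            path.append(parent)
            seen.add(parent)
        return path

    def lca(self, taxa: Iterable[int]) -> int:
        taxa = list(taxa)
        if not taxa:
            raise ValueError("LCA of an empty taxon set")
        common = set(self.path_to_root(taxa[0]))
        for t in taxa[1:]:
            common &= set(self.path_to_root(t))
        # deepest shared node = first on any member's root path
        for node in self.path_to_root(taxa[0]):
            if node in common:
                return node
        return self.root

    def is_within(self, tid: int, ancestor: int) -> bool:
        return ancestor in self.path_to_root(tid)

    def rank(self, tid: int) -> str:
        return self.nodes[tid][1]

    def name(self, tid: int) -> str:
        return self.nodes[tid][2]


def read_taxonomy(path: str | Path, root_name: str = "root") -> TaxonomyTree:
    """Read a (child, parent, rank, name) TSV edge list; the root is the node
    that is its own parent (or named ``root_name``)."""
    nodes: dict[int, tuple[int, str, str]] = {}
    root = None
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        child, parent, rank, name = line.rstrip("\n").split("\t")
        child_i, parent_i = int(child), int(parent)
        nodes[child_i] = (parent_i, rank, name)
        if child_i == parent_i or name == root_name:
            root = child_i
    if root is None:
        raise ValueError(f"no root found in taxonomy {path}")
    return TaxonomyTree(nodes, root)


def read_hits_table(path: str | Path) -> dict[str, list[HitRecord]]:
    """Read 12+1-column tabular hits (query, subject, %id, length, mismatches,
    gapopen, qstart, qend, sstart, send, evalue, bitscore, taxid) grouped by
    query.  Query coverage is derived from qstart/qend against the aligned
    length when possible; queries absent from the table are simply absent."""
    cols = ["query", "subject", "identity", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore", "taxid"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    out: dict[str, list[HitRecord]] = defaultdict(list)
    for row in df.itertuples(index=False):
        out[str(row.query)].append(HitRecord(
            query_id=str(row.query), subject_id=str(row.subject),
            identity=float(row.identity), length=int(row.length),
            evalue=float(row.evalue), bitscore=float(row.bitscore),
            taxon_id=int(row.taxid),
        ))
    return dict(out)


def naive_lca(
    hits_per_query: Mapping[str, Sequence[HitRecord]],
    tree: TaxonomyTree,
    cfg: PipelineConfig | None = None,
) -> dict[str, int]:
    """Assign each query the LCA of its surviving hits, then fold
    weakly supported taxa into their parents.

    Hits failing the bitscore / e-value / identity / query-cover thresholds
    are dropped; of the survivors only those within ``lca_top_percent`` of
    the best bitscore (inclusive boundary) vote.  After assignment, any
    taxon holding fewer than ``lca_min_support`` percent of all assigned
    queries is reassigned to its parent, repeatedly, until the support
    threshold is met or the root is reached.
    """
    cfg = cfg or PipelineConfig()
    assignments: dict[str, int] = {}
    for query, hits in hits_per_query.items():
        surviving = [h for h in hits
                     if h.bitscore >= cfg.lca_min_score
                     and h.evalue <= cfg.lca_max_evalue
                     and h.identity >= cfg.lca_min_identity
                     and h.query_cover >= cfg.lca_min_cover]
        if not surviving:
            continue
        best = max(h.bitscore for h in surviving)
        cutoff = (1.0 - cfg.lca_top_percent / 100.0) * best
        top = [h for h in surviving if h.bitscore >= cutoff]
        assignments[query] = tree.lca(h.taxon_id for h in top)

    n_assigned = len(assignments)
    if n_assigned == 0:
        return assignments
    min_count = cfg.lca_min_support / 100.0 * n_assigned
    # Fold weak taxa into parents bottom-up (deepest node first) so that weak
    # siblings can pool enough joint support at a shared ancestor.
    tally = Counter(assignments.values())
    depth = {t: len(tree.path_to_root(t)) for t in tree.nodes}
    relocated: dict[int, int] = {}
    for taxon in sorted(tree.nodes, key=lambda t: (-depth[t], t)):
        if taxon == tree.root or tally.get(taxon, 0) == 0:
            continue
        if tally[taxon] < min_count:
            parent = tree.nodes[taxon][0]
            tally[parent] += tally.pop(taxon)
            relocated[taxon] = parent

    def resolve(t: int) -> int:
        while t in relocated:
            t = relocated[t]
        return t

    return {q: resolve(t) for q, t in assignments.items()}


def competitive_filter(
    reads: Sequence[tuple[str, float, Sequence[HitRecord]]],
    tree: TaxonomyTree,
    target_genus: int,
) -> list[str]:
    """Reference-versus-database competitive filter.

    ``reads`` holds (read_id, reference bitscore, database hits).  A read is
    retained if its reference bitscore beats the best database hit, or if it
    does not but the LCA of the best-bitscore database hits falls within the
    target genus.
    """
    retained: list[str] = []
    for read_id, ref_score, db_hits in reads:
        if not db_hits:
            retained.append(read_id)
            continue
        best = max(h.bitscore for h in db_hits)
        if ref_score > best:
            retained.append(read_id)
            continue
        best_taxa = [h.taxon_id for h in db_hits if h.bitscore == best]
        if tree.is_within(tree.lca(best_taxa), target_genus):
            retained.append(read_id)
    return retained


def reads_per_mb(n_mapped: int, genome_length: int) -> float:
    """Mapped-read density per megabase of genome sequence."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return n_mapped / (genome_length / 1e6)


def _round2(x: float) -> float:
    """Round half away from zero to two decimals (printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summary_table(
    category_counts: Mapping[str, int],
    n_identified: int,
    n_analysed: int,
) -> pd.DataFrame:
    """Identified-sequence summary with I% (of identified) and A% (of all
    sequences entering the analysis), both rounded to two decimals, rows
    sorted by count descending."""
    if n_identified <= 0 or n_analysed <= 0:
        raise ValueError("denominators must be positive")
    if n_identified > n_analysed:
        raise ValueError("n_identified exceeds n_analysed")
    rows = []
    for name, n in category_counts.items():
        if n > n_identified:
            raise ValueError(f"category {name}: N exceeds n_identified")
        rows.append({
            "taxon": name,
            "N": n,
            "I": _round2(100.0 * n / n_identified),
            "A": _round2(100.0 * n / n_analysed),
        })
    df = pd.DataFrame(rows, columns=["taxon", "N", "I", "A"])
    return df.sort_values("N", ascending=False, kind="stable").reset_index(drop=True)


def unique_mapping_crosstab(
    id_sets: Mapping[str, set[str]],
) -> tuple[dict[str, int], dict[tuple[str, str], int]]:
    """Per-genome counts of reads mapping only there, and pairwise overlaps."""
    genomes = list(id_sets)
    unique: dict[str, int] = {}
    for g in genomes:
        others = set().union(*(id_sets[h] for h in genomes if h != g)) \
            if len(genomes) > 1 else set()
        unique[g] = len(id_sets[g] - others)
    shared = {(a, b): len(id_sets[a] & id_sets[b])
              for i, a in enumerate(genomes) for b in genomes[i + 1:]}
    return unique, shared
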