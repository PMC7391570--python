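"""Taxonomic attribution of enzyme genes by lowest common ancestor.

Each gene's alignment hits against a taxonomy-labelled protein set are
reduced to the *valid matches* — hits whose e-value is within a factor
(default 10×) of the best e-value for that gene — and the gene is placed at
the lowest common ancestor of the matched taxa, MEGAN-style. Genes whose
LCA falls above genus are reported but excluded from genus-level abundance
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .containers import AbundanceMatrix
from .profiling import aggregate_to_features

logger = logging.getLogger(__name__)


class TaxonomyTree:
    """Rooted, rank-labelled taxonomy with ancestor and LCA queries.

    Built from a node table (node_id, parent_id, rank, name); the root is
    the unique node whose parent is itself.
    """

    def __init__(self, nodes: pd.DataFrame):
        self.parent: dict = dict(zip(nodes["node_id"], nodes["parent_id"]))
        self.rank: dict = dict(zip(nodes["node_id"], nodes["rank"]))
        self.name: dict = dict(zip(nodes["node_id"], nodes["name"]))
        if len(self.parent) != len(nodes):
            raise ValueError("duplicate node ids in taxonomy table")
        roots = [n for n, p in self.parent.items() if n == p]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._depth: dict = {self.root: 0}
        for node in self.parent:
            self.depth(node)  # also detects cycles / orphans

    def depth(self, node: str) -> int:
        """Edges from the root; raises KeyError on unknown nodes."""
        chain = []
        cur = node
        while cur not in self._depth:
            chain.append(cur)
            nxt = self.parent.get(cur)
            if nxt is None:
                raise KeyError(f"unknown taxonomy node: {cur}")
            if nxt in chain:
                raise ValueError(f"cycle in taxonomy at node {cur}")
            cur = nxt
        d = self._depth[cur]
        for n in reversed(chain):
            d += 1
            self._depth[n] = d
        return self._depth[node]

    def path_to_root(self, node: str) -> list:
        if node not in self.parent:
            raise KeyError(f"unknown taxonomy node: {node}")
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def lca(self, nodes: Iterable[str]) -> str:
        """Deepest node that is an ancestor-or-self of every input node."""
        nodes = list(nodes)
        if not nodes:
            raise ValueError("lca of an empty node set is undefined")
        cur = nodes[0]
        self.depth(cur)
        for other in nodes[1:]:
            a, b = cur, other
            da, db = self.depth(a), self.depth(b)
            while da > db:
                a, da = self.parent[a], da - 1
            while db > da:
                b, db = self.parent[b], db - 1
            while a != b:
                a, b = self.parent[a], self.parent[b]
            cur = a
        return cur

    def ancestor_at_rank(self, node: str, rank: str) -> Optional[str]:
        for n in self.path_to_root(node):
            if self.rank[n] == rank:
                return n
        return None


@dataclass
class TaxonAssignment:
    gene_id: str
    node_id: Optional[str]
    rank: Optional[str]
    n_valid_matches: int


def valid_matches(hits: pd.DataFrame, factor: float = 10.0) -> pd.DataFrame:
    """Hits whose e-value is within ``factor`` × the gene's best e-value.

    The top hit always qualifies; a top e-value of exactly 0 admits only
    other zero e-values (10 × 0 = 0, handled exactly).
    """
    if hits.empty:
        return hits
    top = hits["evalue"].min()
    return hits[hits["evalue"] <= factor * top]


def assign_taxa(hits: pd.DataFrame, tree: TaxonomyTree,
                subject_taxon: Mapping, factor: float = 10.0) -> dict:
    """Place every gene with mapped hits at the LCA of its valid matches.

    Hits whose subject has no taxon label are skipped (counted in a single
    warning). Returns gene_id -> :class:`TaxonAssignment`.
    """
    mapped = hits["sseqid"].isin(subject_taxon)
    skipped = int((~mapped).sum())
    if skipped:
        logger.warning("skipping %d hits with unmapped subjects", skipped)
    usable = hits[mapped]
    out: dict = {}
    for gene, gene_hits in usable.groupby("qseqid", sort=True):
        valid = valid_matches(gene_hits, factor=factor)
        taxa = {subject_taxon[s] for s in valid["sseqid"]}
        node = tree.lca(taxa)
        out[gene] = TaxonAssignment(gene_id=gene, node_id=node,
                                    rank=tree.rank[node],
                                    n_valid_matches=len(valid))
    return out


def genus_abundance(assignments: Mapping, gene_abund: AbundanceMatrix,
                    tree: TaxonomyTree) -> AbundanceMatrix:
    """Sum gene abundance into genus-level features.

    A gene assigned at or below genus contributes to its genus; a gene whose
    assignment sits above genus is excluded (its placement is too coarse to
    attribute), so genus mass never exceeds total gene mass.
    """
    gene_to_genus = {}
    for gene, asn in assignments.items():
        if asn.node_id is None:
            continue
        genus = tree.ancestor_at_rank(asn.node_id, "genus")
        if genus is not None:
            gene_to_genus[gene] = genus
    return aggregate_to_features(gene_abund, gene_to_genus)


def assignments_table(assignments: Mapping) -> pd.DataFrame:
    rows = [{"gene_id": a.gene_id, "node_id": a.node_id or "",
             "rank": a.rank or "", "n_valid_matches": a.n_valid_matches}
            for a in assignments.values()]
    return pd.DataFrame(rows, columns=["gene_id", "node_id", "rank",
                                       "n_valid_matches"]).sort_values("gene_id")
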