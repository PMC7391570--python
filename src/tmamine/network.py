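"""Thresholded Spearman correlation network across feature universes.

Correlations are computed between the rows of two abundance matrices on the
same samples (rank-transform with midrank ties, then Pearson on the ranks;
two-sided p from the t approximation). Edges survive a BH correction over
the whole tested block at q < 0.05 combined with |rho| > 0.4 (strict), and
are flagged strong at |rho| > 0.6. The genus ↔ enzyme and enzyme ↔ function
edge lists assemble into a tripartite (Sankey-style) network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix
from .enrichment import bh_qvalues

EDGE_COLUMNS = ["source", "target", "rho", "p", "q", "sign", "strong", "tier"]


def spearman_matrix(x: AbundanceMatrix, y: AbundanceMatrix
                    ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p between every row of x and every row of y.

    Constant rows have no rank variation; their correlations are recorded
    as rho = 0 with p = 1.
    """
    if list(x.samples) != list(y.samples):
        only_x = sorted(set(x.samples) - set(y.samples))
        only_y = sorted(set(y.samples) - set(x.samples))
        raise ValueError(
            "sample sets/order differ between matrices: "
            f"only in x: {only_x}; only in y: {only_y}; "
            f"order mismatch: {sorted(x.samples) == sorted(y.samples)}")
    n = len(x.samples)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")

    def _ranked(a: pd.DataFrame) -> tuple:
        ranks = np.apply_along_axis(stats.rankdata, 1, a.to_numpy(dtype=float))
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered ** 2).sum(axis=1))
        constant = norms == 0
        norms[constant] = 1.0
        return centered / norms[:, None], constant

    rx, const_x = _ranked(x.data)
    ry, const_y = _ranked(y.data)
    rho = rx @ ry.T
    rho = np.clip(rho, -1.0, 1.0)
    rho[const_x, :] = 0.0
    rho[:, const_y] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0
    p[const_x, :] = 1.0
    p[:, const_y] = 1.0
    idx, cols = x.data.index, y.data.index
    return (pd.DataFrame(rho, index=idx, columns=cols),
            pd.DataFrame(p, index=idx, columns=cols))


def select_edges(rho: pd.DataFrame, p: pd.DataFrame, alpha: float = 0.05,
                 r_min: float = 0.4, r_strong: float = 0.6) -> pd.DataFrame:
    """BH-correct the whole block, then keep q < alpha and |rho| > r_min.

    Both thresholds are strict. Edges carry a significance tier from the
    q-value ("**" for q < 0.01, "+" for q < alpha) and a ``strong`` flag at
    |rho| > r_strong.
    """
    if rho.shape != p.shape:
        raise ValueError("rho and p blocks must share a shape")
    flat_p = p.to_numpy(dtype=float).ravel()
    if flat_p.size == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    q = bh_qvalues(flat_p).reshape(p.shape)
    rows = []
    rho_v = rho.to_numpy(dtype=float)
    for i, src in enumerate(rho.index):
        for j, tgt in enumerate(rho.columns):
            r = rho_v[i, j]
            if q[i, j] < alpha and abs(r) > r_min:
                rows.append({
                    "source": src, "target": tgt, "rho": r,
                    "p": p.iat[i, j], "q": q[i, j],
                    "sign": "positive" if r > 0 else "negative",
                    "strong": bool(abs(r) > r_strong),
                    "tier": "**" if q[i, j] < 0.01 else "+",
                })
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return edges.sort_values(["source", "target"]).reset_index(drop=True)


@dataclass
class TripartiteNetwork:
    """Genera ↔ enzyme genes ↔ functions with thresholded correlation edges."""

    layers: Tuple[str, str, str] = ("genera", "enzyme_genes", "functions")
    nodes: dict = field(default_factory=dict)  # layer -> ordered node list
    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EDGE_COLUMNS))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for layer in self.layers:
            for node in self.nodes.get(layer, []):
                g.add_node(node, layer=layer)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, rho=row.rho, q=row.q,
                       sign=row.sign, strong=row.strong)
        return g

    def to_node_link(self) -> dict:
        return {
            "layers": list(self.layers),
            "nodes": [{"id": n, "layer": layer}
                      for layer in self.layers for n in self.nodes.get(layer, [])],
            "links": [{"source": r.source, "target": r.target,
                       "weight": abs(r.rho), "sign": r.sign,
                       "strong": bool(r.strong)}
                      for r in self.edges.itertuples(index=False)],
        }


def build_tripartite(genus_edges: pd.DataFrame,
                     function_edges: pd.DataFrame) -> TripartiteNetwork:
    """Assemble the genus–enzyme–function network.

    ``genus_edges`` link genera (source) to enzyme genes (target);
    ``function_edges`` link enzyme genes (source) to functions (target).
    Only genera and functions with at least one enzyme edge appear; node
    order within a layer is by descending edge count, ties by id.
    """
    def _ordered(series: pd.Series) -> List[str]:
        counts = series.value_counts()
        return sorted(counts.index, key=lambda n: (-counts[n], n))

    genera = _ordered(genus_edges["source"]) if len(genus_edges) else []
    functions = _ordered(function_edges["target"]) if len(function_edges) else []
    enzyme_counts: dict = {}
    for series in (genus_edges["target"] if len(genus_edges) else pd.Series(dtype=object),
                   function_edges["source"] if len(function_edges) else pd.Series(dtype=object)):
        for node in series:
            enzyme_counts[node] = enzyme_counts.get(node, 0) + 1
    enzymes = sorted(enzyme_counts, key=lambda n: (-enzyme_counts[n], n))
    edges = pd.concat([genus_edges, function_edges], ignore_index=True) \
        if (len(genus_edges) or len(function_edges)) \
        else pd.DataFrame(columns=EDGE_COLUMNS)
    return TripartiteNetwork(
        nodes={"genera": genera, "enzyme_genes": enzymes, "functions": functions},
        edges=edges,
    )
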