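"""Functional annotation of catalog genes from tabular alignment hits.

Two passes mirror how shotgun catalogs are annotated in practice:

* KEGG ortholog assignment — among hits whose subject carries a KO label and
  whose bit score exceeds 60, the highest-scoring hit's KO wins; the gene
  inherits every module containing that KO.
* TMA-enzyme assignment — among hits to CutC/CntA/GrdH/TorA reference
  proteins passing strict best-hit filters (E-value < 1e-5, identity > 50%,
  query coverage > 50%), the highest-scoring hit's family wins.

Ties on bit score break by smaller e-value, then lexicographically smallest
subject id, so annotation is deterministic for any hit ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .containers import FeatureMaps


@dataclass
class GeneAnnotation:
    """Best-hit functional labels for one catalog gene."""

    gene_id: str
    ko: Optional[str] = None
    modules: frozenset = frozenset()
    enzyme_family: Optional[str] = None
    bit_score: Optional[float] = None
    e_value: Optional[float] = None
    subject_id: Optional[str] = None


def _best_per_gene(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per query: highest bit score, ties by e-value then subject id."""
    ordered = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("qseqid", keep="first")


def assign_kegg(hits: pd.DataFrame, maps: FeatureMaps,
                min_hsp_score: float = 60.0) -> dict:
    """Best-hit KO assignment over hits scoring strictly above ``min_hsp_score``.

    Returns a map gene_id -> :class:`GeneAnnotation`; genes with no
    qualifying hit are absent (unannotated).
    """
    qualifying = hits[(hits["bitscore"] > min_hsp_score)
                      & hits["sseqid"].isin(maps.protein_to_ko)]
    out: dict = {}
    for row in _best_per_gene(qualifying).itertuples(index=False):
        ko = maps.protein_to_ko[row.sseqid]
        out[row.qseqid] = GeneAnnotation(
            gene_id=row.qseqid,
            ko=ko,
            modules=frozenset(maps.ko_to_module.get(ko, frozenset())),
            bit_score=float(row.bitscore),
            e_value=float(row.evalue),
            subject_id=row.sseqid,
        )
    return out


def assign_enzyme(hits: pd.DataFrame, maps: FeatureMaps,
                  max_evalue: float = 1e-5, min_identity: float = 50.0,
                  min_coverage: float = 50.0) -> dict:
    """Best-hit enzyme-family assignment with strict filter inequalities.

    Coverage is computed on the query: 100 × alignment_length / query_length.
    Returns a map gene_id -> family name.
    """
    enz = hits[hits["sseqid"].isin(maps.protein_to_enzyme)].copy()
    if enz.empty:
        return {}
    bad_qlen = enz["qlen"].isna() | (enz["qlen"] <= 0)
    if bad_qlen.any():
        row = enz[bad_qlen].iloc[0]
        raise ValueError(
            f"hit {row['qseqid']} -> {row['sseqid']} lacks a valid query length")
    coverage = 100.0 * enz["length"] / enz["qlen"]
    passing = enz[(enz["evalue"] < max_evalue)
                  & (enz["pident"] > min_identity)
                  & (coverage > min_coverage)]
    best = _best_per_gene(passing)
    return {row.qseqid: maps.protein_to_enzyme[row.sseqid]
            for row in best.itertuples(index=False)}


def annotation_table(kegg: dict, enzyme: dict) -> pd.DataFrame:
    """Combine the two passes into one exportable gene-annotation table."""
    genes = sorted(set(kegg) | set(enzyme))
    rows = []
    for g in genes:
        anno = kegg.get(g)
        rows.append({
            "gene_id": g,
            "ko": anno.ko if anno else "",
            "modules": ";".join(sorted(anno.modules)) if anno else "",
            "enzyme_family": enzyme.get(g, ""),
            "score": anno.bit_score if anno else "",
            "evalue": anno.e_value if anno else "",
        })
    return pd.DataFrame(rows, columns=["gene_id", "ko", "modules",
                                       "enzyme_family", "score", "evalue"])
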