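"""Gene abundance profiling.

Mapped-read counts become gene abundances by dividing each gene's count by
its length in bp (reads mapped to a long gene are not evidence of higher
copy number). Gene abundances are then summed into feature-level matrices
(KEGG ortholog, module, enzyme family, genus) and optionally rescaled to
per-sample proportions within one feature universe at a time.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import RAW_LENGTHNORM, RELATIVE, AbundanceMatrix


def filter_genes(counts: pd.DataFrame, min_total_reads: int = 2) -> pd.DataFrame:
    """Keep genes whose total mapped reads across all samples reach the floor.

    The default of 2 drops singleton mappings; the sample set is never
    changed and an empty result is legal.
    """
    totals = counts.sum(axis=1)
    return counts.loc[totals >= min_total_reads]


def gene_abundance(counts: pd.DataFrame, catalog: pd.DataFrame) -> AbundanceMatrix:
    """Length-normalize counts: abundance(g, s) = count(g, s) / length_bp(g)."""
    lengths = catalog.set_index("gene_id")["length_bp"]
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"genes missing from catalog: {list(missing[:5])}")
    lens = lengths.loc[counts.index].to_numpy(dtype=float)
    data = counts.to_numpy(dtype=float) / lens[:, None]
    return AbundanceMatrix(pd.DataFrame(data, index=counts.index, columns=counts.columns),
                           RAW_LENGTHNORM)


def aggregate_to_features(abund: AbundanceMatrix,
                          assignment: Mapping) -> AbundanceMatrix:
    """Sum gene abundances into features.

    ``assignment`` maps gene id to a feature id or to an iterable of feature
    ids (a gene's KO may belong to several modules). Unassigned genes are
    ignored; mass of assigned genes is conserved per feature.
    """
    rows: dict = {}
    index = abund.data.index
    values = abund.data.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(index)}
    for gene, feats in assignment.items():
        if gene not in pos:
            continue
        if isinstance(feats, str) or not isinstance(feats, Iterable):
            feats = (feats,)
        for feat in feats:
            acc = rows.get(feat)
            if acc is None:
                rows[feat] = values[pos[gene]].copy()
            else:
                acc += values[pos[gene]]
    if not rows:
        data = pd.DataFrame(np.empty((0, len(abund.samples))),
                            index=pd.Index([], name="feature_id"),
                            columns=abund.data.columns)
    else:
        feats = sorted(rows)
        data = pd.DataFrame(np.vstack([rows[f] for f in feats]),
                            index=feats, columns=abund.data.columns)
    return AbundanceMatrix(data, abund.normalization)


def to_relative(abund: AbundanceMatrix) -> AbundanceMatrix:
    """Rescale every sample column to proportions; all-zero columns stay zero."""
    values = abund.data.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    scale = np.where(sums > 0, sums, 1.0)
    return AbundanceMatrix(pd.DataFrame(values / scale, index=abund.data.index,
                                        columns=abund.data.columns), RELATIVE)
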