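"""Shared in-memory containers for the pipeline stages.

Tabular data travels as :class:`pandas.DataFrame` with documented schemas;
the only wrapper type is :class:`AbundanceMatrix`, which carries the
normalization state alongside its features × samples values so downstream
stages can refuse the wrong form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: normalization tags an AbundanceMatrix may carry
RAW_LENGTHNORM = "raw_lengthnorm"
RELATIVE = "relative"

#: BLAST tabular (outfmt 6) columns, plus query length as 13th column
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen",
]

#: the four bacterial TMA-synthesis enzyme families
ENZYME_FAMILIES = ("CutC", "CntA", "GrdH", "TorA")


@dataclass
class AbundanceMatrix:
    """Features × samples abundance values with a normalization tag.

    ``data`` is indexed by feature id with one column per sample id. Values
    are non-negative reals: either length-normalized read counts
    (``raw_lengthnorm``) or per-sample proportions (``relative``, every
    non-zero column summing to one).
    """

    data: pd.DataFrame
    normalization: str = RAW_LENGTHNORM

    def __post_init__(self) -> None:
        if self.normalization not in (RAW_LENGTHNORM, RELATIVE):
            raise ValueError(f"unknown normalization tag: {self.normalization!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and (values < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.normalization == RELATIVE and values.size:
            sums = values.sum(axis=0)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0.0))
            if bad.any():
                cols = list(self.data.columns[bad])
                raise ValueError(f"relative columns must sum to 1: {cols}")

    @property
    def features(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    def subset_samples(self, samples) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.loc[:, list(samples)], self.normalization)


@dataclass
class FeatureMaps:
    """Reference maps connecting proteins, KEGG orthologs, modules and taxa.

    ``protein_to_ko`` and ``protein_to_enzyme`` label the functional
    reference proteins; ``ko_to_module`` is many-to-many (a KO may sit in
    several modules); ``protein_to_taxon`` labels the taxonomy reference
    proteins with tree node ids.
    """

    protein_to_ko: dict = field(default_factory=dict)
    ko_to_module: dict = field(default_factory=dict)  # ko -> frozenset of modules
    protein_to_enzyme: dict = field(default_factory=dict)
    protein_to_taxon: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {f for f in self.protein_to_enzyme.values() if f not in ENZYME_FAMILIES}
        if bad:
            raise ValueError(f"unknown enzyme families: {sorted(bad)}")
        self.ko_to_module = {k: frozenset(v) for k, v in self.ko_to_module.items()}
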