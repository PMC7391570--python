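"""Readers and writers for the plain-text table formats.

All tables are TSV. Alignment hits use headerless BLAST outfmt-6 columns
plus query length; abundance matrices carry a ``# normalization:`` header
comment so the tag survives a round trip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .containers import HIT_COLUMNS, AbundanceMatrix, FeatureMaps

_MAP_NAMES = ("protein_ko", "ko_module", "protein_enzyme", "protein_taxon")


def write_gene_catalog(catalog: pd.DataFrame, path) -> None:
    catalog[["gene_id", "length_bp"]].to_csv(path, sep="\t", index=False)


def read_gene_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    df["length_bp"] = df["length_bp"].astype(int)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.astype(int)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta[["sample_id", "group", "subtype"]].to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_hits(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS,
                     dtype={"qseqid": str, "sseqid": str})
    return df


def write_taxonomy(nodes: pd.DataFrame, path) -> None:
    nodes[["node_id", "parent_id", "rank", "name"]].to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_feature_maps(maps: FeatureMaps, path) -> None:
    rows = []
    for protein, ko in sorted(maps.protein_to_ko.items()):
        rows.append(("protein_ko", protein, ko))
    for ko, modules in sorted(maps.ko_to_module.items()):
        for module in sorted(modules):
            rows.append(("ko_module", ko, module))
    for protein, fam in sorted(maps.protein_to_enzyme.items()):
        rows.append(("protein_enzyme", protein, fam))
    for protein, node in sorted(maps.protein_to_taxon.items()):
        rows.append(("protein_taxon", protein, node))
    pd.DataFrame(rows, columns=["map", "key", "value"]).to_csv(path, sep="\t", index=False)


def read_feature_maps(path) -> FeatureMaps:
    df = pd.read_csv(path, sep="\t", dtype=str)
    unknown = set(df["map"]) - set(_MAP_NAMES)
    if unknown:
        raise ValueError(f"unknown map names in {path}: {sorted(unknown)}")
    ko_to_module: dict = {}
    for _, row in df[df["map"] == "ko_module"].iterrows():
        ko_to_module.setdefault(row["key"], set()).add(row["value"])
    pick = lambda name: dict(zip(df.loc[df["map"] == name, "key"],
                                 df.loc[df["map"] == name, "value"]))
    return FeatureMaps(
        protein_to_ko=pick("protein_ko"),
        ko_to_module=ko_to_module,
        protein_to_enzyme=pick("protein_enzyme"),
        protein_to_taxon=pick("protein_taxon"),
    )


def write_abundance(abund: AbundanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# normalization: {abund.normalization}\n")
        abund.data.to_csv(fh, sep="\t", index_label="feature_id")


def read_abundance(path) -> AbundanceMatrix:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# normalization:"):
            raise ValueError(f"{path}: missing normalization header comment")
        tag = first.split(":", 1)[1].strip()
        data = pd.read_csv(fh, sep="\t", index_col="feature_id")
    return AbundanceMatrix(data, tag)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def file_manifest(directory, names) -> dict:
    """Checksum manifest for a set of files under ``directory``."""
    directory = Path(directory)
    entries = []
    for name in sorted(names):
        p = directory / name
        entries.append({"name": name, "sha256": sha256_of(p), "bytes": p.stat().st_size})
    return {"files": entries}


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
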