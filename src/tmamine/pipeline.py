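"""End-to-end orchestration: counts → abundances → annotations → enrichment
→ correlation network, with a config file and a reproducible run manifest.

Stage order follows the analysis it implements: filter low-evidence genes,
length-normalize, annotate (KO/module/enzyme), attribute enzyme genes to
genera by LCA, build per-universe relative abundance, test the three
contrasts (CTR vs AF, PAF vs psAF, Pers<12m vs Pers>12m), then threshold
Spearman correlations into the genus–enzyme–function network.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, annotation, enrichment, io, network, profiling, taxonomy
from .containers import AbundanceMatrix
from .enrichment import DEFAULT_CONTRASTS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths, stage thresholds and output location for one run."""

    gene_catalog: str
    read_counts: str
    sample_metadata: str
    kegg_hits: str
    nr_hits: str
    taxonomy: str
    feature_maps: str
    output_dir: str
    min_total_reads: int = 2
    min_hsp_score: float = 60.0
    max_evalue: float = 1e-5
    min_identity: float = 50.0
    min_coverage: float = 50.0
    lca_factor: float = 10.0
    or_high: float = 2.0
    or_low: float = 0.5
    alpha: float = 0.05
    r_min: float = 0.4
    r_strong: float = 0.6
    or_orientation: str = "af_numerator"  # or "printed"
    seed: int = 0

    def validate(self) -> None:
        for name in ("min_hsp_score", "max_evalue", "min_identity", "min_coverage",
                     "lca_factor", "or_high", "or_low", "alpha", "r_min", "r_strong"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.or_low >= self.or_high:
            raise ValueError(f"or_low ({self.or_low}) must be < or_high ({self.or_high})")
        if self.or_orientation not in ("af_numerator", "printed"):
            raise ValueError(f"unknown or_orientation: {self.or_orientation!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles to the tables a run produced."""

    gene_abundance: AbundanceMatrix
    universes: dict                      # name -> relative AbundanceMatrix
    annotations: pd.DataFrame
    taxon_assignments: pd.DataFrame
    enrichment: dict                     # (universe, contrast) -> DataFrame
    edges: dict                          # block name -> DataFrame
    tripartite: network.TripartiteNetwork
    manifest: dict


def _orientation(config: PipelineConfig) -> str:
    return "case_numerator" if config.or_orientation == "af_numerator" else "printed"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = io.read_gene_catalog(config.gene_catalog)
    counts = io.read_counts(config.read_counts)
    meta = io.read_metadata(config.sample_metadata)
    kegg_hits = io.read_hits(config.kegg_hits)
    nr_hits = io.read_hits(config.nr_hits)
    tree = taxonomy.TaxonomyTree(io.read_taxonomy(config.taxonomy))
    maps = io.read_feature_maps(config.feature_maps)

    kept = profiling.filter_genes(counts, config.min_total_reads)
    logger.info("gene filter: %d of %d genes kept (total reads >= %d)",
                len(kept), len(counts), config.min_total_reads)
    gene_abund = profiling.gene_abundance(kept, catalog)

    kegg = annotation.assign_kegg(kegg_hits, maps, config.min_hsp_score)
    enzymes = annotation.assign_enzyme(kegg_hits, maps, config.max_evalue,
                                       config.min_identity, config.min_coverage)
    logger.info("annotation: %d KO-annotated, %d enzyme-annotated genes",
                len(kegg), len(enzymes))
    annotations = annotation.annotation_table(kegg, enzymes)

    assignments = taxonomy.assign_taxa(nr_hits, tree, maps.protein_to_taxon,
                                       config.lca_factor)
    assignments_df = taxonomy.assignments_table(assignments)
    logger.info("taxon attribution: %d genes placed", len(assignments))

    # per-universe abundance matrices (relative within each universe)
    ko_map = {g: a.ko for g, a in kegg.items()}
    module_map = {g: a.modules for g, a in kegg.items() if a.modules}
    enzyme_abund_genes = AbundanceMatrix(
        gene_abund.data.loc[gene_abund.data.index.intersection(list(enzymes))],
        gene_abund.normalization)
    universes = {
        "ko": profiling.to_relative(profiling.aggregate_to_features(gene_abund, ko_map)),
        "module": profiling.to_relative(profiling.aggregate_to_features(gene_abund, module_map)),
        "enzyme": profiling.to_relative(
            profiling.aggregate_to_features(gene_abund, {g: f for g, f in enzymes.items()})),
        "genus": profiling.to_relative(
            taxonomy.genus_abundance(assignments, enzyme_abund_genes, tree)),
    }

    results: dict = {}
    for uni_name, abund in universes.items():
        if abund.data.empty:
            continue
        for contrast in DEFAULT_CONTRASTS:
            table = enrichment.enrichment_table(
                abund, meta, contrast, or_high=config.or_high, or_low=config.or_low,
                orientation=_orientation(config))
            results[(uni_name, contrast.name)] = table

    # correlation blocks: genera vs enzyme genes; enzyme genes vs functions
    edges: dict = {}
    genus_edges = pd.DataFrame(columns=network.EDGE_COLUMNS)
    function_edges = pd.DataFrame(columns=network.EDGE_COLUMNS)
    enzyme_rel = universes["enzyme"]
    if not enzyme_rel.data.empty:
        if not universes["genus"].data.empty:
            rho, p = network.spearman_matrix(universes["genus"], enzyme_rel)
            genus_edges = network.select_edges(rho, p, config.alpha,
                                               config.r_min, config.r_strong)
        func = pd.concat([universes["ko"].data, universes["module"].data])
        if not func.empty:
            # each function row keeps its own per-universe relative scale;
            # Spearman is rank-based per row, so mixing KO and module rows in
            # one block is safe (tagged raw to skip the column-sum check)
            func_abund = AbundanceMatrix(func, "raw_lengthnorm")
            rho, p = network.spearman_matrix(enzyme_rel, func_abund)
            function_edges = network.select_edges(rho, p, config.alpha,
                                                  config.r_min, config.r_strong)
    edges["genus_enzyme"] = genus_edges
    edges["enzyme_function"] = function_edges
    tri = network.build_tripartite(genus_edges, function_edges)

    # ---- write outputs ----
    io.write_abundance(gene_abund, outdir / "gene_abundance.tsv")
    annotations.to_csv(outdir / "gene_annotations.tsv", sep="\t", index=False)
    assignments_df.to_csv(outdir / "taxon_assignments.tsv", sep="\t", index=False)
    written = ["gene_abundance.tsv", "gene_annotations.tsv", "taxon_assignments.tsv"]
    for uni_name, abund in universes.items():
        if abund.data.empty:
            continue
        name = f"abundance_{uni_name}.tsv"
        io.write_abundance(abund, outdir / name)
        written.append(name)
        zname = f"zscore_{uni_name}.tsv"
        enrichment.zscore_profile(abund).to_csv(outdir / zname, sep="\t",
                                                index_label="feature_id")
        written.append(zname)
    for (uni_name, contrast_name), table in results.items():
        name = f"enrichment_{uni_name}_{contrast_name}.tsv"
        table.to_csv(outdir / name, sep="\t")
        written.append(name)
    for block, edge_df in edges.items():
        name = f"edges_{block}.tsv"
        edge_df.to_csv(outdir / name, sep="\t", index=False)
        written.append(name)
    io.write_json(tri.to_node_link(), outdir / "tripartite_network.json")
    written.append("tripartite_network.json")

    manifest = {
        "config": asdict(config),
        "versions": {"tmamine": __version__,
                     "pandas": pd.__version__},
        "stage_counts": {
            "genes_input": int(len(counts)),
            "genes_kept": int(len(kept)),
            "genes_ko_annotated": int(len(kegg)),
            "genes_enzyme_annotated": int(len(enzymes)),
            "genes_taxon_assigned": int(len(assignments)),
            "edges_genus_enzyme": int(len(genus_edges)),
            "edges_enzyme_function": int(len(function_edges)),
        },
        **io.file_manifest(outdir, written),
    }
    io.write_json(manifest, outdir / "run_manifest.json")
    # timestamp isolated outside the checksummed manifest for reproducibility
    io.write_json({"completed_utc": datetime.now(timezone.utc).isoformat()},
                  outdir / "run_timestamp.json")
    return PipelineResult(gene_abund, universes, annotations, assignments_df,
                          results, edges, tri, manifest)
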