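"""Synthetic metagenomic study generator with planted effects.

Emulates every input the analysis consumes — a gene catalog, a genes ×
samples mapped-read-count matrix, sample metadata, two BLAST-style hit
tables (functional reference and taxonomy-labelled reference), a taxonomy
tree and the protein/KO/module/enzyme feature maps — together with the
ground truth needed to score recovery.

Count model: the expected count of gene *g* in sample *s* is

    depth_s × (length_g / 1000) × reads_per_kb × expr_g × effect_gs

with ``expr_g`` log-normal (gene baseline), ``depth_s`` log-normal
(sequencing depth), and negative-binomial observation noise. Planted
effects multiply the mean of the affected genes' counts in one study arm.

Alignment hits come in true and decoy flavors. Every annotated gene gets
one true functional hit that passes the annotation filters and, for enzyme
genes, true taxonomic hits to its own genus inside the 10× e-value window.
Decoys either fail an annotation filter (low bit score, unlabelled subject,
weak identity/coverage/e-value) or point at a wrong genus with an e-value
inflated beyond the valid-match window, so each downstream filter is
exercised independently.

A single NumPy generator stream drives all randomness in a fixed order
(lengths → KO assignment → genus assignment → enzyme-gene choice →
baselines → depths → counts → functional hits → taxonomic hits), so a fixed
seed yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import io
from .containers import ENZYME_FAMILIES, FeatureMaps
from .taxonomy import TaxonomyTree

_KEGG_PROTEINS_PER_KO = 2
_ENZYME_PROTEINS_PER_FAMILY = 3
_NR_PROTEINS_PER_GENUS = 3


@dataclass(frozen=True)
class PlantedFeature:
    """A KEGG ortholog whose genes get a fold-change in one study arm."""

    feature_id: str
    fold_change: float
    direction: str = "AF"  # arm whose mean is multiplied: "AF" or "CTR"


@dataclass(frozen=True)
class PlantedTaxon:
    """A genus harboring an enzyme family, enriched in the AF arm."""

    genus: str
    enzyme_family: str
    fold_change: float


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror the cohort the pipeline targets: 50 controls and 50 AF
    patients, the AF arm split 30/12/8 into paroxysmal, persistent < 12
    months and persistent > 12 months.
    """

    n_ctr: int = 50
    n_af: int = 50
    af_subtype_split: Tuple[float, float, float] = (0.6, 0.24, 0.16)
    n_genes: int = 600
    gene_length_range: Tuple[int, int] = (300, 3000)
    n_kos: int = 200
    n_modules: int = 25
    n_genera: int = 40
    planted_features: Tuple[PlantedFeature, ...] = ()
    planted_taxa: Tuple[PlantedTaxon, ...] = ()
    decoy_hit_rate: float = 0.1
    dispersion: float = 8.0        # negative-binomial shape; larger = less noise
    baseline_sigma: float = 1.0    # sd of log gene baseline
    depth_sigma: float = 0.15      # sd of log per-sample depth factor
    reads_per_kb: float = 30.0     # expected reads per kb at unit baseline/depth
    enzyme_genes_per_taxon: int = 3
    background_enzyme_genes: int = 2  # extra enzyme genes per family, random genera
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "planted_features",
                           tuple(PlantedFeature(*f) if not isinstance(f, PlantedFeature)
                                 else f for f in self.planted_features))
        object.__setattr__(self, "planted_taxa",
                           tuple(PlantedTaxon(*t) if not isinstance(t, PlantedTaxon)
                                 else t for t in self.planted_taxa))
        for name in ("n_ctr", "n_af", "n_genes", "n_kos", "n_modules", "n_genera"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.af_subtype_split) - 1.0) > 1e-9:
            raise ValueError("af_subtype_split must sum to 1")
        if self.gene_length_range[0] < 1 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be a positive interval")
        if not 0 <= self.decoy_hit_rate <= 1:
            raise ValueError("decoy_hit_rate must be in [0, 1]")
        if self.dispersion <= 0 or self.reads_per_kb <= 0:
            raise ValueError("dispersion and reads_per_kb must be positive")
        for pf in self.planted_features:
            if pf.fold_change <= 0:
                raise ValueError(f"fold_change must be > 0 for {pf.feature_id}")
            if pf.direction not in ("AF", "CTR"):
                raise ValueError(f"direction must be AF or CTR for {pf.feature_id}")
        for pt in self.planted_taxa:
            if pt.fold_change <= 0:
                raise ValueError(f"fold_change must be > 0 for {pt.genus}")
            if pt.enzyme_family not in ENZYME_FAMILIES:
                raise ValueError(f"unknown enzyme family: {pt.enzyme_family}")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream recovery."""

    feature_effects: dict = field(default_factory=dict)  # feature -> AF:CTR mean ratio
    gene_feature_map: dict = field(default_factory=dict)  # gene -> (ko, modules, enzyme|None)
    gene_taxon_map: dict = field(default_factory=dict)    # gene -> genus node id
    enriched_taxa: set = field(default_factory=set)


@dataclass
class StudyBundle:
    """All generated tables plus ground truth and the config that made them."""

    catalog: pd.DataFrame
    counts: pd.DataFrame
    metadata: pd.DataFrame
    kegg_hits: pd.DataFrame
    nr_hits: pd.DataFrame
    taxonomy: pd.DataFrame
    maps: FeatureMaps
    truth: GroundTruth
    config: SimulationConfig

    def taxonomy_tree(self) -> TaxonomyTree:
        return TaxonomyTree(self.taxonomy)


def ko_id(i: int) -> str:
    return f"K{i + 1:05d}"


def module_id(i: int) -> str:
    return f"M{i + 1:05d}"


def genus_id(i: int) -> str:
    return f"g{i + 1:03d}"


def _subtype_counts(n_af: int, split: Tuple[float, float, float]) -> list:
    # largest-remainder rounding so counts always total n_af
    raw = [p * n_af for p in split]
    counts = [math.floor(r) for r in raw]
    remainders = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(n_af - sum(counts)):
        counts[remainders[i % 3]] += 1
    return counts


def _make_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = [(f"CTR{i + 1:03d}", "CTR", "none") for i in range(config.n_ctr)]
    n_paf, n_lt, n_gt = _subtype_counts(config.n_af, config.af_subtype_split)
    subtypes = ["PAF"] * n_paf + ["PersLt12m"] * n_lt + ["PersGt12m"] * n_gt
    rows += [(f"AF{i + 1:03d}", "AF", subtypes[i]) for i in range(config.n_af)]
    return pd.DataFrame(rows, columns=["sample_id", "group", "subtype"])


def _make_taxonomy(config: SimulationConfig) -> pd.DataFrame:
    n_phyla = min(4, config.n_genera)
    rows = [("root", "root", "root", "root")]
    for p in range(n_phyla):
        rows.append((f"p{p + 1:02d}", "root", "phylum", f"Phylum_{p + 1:02d}"))
    for g in range(config.n_genera):
        phylum = f"p{(g % n_phyla) + 1:02d}"
        rows.append((genus_id(g), phylum, "genus", f"Genus_{g + 1:03d}"))
    return pd.DataFrame(rows, columns=["node_id", "parent_id", "rank", "name"])


def _make_maps(config: SimulationConfig) -> FeatureMaps:
    protein_to_ko = {}
    ko_to_module: dict = {}
    for k in range(config.n_kos):
        ko = ko_id(k)
        for j in range(_KEGG_PROTEINS_PER_KO):
            protein_to_ko[f"KP_{ko}_{j + 1}"] = ko
        modules = {module_id(k % config.n_modules)}
        if k % 7 == 0:  # some KOs sit in two modules: membership is many-to-many
            modules.add(module_id((k + 1) % config.n_modules))
        ko_to_module[ko] = modules
    protein_to_enzyme = {f"EP_{fam}_{j + 1}": fam
                         for fam in ENZYME_FAMILIES
                         for j in range(_ENZYME_PROTEINS_PER_FAMILY)}
    protein_to_taxon = {f"NR_{genus_id(g)}_{j + 1}": genus_id(g)
                        for g in range(config.n_genera)
                        for j in range(_NR_PROTEINS_PER_GENUS)}
    return FeatureMaps(protein_to_ko, ko_to_module, protein_to_enzyme,
                       protein_to_taxon)


def _hit_row(gene, subject, pident, alen, evalue, bitscore, qlen):
    return {"qseqid": gene, "sseqid": subject, "pident": round(float(pident), 2),
            "length": int(alen), "mismatch": int(alen * (100 - pident) / 100),
            "gapopen": 0, "qstart": 1, "qend": int(alen), "sstart": 1,
            "send": int(alen), "evalue": float(evalue),
            "bitscore": round(float(bitscore), 1), "qlen": int(qlen)}


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate a complete synthetic study; deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    genes = [f"gene_{i + 1:06d}" for i in range(config.n_genes)]
    samples_meta = _make_metadata(config)
    samples = samples_meta["sample_id"].tolist()
    af_mask = (samples_meta["group"] == "AF").to_numpy()
    taxonomy = _make_taxonomy(config)
    maps = _make_maps(config)

    planted_ids = {pf.feature_id for pf in config.planted_features}
    universe = {ko_id(k) for k in range(config.n_kos)}
    missing = planted_ids - universe
    if missing:
        raise ValueError(f"planted features outside the feature universe: {sorted(missing)}")
    genus_universe = {genus_id(g) for g in range(config.n_genera)}
    missing_taxa = {pt.genus for pt in config.planted_taxa} - genus_universe
    if missing_taxa:
        raise ValueError(f"planted taxa outside the genus universe: {sorted(missing_taxa)}")

    # --- deterministic draw order starts here ---
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, config.n_genes)
    ko_assign = rng.permutation(np.arange(config.n_genes) % config.n_kos)
    genus_assign = rng.integers(0, config.n_genera, config.n_genes)

    # enzyme genes: planted genera first, then background families
    enzyme_of_gene: dict = {}
    for pt in config.planted_taxa:
        g_idx = int(pt.genus[1:]) - 1
        candidates = np.flatnonzero((genus_assign == g_idx)
                                    & ~np.isin(np.arange(config.n_genes),
                                               list(enzyme_of_gene)))
        if len(candidates) == 0:
            raise ValueError(f"planted genus {pt.genus} has no genes to host "
                             f"{pt.enzyme_family}")
        take = min(config.enzyme_genes_per_taxon, len(candidates))
        chosen = rng.choice(candidates, size=take, replace=False)
        for c in chosen:
            enzyme_of_gene[int(c)] = pt.enzyme_family
    planted_genus_idx = {int(pt.genus[1:]) - 1 for pt in config.planted_taxa}
    for fam in ENZYME_FAMILIES:
        pool = np.flatnonzero(~np.isin(genus_assign, list(planted_genus_idx))
                              & ~np.isin(np.arange(config.n_genes),
                                         list(enzyme_of_gene)))
        take = min(config.background_enzyme_genes, len(pool))
        if take:
            for c in rng.choice(pool, size=take, replace=False):
                enzyme_of_gene[int(c)] = fam

    expr = rng.lognormal(0.0, config.baseline_sigma, config.n_genes)
    depth = rng.lognormal(0.0, config.depth_sigma, len(samples))

    # planted effects multiply the mean counts of the affected genes/arm
    effect = np.ones((config.n_genes, len(samples)))
    feature_effects: dict = {}
    for pf in config.planted_features:
        rows = ko_assign == (int(pf.feature_id[1:]) - 1)
        cols = af_mask if pf.direction == "AF" else ~af_mask
        effect[np.ix_(rows, cols)] *= pf.fold_change
        feature_effects[pf.feature_id] = (pf.fold_change if pf.direction == "AF"
                                          else 1.0 / pf.fold_change)
    for pt in config.planted_taxa:
        g_idx = int(pt.genus[1:]) - 1
        rows = np.array([enzyme_of_gene.get(i) == pt.enzyme_family
                         and genus_assign[i] == g_idx
                         for i in range(config.n_genes)])
        effect[np.ix_(rows, af_mask)] *= pt.fold_change

    mean = (depth[None, :] * (lengths / 1000.0)[:, None] * config.reads_per_kb
            * expr[:, None] * effect)
    k = config.dispersion
    counts = rng.negative_binomial(k, k / (k + mean))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=samples)

    # --- functional hits: one true KO hit per gene, plus enzyme hits ---
    kegg_rows = []
    for i, gene in enumerate(genes):
        ko = ko_id(int(ko_assign[i]))
        subj = f"KP_{ko}_{rng.integers(1, _KEGG_PROTEINS_PER_KO + 1)}"
        qlen = int(lengths[i])
        alen = max(1, int(rng.uniform(0.6, 0.95) * qlen))
        kegg_rows.append(_hit_row(gene, subj, rng.uniform(60, 95), alen,
                                  10.0 ** rng.uniform(-50, -10),
                                  rng.uniform(80, 300), qlen))
        if rng.random() < config.decoy_hit_rate:
            # decoy flavor A: fails the bit-score filter or lacks a KO label
            if rng.random() < 0.5:
                subj_d = f"KP_{ko_id(int(rng.integers(config.n_kos)))}_1"
                score, ev = rng.uniform(20, 59), rng.uniform(1e-3, 1.0)
            else:
                subj_d = f"XP_{int(rng.integers(10000)):05d}"  # unlabelled subject
                score, ev = rng.uniform(80, 200), 10.0 ** rng.uniform(-20, -5)
            alen_d = max(1, int(rng.uniform(0.3, 0.9) * qlen))
            kegg_rows.append(_hit_row(gene, subj_d, rng.uniform(30, 60), alen_d,
                                      ev, score, qlen))
    for i in sorted(enzyme_of_gene):
        fam = enzyme_of_gene[i]
        qlen = int(lengths[i])
        subj = f"EP_{fam}_{rng.integers(1, _ENZYME_PROTEINS_PER_FAMILY + 1)}"
        alen = max(1, int(math.ceil(rng.uniform(0.55, 0.95) * qlen)))
        kegg_rows.append(_hit_row(genes[i], subj, rng.uniform(55, 95), alen,
                                  10.0 ** rng.uniform(-30, -8),
                                  rng.uniform(100, 400), qlen))
    for i in range(config.n_genes):  # enzyme decoys: each fails one strict filter
        if rng.random() < config.decoy_hit_rate:
            fam = ENZYME_FAMILIES[int(rng.integers(4))]
            subj = f"EP_{fam}_{rng.integers(1, _ENZYME_PROTEINS_PER_FAMILY + 1)}"
            qlen = int(lengths[i])
            mode = int(rng.integers(3))
            pident = rng.uniform(20, 49) if mode == 0 else rng.uniform(55, 95)
            cov = rng.uniform(0.10, 0.49) if mode == 1 else rng.uniform(0.55, 0.95)
            ev = rng.uniform(2e-5, 1e-2) if mode == 2 else 10.0 ** rng.uniform(-30, -8)
            alen = max(1, int(cov * qlen))
            kegg_rows.append(_hit_row(genes[i], subj, pident, alen, ev,
                                      rng.uniform(150, 500), qlen))
    kegg_hits = pd.DataFrame(kegg_rows)

    # --- taxonomic hits for enzyme genes: own genus inside the 10x window ---
    nr_rows = []
    for i in sorted(enzyme_of_gene):
        gene, qlen = genes[i], int(lengths[i])
        genus = genus_id(int(genus_assign[i]))
        n_true = int(rng.integers(1, _NR_PROTEINS_PER_GENUS + 1))
        subjects = rng.choice([f"NR_{genus}_{j + 1}" for j in range(_NR_PROTEINS_PER_GENUS)],
                              size=n_true, replace=False)
        e0 = 10.0 ** rng.uniform(-40, -15)
        evs = e0 * np.concatenate([[1.0], rng.uniform(1.0, 9.0, n_true - 1)])
        for subj, ev in zip(subjects, evs):
            alen = max(1, int(rng.uniform(0.6, 0.95) * qlen))
            nr_rows.append(_hit_row(gene, subj, rng.uniform(60, 95), alen, ev,
                                    rng.uniform(100, 400), qlen))
        if rng.random() < config.decoy_hit_rate:
            # taxonomy-conflicting decoy, inflated beyond the 10x window
            wrong = int(rng.integers(config.n_genera))
            if wrong == int(genus_assign[i]):
                wrong = (wrong + 1) % config.n_genera
            subj = f"NR_{genus_id(wrong)}_{rng.integers(1, _NR_PROTEINS_PER_GENUS + 1)}"
            ev = e0 * rng.uniform(50.0, 1e4)
            alen = max(1, int(rng.uniform(0.4, 0.9) * qlen))
            nr_rows.append(_hit_row(gene, subj, rng.uniform(50, 90), alen, ev,
                                    rng.uniform(60, 200), qlen))
    nr_hits = pd.DataFrame(nr_rows) if nr_rows else pd.DataFrame(
        columns=list(kegg_hits.columns))

    truth = GroundTruth(
        feature_effects=feature_effects,
        gene_feature_map={genes[i]: (ko_id(int(ko_assign[i])),
                                     tuple(sorted(maps.ko_to_module[ko_id(int(ko_assign[i]))])),
                                     enzyme_of_gene.get(i))
                          for i in range(config.n_genes)},
        gene_taxon_map={genes[i]: genus_id(int(genus_assign[i]))
                        for i in range(config.n_genes)},
        enriched_taxa={pt.genus for pt in config.planted_taxa if pt.fold_change != 1.0},
    )
    catalog = pd.DataFrame({"gene_id": genes, "length_bp": lengths.astype(int)})
    return StudyBundle(catalog, counts_df, samples_meta, kegg_hits, nr_hits,
                       taxonomy, maps, truth, config)


BUNDLE_FILES = {
    "gene_catalog.tsv": ("catalog", io.write_gene_catalog),
    "read_counts.tsv": ("counts", io.write_counts),
    "sample_metadata.tsv": ("metadata", io.write_metadata),
    "kegg_hits.tsv": ("kegg_hits", io.write_hits),
    "nr_hits.tsv": ("nr_hits", io.write_hits),
    "taxonomy.tsv": ("taxonomy", io.write_taxonomy),
    "feature_maps.tsv": ("maps", io.write_feature_maps),
}


def write_fixture_bundle(bundle: StudyBundle, directory) -> dict:
    """Serialize all seven tables plus a checksum manifest (manifest.json)."""
    if len(bundle.metadata) == 0:
        raise ValueError("sample_metadata.tsv would be empty: no samples to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, (attr, writer) in BUNDLE_FILES.items():
        try:
            writer(getattr(bundle, attr), directory / name)
        except OSError as exc:
            raise OSError(f"failed writing {directory / name}: {exc}") from exc
    manifest = io.file_manifest(directory, BUNDLE_FILES)
    io.write_json(manifest, directory / "manifest.json")
    return manifest


def read_fixture_bundle(directory) -> StudyBundle:
    """Re-read a written bundle (ground truth and config are not serialized)."""
    directory = Path(directory)
    return StudyBundle(
        catalog=io.read_gene_catalog(directory / "gene_catalog.tsv"),
        counts=io.read_counts(directory / "read_counts.tsv"),
        metadata=io.read_metadata(directory / "sample_metadata.tsv"),
        kegg_hits=io.read_hits(directory / "kegg_hits.tsv"),
        nr_hits=io.read_hits(directory / "nr_hits.tsv"),
        taxonomy=io.read_taxonomy(directory / "taxonomy.tsv"),
        maps=io.read_feature_maps(directory / "feature_maps.tsv"),
        truth=GroundTruth(),
        config=None,
    )


def example_study_config(seed: int = 0, fold: float = 4.0) -> SimulationConfig:
    """The canonical planted-effect study: 12 enriched orthologs and one
    enzyme-harboring genus per family, all at the given fold in the AF arm."""
    planted_features = tuple(PlantedFeature(ko_id(k), fold, "AF") for k in range(12))
    planted_taxa = tuple(PlantedTaxon(genus_id(g), fam, fold)
                         for g, fam in enumerate(ENZYME_FAMILIES))
    return SimulationConfig(planted_features=planted_features,
                            planted_taxa=planted_taxa, seed=seed)


def null_study_config(seed: int = 0) -> SimulationConfig:
    """Same design with nothing planted (all fold changes 1)."""
    return SimulationConfig(seed=seed)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
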