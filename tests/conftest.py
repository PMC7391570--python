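"""Shared fixtures: synthetic study bundles and small toy tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import tmamine as tm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_bundle():
    """The canonical planted study: 50+50 samples, 12 orthologs and 4
    enzyme-harboring genera planted at fold 4."""
    return tm.simulate_study(tm.example_study_config(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A fast config for determinism / round-trip checks."""
    return tm.SimulationConfig(
        n_ctr=6, n_af=6, n_genes=80, n_kos=20, n_modules=5, n_genera=8,
        planted_features=(tm.PlantedFeature("K00003", 4.0, "AF"),),
        planted_taxa=(tm.PlantedTaxon("g002", "CutC", 4.0),),
        seed=7,
    )


@pytest.fixture
def toy_abundance():
    """3 features × 4 samples with easy hand-checkable sums."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [0.0, 1.0, 1.0, 2.0],
         [3.0, 1.0, 0.0, 2.0]],
        index=["f1", "f2", "f3"], columns=["s1", "s2", "s3", "s4"])
    return tm.AbundanceMatrix(data)


@pytest.fixture
def toy_tree():
    """root -> (p1 -> g1, g2; p2 -> g3)."""
    nodes = pd.DataFrame(
        [("root", "root", "root", "root"),
         ("p1", "root", "phylum", "P1"),
         ("p2", "root", "phylum", "P2"),
         ("g1", "p1", "genus", "G1"),
         ("g2", "p1", "genus", "G2"),
         ("g3", "p2", "genus", "G3")],
        columns=["node_id", "parent_id", "rank", "name"])
    return tm.TaxonomyTree(nodes)


def make_hit(qseqid, sseqid, pident=80.0, length=500, evalue=1e-20,
             bitscore=200.0, qlen=1000):
    return {"qseqid": qseqid, "sseqid": sseqid, "pident": pident,
            "length": length, "mismatch": 0, "gapopen": 0, "qstart": 1,
            "qend": length, "sstart": 1, "send": length, "evalue": evalue,
            "bitscore": bitscore, "qlen": qlen}


@pytest.fixture
def hit_factory():
    return make_hit


def random_abundance(rng, n_features=8, n_samples=10, positive=True):
    low = 0.1 if positive else 0.0
    data = rng.uniform(low, 1.0, size=(n_features, n_samples))
    return tm.AbundanceMatrix(pd.DataFrame(
        data, index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)]))


def balanced_metadata(n_ctr, n_af):
    rows = [(f"s{j}", "CTR" if j < n_ctr else "AF", "none" if j < n_ctr else "PAF")
            for j in range(n_ctr + n_af)]
    return pd.DataFrame(rows, columns=["sample_id", "group", "subtype"])
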