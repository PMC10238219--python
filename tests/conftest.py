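"""Shared fixtures: the committed small dataset and a default-scale
synthetic study reused by the slower integration checks."""

from __future__ import annotations

import numpy as np
import pytest

from fibronet import datasets
from fibronet import differential as diff
from fibronet import network as net
from fibronet import simulate as sim
from fibronet.matrix import OmicsMatrix


@pytest.fixture(scope="session")
def fixture_data():
    return datasets.load_fixture()


@pytest.fixture(scope="session")
def fixture_config():
    return sim.fixture_config(1)


@pytest.fixture(scope="session")
def default_study():
    """Default-scale study (2000 genes, 300 metabolites, 5 x 5 design,
    seed 0) with the derived networks; shared across the slow tests."""
    cfg = sim.SimConfig(seed=0)
    counts, design, truth = sim.generate_counts(cfg)
    mets_raw, mdesign = sim.generate_metabolites(cfg, truth)
    phenos, _ = sim.generate_phenotypes(cfg, truth)
    factors = diff.size_factors(counts)
    gene_mat = OmicsMatrix(np.log2(counts.values / factors + 1.0), "tpm")
    gcn = net.build_network_with_phenotypes(gene_mat, phenos)
    gcn_part = net.detect_subnetworks(gcn, seed=0)
    return {
        "config": cfg,
        "counts": counts,
        "design": design,
        "truth": truth,
        "metabolites_raw": mets_raw,
        "met_design": mdesign,
        "phenotypes": phenos,
        "factors": factors,
        "gene_matrix": gene_mat,
        "gcn": gcn,
        "gcn_partition": gcn_part,
    }
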