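from __future__ import annotations

import pytest

from suppnet import (
    SimConfig,
    SuppressionNetwork,
    SuppressionRecord,
    gen_annotation_universe,
    gen_suppression_network,
)


def rec(query, suppressor, pmid="PM1", study="cell", **kw) -> SuppressionRecord:
    """Shorthand record constructor for handcrafted fixtures."""
    return SuppressionRecord(pmid=pmid, query=query, suppressor=suppressor, study_type=study, **kw)


@pytest.fixture
def tiny_net() -> SuppressionNetwork:
    """Six records over four unique pairs, with duplicates and both study types."""
    return SuppressionNetwork(
        [
            rec("QA", "SA", pmid="PM1"),
            rec("QA", "SA", pmid="PM2", study="patient"),
            rec("QA", "SB", pmid="PM3"),
            rec("QB", "SA", pmid="PM4", study="patient"),
            rec("SB", "QA", pmid="PM5"),  # reverse direction of an existing pair
            rec("QB", "SA", pmid="PM4", study="patient"),  # exact duplicate report
        ]
    )


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A reduced-universe configuration for fast unit tests."""
    return SimConfig(
        seed=11,
        n_genes=400,
        n_complexes=30,
        n_pathways=40,
        n_queries=30,
        n_samples=200,
        n_screen_genes=80,
        flagged_extra_records=10,
    )


@pytest.fixture(scope="session")
def small_universe(small_cfg):
    return gen_annotation_universe(small_cfg)


@pytest.fixture(scope="session")
def small_network(small_cfg, small_universe):
    net, truth = gen_suppression_network(small_cfg, small_universe)
    return net, truth
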