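from __future__ import annotations

import pytest

from venomiso.pipeline import run_pipeline
from venomiso.simulate import SCENARIO_NAMES, build_locus, scenario

SCENARIO_SEED = 1


@pytest.fixture(scope="session")
def bundles():
    """All scenario bundles at a fixed seed, built once per session."""
    return {name: scenario(name, seed=SCENARIO_SEED) for name in SCENARIO_NAMES}


@pytest.fixture(scope="session")
def pipeline_results(bundles):
    return {
        name: run_pipeline(b.models, b.clusters, b.reads_dict(), b.chains_dict())
        for name, b in bundles.items()
    }


@pytest.fixture(scope="session")
def mp17():
    """A metalloproteinase-like 17-exon locus with its sequence."""
    return build_locus("MP17", 42, scaffold="sc_mp17", gene_id="mp17g")


@pytest.fixture(scope="session")
def sp6():
    return build_locus("SP6", 42, scaffold="sc_sp6", gene_id="sp6g")
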