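import numpy as np
import pytest

from lineone import rm_catalog
from lineone.intactness import call_intact
from lineone.pipeline import PipelineConfig, PipelineInputs, run_pipeline
from lineone.simulate import SimParams, simulate_family


@pytest.fixture(scope="session")
def sim():
    """The default synthetic study (seed 1), shared across the suite."""
    return simulate_family(SimParams(seed=1))


@pytest.fixture(scope="session")
def elements(sim):
    """Full-length elements per genome, extracted through the catalog module."""
    out = {}
    for g in ("A", "B"):
        anns = rm_catalog.parse_repeatmasker(sim.rm_out[g])
        out[g] = rm_catalog.extract_full_length(anns, sim.genomes[g], genome_id=g)
    return out


@pytest.fixture(scope="session")
def intact_calls(sim, elements):
    return {
        g: {e.element_id: call_intact(e, sim.ref_orfs) for e in elements[g]}
        for g in ("A", "B")
    }


@pytest.fixture(scope="session")
def pipeline_result(sim):
    """One full end-to-end run (frameshift stage included)."""
    return run_pipeline(PipelineInputs.from_sim(sim), PipelineConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
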