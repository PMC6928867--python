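import pandas as pd
import pytest
from hypothesis import settings

import cordhox as cx

# reproducible property tests: fixed example order, no failure database
settings.register_profile("det", derandomize=True, database=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def median_matrix() -> cx.ExpressionMatrix:
    """The published 10-gene x 4-region median TPM worked example."""
    return cx.spinal_cord_median_matrix()


@pytest.fixture(scope="session")
def sim_config() -> cx.SimulationConfig:
    return cx.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def interactome_bundle(sim_config) -> cx.InteractomeBundle:
    return cx.gen_interactome(sim_config)


@pytest.fixture()
def small_library() -> cx.GeneSetLibrary:
    return cx.GeneSetLibrary(entries={
        "HOMEOBOX": frozenset({"HOXA5", "HOXB8", "HOXB2", "HOXD8"}),
        "OTHER": frozenset({"GFAP", "AQP4"}),
    }, source_tag="unit-test")


@pytest.fixture()
def sample_groups():
    """Tiny two-group per-gene sample frames with known Welch statistics."""
    g1 = pd.DataFrame([[10.0, 12.0, 14.0]], index=["G1"], columns=["a1", "a2", "a3"])
    g2 = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"], columns=["b1", "b2", "b3"])
    return g1, g2
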