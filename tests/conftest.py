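import numpy as np
import pytest

from paralogon_kit import pipeline as pl
from paralogon_kit import synthgenome as sg


@pytest.fixture(scope="session")
def fig8_state():
    """Full pipeline run on the packaged metazoan WGD scenario (seed 1)."""
    return pl.run_all(pl.scenario_path("fig8_metazoa"), seed=1, n_boot=100)


@pytest.fixture(scope="session")
def fig8_truth(fig8_state):
    return fig8_state.history


@pytest.fixture(scope="session")
def fig6_results():
    """Synteny analysis of the planted gnathostome paralogon layout."""
    return pl.run_layout(pl.scenario_path("fig6_gnathostome"), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(17)


@pytest.fixture()
def two_species_config():
    """Minimal valid simulation config factory."""

    def make(**overrides):
        base = dict(
            species_tree="(A:0.1,B:0.1)Root;",
            root_genes=[
                sg.RootGene("G1", "G1", "chr1", 1_000_000),
                sg.RootGene("G2", "G2", "chr1", 2_000_000),
                sg.RootGene("G3", "G3", "chr2", 1_000_000),
            ],
            seed=3,
        )
        base.update(overrides)
        return sg.SimConfig(**base)

    return make
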