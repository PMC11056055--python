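import numpy as np
import pytest

from stcar import PanelData, Scenario, generate_panel, temporal_adjacency


@pytest.fixture(scope="session")
def small_panel():
    """One fixed small synthetic panel shared by read-only tests."""
    return generate_panel(Scenario(sp=0.5, tm=0.5, n_units=12, n_times=6, seed=42))


@pytest.fixture(scope="session")
def small_data(small_panel):
    return PanelData(
        y=small_panel.y,
        offset=small_panel.offset,
        X=small_panel.X,
        graph=small_panel.graph,
        tgraph=temporal_adjacency(small_panel.y.shape[1]),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240427)
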