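import pandas as pd
import pytest

from nrseqkit.cb import CBTable
from nrseqkit.mixture import GlobalRates
from nrseqkit.simulate import SimConfig, simulate_one_rep


@pytest.fixture(scope="session")
def small_cb() -> CBTable:
    """Tiny hand-written cB table with two samples and three features."""
    df = pd.DataFrame({
        "sample": ["s1"] * 4 + ["s2"] * 3,
        "feature": ["geneA", "geneA", "geneB", "__no_feature",
                    "geneA", "geneA+geneB", "geneB"],
        "nT": [20, 18, 25, 10, 20, 22, 25],
        "TC": [2, 0, 1, 0, 3, 1, 0],
        "n": [5, 3, 2, 4, 6, 1, 2],
    })
    return CBTable(df, ("TC",))


@pytest.fixture(scope="session")
def known_rates() -> GlobalRates:
    return GlobalRates.from_values(["s1", "s2", "s"], ["TC"], 0.05, 0.002)


@pytest.fixture(scope="session")
def sim_two_component():
    """Medium-size seeded two-component simulation shared across tests."""
    cfg = SimConfig(n_features=100, reads_per_feature=500, reads_law="fixed",
                    seed=202)
    cb, truth = simulate_one_rep(cfg)
    return cfg, cb, truth
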