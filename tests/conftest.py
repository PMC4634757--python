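import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from follisig import simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design() -> pd.DataFrame:
    """The study's 34-sample layout: 31 LCM samples + 3 MT pools."""
    return simulate.generate_design()


@pytest.fixture(scope="session")
def small_panel(design):
    """A small deterministic hurdle panel with its generator parameters."""
    params = simulate.HurdleSimParams(n_genes=12, seed=7)
    return simulate.simulate_hurdle_panel(design, params), params


@pytest.fixture(scope="session")
def fitted_panel(design):
    """A correlated-stages panel together with its hurdle fit (session-wide,
    reused by prediction and serialization tests)."""
    from follisig import hurdle

    params = simulate.HurdleSimParams.correlated_stages(seed=3)
    panel = simulate.simulate_hurdle_panel(design, params)
    fit = hurdle.fit_hurdle(panel.det, panel.rel, design)
    return panel, params, fit


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
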