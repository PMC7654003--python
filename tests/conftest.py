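import numpy as np
import pandas as pd
import pytest

from stageyield import TrialConfig, simulate_trial
from stageyield.growth import STAGES


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial, shared across tests (seed 42)."""
    return simulate_trial(TrialConfig(seed=42))


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory, default_trial):
    """The default trial written out as a CLI-consumable fixture tree."""
    from stageyield.simulate import write_fixture_tree

    out = tmp_path_factory.mktemp("trial")
    write_fixture_tree(default_trial, out)
    return out


@pytest.fixture
def toy_obs():
    """A tiny complete 3-plot x 5-stage observation table."""
    rng = np.random.default_rng(0)
    rows = []
    for pid in ("p1", "p2", "p3"):
        for s in STAGES:
            rows.append({"plot_id": pid, "stage": s,
                         "lai": float(rng.uniform(0.5, 4.0)),
                         "CIrededge": float(rng.uniform(0.2, 2.0))})
    return pd.DataFrame(rows)


@pytest.fixture
def toy_plots():
    return pd.DataFrame({
        "plot_id": ["p1", "p2", "p3"],
        "water": ["NM", "NM", "IM"],
        "nitrogen": ["N2", "N1", "N2"],
        "replicate": [1, 1, 1],
        "yield_kg": [10.0, 8.5, 7.2],
    })
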