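import numpy as np
import pandas as pd
import pytest

from foodsec import survey, synthetic_data


@pytest.fixture(scope="session")
def default_population():
    """One mid-sized synthetic population shared by read-only tests."""
    cfg = synthetic_data.GeneratorConfig(n=10_000, seed=20_240)
    table, ledger = synthetic_data.generate_population(cfg)
    return cfg, table, ledger


@pytest.fixture()
def srs_design():
    """Factory: simple-random-sample design (one stratum, one obs per PSU)."""

    def make(n, weights=None):
        w = np.ones(n) if weights is None else np.asarray(weights, float)
        return survey.SurveyDesign(np.zeros(n, dtype=int), np.arange(n), w)

    return make


@pytest.fixture()
def item_battery_factory():
    """Factory for minimal respondent tables with complete item batteries."""

    def make(n, afssm_raw=0, pfs_raw=0, age=70):
        table = pd.DataFrame({"age_years": np.full(n, age)})
        for i in range(1, 11):
            table[f"afssm{i}"] = (np.arange(n) * 0 + (i <= afssm_raw)).astype(float)
        for j in range(1, 7):
            table[f"pfs{j}"] = float(1 if j <= pfs_raw else 0)
        return table

    return make
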