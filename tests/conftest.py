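import numpy as np
import pandas as pd
import pytest

from sphmm import EffectDistribution, SummaryTable, make_grid


@pytest.fixture(scope="session")
def default_grid():
    return make_grid()


@pytest.fixture(scope="session")
def pm05(default_grid):
    """Symmetric point-mass effect distribution at +-0.05."""
    return EffectDistribution.from_point_masses(default_grid, {-0.05: 0.5, 0.05: 0.5})


@pytest.fixture
def make_table():
    """Factory for in-memory SummaryTables from bare (beta, var) arrays."""

    def _make(beta, var, n_cases=1000, n_controls=1000, ids=None):
        beta = np.asarray(beta, float)
        var = np.asarray(var, float)
        if ids is None:
            ids = [f"rs{i}" for i in range(beta.size)]
        df = pd.DataFrame(
            {
                "snp_id": ids,
                "effect_allele": "A",
                "other_allele": "G",
                "beta_hat": beta,
                "var_hat": var,
                "p_value": np.nan,
                "maf": np.nan,
            }
        )
        return SummaryTable(df=df, n_cases=n_cases, n_controls=n_controls)

    return _make
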