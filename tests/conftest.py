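import numpy as np
import pandas as pd
import pytest

from m6atlas.io import ClinicalTable, ExpressionMatrix
from m6atlas.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (n=400, K=4) shared across tests."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for fast pipeline-level tests."""
    return generate_cohort(SimulationConfig(n_samples=150, seed=5))


@pytest.fixture()
def toy_survival():
    """Deterministic 300-sample survival data with a planted log-HR of 0.7."""
    rng = np.random.default_rng(42)
    n = 300
    x = rng.normal(size=n)
    T = np.exp(-0.7 * x) * rng.exponential(1000, n)
    C = rng.uniform(0, 2500, n)
    t_obs = np.minimum(T, C)
    event = (T <= C).astype(int)
    ids = [f"S{i}" for i in range(n)]
    clin = ClinicalTable(pd.DataFrame({"os_time": t_obs, "os_event": event}, index=ids))
    cov = pd.DataFrame({"x": x}, index=ids)
    return clin, cov


def make_expression(values, genes=None, samples=None):
    values = np.asarray(values, float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
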