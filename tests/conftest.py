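import numpy as np
import pandas as pd
import pytest

from prognet import ClinicalTable, ExpressionMatrix
from prognet.simulate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort: 300 genes, 3 planted 13-gene modules
    (one prognostic), 200 samples."""
    cfg = SyntheticConfig(
        n_genes=300,
        n_samples=200,
        module_sizes=(13, 13, 13),
        prognostic_effects={0: 1.0},
        seed=7,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the generator's default study conditions."""
    return generate(SyntheticConfig(seed=0))


@pytest.fixture()
def tiny_expression():
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.standard_normal((8, 10)),
        index=[f"g{i}" for i in range(8)],
        columns=[f"s{i}" for i in range(10)],
    )
    return ExpressionMatrix(data)


@pytest.fixture()
def tiny_clinical():
    rng = np.random.default_rng(43)
    idx = pd.Index([f"s{i}" for i in range(10)], name="sample")
    return ClinicalTable(
        pd.DataFrame(
            {"time": rng.exponential(50, 10).round(1), "event": [1, 0, 1, 1, 0, 1, 1, 0, 1, 1]},
            index=idx,
        )
    )
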