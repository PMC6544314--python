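import numpy as np
import pandas as pd
import pytest

from socint.datamodel import ExpressionMatrix
from socint.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One default-parameter experiment shared across read-only tests."""
    cfg = SimConfig(n_genes_per_tissue=150, seed=11)
    expr, truth = simulate_experiment(cfg)
    return cfg, expr, truth


@pytest.fixture()
def toy_expression():
    """Three genes x two larva samples, hand-checkable."""
    values = pd.DataFrame(
        {"s1": [1.0, 2.0, 0.0], "s2": [3.0, 2.0, 5.0]},
        index=["gA", "gB", "gC"],
    )
    meta = pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "tissue": ["larva", "larva"],
        "nurse_type": ["not_applicable"] * 2,
        "stage": ["L1", "L2"],
        "colony": ["c1", "c2"],
        "caste": ["worker", "worker"],
        "queen_present": [True, False],
    }).set_index("sample_id")
    return ExpressionMatrix(values, meta)


def make_stratum_matrix(values: np.ndarray, stages, tissue="larva",
                        nurse_type=None, colonies=None):
    """Build a one-stratum ExpressionMatrix from a gene x sample array."""
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    colonies = colonies or [f"c{i}" for i in range(n_samples)]
    ids = [f"{tissue[:2]}_{i}" for i in range(n_samples)]
    meta = pd.DataFrame({
        "sample_id": ids,
        "tissue": tissue,
        "nurse_type": nurse_type or ("not_applicable" if tissue == "larva"
                                     else "stage_specific"),
        "stage": list(stages),
        "colony": colonies,
        "caste": "worker" if tissue == "larva" else "not_applicable",
        "queen_present": True,
    }).set_index("sample_id")
    vals = pd.DataFrame(values, columns=ids,
                        index=[f"g{i:03d}" for i in range(values.shape[0])])
    return ExpressionMatrix(vals, meta)
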