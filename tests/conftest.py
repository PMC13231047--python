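import numpy as np
import pandas as pd
import pytest

from comorbhub.containers import ExpressionMatrix
from comorbhub.synthio import SynthConfig, generate_all


def make_expression(
    n_genes=50, n_case=10, n_ctrl=10, seed=0, effect_genes=(), effect=0.0
) -> ExpressionMatrix:
    """Small iid-normal expression matrix with optional case shift."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_case + n_ctrl)]
    x = rng.standard_normal((n_genes, len(samples)))
    groups = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=samples)
    df = pd.DataFrame(x, index=genes, columns=samples)
    for g in effect_genes:
        df.loc[g, groups == "case"] += effect
    return ExpressionMatrix(df, groups)


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic study at the default conditions (seed 0)."""
    return generate_all(SynthConfig(seed=0))


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig(seed=0)
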