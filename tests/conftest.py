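import numpy as np
import pandas as pd
import pytest

from smadsig.core import ExpressionMatrix, GeneSignature
from smadsig.simulate import simulate_cohort_expression, simulate_survival_cohort


@pytest.fixture(scope="session")
def small_signature() -> GeneSignature:
    genes = [f"G{i}" for i in range(8)]
    return GeneSignature.from_weights({g: 1 if i % 2 else -1 for i, g in enumerate(genes)})


@pytest.fixture(scope="session")
def small_cohort(small_signature):
    """A 60-sample cohort with a moderate planted score effect."""
    expr = simulate_cohort_expression(small_signature.gene_ids, 60, seed=11)
    cohort = simulate_survival_cohort(
        expr, small_signature, beta=0.25, er_effect_only=False, seed=12
    )
    return expr, cohort


@pytest.fixture()
def tiny_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(values)
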