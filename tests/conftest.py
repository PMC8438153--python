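import numpy as np
import pandas as pd
import pytest

from icipattern import ExpressionMatrix, GeneSetCollection, SignatureMatrix


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    df = pd.DataFrame(
        {"s1": [4.0, 3.0, 2.0, 1.0], "s2": [1.0, 2.0, 3.0, 4.0]},
        index=["G1", "G2", "G3", "G4"],
    )
    return ExpressionMatrix(df, "TPM")


@pytest.fixture
def random_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.gamma(2.0, 10.0, size=(50, 10)),
        index=[f"G{i:03d}" for i in range(50)],
        columns=[f"S{j}" for j in range(10)],
    )
    return ExpressionMatrix(df, "TPM")


@pytest.fixture
def gene_sets(random_expression) -> GeneSetCollection:
    rng = np.random.default_rng(7)
    genes = random_expression.genes
    return GeneSetCollection(
        {f"set{k}": list(rng.choice(genes, size=rng.integers(3, 12), replace=False)) for k in range(5)}
    )


@pytest.fixture
def small_signature() -> SignatureMatrix:
    from icipattern import make_signature_matrix

    return make_signature_matrix(100, 5, 10, seed=1)
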