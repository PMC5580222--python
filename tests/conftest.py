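import numpy as np
import pandas as pd
import pytest

from radr.datatypes import ExpressionMatrix, SignatureGeneSet
from radr.simulate import GeneratorConfig


@pytest.fixture
def small_cfg() -> GeneratorConfig:
    """Scaled-down generator for fast module tests."""
    return GeneratorConfig(
        n_genes=400, n_pairs=20, n_lines=16, n_rr=9, n_patients=120,
        n_drug_lines=200, n_hallmark_sets=12, n_drugs=30, n_proteins=20,
    )


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    genes = [f"G{i:02d}" for i in range(1, 21)]
    samples = [f"S{i}" for i in range(1, 7)]
    return ExpressionMatrix(
        pd.DataFrame(rng.normal(8, 2, (20, 6)), index=genes, columns=samples))


@pytest.fixture
def tiny_signature() -> SignatureGeneSet:
    return SignatureGeneSet("sig", frozenset({"G01", "G02"}),
                            frozenset({"G10", "G11", "G12"}))
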