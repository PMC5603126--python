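import numpy as np
import pandas as pd
import pytest

from methylpanel.synthetic import SyntheticDesign, generate


@pytest.fixture
def tiny_matrix() -> pd.DataFrame:
    rng = np.random.default_rng(42)
    values = rng.random((3, 4))
    return pd.DataFrame(
        values,
        index=["cg0000001", "cg0000002", "cg0000003"],
        columns=["S1", "S2", "S3", "S4"],
    )


@pytest.fixture
def table1_phenotypes() -> pd.Series:
    """Phenotype table with the study's cohort sizes (27/94/189/12)."""
    ids, labels = [], []
    for prefix, pheno, n in (
        ("N", "normal", 27),
        ("TN", "LN_negative", 94),
        ("TP", "LN_positive", 189),
        ("TU", "unclassified", 12),
    ):
        ids += [f"{prefix}{i:03d}" for i in range(n)]
        labels += [pheno] * n
    return pd.Series(labels, index=ids, name="phenotype")


@pytest.fixture(scope="session")
def study_dataset():
    """Default synthetic study (cohort sizes and effect structure as designed)."""
    design = SyntheticDesign(seed=3)
    matrix, pheno, truth = generate(design)
    return design, matrix, pheno, truth
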