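import numpy as np
import pandas as pd
import pytest

from sexsig import ExpressionMatrix, SampleAnnotation


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, log2 scale, hand-set values."""
    data = pd.DataFrame(
        [[8.0, 8.2, 7.9, 8.1],
         [5.0, 5.1, 4.9, 5.2],
         [9.5, 9.4, 9.6, 9.3]],
        index=["g1", "g2", "g3"], columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def sexed_annotations() -> list[SampleAnnotation]:
    return [
        SampleAnnotation("S1", "male", "non_failing", 50.0),
        SampleAnnotation("S2", "male", "non_failing", 61.0),
        SampleAnnotation("S3", "female", "non_failing", 55.0),
        SampleAnnotation("S4", "female", "failing", 58.0),
    ]


def sexed_matrix(n_genes=20, n_per_sex=6, effect_genes=(), effect=1.0,
                 sd=0.3, seed=0):
    """Small sexed cohort for unit tests; effect_genes get +effect in males."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    males = [f"M{i}" for i in range(n_per_sex)]
    females = [f"F{i}" for i in range(n_per_sex)]
    vals = rng.normal(8.0, sd, (n_genes, 2 * n_per_sex))
    for g in effect_genes:
        vals[genes.index(g), :n_per_sex] += effect
    matrix = ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=males + females))
    anns = [SampleAnnotation(s, "male", "non_failing", 50.0 + i)
            for i, s in enumerate(males)]
    anns += [SampleAnnotation(s, "female", "non_failing", 50.0 + i)
             for i, s in enumerate(females)]
    return matrix, anns
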