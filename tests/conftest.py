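import numpy as np
import pytest

from kmmdeconv import CellAnnotation, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_reference():
    """10 cells, 2 types, 6 genes; g0 marks typeA, g1 marks typeB."""
    rng = np.random.default_rng(7)
    n_genes, n_cells = 6, 10
    labels = ["typeA"] * 6 + ["typeB"] * 4
    values = rng.uniform(1.0, 5.0, size=(n_genes, n_cells))
    values[0, 6:] = 0.0  # g0 exclusive to typeA
    values[1, :6] = 0.0  # g1 exclusive to typeB
    em = ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        column_ids=[f"c{i}" for i in range(n_cells)],
    )
    ann = CellAnnotation(cell_ids=em.column_ids, cell_type=labels)
    return em, ann
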