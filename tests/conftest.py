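import numpy as np
import pandas as pd
import pytest

from oiserum.containers import ExpressionMatrix


def make_paired_matrix(values: np.ndarray, n_lines: int, gene_ids=None) -> ExpressionMatrix:
    """Wrap a genes x (2*n_lines) array as a paired ExpressionMatrix.

    Columns alternate basal/post per line: L01_basal, L01_post, L02_basal, ...
    """
    values = np.asarray(values, dtype=float)
    assert values.shape[1] == 2 * n_lines
    cols, line_ids, conditions = [], [], []
    for j in range(n_lines):
        line = f"L{j + 1:02d}"
        cols += [f"{line}_basal", f"{line}_post"]
        line_ids += [line, line]
        conditions += ["basal", "post"]
    genes = gene_ids or [f"g{i + 1:03d}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=genes, columns=cols)
    pairing = pd.DataFrame(
        {"line_id": line_ids, "condition": conditions},
        index=pd.Index(cols, name="sample_id"),
    )
    return ExpressionMatrix(values=frame, pairing=pairing)


@pytest.fixture
def paired_matrix_factory():
    return make_paired_matrix
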