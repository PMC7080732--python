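import numpy as np
import pandas as pd
import pytest

from tqrank import CANONICAL_CELL_TYPES, CountMatrix, SampleSheet


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def toy_counts():
    """3 genes (one spike-in) × 4 samples."""
    df = pd.DataFrame(
        {
            "s1": [2, 8, 7],
            "s2": [3, 7, 0],
            "s3": [5, 5, 1],
            "s4": [1, 9, 2],
        },
        index=["g1", "g2", "ERCC-00002"],
    )
    return CountMatrix(df)


@pytest.fixture
def two_embryo_sheet():
    """Complete design: 8 cell types × 2 embryos."""
    rows = [
        {"sample_id": f"E{e}_{ct}", "embryo": f"E{e}", "cell_type": ct}
        for e in (1, 2)
        for ct in CANONICAL_CELL_TYPES
    ]
    return SampleSheet(pd.DataFrame(rows))


def make_phi_frame(values: np.ndarray, sheet: SampleSheet, gene_ids=None) -> pd.DataFrame:
    """Arrange a genes × (cell types × embryos) array as a φ DataFrame whose
    columns follow the sheet's sample ids."""
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=gene_ids, columns=sheet.sample_ids)
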