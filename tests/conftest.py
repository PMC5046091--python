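from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mircnet.io_formats import ExpressionDataset, Motif, MotifSet


def make_dataset(
    values: dict[str, list[float]],
    n_case: int,
    dataset_id: str = "ds",
) -> ExpressionDataset:
    """Build an ExpressionDataset from feature → row values; the first
    ``n_case`` columns are cases, the rest controls."""
    df = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    n = df.shape[1]
    samples = [f"s{i}" for i in range(n)]
    df.columns = samples
    groups = {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}
    return ExpressionDataset(dataset_id, df, groups)


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    return make_dataset(
        {
            "featA": [10, 10, 10, 10, 5, 5, 5, 6],
            "featB": [1, 2, 1, 2, 1, 2, 1, 2],
            "featC": [3, 4, 5, 6, 7, 8, 9, 10],
        },
        n_case=4,
    )


@pytest.fixture
def sharp_motifset() -> MotifSet:
    """One sharp 5-mer motif (consensus ACGTA) over a uniform background."""
    mat = np.full((5, 4), 0.04)
    for pos, base in enumerate([0, 1, 2, 3, 0]):  # A C G T A
        mat[pos] = 0.04
        mat[pos, base] = 0.88
    return MotifSet(
        motifs=[Motif("TFX", mat)], background=np.full(4, 0.25)
    )


def random_motif(rng: np.random.Generator, length: int, name: str = "M") -> Motif:
    mat = rng.dirichlet(np.ones(4), size=length)
    return Motif(name, mat)
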