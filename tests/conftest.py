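import numpy as np
import pandas as pd
import pytest

from mepscope import (
    assign_populations,
    build_default_panel,
    filter_assays,
    filter_cells,
    normalize_to_housekeeping,
    run_pca,
    simulate_cells,
)
from mepscope.qc import CtMatrix
from mepscope.synthetic import PopulationParams


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def dataset(panel):
    """Default synthetic experiment used across the suite (fixed seed)."""
    return simulate_cells(panel, PopulationParams(seed=11), n_cells=400)


@pytest.fixture(scope="session")
def qc_passed(dataset):
    ct, _ = filter_assays(dataset.ct)
    ct, _ = filter_cells(ct)
    return ct


@pytest.fixture(scope="session")
def expr(qc_passed):
    return normalize_to_housekeeping(qc_passed)


@pytest.fixture(scope="session")
def pca(expr):
    return run_pca(expr)


@pytest.fixture(scope="session")
def assignment(pca, expr, panel):
    return assign_populations(pca, expr, panel, seed=11)


def toy_ct(values, assays=None, lod=40.0, meta=None):
    """CtMatrix from a nested list; entries equal to lod become drop-outs."""
    arr = np.asarray(values, dtype=float)
    cells = [f"c{i}" for i in range(arr.shape[0])]
    assays = assays or [f"g{j}" for j in range(arr.shape[1])]
    ct = pd.DataFrame(arr, index=cells, columns=assays)
    dropout = ct >= lod
    ct = ct.where(~dropout, lod)
    meta_df = pd.DataFrame(meta, index=cells) if meta else pd.DataFrame(index=cells)
    return CtMatrix(ct=ct, dropout=dropout, cell_meta=meta_df, lod=lod)
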