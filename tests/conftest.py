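import warnings

import numpy as np
import pandas as pd
import pytest

from coexnet.simulate import SimDesign, SimParams, simulate_counts


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # stages legitimately warn about degenerate fixtures; keep test output readable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """One-tissue 2x2x1 factorial, 400 genes, with planted DE and wiring."""
    design = SimDesign(n_genes=400, breeds=("CH", "HF"), diet_phases=("H1",),
                       tissues=("liver",), n_per_cell=10, seed=11)
    params = SimParams(n_de_per_contrast=40, de_log2fc=2.0, n_modules=2,
                       module_size=15, n_tfs=60, n_secretome=30,
                       n_wired_targets=20, wired_coupling=0.8)
    counts, design_tbl, truth = simulate_counts(design, params)
    return counts, design_tbl, truth


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(3)
    mat = rng.poisson(rng.lognormal(3.0, 1.2, (120, 1)) * np.ones((1, 6)))
    return pd.DataFrame(mat, index=[f"G{i:03d}" for i in range(120)],
                        columns=list("abcdef"))
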