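import numpy as np
import pandas as pd
import pytest

import mapkstress as m


@pytest.fixture(scope="session")
def default_sim():
    """Canonical 18-library simulation: 2000 genes, 200 planted responsive
    genes at |effect| 3, three 60-gene co-expression blocks, dispersion 0.05."""
    cfg = m.SimulationConfig(seed=0)
    cm, design, truth = m.simulate_counts(cfg)
    return cfg, cm, design, truth


@pytest.fixture(scope="session")
def block_expr(default_sim):
    """logCLR expression of the planted 3-block genes (full-matrix TMM+CLR
    first, then subset), with their true block labels."""
    _, cm, _, truth = default_sim
    expr_full = m.tmm_logclr(cm)
    genes = truth.module_id.index[truth.module_id >= 0]
    sub = m.ExpressionMatrix(expr_full.values.loc[genes], "logclr")
    return sub, truth.module_id.loc[genes]


@pytest.fixture
def small_counts():
    """Tiny deterministic count matrix (5 genes × 3 samples, WT design)."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(rng.integers(0, 500, (5, 3)),
                          index=[f"g{i}" for i in range(5)],
                          columns=["WT_CK_0", "WT_SOB_0.5", "WT_SOB_12"])
    lengths = pd.Series(rng.integers(500, 3000, 5), index=counts.index)
    return m.CountMatrix(counts, lengths)
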