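import numpy as np
import pandas as pd
import pytest

from netprog.io import ModuleSet
from netprog.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """Compact planted-signal cohort for fast pipeline-level tests."""
    cfg = SyntheticConfig(n_genes=300, n_patients=100, n_modules=20,
                          n_planted=3, effect_size=2.0, master_seed=42)
    return generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size planted-signal cohort (generator defaults)."""
    return generate(SyntheticConfig(master_seed=7))


@pytest.fixture()
def tiny_expr():
    """5 genes x 6 patients, hand-checkable, one missing value."""
    genes = ["g1", "g2", "g3", "g4", "g5"]
    patients = ["p1", "p2", "p3", "p4", "p5", "p6"]
    data = np.array([
        [1.0, 3.0, 2.0, 4.0, 6.0, 5.0],
        [2.0, 4.0, 3.0, 5.0, 7.0, 6.0],
        [0.0, 2.0, 1.0, 3.0, 5.0, 4.0],
        [1.0, 1.5, 2.5, 3.5, 4.5, 5.5],
        [np.nan, 2.0, 3.0, 4.0, 5.0, 6.0],
    ])
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=patients)


@pytest.fixture()
def tiny_labels():
    # p1-p3 good, p4-p6 bad
    return pd.Series([0, 0, 0, 1, 1, 1],
                     index=["p1", "p2", "p3", "p4", "p5", "p6"], dtype=int)


@pytest.fixture()
def tiny_modules():
    return ModuleSet([
        ("M1", frozenset({"g1", "g2"})),
        ("M2", frozenset({"g3"})),
        ("M3", frozenset({"g2", "g4", "g5"})),
    ])
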