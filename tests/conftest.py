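import numpy as np
import pandas as pd
import pytest

from tempax import synthetic


@pytest.fixture(scope="session")
def study_dataset():
    """Array-design dataset: E11/E14/E16 with 30/70/28 cells."""
    cfg = synthetic.SimConfig(seed=11)
    matrix, truth = synthetic.simulate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def qpcr_dataset():
    """qPCR-design dataset: wild-type cells pooled over E10-E14."""
    cfg = synthetic.qpcr_config(seed=23)
    truth = synthetic.build_truth(cfg)
    panel = list(synthetic.TEMPORAL_PANEL) + [
        "Gapdh", "Ki67", "Ttyh1", "Tbr2", "Egfp",
    ]
    table = synthetic.simulate_qpcr(truth, panel, cfg)
    return cfg, truth, table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_log2():
    """3 probes x 3 samples with hand-checkable correlations."""
    return pd.DataFrame(
        {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": [3.0, 2.0, 1.0]},
        index=["g1", "g2", "g3"],
    )
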