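import numpy as np
import pandas as pd
import pytest

from soilrisk import synthetic
from soilrisk.sampletable import SampleTable


@pytest.fixture(scope="session")
def study_table():
    """Default 30-sample, 12-element survey with known sources."""
    cfg = synthetic.study_config(seed=7)
    table, true_g, true_f = synthetic.generate_dataset(cfg)
    return cfg, table, true_g, true_f


@pytest.fixture(scope="session")
def three_source():
    """200-sample, 3-source benchmark at 10% measurement noise."""
    cfg = synthetic.three_source_config(n_samples=200, noise_cv=0.10, seed=1)
    table, true_g, true_f = synthetic.generate_dataset(cfg)
    return cfg, table, true_g, true_f


def make_table(conc: np.ndarray, elements=None, clay=25.0, om=10.0) -> SampleTable:
    """Hand-rolled SampleTable for small numeric fixtures."""
    conc = np.asarray(conc, dtype=float)
    n, m = conc.shape
    elements = elements or [f"E{j}" for j in range(m)]
    idx = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    return SampleTable(
        conc=pd.DataFrame(conc, index=idx, columns=elements),
        clay=pd.Series(np.full(n, clay), index=idx),
        om=pd.Series(np.full(n, om), index=idx),
    )
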