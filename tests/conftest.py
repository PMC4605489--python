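import logging

import numpy as np
import pytest

from phenostruct.io_tables import CraniometricTable
from phenostruct.synthetic import SyntheticConfig, simulate_dataset

logging.getLogger("phenostruct").setLevel(logging.ERROR)


def make_table(values, series, variables, mask=None, sex=None, region=None,
               ids=None):
    """Convenience constructor for small hand-written tables."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    series = np.asarray(series, dtype=object)
    return CraniometricTable(
        individual_id=np.asarray(ids if ids is not None
                                 else [f"ind{i}" for i in range(n)], dtype=object),
        series=series,
        region=np.asarray(region if region is not None else [""] * n, dtype=object),
        sex=np.asarray(sex if sex is not None else ["U"] * n, dtype=object),
        values=values,
        mask=np.zeros(values.shape, dtype=bool) if mask is None
        else np.asarray(mask, dtype=bool),
        variables=list(variables),
    )


@pytest.fixture
def small_panel():
    """4 series x 25 individuals x 8 variables with mild structure, complete."""
    cfg = SyntheticConfig(k=4, n=25, t=8, fst=0.15, h2=0.55, seed=11)
    table, truth = simulate_dataset(cfg)
    return table, truth


@pytest.fixture
def missing_panel():
    """As small_panel but with 10% MCAR missing cells (and its complete twin)."""
    cfg = SyntheticConfig(k=4, n=30, t=10, fst=0.15, h2=0.55,
                          missing_rate=0.10, seed=19)
    table, _ = simulate_dataset(cfg)
    complete, _ = simulate_dataset(
        SyntheticConfig(k=4, n=30, t=10, fst=0.15, h2=0.55,
                        missing_rate=0.0, seed=19))
    return table, complete
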