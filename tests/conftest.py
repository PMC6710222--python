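import numpy as np
import pytest

import lbaselect as lb


@pytest.fixture(scope="session")
def baseline_params():
    return lb.BASELINE


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-condition dataset from the null generating model."""
    return lb.simulate_trials([lb.BASELINE, lb.BASELINE], 50, seed=123)


@pytest.fixture(scope="session")
def moderate_extreme_dataset():
    """Both effects moderate, speeding up condition 2."""
    cell = lb.DesignCell("moderate", "moderate", "extreme")
    return lb.generate_dataset(cell, master_seed=7)


@pytest.fixture(scope="session")
def fitted_complex(moderate_extreme_dataset):
    """One reduced-size complex-model fit shared across metric tests."""
    model = lb.LBAModel(moderate_extreme_dataset, "complex")
    return model.fit(burn=300, keep=300, seed=11)
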