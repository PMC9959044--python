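import numpy as np
import pytest

from beadopt import datasets, fit_quadratic_rsm
from beadopt.doe import code_point


@pytest.fixture(scope="session")
def design():
    """The packaged 17-run study design with measured responses."""
    return datasets.load_design()


@pytest.fixture(scope="session")
def models(design):
    """Fitted quadratic surfaces for all three responses."""
    return {
        name: fit_quadratic_rsm(design, name)
        for name in datasets.RESPONSE_NAMES
    }


@pytest.fixture(scope="session")
def optimum_coded():
    """Coded image of the reported optimized formulation."""
    return code_point(datasets.OPTIMUM_ACTUAL, datasets.FACTORS)
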