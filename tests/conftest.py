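import numpy as np
import pytest

from combotrans.dose_response import CombinationMatrix, log_logistic


@pytest.fixture
def half_log_grids():
    """Zero-margin half-log dose grids: panRAFi to 10 µM, MEKi to 5 µM."""
    doses_a = np.concatenate([[0.0], 10.0 * 10.0 ** (-0.5 * np.arange(8)[::-1])])
    doses_b = np.concatenate([[0.0], 5.0 * 10.0 ** (-0.5 * np.arange(8)[::-1])])
    return doses_a, doses_b


@pytest.fixture
def independent_matrix(half_log_grids):
    """Noiseless Bliss-independent checkerboard from log-logistic margins."""
    doses_a, doses_b = half_log_grids
    va = log_logistic(doses_a, 1.0, 0.1, 0.3, 1.5)
    vb = log_logistic(doses_b, 1.0, 0.2, 0.05, 1.2)
    return CombinationMatrix("belvarafenib", "cobimetinib", doses_a, doses_b,
                             va[:, None] * vb[None, :], cell_line="synthetic")
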