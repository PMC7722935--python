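import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def brute_force_bh(p_values, q_star=0.05):
    """Step-up BH decisions straight from the definition.

    Sort the p-values, find the largest i with p_(i) <= i * q / m, reject
    exactly the hypotheses with p <= p_(i).  Independent of any library
    implementation; used as the oracle for BH-based decisions.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) / m) * q_star
    if not below.any():
        return np.zeros(m, dtype=bool)
    k = int(np.max(np.nonzero(below)[0]))
    return p <= sorted_p[k]
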