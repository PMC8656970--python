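"""Independent brute-force oracles shared by the test suite."""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def brute_force_two_sided_p(a, b):
    """Two-sided Mann-Whitney p by enumerating every split of the pooled
    sample; independent of the implementation under test."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    n = len(pooled)
    offset = n_a * (n_a + 1) / 2.0
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in combinations(range(n), n_a)]
    )
    u_obs = ranks[:n_a].sum() - offset
    cdf = np.mean(us <= u_obs + 1e-9)
    sf = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))
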