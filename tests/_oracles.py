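"""Independent brute-force oracles shared by the test modules.

These implementations deliberately avoid the package's own code paths:
the quadrature oracle integrates random effects by 50-node adaptive
Gauss-Hermite on scalar functions, and the graph oracle evaluates the
relative-neighborhood definition by cubic enumeration.
"""

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from scipy.special import logsumexp

Z50, W50 = hermgauss(50)
LOGW50 = np.log(W50)


def agh_1d(neg_log_integrand, half_width=25.0):
    """50-node adaptive Gauss-Hermite integral of exp(-f), on the log scale."""
    res = minimize_scalar(neg_log_integrand, bounds=(-half_width, half_width),
                          method="bounded", options={"xatol": 1e-12})
    mode = res.x
    h = 1e-5
    curv = (neg_log_integrand(mode + h) - 2 * neg_log_integrand(mode)
            + neg_log_integrand(mode - h)) / h ** 2
    s = 1.0 / np.sqrt(max(curv, 1e-12))
    pts = mode + np.sqrt(2.0) * s * Z50
    vals = np.array([-neg_log_integrand(p) for p in pts])
    return logsumexp(LOGW50 + Z50 ** 2 + vals) + np.log(np.sqrt(2.0) * s)


def brute_force_rng(coords):
    """O(n^3) evaluation of the relative-neighborhood definition."""
    d = squareform(pdist(coords))
    n = len(coords)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            blocked = any(
                max(d[i, k], d[j, k]) < d[i, j]
                for k in range(n) if k not in (i, j)
            )
            if not blocked:
                edges.add((i, j))
    return edges
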