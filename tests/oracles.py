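"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid numpy/scipy vectorised code paths and the package's
own functions: plain-Python enumeration with ``math.lgamma`` pmfs for the
conditional count test, per-position direct sums for the convolution, and
adaptive quadrature for the Bayes-factor marginals.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def direct_convolution(values, weights, radius):
    """response[p] = sum_x w[x] * v[p+x], zero-padded, edge margins zeroed."""
    n = len(values)
    padded = [0.0] * radius + list(values) + [0.0] * radius
    out = []
    for p in range(n):
        acc = 0.0
        for x in range(2 * radius + 1):
            acc += weights[x] * padded[p + x]
        out.append(acc)
    for p in range(min(radius, n)):
        out[p] = 0.0
        out[n - 1 - p] = 0.0
    return np.array(out)


def _pmf(k: int, mean: float, var: float) -> float:
    """Poisson or moment-matched NB pmf via lgamma (no scipy.stats)."""
    if mean <= 0:
        return 1.0 if k == 0 else 0.0
    if var <= mean * (1 + 1e-12):
        return math.exp(-mean + k * math.log(mean) - math.lgamma(k + 1))
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return math.exp(
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1)
        + r * math.log(p)
        + k * math.log(1 - p)
    )


def exact_test_p(k_rip, k_control, s_rip, s_control, alpha) -> float:
    """Enumeration of every split of the total count, in pure Python."""
    obs_a = sum(k_rip)
    total_k = obs_a + sum(k_control)
    if total_k == 0:
        return 1.0
    sa, sb = sum(s_rip), sum(s_control)
    q0 = total_k / (sa + sb)
    mu_a, mu_b = q0 * sa, q0 * sb
    var_a = mu_a + alpha * q0 * q0 * sum(s * s for s in s_rip)
    var_b = mu_b + alpha * q0 * q0 * sum(s * s for s in s_control)
    probs = [
        _pmf(a, mu_a, var_a) * _pmf(total_k - a, mu_b, var_b)
        for a in range(total_k + 1)
    ]
    total = sum(probs)
    p_obs = probs[obs_a]
    p = sum(q for q in probs if q <= p_obs * (1 + 1e-9)) / total
    return min(1.0, p)


def beta_integral(a: int, b: int) -> float:
    """Numerical integral of theta^a (1-theta)^b over (0, 1)."""
    val, _ = quad(lambda t: t**a * (1 - t) ** b, 0, 1, epsabs=0, epsrel=1e-12)
    return val


def bayes_factor_numeric(i1: int, e1: int, i2: int, e2: int) -> float:
    m1 = beta_integral(i1, e1) * beta_integral(i2, e2)
    m0 = beta_integral(i1 + i2, e1 + e2)
    return m1 / m0
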