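"""Independent oracles used across the test suite.

These deliberately avoid the package's closed-form code paths: the fitted
heavy count is found by bisection on the monotone odds-ratio function, and
the Holm decisions by literal evaluation of the step-down rule.
"""

from __future__ import annotations

import numpy as np


def mh_or_oracle(strata) -> float:
    num = sum(a * d / (a + b + c + d) for a, b, c, d in strata)
    den = sum(b * c / (a + b + c + d) for a, b, c, d in strata)
    return num / den


def expected_a_oracle(r1: float, c1: float, n: float, common_or: float, tol: float = 1e-10) -> float:
    """Bisection root of R = a(n-r1-c1+a)/((r1-a)(c1-a)) on the admissible interval."""
    lo = max(0.0, r1 + c1 - n)
    hi = min(r1, c1)

    def f(a: float) -> float:
        return a * (n - r1 - c1 + a) / ((r1 - a) * (c1 - a)) - common_or

    eps = 1e-12 * (hi - lo)
    a, b = lo + eps, hi - eps
    fa, fb = f(a), f(b)
    assert fa < 0 < fb, "odds-ratio function must bracket the root"
    while b - a > tol:
        m = 0.5 * (a + b)
        if f(m) < 0:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def bd_statistic_oracle(strata, tarone: bool = False) -> float:
    """Breslow-Day statistic evaluated from the bisection-fitted counts."""
    common = mh_or_oracle(strata)
    stat = 0.0
    dev = 0.0
    var_sum = 0.0
    for a, b, c, d in strata:
        n = a + b + c + d
        r1, c1 = a + b, a + c
        a_fit = expected_a_oracle(r1, c1, n, common)
        var = 1.0 / (
            1.0 / a_fit + 1.0 / (r1 - a_fit) + 1.0 / (c1 - a_fit) + 1.0 / (n - r1 - c1 + a_fit)
        )
        stat += (a - a_fit) ** 2 / var
        dev += a - a_fit
        var_sum += var
    if tarone:
        stat -= dev**2 / var_sum
    return stat


def holm_oracle(p_values, alpha: float):
    """Literal Holm step-down: reject the k-th smallest iff p(k) < alpha/(n+1-k)
    and every smaller-ranked hypothesis was rejected."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: (p_values[i], i))
    reject = [False] * n
    for k, idx in enumerate(order, start=1):
        if p_values[idx] < alpha / (n + 1 - k):
            reject[idx] = True
        else:
            break
    return reject


def random_corrected_strata(rng: np.random.Generator):
    """Two random 2x2 strata with cells <= 50, Haldane-corrected when needed."""
    cells = rng.integers(0, 51, size=8).astype(float)
    strata = [tuple(cells[:4]), tuple(cells[4:])]
    out = []
    for s in strata:
        if sum(s) == 0:
            s = (1.0, 1.0, 1.0, 1.0)
        if any(x == 0 for x in s):
            s = tuple(x + 0.5 for x in s)
        out.append(s)
    return out
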