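"""Independent brute-force oracles the implementation is checked against.

Every function here recomputes a quantity by direct enumeration or via a
third-party routine, deliberately avoiding the code paths in ``asekit``.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.stats import nbinom

REL_TOL = 1 + 1e-9


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-fraction enumeration of the conditional HWE distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_alt, 2 * n - n_alt)
    weights: dict[int, Fraction] = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        w = (
            Fraction(math.factorial(n),
                     math.factorial(hom_common) * math.factorial(het)
                     * math.factorial(hom_rare))
            * Fraction(2) ** het
        )
        weights[het] = w
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def binom_two_sided_oracle(k: int, n: int, p: float) -> float:
    """Minimum-likelihood two-sided binomial p by direct pmf summation."""
    pmf = np.array([math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)])
    return float(min(1.0, pmf[pmf <= pmf[k] * REL_TOL].sum()))


def betabinom_pmf_oracle(k: int, n: int, a: float, b: float) -> float:
    """Beta-binomial pmf via the ascending-factorial product formula."""
    val = math.comb(n, k)
    for i in range(k):
        val *= (a + i)
    for i in range(n - k):
        val *= (b + i)
    for i in range(n):
        val /= (a + b + i)
    return val


def nb_conditional_oracle(s_ref: int, total: int, n: int, phi: float) -> float:
    """Conditional distribution of the REF-group sum given the pooled total
    for two groups of n NB(mu, phi) counts each, built from nbinom pmf
    products at an arbitrary nuisance mean (it cancels)."""
    r = n / phi
    mu = 7.3  # arbitrary; the conditional law does not depend on it
    pnb = r / (r + mu)
    k = np.arange(total + 1)
    w = nbinom.pmf(k, r, pnb) * nbinom.pmf(total - k, r, pnb)
    probs = w / w.sum()
    return float(min(1.0, probs[probs <= probs[s_ref] * REL_TOL].sum()))


def two_prop_lrt_oracle(k1: int, n1: int, k2: int, n2: int) -> float:
    """Deviance of the two-proportion binomial likelihood-ratio test."""
    def ll(k, n, p):
        if p <= 0 or p >= 1:
            p = min(max(p, 1e-12), 1 - 1e-12)
        return k * math.log(p) + (n - k) * math.log(1 - p)

    p0 = (k1 + k2) / (n1 + n2)
    return 2 * (ll(k1, n1, k1 / n1) + ll(k2, n2, k2 / n2)
                - ll(k1, n1, p0) - ll(k2, n2, p0))
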