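"""Independent oracles used to cross-check the package's statistics.

These deliberately avoid the code paths they verify: the exact binomial test
is checked by direct enumeration of the binomial pmf, and t / chi-square
tail probabilities by numerical integration of the closed-form densities.
"""

import math

from scipy.integrate import quad


def exact_binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p-value by full enumeration: sum the
    probabilities of all outcomes no more likely than the observed one."""
    probs = [math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)]
    observed = probs[k]
    # the relative fudge mirrors the usual guard against floating-point ties
    return min(1.0, sum(pr for pr in probs if pr <= observed * (1 + 1e-10)))


def t_density(x: float, df: int) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def t_two_sided_p(t: float, df: int) -> float:
    """Two-sided t tail probability via numerical integration of the density."""
    tail, _ = quad(t_density, abs(t), math.inf, args=(df,))
    return min(1.0, 2 * tail)


def chi2_density(x: float, df: int) -> float:
    if x <= 0:
        return 0.0
    return x ** (df / 2 - 1) * math.exp(-x / 2) / (2 ** (df / 2) * math.gamma(df / 2))


def chi2_upper_p(stat: float, df: int) -> float:
    """Chi-square upper-tail probability via numerical integration."""
    if stat <= 0:
        return 1.0
    tail, _ = quad(chi2_density, stat, math.inf, args=(df,))
    return min(1.0, tail)


def bh_qvalues(pvals):
    """Benjamini–Hochberg step-up q-values (independence-valid FDR)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pvals[i] * m / rank)
        q[i] = best
    return q
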