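"""Independent brute-force oracles used only by the tests."""

import math

import numpy as np


def wright_fisher_sample(p: float, b: float, n: int, N: int,
                         rng: np.random.Generator):
    """Allele-frequency sample after discrete Wright-Fisher drift.

    Resamples a population of N individuals binomially for g
    generations, where g is chosen so the variance matches the target
    drift parameter: Var = p(1-p)(1 - (1-1/N)^g).  Returns the sample
    and the *achieved* drift parameter (1-1/N)^g, which differs from b
    only through rounding g.
    """
    g = max(1, round(math.log(b) / math.log(1.0 - 1.0 / N)))
    freq = np.full(n, p)
    for _ in range(g):
        freq = rng.binomial(N, freq) / N
    return freq, (1.0 - 1.0 / N) ** g


def binomial_pmf(k: np.ndarray, n: int, p: float) -> np.ndarray:
    """Direct binomial pmf (independent of scipy) for the chi-squared check."""
    k = np.asarray(k)
    out = np.array([math.comb(n, int(ki)) * p**ki * (1 - p) ** (n - ki)
                    for ki in k], dtype=float)
    return out
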