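"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library calls used by the implementation:
the Fisher oracle enumerates the hypergeometric support with exact
integer combinatorics; the chi-square oracle applies the textbook
formula; the set-cover oracle enumerates all subsets.
"""

import math
from itertools import combinations

import numpy as np


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins.

    Sums the point probabilities of every table whose probability does not
    exceed the observed one (with the customary 1+1e-7 relative guard
    against floating ties).  Convention: a table with no minor alleles
    (a + b == 0) is monomorphic, p = 1.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = [math.comb(r1, x) * math.comb(r2, c1 - x) / denom for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


def chi_square_2x2(table):
    """Textbook 1-df Pearson chi-square (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    expected = np.outer(rows, cols) / n
    return float(((table - expected) ** 2 / expected).sum())


def min_cover_size(covers):
    """Smallest tag set covering all variants, by exhaustive subset search.

    ``covers`` is a boolean matrix: covers[i, j] means i tags j
    (diagonal True).
    """
    m = covers.shape[0]
    for k in range(1, m + 1):
        for subset in combinations(range(m), k):
            if covers[list(subset)].any(axis=0).all():
                return k
    return m
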