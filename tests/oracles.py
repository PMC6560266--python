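"""Independent brute-force / textbook-formula oracles.

Everything here is written directly from first principles (pairwise
enumeration over allele lists, literal transcription of published formulas)
and never calls the package's own statistics code, so agreement is a real
cross-check rather than a tautology.
"""
from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def pi_site_bruteforce(i: int, n: int) -> float:
    """Mean pairwise difference over all C(n,2) allele pairs at one site."""
    alleles = [1] * i + [0] * (n - i)
    pairs = list(combinations(range(n), 2))
    diff = sum(alleles[a] != alleles[b] for a, b in pairs)
    return diff / len(pairs)


def pi_window_bruteforce(alt: np.ndarray, called: np.ndarray) -> float:
    """Window pi = mean over sites of the per-site pairwise difference."""
    vals = [pi_site_bruteforce(int(i), int(n)) for i, n in zip(alt, called)]
    return float(np.mean(vals))


def theta_w_textbook(alt: np.ndarray, called: np.ndarray) -> float:
    """Watterson's theta per SNP: S / (a1 * L), constant sample size n."""
    n = int(called[0])
    S = int(np.sum((alt > 0) & (alt < called)))
    a1 = sum(1.0 / k for k in range(1, n))
    return S / a1 / len(alt)


def tajimas_d_textbook(alt: np.ndarray, called: np.ndarray) -> float:
    """Tajima (1989), literal transcription, constant sample size."""
    n = int(called[0])
    S = int(np.sum((alt > 0) & (alt < called)))
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / k for k in range(1, n))
    a2 = sum(1.0 / k ** 2 for k in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    pi_total = sum(pi_site_bruteforce(int(i), n) for i in alt)
    d = pi_total - S / a1
    return d / np.sqrt(e1 * S + e2 * S * (S - 1))


def fay_wu_h_textbook(derived: np.ndarray, called: np.ndarray) -> float:
    """H = sum(pi) - sum(theta_H), theta_H = 2 i^2 / (n (n-1))."""
    total = 0.0
    for i, n in zip(derived, called):
        i, n = int(i), int(n)
        total += pi_site_bruteforce(i, n) - 2.0 * i * i / (n * (n - 1))
    return total


def wc_fst_textbook(i1: int, n1: int, i2: int, n2: int) -> float:
    """Weir & Cockerham theta-hat, two demes, alleles as sampling unit.

    Written as the ANOVA decomposition: among- and within-deme mean squares
    with n_c the effective deme size correction.
    """
    p1, p2 = i1 / n1, i2 / n2
    pbar = (i1 + i2) / (n1 + n2)
    msa = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (2 - 1)
    msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / ((n1 - 1) + (n2 - 1))
    nc = ((n1 + n2) - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (2 - 1)
    denom = msa + (nc - 1) * msw
    if denom == 0:
        return float("nan")
    return (msa - msw) / denom


def dxy_bruteforce(i1: int, n1: int, i2: int, n2: int) -> float:
    """Mean difference over all n1*n2 between-population allele pairs."""
    a = [1] * i1 + [0] * (n1 - i1)
    b = [1] * i2 + [0] * (n2 - i2)
    return sum(x != y for x in a for y in b) / (n1 * n2)


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(|draw of size n intersects fixed K-set| >= k) by counting
    combinations exhaustively; only feasible for small N."""
    universe = list(range(N))
    target = set(range(K))
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(target & set(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_comb(N: int, K: int, n: int, k: int) -> float:
    """Exact tail via binomial coefficients (independent of scipy)."""
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(k, min(K, n) + 1))
    return num / comb(N, n)
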