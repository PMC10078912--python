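"""Independent brute-force reference implementations used as test oracles.

Everything here is written for clarity over speed (explicit loops,
enumeration, exact integer combinatorics) and stays independent of the
package's vectorized code paths.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

MISSING = -1


def pair_genotype_distance(a: int, b: int) -> float:
    """Expected allele mismatch between two diploid dosages."""
    return a / 2 + b / 2 - a * b / 2


def brute_pi(dosage: np.ndarray, length: int) -> float:
    """pi as the mean per-bp mismatch over all allele-slot pairs (loops).

    Each diploid contributes two allele slots.  Between two individuals the
    four slot pairings mismatch 4 * (a/2 + b/2 - a*b/2) times in total (a
    heterozygote shares either allele with probability 1/2); within a
    heterozygote the single slot pair mismatches once.  Complete data only.
    """
    n, s = dosage.shape
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(s):
                total += 4 * pair_genotype_distance(
                    int(dosage[i, k]), int(dosage[j, k])
                )
    for i in range(n):
        for k in range(s):
            if dosage[i, k] == 1:
                total += 1.0
    n_hap = 2 * n
    n_pairs = n_hap * (n_hap - 1) / 2
    return total / n_pairs / length


def brute_dxy(dos_a: np.ndarray, dos_b: np.ndarray, length: int) -> float:
    """Mean per-bp genotype distance over all inter-group pairs (loops)."""
    total = 0.0
    pairs = 0
    for i in range(dos_a.shape[0]):
        for j in range(dos_b.shape[0]):
            d = 0.0
            n_comp = 0
            for k in range(dos_a.shape[1]):
                a, b = int(dos_a[i, k]), int(dos_b[j, k])
                if a == MISSING or b == MISSING:
                    continue
                d += pair_genotype_distance(a, b)
                n_comp += 1
            if n_comp:
                eff_len = length * n_comp / dos_a.shape[1]
                total += d / eff_len
                pairs += 1
    return total / pairs


def brute_rndmin(dos_a, dos_b, dos_out, length) -> tuple[float, float]:
    """(d_min, d_out) by full pair enumeration (complete data)."""
    def dist(x, y):
        return sum(
            pair_genotype_distance(int(a), int(b)) for a, b in zip(x, y)
        ) / length

    d_min = min(
        dist(dos_a[i], dos_b[j])
        for i in range(dos_a.shape[0])
        for j in range(dos_b.shape[0])
    )
    dists = []
    for block in (dos_a, dos_b):
        for i in range(block.shape[0]):
            for o in range(dos_out.shape[0]):
                dists.append(dist(block[i], dos_out[o]))
    return d_min, sum(dists) / len(dists)


def brute_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation by the textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a.mean(), b.mean()
    cov = ((a - am) * (b - bm)).sum()
    va = ((a - am) ** 2).sum()
    vb = ((b - bm) ** 2).sum()
    return (cov * cov) / (va * vb)


def tajimas_d_reference(derived_counts: list[int], n: int) -> float:
    """Tajima's D from scratch: scalar constants, explicit sums."""
    s = len(derived_counts)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi = sum(2 * j * (n - j) / (n * (n - 1)) for j in derived_counts)
    theta_w = s / a1
    return (pi - theta_w) / math.sqrt(e1 * s + e2 * s * (s - 1))


def bh_reference(p: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def by_reference(p: list[float]) -> list[float]:
    """Benjamini-Yekutieli: BH with the harmonic-sum penalty c(m)."""
    m = len(p)
    c = sum(1.0 / i for i in range(1, m + 1))
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, min(1.0, p[i] * c * m / rank))
        q[i] = val
        prev = val
    return q


def hypergeom_tail_exact(k: int, big_n: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) with exact integer combinatorics."""
    total = Fraction(0)
    denom = math.comb(big_n, n)
    for x in range(k, min(big_k, n) + 1):
        total += Fraction(math.comb(big_k, x) * math.comb(big_n - big_k, n - x), denom)
    return float(total)


def hypergeom_projection_exact(n_from: int, j: int, n_to: int) -> list[float]:
    """P(i derived among n_to | j derived among n_from), exact fractions."""
    denom = math.comb(n_from, n_to)
    out = []
    for i in range(n_to + 1):
        if i > j or n_to - i > n_from - j:
            out.append(0.0)
        else:
            out.append(
                float(
                    Fraction(
                        math.comb(j, i) * math.comb(n_from - j, n_to - i), denom
                    )
                )
            )
    return out


def sweep_spectrum_reference(phi: np.ndarray, n: int, pe: float) -> np.ndarray | None:
    """Sweep-distorted spectrum by explicit enumeration over escape subsets.

    Enumerates every subset of lineages as escapees, every pre-sweep derived
    count, and the identity of the swept ancestor — feasible for small n.
    """
    from itertools import combinations

    out = np.zeros(n + 1)
    for k in range(n + 1):
        p_k = math.comb(n, k) * pe**k * (1 - pe) ** (n - k)
        if k == n:
            out += p_k * phi
            continue
        m = k + 1
        for j in range(n + 1):  # background derived count at size n
            if phi[j] == 0:
                continue
            proj = hypergeom_projection_exact(n, j, m)
            for i in range(m + 1):
                if proj[i] == 0:
                    continue
                w = p_k * phi[j] * proj[i]
                # swept ancestor uniform among the m members
                out[i - 1 + (n - k)] += w * (i / m)  # swept member derived
                out[i] += w * (1 - i / m)            # swept member ancestral
    out[0] = out[n] = 0.0
    mass = out.sum()
    if mass < 1e-12:
        return None
    return out / mass


def brute_omega(positions, r2, centre, min_side=3, floor=1e-6):
    """omega by direct enumeration over all flank extents (complete r2)."""
    left = [i for i, p in enumerate(positions) if p < centre]
    right = [i for i, p in enumerate(positions) if p >= centre]
    left = sorted(left, key=lambda i: centre - positions[i])
    right = sorted(right, key=lambda i: positions[i] - centre)
    best = float("nan")
    for nl in range(min_side, len(left) + 1):
        for nr in range(min_side, len(right) + 1):
            lset = left[:nl]
            rset = right[:nr]
            within = []
            for a in range(nl):
                for b in range(a + 1, nl):
                    within.append(r2[lset[a], lset[b]])
            for a in range(nr):
                for b in range(a + 1, nr):
                    within.append(r2[rset[a], rset[b]])
            between = [r2[i, j] for i in lset for j in rset]
            w = sum(within) / len(within)
            bt = max(sum(between) / len(between), floor)
            val = w / bt
            if not best == best or val > best:
                best = val
    return best
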