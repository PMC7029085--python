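"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or elementwise
summation, deliberately sharing no code path with the implementation it
checks.
"""

from __future__ import annotations

from math import exp, lgamma, log

import numpy as np

from snpkin.io_formats import MISSING
from snpkin.pedsim import Pedigree


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by direct log-factorial evaluation of every
    heterozygote count compatible with the allele counts."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    def logprob(h: int) -> float:
        hom_r = (rare - h) // 2
        hom_c = (2 * n - rare - h) // 2
        return (
            lgamma(n + 1)
            - lgamma(hom_r + 1)
            - lgamma(h + 1)
            - lgamma(hom_c + 1)
            + h * log(2.0)
            + lgamma(rare + 1)
            + lgamma(2 * n - rare + 1)
            - lgamma(2 * n + 1)
        )

    hs = list(range(rare % 2, rare + 1, 2))
    probs = np.array([exp(logprob(h)) for h in hs])
    probs /= probs.sum()
    p_obs = probs[hs.index(n_Aa)]
    return min(float(probs[probs <= p_obs * (1 + 1e-12)].sum()), 1.0)


def grm_bruteforce(calls: np.ndarray, p: np.ndarray):
    """Element-by-element A_g and D_g with pairwise-complete loci.

    Triple loop over pairs and loci; missing entries skip the locus for
    that pair.
    """
    n, m = calls.shape
    q = 1.0 - p
    A = np.zeros((n, n))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            sa = sd = 0.0
            cnt = 0
            for k in range(m):
                xi, xj = int(calls[i, k]), int(calls[j, k])
                if xi == MISSING or xj == MISSING:
                    continue
                pk, qk = p[k], q[k]
                sa += (xi - 2 * pk) * (xj - 2 * pk) / (2 * pk * qk)
                w = {0: -2 * pk**2, 1: 2 * pk * qk, 2: -2 * qk**2}
                sd += w[xi] * w[xj] / (2 * pk * qk) ** 2
                cnt += 1
            A[i, j] = A[j, i] = sa / cnt
            D[i, j] = D[j, i] = sd / cnt
    return A, D


def pedigree_enumeration(ped: Pedigree, i: str, j: str):
    """Exact kinship, inbreeding and dominance by enumerating every
    transmission pattern (2 bits per non-founder), weighting each
    pattern equally.

    Returns (kinship_ij, F_i, F_j, dominance_ij) where dominance is the
    probability both alleles of i are IBD to both alleles of j under
    one of the two pairings.
    """
    order = ped.topological_order
    nonfounders = [x for x in order if ped.parents.get(x) is not None]
    n_bits = 2 * len(nonfounders)
    assert n_bits <= 24, "enumeration oracle limited to small pedigrees"

    kin = F_i = F_j = dom = 0.0
    n_pat = 2**n_bits
    for pattern in range(n_pat):
        alleles: dict[str, tuple] = {}
        for x in order:
            par = ped.parents.get(x)
            if par is None:
                alleles[x] = ((x, 0), (x, 1))
        for b, x in enumerate(nonfounders):
            s, d = ped.parents[x]
            bit_s = (pattern >> (2 * b)) & 1
            bit_d = (pattern >> (2 * b + 1)) & 1
            alleles[x] = (alleles[s][bit_s], alleles[d][bit_d])
        ai, aj = alleles[i], alleles[j]
        kin += sum(a == b for a in ai for b in aj) / 4.0
        F_i += ai[0] == ai[1]
        F_j += aj[0] == aj[1]
        dom += (ai[0] == aj[0] and ai[1] == aj[1]) or (
            ai[0] == aj[1] and ai[1] == aj[0]
        )
    return kin / n_pat, F_i / n_pat, F_j / n_pat, dom / n_pat


def ibs_enumeration(x, y):
    """IBS class counts by explicit per-locus case analysis on allele
    multisets."""
    geno = {0: ("r", "r"), 1: ("r", "a"), 2: ("a", "a")}
    c = [0, 0, 0]
    n = 0
    for xi, yi in zip(x, y):
        if xi == MISSING or yi == MISSING:
            continue
        gx, gy = list(geno[int(xi)]), list(geno[int(yi)])
        shared = 0
        gy2 = gy.copy()
        for a in gx:
            if a in gy2:
                gy2.remove(a)
                shared += 1
        c[shared] += 1
        n += 1
    return c[0], c[1], c[2], n


def anova_textbook(groups: list[np.ndarray]):
    """One-way ANOVA F statistic from the sum-of-squares decomposition."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)
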