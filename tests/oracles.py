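"""Independent brute-force oracles, written from first principles.

Everything here uses scalar Python loops and explicit allele enumeration,
deliberately sharing no code with the package implementation.
"""
from __future__ import annotations

from itertools import combinations
from math import comb

MISSING = -1


def mendel_vector(father: int, mother: int) -> list[float]:
    """Offspring genotype distribution by enumerating transmitted alleles."""
    transmit = {0: [0, 0], 1: [0, 1], 2: [1, 1]}
    out = [0.0, 0.0, 0.0]
    for af in transmit[father]:
        for am in transmit[mother]:
            out[af + am] += 0.25
    return out


def possible_offspring_multiset(father: int, mother: int) -> list[int]:
    transmit = {0: [0, 0], 1: [0, 1], 2: [1, 1]}
    return sorted(af + am for af in transmit[father] for am in transmit[mother])


def corrected_vectors(child, father, mother, usable, j, tol=1e-9, max_iter=500):
    """Per-trio corrected expected 3-vectors at marker j.

    Repeats multiply-by-(observed/expected)-and-renormalize until the
    expected genotype counts match the observed ones (the marginal-matching
    fixed point) to within ``tol``, or the sweep budget runs out.  The
    stopping rule matches the one the tested implementation declares, so
    both stop at the same iterate of the same map.
    """
    n = len(child)
    num = [0.0, 0.0, 0.0]
    vecs = {}
    for t in range(n):
        if usable[t][j]:
            num[child[t][j]] += 1.0
            vecs[t] = mendel_vector(father[t][j], mother[t][j])
    for _ in range(max_iter):
        den = [0.0, 0.0, 0.0]
        for v in vecs.values():
            for g in range(3):
                den[g] += v[g]
        resid = max(abs(num[g] - den[g]) for g in range(3))
        if resid < tol:
            break
        fac = [num[g] / den[g] if den[g] > 0 else 1.0 for g in range(3)]
        for t, v in vecs.items():
            w = [v[g] * fac[g] for g in range(3)]
            s = sum(w)
            vecs[t] = [x / s for x in w]
    return vecs


def pair_table(child, father, mother, usable, a, b):
    """Observed and expected 3x3 tables for one marker pair (nested lists)."""
    va = corrected_vectors(child, father, mother, usable, a)
    vb = corrected_vectors(child, father, mother, usable, b)
    obs = [[0] * 3 for _ in range(3)]
    exp = [[0.0] * 3 for _ in range(3)]
    n_pair = 0
    for t in range(len(child)):
        if usable[t][a] and usable[t][b]:
            n_pair += 1
            obs[child[t][a]][child[t][b]] += 1
            for j in range(3):
                for k in range(3):
                    exp[j][k] += va[t][j] * vb[t][k]
    return obs, exp, n_pair


def chi2_like_score(obs, exp) -> float:
    s = 0.0
    for j in range(3):
        for k in range(3):
            if exp[j][k] > 0:
                s += (obs[j][k] - exp[j][k]) ** 2 / exp[j][k]
    return s


def count_pvalue(observed, null, smoothed=True) -> float:
    k = sum(1 for x in null if x >= observed)
    return (1 + k) / (1 + len(null)) if smoothed else k / len(null)


def bh_qvalues(pvalues) -> list[float]:
    """Step-up BH by the textbook formula, order-preserving."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def hypergeom_tail_by_enumeration(universe, partners_a, partners_b, focal_a, focal_b):
    """P(overlap >= observed) by enumerating all draws of |A| loci.

    The two focal loci are removed from the universe and both partner sets
    first.  Exact for small universes.
    """
    excl = {focal_a, focal_b}
    uni = sorted(set(universe) - excl)
    A = set(partners_a) - excl
    B = set(partners_b) - excl
    shared = len(A & B)
    total = comb(len(uni), len(A))
    hits = sum(1 for draw in combinations(uni, len(A)) if len(set(draw) & B) >= shared)
    return hits / total if total else 1.0
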