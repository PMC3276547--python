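"""Pseudo-control permutation nulls, p-values and BH false discovery rates.

For every trio, the four genotypes the child could have inherited at a
marker (one transmitted allele per parent, duplicates kept) are enumerated;
pseudo-offspring are assembled by drawing one of the four uniformly and
independently at every marker.  Each pseudo cohort is pushed through the
*identical* statistic pipeline — Mendelian expectation, distortion
correction recomputed from the pseudo data, renormalization, joint table,
score — giving a marker-pair-specific empirical null distribution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .genotype_io import MISSING, GenotypeMatrix, TrioSet
from .mendel import MENDELIAN
from . import core
from .core import InsufficientPairTrios


def _possible_table() -> np.ndarray:
    t = np.zeros((3, 3, 4), dtype=np.int8)
    transmit = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    for f in range(3):
        for m in range(3):
            t[f, m] = sorted(af + am for af in transmit[f] for am in transmit[m])
    return t


#: (father, mother) -> the 4 equally likely offspring genotypes (multiset)
POSSIBLE_OFFSPRING: np.ndarray = _possible_table()
POSSIBLE_OFFSPRING.setflags(write=False)


def possible_offspring(father_gt: int, mother_gt: int) -> np.ndarray:
    """The four offspring genotypes (with multiplicity) a trio allows.

    Uniform sampling over the returned multiset reproduces the Mendelian
    transmission probabilities.
    """
    f, m = int(father_gt), int(mother_gt)
    if f not in (0, 1, 2) or m not in (0, 1, 2):
        raise ValueError("parental genotypes must be non-missing (in {0,1,2})")
    return POSSIBLE_OFFSPRING[f, m].copy()


@dataclass
class PseudoOffspringDraw:
    """One pseudo-offspring genome per trio; MISSING where the trio is unusable."""

    genotypes: np.ndarray  # (n_trios, n_markers) int8
    state: dict


def sample_pseudo_offspring(
    gm: GenotypeMatrix, trios: TrioSet, rng: np.random.Generator
) -> PseudoOffspringDraw:
    """Draw one pseudo-offspring genotype per (trio, marker), independently."""
    g = gm.genotypes
    fg, mg = g[trios.father], g[trios.mother]
    u = trios.usable
    idx = rng.integers(0, 4, size=u.shape)
    draw = POSSIBLE_OFFSPRING[np.where(u, fg, 0), np.where(u, mg, 0), idx]
    draw = np.where(u, draw, MISSING).astype(np.int8)
    return PseudoOffspringDraw(draw, {"bit_generator": type(rng.bit_generator).__name__})


@dataclass
class PermutationResult:
    marker_a: int
    marker_b: int
    observed_S: float
    null_S: np.ndarray  # (B,)
    p_value: float
    B: int
    n_pair: int


def pvalue_from_null(observed_S: float, null_S: np.ndarray, smoothed: bool = True) -> float:
    """Fraction of null scores at or above the observed score.

    With ``smoothed`` (default) the add-one estimate ``(1 + k) / (1 + B)`` is
    used, guaranteeing p > 0; otherwise the raw fraction ``k / B``.  Ties
    count against the observed score.
    """
    null_S = np.asarray(null_S, dtype=float)
    k = int((null_S >= observed_S).sum())
    B = null_S.size
    return (1 + k) / (1 + B) if smoothed else k / B


def pair_rng(seed: int, marker_a: int, marker_b: int) -> np.random.Generator:
    """Independent, order-stable RNG stream for one marker pair."""
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(int(marker_a), int(marker_b)))
    )


def _pair_pipeline_scores(
    children_a: np.ndarray,  # (B, k) genotypes at marker a (MISSING where unusable)
    children_b: np.ndarray,
    probs_a: np.ndarray,  # (k, 3) Mendelian probs, zero where unusable
    probs_b: np.ndarray,
    usable_a: np.ndarray,
    usable_b: np.ndarray,
) -> np.ndarray:
    """Run correction + normalization + joint table + score for B child cohorts.

    Vectorized over the leading axis; used for both the observed cohort
    (B = 1) and the pseudo-control cohorts, so observed and null statistics
    pass through byte-identical code.
    """
    pu = usable_a & usable_b

    def marginals(children, probs, usable, tol=core.CORRECTION_TOL,
                  max_iter=core.CORRECTION_MAX_SWEEPS):
        # Iterated per-marker correction, as in core.normalized_expected_field,
        # run independently for every cohort (so observed and pseudo-control
        # cohorts pass through the identical map).  Because one sweep maps
        # v -> (v*f)/sum(v*f), the state after any number of sweeps is
        # v*F/sum(v*F) for the cumulative factor F: it suffices to iterate F
        # on the <= 9 distinct parental Mendelian vectors at this marker.
        onehot = ((children[..., None] == np.arange(3)) & usable[None, :, None]).astype(float)
        obs = onehot.sum(axis=1)  # (B, 3)
        B = obs.shape[0]
        v, counts = np.unique(probs[usable], axis=0, return_counts=True)  # (C, 3)
        F = np.ones((B, 3))
        still = np.ones(B, dtype=bool)
        for _ in range(max_iter):
            w = v[None, :, :] * F[still][:, None, :]  # (B_active, C, 3)
            s = w.sum(axis=2)
            exp = np.einsum("c,bcg->bg", counts.astype(float), w / s[:, :, None])
            if ((obs[still] > 0) & (exp == 0)).any():
                raise RuntimeError("observed genotype with zero Mendelian expectation")
            conv = np.abs(obs[still] - exp).max(axis=1) < tol
            fac = np.divide(obs[still], exp, out=np.ones_like(exp), where=exp > 0)
            fac[conv] = 1.0
            F[still] *= fac
            F[still] /= F[still].max(axis=1, keepdims=True)  # guard against drift
            still[still] = ~conv
            if not still.any():
                break
        w = probs[None, :, :] * F[:, None, :]  # (B, k, 3)
        s = w.sum(axis=2)
        if (s[:, usable] <= 0).any():
            raise ValueError("corrected expectation sums to zero for a usable entry")
        norm = np.divide(w, s[..., None], out=np.zeros_like(w), where=s[..., None] > 0)
        return onehot * pu[None, :, None], norm * pu[None, :, None]

    Ia, Pa = marginals(children_a, probs_a, usable_a)
    Ib, Pb = marginals(children_b, probs_b, usable_b)
    E = np.einsum("btj,btk->bjk", Pa, Pb)
    O = np.einsum("btj,btk->bjk", Ia, Ib)
    nz = E > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(nz, (O - E) ** 2 / np.where(nz, E, 1.0), 0.0)
    return contrib.sum(axis=(1, 2))


def permutation_pvalue(
    gm: GenotypeMatrix,
    trios: TrioSet,
    marker_a: int,
    marker_b: int,
    B: int = 1000,
    seed: int = 0,
    min_pair_trios: int = 20,
    smoothed: bool = True,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Marker-pair permutation p-value from B pseudo-control cohorts.

    The RNG stream is derived from ``(seed, marker_a, marker_b)`` so results
    do not depend on the order in which pairs are evaluated.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    a, b = int(marker_a), int(marker_b)
    if rng is None:
        rng = pair_rng(seed, a, b)
    g = gm.genotypes
    fa, ma = g[trios.father][:, a], g[trios.mother][:, a]
    fb, mb = g[trios.father][:, b], g[trios.mother][:, b]
    ua, ub = trios.usable[:, a], trios.usable[:, b]
    n_pair = int((ua & ub).sum())
    if n_pair < min_pair_trios:
        raise InsufficientPairTrios(
            f"pair ({a}, {b}): {n_pair} usable trios < minimum {min_pair_trios}"
        )
    pa = MENDELIAN[np.where(ua, fa, 0), np.where(ua, ma, 0)] * ua[:, None]
    pb = MENDELIAN[np.where(ub, fb, 0), np.where(ub, mb, 0)] * ub[:, None]
    ca_obs = gm.genotypes[trios.child][:, a][None, :]
    cb_obs = gm.genotypes[trios.child][:, b][None, :]
    observed_S = float(_pair_pipeline_scores(ca_obs, cb_obs, pa, pb, ua, ub)[0])

    idx_a = rng.integers(0, 4, size=(B, trios.n_trios))
    idx_b = rng.integers(0, 4, size=(B, trios.n_trios))
    ca = POSSIBLE_OFFSPRING[np.where(ua, fa, 0), np.where(ua, ma, 0), idx_a]
    cb = POSSIBLE_OFFSPRING[np.where(ub, fb, 0), np.where(ub, mb, 0), idx_b]
    ca = np.where(ua[None, :], ca, MISSING)
    cb = np.where(ub[None, :], cb, MISSING)
    null_S = _pair_pipeline_scores(ca, cb, pa, pb, ua, ub)
    p = pvalue_from_null(observed_S, null_S, smoothed=smoothed)
    return PermutationResult(a, b, observed_S, null_S, p, B, n_pair)


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
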