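"""The imbalanced-allele-pair (ImAP) test statistic.

For every trio and marker, the child's expected genotype distribution is the
Mendelian transmission probability given the parents.  Sample-wide departures
from Mendelian expectation at a single marker (segregation distortion,
single-locus viability selection) are absorbed by multiplying each expected
3-vector with per-marker, per-genotype correction factors — the ratio of the
sample-wide observed to expected genotype frequency — and renormalizing each
individual's vector to sum to one.  For a marker pair, observed 3x3 joint
genotype counts are compared with expected counts built from the product of
the two corrected marginals (the independence null), via the chi-square-like
score

    S = sum_{j,k: E_jk > 0} (O_jk - E_jk)^2 / E_jk .
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, TrioSet
from .mendel import MENDELIAN, mendelian_offspring_probs  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)


class InsufficientPairTrios(ValueError):
    """Raised when a marker pair has fewer jointly usable trios than required."""


@dataclass
class ExpectedGenotypeField:
    """Per (trio, marker) expected genotype 3-vectors.

    ``probs[t, m]`` is zero everywhere the trio is unusable at the marker;
    at stages ``mendelian`` and ``normalized`` every usable vector sums to 1.
    """

    probs: np.ndarray  # (n_trios, n_markers, 3) float64
    usable: np.ndarray  # (n_trios, n_markers) bool
    stage: str

    def validate(self, atol: float = 1e-9) -> None:
        if (self.probs < 0).any():
            raise ValueError("negative expected probabilities")
        if self.stage in ("mendelian", "normalized"):
            sums = self.probs.sum(axis=2)
            if not np.allclose(sums[self.usable], 1.0, atol=atol):
                raise ValueError(f"usable 3-vectors do not sum to 1 at stage {self.stage}")
            if np.abs(sums[~self.usable]).max(initial=0.0) > atol:
                raise ValueError("unusable entries must be zero")


@dataclass
class CorrectionFactors:
    """Per-marker, per-genotype observed/expected frequency ratios."""

    factors: np.ndarray  # (n_markers, 3) float64

    def validate(self) -> None:
        if not np.isfinite(self.factors).all() or (self.factors < 0).any():
            raise ValueError("correction factors must be finite and non-negative")


@dataclass
class JointGenotypeTable:
    """Observed and expected 3x3 joint genotype counts for one marker pair."""

    observed: np.ndarray  # (3, 3) int
    expected: np.ndarray  # (3, 3) float
    n_pair: int
    marker_a: int
    marker_b: int

    def validate(self, atol: float = 1e-6) -> None:
        if (self.observed < 0).any():
            raise ValueError("negative observed counts")
        if int(self.observed.sum()) != self.n_pair:
            raise ValueError("observed counts do not sum to n_pair")
        if (self.expected < -atol).any():
            raise ValueError("negative expected counts")
        if abs(float(self.expected.sum()) - self.n_pair) > atol:
            raise ValueError("expected counts do not sum to n_pair")
        if ((self.expected == 0) & (self.observed > 0)).any():
            raise ValueError("observed count in a zero-expectation cell")


@dataclass
class ImapScore:
    statistic: float
    n_pair: int
    n_nonzero_cells: int


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def expected_field(gm: GenotypeMatrix, trios: TrioSet) -> ExpectedGenotypeField:
    """Mendelian expected genotype field from the parental genotypes."""
    g = gm.genotypes
    fg = g[trios.father]
    mg = g[trios.mother]
    u = trios.usable
    probs = MENDELIAN[np.where(u, fg, 0), np.where(u, mg, 0)]
    probs = probs * u[..., None]
    return ExpectedGenotypeField(probs, u, "mendelian")


def correction_factors(gm: GenotypeMatrix, trios: TrioSet, field: ExpectedGenotypeField) -> CorrectionFactors:
    """Observed/expected sample-wide genotype frequency ratio per marker.

    When a genotype class is neither observed nor expected at a marker the
    factor is defined as 1 (it multiplies a zero anyway).  A positive observed
    count with zero expectation cannot occur once Mendelian-inconsistent calls
    have been masked upstream, and is reported as an internal error.
    """
    if field.stage != "mendelian":
        raise ValueError("correction_factors requires a mendelian-stage field")
    cg = gm.genotypes[trios.child]
    u = trios.usable
    obs = np.stack([((cg == g) & u).sum(axis=0) for g in range(3)], axis=1).astype(float)
    exp = field.probs.sum(axis=0)  # (m, 3)
    if ((obs > 0) & (exp == 0)).any():
        raise RuntimeError(
            "observed genotype with zero Mendelian expectation; "
            "Mendelian-inconsistent trios were not masked"
        )
    factors = np.divide(obs, exp, out=np.ones_like(obs), where=exp > 0)
    cf = CorrectionFactors(factors)
    cf.validate()
    return cf


def apply_correction_and_normalize(
    field: ExpectedGenotypeField, cf: CorrectionFactors
) -> ExpectedGenotypeField:
    """Multiply by the marker's factors, renormalize each usable 3-vector."""
    if field.stage != "mendelian":
        raise ValueError("expected a mendelian-stage field")
    corrected = field.probs * cf.factors[None, :, :]
    sums = corrected.sum(axis=2)
    if (sums[field.usable] <= 0).any():
        raise ValueError("corrected expectation sums to zero for a usable entry")
    probs = np.divide(corrected, sums[..., None], out=np.zeros_like(corrected), where=sums[..., None] > 0)
    return ExpectedGenotypeField(probs, field.usable, "normalized")


#: stopping rule of the marginal-matching sweep; part of the algorithm
#: definition so that independent implementations stop at the same iterate
CORRECTION_TOL: float = 1e-9
CORRECTION_MAX_SWEEPS: int = 500


def normalized_expected_field(
    gm: GenotypeMatrix,
    trios: TrioSet,
    tol: float = CORRECTION_TOL,
    max_iter: int = CORRECTION_MAX_SWEEPS,
) -> ExpectedGenotypeField:
    """Distortion-corrected expected field with matched sample-wide marginals.

    One multiply-and-renormalize sweep (``correction_factors`` followed by
    ``apply_correction_and_normalize``) moves the sample-wide expected
    genotype frequencies toward the observed ones but, because the
    per-individual renormalization redistributes mass, does not land on them
    exactly.  The sweep is therefore repeated per marker — a biproportional
    (iterative proportional fitting) scheme with unit row sums and the
    observed genotype counts as column targets — until that marker's
    expected counts match the observed ones to within ``tol`` or the sweep
    budget is exhausted (degenerate tables can approach the match only in
    the limit).  Each marker stops at the first sweep that satisfies ``tol``,
    so the result does not depend on the other markers in the panel.
    """
    field = expected_field(gm, trios)
    cg = gm.genotypes[trios.child]
    u = trios.usable
    obs = np.stack([((cg == g) & u).sum(axis=0) for g in range(3)], axis=1).astype(float)
    probs = field.probs
    active = np.ones(probs.shape[1], dtype=bool)
    for _ in range(max_iter):
        exp = probs[:, active, :].sum(axis=0)
        resid = np.abs(obs[active] - exp).max(axis=1)
        if ((obs[active] > 0) & (exp == 0)).any():
            raise RuntimeError(
                "observed genotype with zero expectation; "
                "Mendelian-inconsistent trios were not masked"
            )
        still = resid >= tol
        active[active] = still
        if not active.any():
            break
        exp = exp[still]
        factors = np.divide(
            obs[active], exp, out=np.ones_like(exp), where=exp > 0
        )
        corrected = probs[:, active, :] * factors[None, :, :]
        sums = corrected.sum(axis=2)
        if (sums[u[:, active]] <= 0).any():
            raise ValueError("corrected expectation sums to zero for a usable entry")
        probs[:, active, :] = np.divide(
            corrected, sums[..., None], out=np.zeros_like(corrected), where=sums[..., None] > 0
        )
    return ExpectedGenotypeField(probs, u, "normalized")


def joint_table(
    gm: GenotypeMatrix,
    trios: TrioSet,
    field: ExpectedGenotypeField,
    marker_a: int,
    marker_b: int,
    min_pair_trios: int = 20,
) -> JointGenotypeTable:
    """Observed and expected 3x3 joint genotype counts over pair-usable trios."""
    if field.stage != "normalized":
        raise ValueError("joint_table requires a normalized-stage field")
    a, b = int(marker_a), int(marker_b)
    pu = trios.usable[:, a] & trios.usable[:, b]
    n_pair = int(pu.sum())
    if n_pair < min_pair_trios:
        raise InsufficientPairTrios(
            f"pair ({a}, {b}): {n_pair} usable trios < minimum {min_pair_trios}"
        )
    cg = gm.genotypes[trios.child]
    ga, gb = cg[pu, a].astype(np.intp), cg[pu, b].astype(np.intp)
    observed = np.bincount(ga * 3 + gb, minlength=9).reshape(3, 3)
    expected = np.einsum("tj,tk->jk", field.probs[pu, a, :], field.probs[pu, b, :])
    tab = JointGenotypeTable(observed, expected, n_pair, a, b)
    tab.validate()
    return tab


def imap_statistic(tab: JointGenotypeTable) -> ImapScore:
    """Chi-square-like score over the nine genotype-combination cells.

    Cells with zero expectation are excluded: the correction pipeline forces
    the observed count there to zero as well, making 0/0 the only case, which
    is defined as contributing 0.
    """
    O = tab.observed.astype(float)
    E = tab.expected
    nz = E > 0
    if ((~nz) & (O > 0)).any():
        raise ValueError("observed count in a cell with zero expectation")
    s = float((((O - E) ** 2)[nz] / E[nz]).sum())
    return ImapScore(s, tab.n_pair, int(nz.sum()))


def score_pair(
    gm: GenotypeMatrix,
    trios: TrioSet,
    field: ExpectedGenotypeField,
    marker_a: int,
    marker_b: int,
    min_pair_trios: int = 20,
) -> ImapScore:
    """Convenience: joint table + statistic for one marker pair."""
    return imap_statistic(joint_table(gm, trios, field, marker_a, marker_b, min_pair_trios))


def score_all_pairs(
    gm: GenotypeMatrix,
    trios: TrioSet,
    field: ExpectedGenotypeField,
    pairs: np.ndarray,
    min_pair_trios: int = 20,
) -> pd.DataFrame:
    """Vectorized statistic for many marker pairs at once.

    Builds the full cross-products ``E[a,j,b,k] = sum_t P[t,a,j] P[t,b,k]``
    and the matching observed counts with two rank-3 matrix products, then
    reads off the requested pairs.  Pairs with fewer than ``min_pair_trios``
    jointly usable trios get ``S = NaN``.  Suitable for marker panels up to a
    few thousand markers (memory grows as ``(3m)^2``).

    Returns a DataFrame with columns ``a, b, n_pair, S``.
    """
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    if field.stage != "normalized":
        raise ValueError("score_all_pairs requires a normalized-stage field")
    k, m = trios.usable.shape
    u = trios.usable
    cg = gm.genotypes[trios.child]
    onehot = ((cg[..., None] == np.arange(3)) & u[..., None]).astype(np.float64)
    P2 = field.probs.reshape(k, 3 * m)
    I2 = onehot.reshape(k, 3 * m)
    E = (P2.T @ P2).reshape(m, 3, m, 3)
    O = (I2.T @ I2).reshape(m, 3, m, 3)
    uf = u.astype(np.float64)
    npair = np.rint(uf.T @ uf).astype(int)

    ia, ib = pairs[:, 0], pairs[:, 1]
    Ep = E[ia, :, ib, :]  # (npairs, 3, 3)
    Op = np.rint(O[ia, :, ib, :])
    nz = Ep > 0
    if (nz.sum() and ((~nz) & (Op > 0)).any()):
        raise ValueError("observed count in a cell with zero expectation")
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.where(nz, (Op - Ep) ** 2 / np.where(nz, Ep, 1.0), 0.0)
    S = contrib.sum(axis=(1, 2))
    n_pair = npair[ia, ib]
    S = np.where(n_pair >= min_pair_trios, S, np.nan)
    return pd.DataFrame({"a": ia, "b": ib, "n_pair": n_pair, "S": S})
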