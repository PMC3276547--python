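"""Mendelian transmission probabilities for biallelic diploid trios.

Genotypes are coded as minor-allele dosage: 0 = AA (major homozygote),
1 = Aa, 2 = aa (minor homozygote).
"""
from __future__ import annotations

import numpy as np


def _transmission_table() -> np.ndarray:
    """P(child genotype | father, mother) assuming fair transmission.

    Each parent passes its minor allele with probability dosage/2.
    """
    t = np.zeros((3, 3, 3))
    for f in range(3):
        for m in range(3):
            pf, pm = f / 2.0, m / 2.0
            t[f, m, 0] = (1 - pf) * (1 - pm)
            t[f, m, 1] = pf * (1 - pm) + (1 - pf) * pm
            t[f, m, 2] = pf * pm
    return t


#: (father, mother, child) -> probability of child genotype
MENDELIAN: np.ndarray = _transmission_table()
MENDELIAN.setflags(write=False)

#: (father, mother, child) -> True iff the child genotype is possible
CONSISTENT: np.ndarray = MENDELIAN > 0
CONSISTENT.setflags(write=False)


def mendelian_offspring_probs(father_gt: int, mother_gt: int) -> np.ndarray:
    """Probability 3-vector of offspring genotypes given parental genotypes.

    Parameters
    ----------
    father_gt, mother_gt
        Parental genotypes as minor-allele dosage in {0, 1, 2}.

    Returns
    -------
    numpy.ndarray
        Length-3 vector ``(P(AA), P(Aa), P(aa))``; symmetric in the parents.
    """
    f, m = int(father_gt), int(mother_gt)
    if f not in (0, 1, 2) or m not in (0, 1, 2):
        raise ValueError(
            f"parental genotypes must be in {{0,1,2}}, got ({father_gt}, {mother_gt});"
            " mask missing genotypes before calling"
        )
    return MENDELIAN[f, m].copy()
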