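import numpy as np
import pandas as pd
import pytest

from imap import genotype_io, pedigree_sim
from imap.genotype_io import MISSING, GenotypeMatrix, PedigreeTable


def make_markers(n, chroms=None):
    """Marker table helper: n markers, optionally split across chromosomes."""
    chroms = chroms or ["1"] * n
    return pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(n)],
            "chromosome": [str(c) for c in chroms],
            "position": _positions(chroms),
            "allele_major": "A",
            "allele_minor": "B",
        }
    )


def _positions(chroms):
    pos, count = [], {}
    for c in chroms:
        count[c] = count.get(c, 0) + 1
        pos.append(count[c] * 1000)
    return pos


def make_gm(genotypes, chroms=None, ids=None):
    g = np.asarray(genotypes, dtype=np.int8)
    ids = ids or [f"i{k}" for k in range(g.shape[0])]
    return GenotypeMatrix(g, ids, make_markers(g.shape[1], chroms))


def random_trio_dataset(rng, n_trios=5, n_markers=4, missing_rate=0.1, chroms=None):
    """Random Mendelian-consistent trio data with some missingness.

    Children are drawn from their parents' transmitted alleles, so the data
    are consistent by construction; missingness is overlaid afterwards.
    """
    transmit = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    fg = rng.integers(0, 3, size=(n_trios, n_markers))
    mg = rng.integers(0, 3, size=(n_trios, n_markers))
    cg = np.empty_like(fg)
    for t in range(n_trios):
        for j in range(n_markers):
            cg[t, j] = transmit[fg[t, j]][rng.integers(2)] + transmit[mg[t, j]][rng.integers(2)]
    geno = np.concatenate([cg, fg, mg]).astype(np.int8)
    mask = rng.random(geno.shape) < missing_rate
    geno[mask] = MISSING
    ids = (
        [f"c{t}" for t in range(n_trios)]
        + [f"f{t}" for t in range(n_trios)]
        + [f"m{t}" for t in range(n_trios)]
    )
    gm = GenotypeMatrix(geno, ids, make_markers(n_markers, chroms))
    rows = [
        {"individual_id": f"c{t}", "father_id": f"f{t}", "mother_id": f"m{t}"}
        for t in range(n_trios)
    ] + [
        {"individual_id": p, "father_id": None, "mother_id": None}
        for t in range(n_trios)
        for p in (f"f{t}", f"m{t}")
    ]
    ped = PedigreeTable(pd.DataFrame(rows))
    return gm, ped


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def null_sim():
    """Session-wide simulated null dataset under the default study conditions."""
    return pedigree_sim.simulate_dataset(7)


@pytest.fixture(scope="session")
def null_qc(null_sim):
    gm = genotype_io.filter_individuals(null_sim.gm)
    gm = genotype_io.filter_markers(gm)
    trios = genotype_io.extract_trios(gm, null_sim.ped)
    return gm, trios
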