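"""Gene-dropping pedigree simulator for trio genotype data.

Emulates a heterogeneous stock: a small number of fully inbred founder
lines, a founder generation homozygous for one line's haplotypes each, and
several generations of random mating with recombination.  Genotyping error
(Mendelian-consistent by construction) and missingness are layered on top.
An optional two-locus Dobzhansky-Muller incompatibility removes offspring
carrying a lethal genotype combination with selection coefficient ``s``
(rejection sampling of gametes).

Because markers are simulated independently within founder lines, data
generated without an incompatibility carry no two-locus interactions —
this is the null-calibration engine for the permutation test, and the
factory for planted-truth power fixtures.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PedigreeTable,
    TrioSet,
    chromosome_slices,
    extract_trios,
)
from .mendel import CONSISTENT, MENDELIAN

logger = logging.getLogger(__name__)


@dataclass
class RecombinationMap:
    """Per-chromosome crossover probabilities for adjacent marker intervals."""

    rates: dict[str, np.ndarray]

    def __post_init__(self):
        self.rates = {str(c): np.asarray(r, dtype=float) for c, r in self.rates.items()}
        for c, r in self.rates.items():
            if ((r < 0) | (r > 0.5)).any():
                raise ValueError(f"chromosome {c}: crossover probabilities must be in [0, 0.5]")

    @classmethod
    def uniform(cls, markers: pd.DataFrame, rate: float = 0.05) -> "RecombinationMap":
        return cls(
            {c: np.full(max(sl.stop - sl.start - 1, 0), rate) for c, sl in chromosome_slices(markers).items()}
        )


@dataclass
class IncompatibilitySpec:
    """A lethal two-locus genotype combination between unlinked markers.

    The default lethal combination ``(1, 1)`` — heterozygous at both loci —
    is the doubly-heterozygous state in which dominant-acting
    incompatibilities classically manifest (the F1-hybrid genotype).  A
    recessive incompatibility is ``lethal=(2, 2)``.  ``s`` is the
    probability that a conceptus carrying the combination dies.
    """

    marker_a: str
    marker_b: str
    lethal: tuple[int, int] = (1, 1)
    s: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("selection coefficient s must be in [0, 1]")
        if not (self.lethal[0] in (0, 1, 2) and self.lethal[1] in (0, 1, 2)):
            raise ValueError("lethal genotypes must be in {0, 1, 2}")


def make_marker_map(
    n_chromosomes: int = 5, markers_per_chromosome: int = 40, spacing_bp: int = 2_000_000
) -> pd.DataFrame:
    """Evenly spaced biallelic marker grid (alleles labelled A/B)."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        for j in range(markers_per_chromosome):
            rows.append(
                {
                    "marker_id": f"c{c}m{j + 1:03d}",
                    "chromosome": str(c),
                    "position": (j + 1) * spacing_bp,
                    "allele_major": "A",
                    "allele_minor": "B",
                }
            )
    return pd.DataFrame(rows)


def generate_founders(
    marker_map: pd.DataFrame,
    n_lines: int = 8,
    n_founders: int = 40,
    line_allele_freq: float = 0.5,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], dict[str, np.ndarray], np.ndarray]:
    """Phased founders: inbred lines assigned round-robin.

    Each line gets one haplotype (alleles i.i.d. Bernoulli(line_allele_freq)
    per marker); each founder is homozygous for its line's haplotype.

    Returns (founder ids, id -> (2, m) haplotype pair, line haplotypes).
    """
    if n_lines < 2:
        logger.warning("n_lines < 2: all founders monomorphic, MAF filters will remove everything")
    rng = np.random.default_rng() if rng is None else rng
    m = len(marker_map)
    line_haps = (rng.random((n_lines, m)) < line_allele_freq).astype(np.int8)
    ids = [f"F0_{i + 1:03d}" for i in range(n_founders)]
    haps = {iid: np.vstack([line_haps[i % n_lines]] * 2) for i, iid in enumerate(ids)}
    return ids, haps, line_haps


def simulate_gamete(
    hap_pair: np.ndarray,
    rmap: RecombinationMap,
    chrom_slices_: dict[str, slice],
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a phased parent.

    Per chromosome: start on either haplotype with probability 1/2, then at
    each adjacent-marker interval switch haplotypes with the interval's
    crossover probability (a first-order Markov walk along the chromosome).
    """
    m = hap_pair.shape[1]
    gamete = np.empty(m, dtype=np.int8)
    for chrom, sl in chrom_slices_.items():
        mc = sl.stop - sl.start
        switches = rng.random(mc - 1) < rmap.rates[chrom]
        source = (rng.integers(0, 2) + np.concatenate(([0], np.cumsum(switches)))) % 2
        gamete[sl] = hap_pair[source, np.arange(sl.start, sl.stop)]
    return gamete


def _marker_indices(marker_map: pd.DataFrame, incompat: IncompatibilitySpec) -> tuple[int, int]:
    mid = {m: j for j, m in enumerate(marker_map["marker_id"])}
    ia, ib = mid[incompat.marker_a], mid[incompat.marker_b]
    ca = marker_map["chromosome"].iloc[ia]
    cb = marker_map["chromosome"].iloc[ib]
    if str(ca) == str(cb):
        raise ValueError("incompatibility loci must be on different chromosomes")
    return ia, ib


def _drop_child(
    father_hap: np.ndarray,
    mother_hap: np.ndarray,
    rmap: RecombinationMap,
    chrom_slices_: dict[str, slice],
    rng: np.random.Generator,
    incompat: IncompatibilitySpec | None,
    loci: tuple[int, int] | None,
    max_rejects: int,
    child_id: str,
) -> np.ndarray:
    for _ in range(max_rejects):
        gam_f = simulate_gamete(father_hap, rmap, chrom_slices_, rng)
        gam_m = simulate_gamete(mother_hap, rmap, chrom_slices_, rng)
        if incompat is not None and incompat.s > 0 and loci is not None:
            ia, ib = loci
            ga = int(gam_f[ia]) + int(gam_m[ia])
            gb = int(gam_f[ib]) + int(gam_m[ib])
            if (ga, gb) == tuple(incompat.lethal):
                if incompat.s >= 1.0 or rng.random() < incompat.s:
                    continue
        return np.vstack([gam_f, gam_m])
    raise RuntimeError(
        f"child {child_id!r}: rejection cap ({max_rejects}) exceeded; "
        "parents may only produce the lethal genotype combination"
    )


def simulate_pedigree(
    founder_haps: dict[str, np.ndarray],
    ped: PedigreeTable,
    marker_map: pd.DataFrame,
    rmap: RecombinationMap,
    rng: np.random.Generator,
    incompat: IncompatibilitySpec | None = None,
    max_rejects: int = 10_000,
) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Gene-drop genotypes through a fixed pedigree.

    Children are simulated in pedigree order (parents before children).
    With an incompatibility, a conceptus whose genotype combination equals
    the lethal one is rejected with probability ``s`` and its gametes
    resampled; exceeding ``max_rejects`` raises, naming the child.  With
    ``s = 0`` the RNG stream is identical to ``incompat=None``.
    """
    slices = chromosome_slices(marker_map)
    loci = _marker_indices(marker_map, incompat) if incompat is not None else None
    haps: dict[str, np.ndarray] = {}
    parents_of = {
        r["individual_id"]: (r["father_id"], r["mother_id"]) for _, r in ped.table.iterrows()
    }
    order = _topological_order(ped)
    for iid in order:
        f, m = parents_of[iid]
        if f is None and m is None:
            if iid not in founder_haps:
                raise ValueError(f"founder {iid!r} has no supplied haplotypes")
            haps[iid] = founder_haps[iid]
        elif f is None or m is None:
            raise ValueError(f"individual {iid!r} has exactly one known parent")
        else:
            haps[iid] = _drop_child(
                haps[f], haps[m], rmap, slices, rng, incompat, loci, max_rejects, iid
            )
    ids = list(ped.table["individual_id"])
    geno = np.stack([haps[i].sum(axis=0) for i in ids]).astype(np.int8)
    gm = GenotypeMatrix(geno, ids, marker_map.copy())
    return gm, haps


def _topological_order(ped: PedigreeTable) -> list[str]:
    t = ped.table
    parents = {
        r["individual_id"]: [p for p in (r["father_id"], r["mother_id"]) if p is not None]
        for _, r in t.iterrows()
    }
    order: list[str] = []
    done: set[str] = set()
    pending = list(t["individual_id"])
    while pending:
        rest = []
        for iid in pending:
            if all(p in done for p in parents[iid]):
                order.append(iid)
                done.add(iid)
            else:
                rest.append(iid)
        if len(rest) == len(pending):
            raise ValueError("pedigree is not topologically orderable")
        pending = rest
    return order


# ---------------------------------------------------------------------------
# error / missingness overlays
# ---------------------------------------------------------------------------

def inject_genotyping_errors(
    gm: GenotypeMatrix,
    trios: TrioSet,
    error_rate: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Flip a fraction of non-missing calls without creating Mendelian errors.

    Each selected entry is replaced by a different genotype drawn uniformly
    from those consistent with every trio the individual belongs to (as
    child and as parent), given the current state of the matrix.  Entries
    with no consistent alternative are left unchanged and another entry is
    drawn instead, so the realized flip count matches the target when
    possible.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    g = gm.genotypes.copy()
    n, m = g.shape
    if error_rate == 0.0:
        return GenotypeMatrix(g, list(gm.individual_ids), gm.markers.copy())

    as_child: dict[int, int] = {}  # individual row -> trio index
    as_father: dict[int, list[int]] = {}
    as_mother: dict[int, list[int]] = {}
    for t in range(trios.n_trios):
        c, f, mo = map(int, trios.trios[t])
        as_child[c] = t
        as_father.setdefault(f, []).append(t)
        as_mother.setdefault(mo, []).append(t)

    def consistent_alternatives(i: int, j: int) -> list[int]:
        cur = g[i, j]
        alts = []
        for cand in (0, 1, 2):
            if cand == cur:
                continue
            ok = True
            t = as_child.get(i)
            if t is not None and trios.usable[t, j]:
                f, mo = int(trios.trios[t, 1]), int(trios.trios[t, 2])
                ok &= bool(CONSISTENT[g[f, j], g[mo, j], cand])
            for t in as_father.get(i, ()):
                if ok and trios.usable[t, j]:
                    c, mo = int(trios.trios[t, 0]), int(trios.trios[t, 2])
                    ok &= bool(CONSISTENT[cand, g[mo, j], g[c, j]])
            for t in as_mother.get(i, ()):
                if ok and trios.usable[t, j]:
                    c, f = int(trios.trios[t, 0]), int(trios.trios[t, 1])
                    ok &= bool(CONSISTENT[g[f, j], cand, g[c, j]])
            if ok:
                alts.append(cand)
        return alts

    nonmissing = np.argwhere(g != MISSING)
    target = int(round(error_rate * len(nonmissing)))
    perm = rng.permutation(len(nonmissing))
    flipped = 0
    for k in perm:
        if flipped >= target:
            break
        i, j = map(int, nonmissing[k])
        alts = consistent_alternatives(i, j)
        if not alts:
            continue
        g[i, j] = alts[int(rng.integers(len(alts)))]
        flipped += 1
    if flipped < target:
        logger.warning("inject_genotyping_errors: only %d/%d entries flippable", flipped, target)
    return GenotypeMatrix(g, list(gm.individual_ids), gm.markers.copy())


def inject_missing(
    gm: GenotypeMatrix,
    pattern: float | np.ndarray,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Set entries to MISSING, either i.i.d. at a rate or by an exact mask."""
    g = gm.genotypes.copy()
    if np.isscalar(pattern):
        rate = float(pattern)  # type: ignore[arg-type]
        if not 0.0 <= rate <= 1.0:
            raise ValueError("missing rate must be in [0, 1]")
        if rng is None:
            raise ValueError("rng required for rate-based missingness")
        mask = rng.random(g.shape) < rate
    else:
        mask = np.asarray(pattern, dtype=bool)
        if mask.shape != g.shape:
            raise ValueError(f"mask shape {mask.shape} != genotype shape {g.shape}")
    g[mask] = MISSING
    return GenotypeMatrix(g, list(gm.individual_ids), gm.markers.copy())


# ---------------------------------------------------------------------------
# full-dataset factory
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Default study conditions for the synthetic heterogeneous stock."""

    n_lines: int = 8
    n_founders: int = 40
    n_generations: int = 3
    children_per_generation: int = 170
    #: ungenotyped random-mating generations between the inbred lines and the
    #: genotyped pedigree (a heterogeneous stock is typically genotyped many
    #: generations after its founding cross); 0 = genotype from the cross on
    premix_generations: int = 0
    premix_population: int = 80
    n_chromosomes: int = 5
    markers_per_chromosome: int = 40
    spacing_bp: int = 2_000_000
    crossover_rate: float = 0.05
    line_allele_freq: float = 0.5
    error_rate: float = 0.01
    missing_rate: float = 0.05


def planted_fixture_config() -> SimConfig:
    """Study conditions for planted-effect (power) runs.

    The genotyped pedigree sits eight ungenotyped mixing generations after
    the founding cross, as in a real heterogeneous stock: trio parents are
    outbred (informative) and planted-MAF targets refer to the mixed stock
    rather than to the inbred lines.  No genotyping-error or missingness
    overlay: this fixture is a positive control whose truth (a structurally
    zero genotype combination) must not be corrupted by measurement noise —
    the error/missingness overlays are exercised by the null fixture.
    """
    return SimConfig(premix_generations=8, error_rate=0.0, missing_rate=0.0)


@dataclass
class SimResult:
    gm: GenotypeMatrix
    ped: PedigreeTable
    truth: dict
    haplotypes: dict[str, np.ndarray] = dc_field(repr=False, default_factory=dict)


def plant_incompatibility(
    allele_freq: np.ndarray,
    marker_map: pd.DataFrame,
    rng: np.random.Generator,
    target_maf: float = 0.3,
    lethal: tuple[int, int] = (1, 1),
    s: float = 1.0,
) -> IncompatibilitySpec:
    """Choose two unlinked loci with current MAF nearest ``target_maf``.

    ``allele_freq`` is the per-marker frequency of the dosage-counted allele
    in the population the incompatibility is planted into (two random
    chromosomes are drawn, then the closest-MAF marker on each).
    """
    freq = np.asarray(allele_freq, dtype=float).reshape(-1)
    maf = np.minimum(freq, 1 - freq)
    chroms = marker_map["chromosome"].astype(str).to_numpy()
    uniq = sorted(set(chroms), key=lambda c: c)
    if len(uniq) < 2:
        raise ValueError("need markers on at least two chromosomes")
    ca, cb = rng.choice(np.array(uniq, dtype=object), size=2, replace=False)
    best = {}
    for c in (ca, cb):
        j = np.flatnonzero(chroms == c)
        best[c] = int(j[np.argmin(np.abs(maf[j] - target_maf))])
    mids = list(marker_map["marker_id"])
    return IncompatibilitySpec(mids[best[ca]], mids[best[cb]], lethal=lethal, s=s)


def simulate_dataset(
    seed: int | np.random.Generator,
    config: SimConfig | None = None,
    incompat: IncompatibilitySpec | str | None = None,
    target_maf: float = 0.3,
    lethal: tuple[int, int] = (1, 1),
    selection: float = 1.0,
) -> SimResult:
    """Founders, random mating, optional planted incompatibility, error overlay.

    ``incompat="auto"`` plants a lethal combination at two automatically
    chosen unlinked loci with founder MAF near ``target_maf``.  The pedigree
    is built generation by generation; under ``s = 1`` a mating that can
    only produce the lethal combination (e.g. AA x aa parents at both loci,
    forcing double heterozygotes) is redrawn — such a pairing leaves no
    surviving offspring.  The redraw consumes randomness only when it
    triggers, so a run with ``s = 0`` is stream-identical to one without an
    incompatibility.
    """
    cfg = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(int(seed))
    marker_map = make_marker_map(cfg.n_chromosomes, cfg.markers_per_chromosome, cfg.spacing_bp)
    founder_ids, haps, line_haps = generate_founders(
        marker_map, cfg.n_lines, cfg.n_founders, cfg.line_allele_freq, rng
    )
    haps = dict(haps)
    rmap = RecombinationMap.uniform(marker_map, cfg.crossover_rate)
    slices = chromosome_slices(marker_map)
    explicit = incompat if isinstance(incompat, IncompatibilitySpec) else None
    loci = _marker_indices(marker_map, explicit) if explicit is not None else None

    def mate(parents, sex_of, n_children, prefix, inc, inc_loci):
        males = [i for i in parents if sex_of[i] == "1"]
        females = [i for i in parents if sex_of[i] == "2"]
        if not males or not females:
            raise RuntimeError("a generation lacks one sex; cannot mate")
        out = []
        for c in range(n_children):
            iid = f"{prefix}{c + 1:03d}"
            for _ in range(1000):
                fa = males[int(rng.integers(len(males)))]
                mo = females[int(rng.integers(len(females)))]
                if (
                    inc is not None
                    and inc.s >= 1.0
                    and _forces_lethal(haps[fa], haps[mo], inc_loci, inc.lethal)
                ):
                    continue  # this pairing can leave no surviving offspring
                break
            else:
                raise RuntimeError(f"child {iid!r}: no viable mating found")
            haps[iid] = _drop_child(
                haps[fa], haps[mo], rmap, slices, rng, inc, inc_loci, 10_000, iid
            )
            sex_of[iid] = "1" if rng.integers(2) == 0 else "2"
            out.append((iid, fa, mo))
        return out

    # alternate sexes within each inbred line (line index cycles faster than
    # sex) so that every line contributes both fathers and mothers
    sex_of = {
        iid: "1" if (i // cfg.n_lines) % 2 == 0 else "2" for i, iid in enumerate(founder_ids)
    }
    # ungenotyped mixing generations; an explicitly supplied incompatibility
    # selects here too, an auto-planted one is chosen only afterwards
    pool = list(founder_ids)
    for k in range(cfg.premix_generations):
        born = mate(pool, sex_of, cfg.premix_population, f"P{k + 1}_", explicit, loci)
        pool = [iid for iid, _, _ in born]

    if incompat == "auto":
        pool_geno = np.stack([haps[i].sum(axis=0) for i in pool])
        freq = pool_geno.mean(axis=0) / 2.0
        incompat = plant_incompatibility(freq, marker_map, rng, target_maf, lethal, selection)
        loci = _marker_indices(marker_map, incompat)
    elif incompat is not None:
        incompat = explicit

    rows = [
        {"individual_id": iid, "father_id": None, "mother_id": None,
         "sex": sex_of[iid], "generation": 0}
        for iid in pool
    ]
    prev = pool
    for gen in range(1, cfg.n_generations + 1):
        born = mate(prev, sex_of, cfg.children_per_generation, f"F{gen}_", incompat, loci)
        rows.extend(
            {"individual_id": iid, "father_id": fa, "mother_id": mo,
             "sex": sex_of[iid], "generation": gen}
            for iid, fa, mo in born
        )
        prev = [iid for iid, _, _ in born]

    ped = PedigreeTable(pd.DataFrame(rows))
    ids = [r["individual_id"] for r in rows]
    geno = np.stack([haps[i].sum(axis=0) for i in ids]).astype(np.int8)
    gm = GenotypeMatrix(geno, ids, marker_map.copy())

    trios = extract_trios(gm, ped, check_mendelian=False)
    if cfg.error_rate > 0:
        gm = inject_genotyping_errors(gm, trios, cfg.error_rate, rng)
    if cfg.missing_rate > 0:
        gm = inject_missing(gm, cfg.missing_rate, rng)

    truth = {
        "config": vars(cfg).copy(),
        "incompatibility": None
        if incompat is None
        else {
            "marker_a": incompat.marker_a,
            "marker_b": incompat.marker_b,
            "lethal": list(incompat.lethal),
            "s": incompat.s,
        },
    }
    return SimResult(gm, ped, truth, haps)


def _forces_lethal(
    father_hap: np.ndarray, mother_hap: np.ndarray, loci: tuple[int, int], lethal: tuple[int, int]
) -> bool:
    """True iff every possible offspring of this pair carries the lethal combo."""
    ia, ib = loci
    fa = int(father_hap[0, ia]) + int(father_hap[1, ia])
    ma = int(mother_hap[0, ia]) + int(mother_hap[1, ia])
    fb = int(father_hap[0, ib]) + int(father_hap[1, ib])
    mb = int(mother_hap[0, ib]) + int(mother_hap[1, ib])
    return (
        MENDELIAN[fa, ma, lethal[0]] == 1.0 and MENDELIAN[fb, mb, lethal[1]] == 1.0
    )
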