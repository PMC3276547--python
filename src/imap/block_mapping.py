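"""Two-step genome scan: LD-block screening and marker-level fine mapping.

Markers are first partitioned into blocks of high local linkage
disequilibrium by greedily chaining adjacent markers whose dosage r-squared
meets a threshold.  One representative marker per block (randomly chosen
among those with the fewest missing calls) is screened against all
representatives on *other* chromosomes — the cross-chromosome restriction
removes false positives driven by local LD.  Block pairs passing a BH FDR
cutoff are then fine-mapped: every cross-block marker pair is retested and
the strongest pair per block pair reported.  Fine-mapping p-values are
ranking scores within a pre-selected region and are not multiplicity
corrected; interpret them with care.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .genotype_io import MISSING, GenotypeMatrix, TrioSet, chromosome_slices
from .null_inference import bh_fdr, pair_rng, permutation_pvalue

logger = logging.getLogger(__name__)


@dataclass
class LDBlock:
    chromosome: str
    start: int  # first marker column index (inclusive)
    stop: int  # last marker column index (exclusive)
    representative: int | None = None

    def __len__(self) -> int:
        return self.stop - self.start

    def contains(self, j: int) -> bool:
        return self.start <= j < self.stop


@dataclass
class LDBlockPartition:
    blocks: list[LDBlock]

    def validate(self, markers: pd.DataFrame) -> None:
        """Blocks must tile each chromosome's marker range without overlap."""
        for chrom, sl in chromosome_slices(markers).items():
            bs = sorted(
                (b for b in self.blocks if b.chromosome == str(chrom)), key=lambda b: b.start
            )
            if not bs or bs[0].start != sl.start or bs[-1].stop != sl.stop:
                raise ValueError(f"blocks do not cover chromosome {chrom}")
            for left, right in zip(bs, bs[1:]):
                if left.stop != right.start:
                    raise ValueError(f"gap or overlap between blocks on chromosome {chrom}")
        for b in self.blocks:
            if b.representative is not None and not b.contains(b.representative):
                raise ValueError("representative outside its block")

    def representatives(self) -> list[int]:
        reps = [b.representative for b in self.blocks]
        if any(r is None for r in reps):
            raise ValueError("representatives not assigned; call choose_representatives")
        return [int(r) for r in reps]  # type: ignore[arg-type]

    def block_of(self, j: int) -> int:
        for i, b in enumerate(self.blocks):
            if b.contains(j):
                return i
        raise KeyError(j)


def pairwise_r2(gm: GenotypeMatrix, i: int, j: int, individuals: np.ndarray | None = None) -> float:
    """Squared Pearson correlation of dosage vectors over shared non-missing calls.

    Zero variance at either marker makes r-squared undefined; 0 is returned
    with a warning (a monomorphic marker carries no linkage information).
    """
    g = gm.genotypes if individuals is None else gm.genotypes[individuals]
    x, y = g[:, i].astype(float), g[:, j].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        raise ValueError(f"markers ({i}, {j}): fewer than 2 jointly non-missing individuals")
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"r2 undefined for markers ({i}, {j}) (zero variance); returning 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def partition_ld_blocks(
    gm: GenotypeMatrix,
    r2_threshold: float = 0.8,
    individuals: np.ndarray | None = None,
) -> LDBlockPartition:
    """Greedy left-to-right chaining of adjacent markers with r2 >= threshold.

    ``individuals`` restricts the LD computation to a subset of rows —
    typically the parents of the trio set, since children are correlated
    with their parents and would inflate LD estimates.
    """
    blocks: list[LDBlock] = []
    for chrom, sl in chromosome_slices(gm.markers).items():
        start = sl.start
        for j in range(sl.start + 1, sl.stop):
            if pairwise_r2(gm, j - 1, j, individuals) < r2_threshold:
                blocks.append(LDBlock(str(chrom), start, j))
                start = j
        blocks.append(LDBlock(str(chrom), start, sl.stop))
    part = LDBlockPartition(blocks)
    part.validate(gm.markers)
    return part


def parent_rows(trios: TrioSet) -> np.ndarray:
    """Row indices of all individuals appearing as a parent in the trio set."""
    return np.unique(np.concatenate([trios.father, trios.mother]))


def choose_representatives(
    partition: LDBlockPartition, gm: GenotypeMatrix, rng: np.random.Generator
) -> LDBlockPartition:
    """Pick one representative per block, uniformly among the markers with
    the block-minimum number of missing calls."""
    n_missing = (gm.genotypes == MISSING).sum(axis=0)
    blocks = []
    for b in partition.blocks:
        counts = n_missing[b.start : b.stop]
        candidates = np.flatnonzero(counts == counts.min()) + b.start
        rep = int(rng.choice(candidates))
        blocks.append(LDBlock(b.chromosome, b.start, b.stop, rep))
    return LDBlockPartition(blocks)


def _call_frame(rows: list[dict]) -> pd.DataFrame:
    cols = [
        "level", "block_a", "block_b", "chrom_a", "marker_a", "chrom_b", "marker_b",
        "n_pair", "S", "p", "q", "significant",
    ]
    return pd.DataFrame(rows, columns=cols)


def screen_block_pairs(
    gm: GenotypeMatrix,
    trios: TrioSet,
    partition: LDBlockPartition,
    B: int = 1000,
    fdr_cutoff: float = 0.25,
    seed: int = 0,
    min_pair_trios: int = 20,
    max_pairs: int | None = None,
    smoothed: bool = True,
) -> pd.DataFrame:
    """Test every inter-chromosomal pair of block representatives.

    Returns one row per tested pair with statistic, permutation p-value,
    BH q-value across all screened pairs, and a significance flag at
    ``fdr_cutoff``.  ``max_pairs`` subsamples the pair list (seeded) for
    calibration runs.  Same-chromosome pairs are never tested.
    """
    reps = partition.representatives()
    chroms = gm.markers["chromosome"].astype(str).to_numpy()
    pairs = [
        (ra, rb)
        for i, ra in enumerate(reps)
        for rb in reps[i + 1 :]
        if chroms[ra] != chroms[rb]
    ]
    if not pairs:
        warnings.warn("no inter-chromosomal representative pairs to screen")
        return _call_frame([])
    if max_pairs is not None and len(pairs) > max_pairs:
        sub = np.random.default_rng(
            np.random.SeedSequence(int(seed), spawn_key=(0x5C_EE_11,))
        ).choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(sub)]

    rep_block = {r: i for i, r in zip(range(len(partition.blocks)), reps)}
    mids = gm.marker_ids
    rows: list[dict] = []
    n_skipped = 0
    for a, b in pairs:
        try:
            res = permutation_pvalue(
                gm, trios, a, b, B=B, seed=seed, min_pair_trios=min_pair_trios, smoothed=smoothed
            )
        except core.InsufficientPairTrios as e:
            logger.info("screen: %s", e)
            n_skipped += 1
            continue
        rows.append(
            {
                "level": "block",
                "block_a": rep_block[a],
                "block_b": rep_block[b],
                "chrom_a": chroms[a],
                "marker_a": mids[a],
                "chrom_b": chroms[b],
                "marker_b": mids[b],
                "n_pair": res.n_pair,
                "S": res.observed_S,
                "p": res.p_value,
            }
        )
    if n_skipped:
        logger.warning("screen: %d pairs skipped (too few usable trios)", n_skipped)
    df = _call_frame([dict(r, q=np.nan, significant=False) for r in rows])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["q"] <= fdr_cutoff
    return df


def fine_map(
    gm: GenotypeMatrix,
    trios: TrioSet,
    partition: LDBlockPartition,
    screen_calls: pd.DataFrame,
    B: int = 1000,
    p_cutoff: float = 0.001,
    seed: int = 0,
    min_pair_trios: int = 20,
    smoothed: bool = True,
) -> pd.DataFrame:
    """Retest all cross-block marker pairs inside significant block pairs.

    Per significant block pair the minimum-p marker pair (ties broken by the
    larger statistic) is flagged ``top_pair``; all pairs with p <= ``p_cutoff``
    are retained alongside it.  The p-values here rank markers within regions
    already selected by the screen and carry no multiplicity correction.
    """
    sig = screen_calls[screen_calls["significant"]] if len(screen_calls) else screen_calls
    chroms = gm.markers["chromosome"].astype(str).to_numpy()
    mids = gm.marker_ids
    out_rows: list[dict] = []
    for _, call in sig.iterrows():
        ba, bb = partition.blocks[int(call["block_a"])], partition.blocks[int(call["block_b"])]
        block_rows: list[dict] = []
        for a in range(ba.start, ba.stop):
            for b in range(bb.start, bb.stop):
                try:
                    res = permutation_pvalue(
                        gm, trios, a, b, B=B, seed=seed,
                        min_pair_trios=min_pair_trios, smoothed=smoothed,
                    )
                except core.InsufficientPairTrios as e:
                    logger.info("fine_map: %s", e)
                    continue
                block_rows.append(
                    {
                        "level": "marker",
                        "block_a": int(call["block_a"]),
                        "block_b": int(call["block_b"]),
                        "chrom_a": chroms[a],
                        "marker_a": mids[a],
                        "chrom_b": chroms[b],
                        "marker_b": mids[b],
                        "n_pair": res.n_pair,
                        "S": res.observed_S,
                        "p": res.p_value,
                        "q": np.nan,
                        "significant": bool(call["significant"]),
                        "top_pair": False,
                    }
                )
        if not block_rows:
            continue
        best = min(range(len(block_rows)), key=lambda i: (block_rows[i]["p"], -block_rows[i]["S"]))
        block_rows[best]["top_pair"] = True
        out_rows.extend(r for i, r in enumerate(block_rows) if i == best or r["p"] <= p_cutoff)
    cols = list(_call_frame([]).columns) + ["top_pair"]
    return pd.DataFrame(out_rows, columns=cols)
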