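"""Genotype, marker-map and pedigree I/O, quality control, and trio extraction.

Supported dialects
------------------
* PLINK text PED/MAP: one individual per PED row (``FID IID PAT MAT SEX PHENO``
  followed by two allele columns per marker, ``0`` = missing allele); MAP rows
  are ``chrom marker_id cM bp`` with two optional trailing allele columns
  (major, minor).
* Genotype TSV: header row of marker ids, one row per individual, first column
  the individual id, cells in ``{0, 1, 2, NA}`` (minor-allele dosage).
* Pedigree: whitespace table, either three columns ``child father mother`` or a
  PLINK FAM-like layout (``FID IID PAT MAT [SEX [PHENO]]``); ``0`` = unknown.

Storage coding is minor-allele dosage with ``MISSING = -1``.
"""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mendel import CONSISTENT

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call
MISSING: int = -1

MARKER_COLUMNS = ["marker_id", "chromosome", "position", "allele_major", "allele_minor"]


def chromosome_sort_key(chrom: str):
    """Sort key placing numeric chromosome names in numeric order first."""
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass(frozen=True)
class MarkerInfo:
    """Metadata for a single biallelic marker."""

    marker_id: str
    chromosome: str
    position: int
    allele_major: str
    allele_minor: str

    def __post_init__(self):
        if self.position < 0:
            raise ValueError(f"marker {self.marker_id}: negative position")
        if self.allele_major == self.allele_minor:
            raise ValueError(f"marker {self.marker_id}: major == minor allele")


@dataclass
class GenotypeMatrix:
    """Individuals x markers minor-allele dosage matrix with marker metadata.

    ``genotypes[i, j]`` counts copies of the minor allele of marker ``j``
    carried by individual ``i`` (0, 1, 2) or ``MISSING``.  Markers are kept
    sorted by (chromosome, position).
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    markers: pd.DataFrame

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.markers = self.markers.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        g = self.genotypes
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x markers)")
        if g.shape != (len(self.individual_ids), len(self.markers)):
            raise ValueError("genotype shape does not match ids/markers")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype entries outside {{0,1,2,MISSING}}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids are not unique")
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker table lacks columns {missing_cols}")
        keys = [
            (chromosome_sort_key(c), int(p))
            for c, p in zip(self.markers["chromosome"], self.markers["position"])
        ]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            raise ValueError("markers not sorted by (chromosome, position)")

    # -- convenience ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers["marker_id"])

    def individual_index(self) -> dict[str, int]:
        return {iid: i for i, iid in enumerate(self.individual_ids)}

    def marker_info(self, j: int) -> MarkerInfo:
        row = self.markers.iloc[j]
        return MarkerInfo(
            str(row["marker_id"]),
            str(row["chromosome"]),
            int(row["position"]),
            str(row["allele_major"]),
            str(row["allele_minor"]),
        )

    @classmethod
    def from_unsorted(
        cls, genotypes: np.ndarray, individual_ids: Sequence[str], markers: pd.DataFrame
    ) -> "GenotypeMatrix":
        """Build a matrix, reordering marker columns by (chromosome, position)."""
        markers = markers.reset_index(drop=True)
        order = sorted(
            range(len(markers)),
            key=lambda j: (
                chromosome_sort_key(markers["chromosome"].iloc[j]),
                int(markers["position"].iloc[j]),
            ),
        )
        return cls(
            np.asarray(genotypes)[:, order],
            list(individual_ids),
            markers.iloc[order].reset_index(drop=True),
        )


@dataclass
class PedigreeTable:
    """Child/father/mother relations; ``None`` marks an unknown (founder) parent."""

    table: pd.DataFrame  # columns: individual_id, father_id, mother_id, sex, generation

    def __post_init__(self):
        t = self.table.copy()
        for col in ("sex", "generation"):
            if col not in t.columns:
                t[col] = None
        t = t[["individual_id", "father_id", "mother_id", "sex", "generation"]]
        t["individual_id"] = t["individual_id"].astype(str)
        for col in ("father_id", "mother_id"):
            t[col] = t[col].map(lambda v: None if v is None or pd.isna(v) or str(v) == "0" else str(v))
        self.table = t.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        ids = list(self.table["individual_id"])
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        known = set(ids)
        parent = {}
        for _, row in self.table.iterrows():
            for p in (row["father_id"], row["mother_id"]):
                if p is not None and p not in known:
                    raise ValueError(
                        f"pedigree references unknown parent {p!r} of {row['individual_id']!r}"
                    )
            parent[row["individual_id"]] = [
                p for p in (row["father_id"], row["mother_id"]) if p is not None
            ]
        # cycle check (an individual must not be its own ancestor)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            stack = [(node, iter(parent[node]))]
            state[node] = 1
            while stack:
                cur, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    state[cur] = 2
                    stack.pop()
                elif state.get(nxt, 0) == 1:
                    raise ValueError(f"cyclic ancestry involving {nxt!r}")
                elif state.get(nxt, 0) == 0:
                    state[nxt] = 1
                    stack.append((nxt, iter(parent[nxt])))

        for iid in ids:
            if state.get(iid, 0) == 0:
                visit(iid)

    def founders(self) -> list[str]:
        t = self.table
        mask = t["father_id"].isna() & t["mother_id"].isna()
        return list(t.loc[mask.values, "individual_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TrioSet:
    """Child/father/mother row-index triples plus a per-marker usability mask.

    ``usable[t, m]`` is True iff child and both parents are non-missing at
    marker ``m`` and the child genotype is Mendelian-consistent with the
    parents there (inconsistent calls are treated as missing for the trio).
    """

    trios: np.ndarray  # (n_trios, 3) int: child, father, mother
    usable: np.ndarray  # (n_trios, n_markers) bool

    def __post_init__(self):
        self.trios = np.asarray(self.trios, dtype=np.intp)
        self.usable = np.asarray(self.usable, dtype=bool)
        if self.trios.ndim != 2 or self.trios.shape[1] != 3:
            raise ValueError("trios must be (n, 3)")
        if self.usable.shape[0] != self.trios.shape[0]:
            raise ValueError("usable mask row count != number of trios")

    @property
    def child(self) -> np.ndarray:
        return self.trios[:, 0]

    @property
    def father(self) -> np.ndarray:
        return self.trios[:, 1]

    @property
    def mother(self) -> np.ndarray:
        return self.trios[:, 2]

    @property
    def n_trios(self) -> int:
        return self.trios.shape[0]


# ---------------------------------------------------------------------------
# allele frequencies and QC filters
# ---------------------------------------------------------------------------

def allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Frequency of the dosage-counted allele among non-missing calls."""
    g = gm.genotypes
    nm = g != MISSING
    counts = np.where(nm, g, 0).sum(axis=0).astype(float)
    denom = 2.0 * nm.sum(axis=0)
    return np.divide(counts, denom, out=np.zeros_like(counts), where=denom > 0)


def minor_allele_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Folded minor allele frequency per marker, computed on non-missing calls."""
    f = allele_frequencies(gm)
    return np.minimum(f, 1.0 - f)


def filter_individuals(gm: GenotypeMatrix, max_missing: float = 0.10) -> GenotypeMatrix:
    """Drop individuals whose missing-call fraction exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    frac = (gm.genotypes == MISSING).mean(axis=1)
    keep = frac <= max_missing
    logger.info("filter_individuals: kept %d/%d", int(keep.sum()), gm.n_individuals)
    return GenotypeMatrix(
        gm.genotypes[keep],
        [iid for iid, k in zip(gm.individual_ids, keep) if k],
        gm.markers.copy(),
    )


def filter_markers(
    gm: GenotypeMatrix,
    max_missing: float = 0.10,
    min_maf: float = 0.05,
    exclude_chromosomes: Iterable[str] = (),
) -> GenotypeMatrix:
    """Drop markers by missingness, minor allele frequency, or chromosome.

    No Hardy-Weinberg filter is applied: trio data are explicitly modelled
    through parental genotypes, and segregation distortion is corrected for
    downstream rather than filtered out here.
    """
    if not (0.0 <= max_missing <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must be in [0, 1]")
    excl = {str(c) for c in exclude_chromosomes}
    frac = (gm.genotypes == MISSING).mean(axis=0)
    maf = minor_allele_frequencies(gm)
    on_excl = gm.markers["chromosome"].astype(str).isin(excl).to_numpy()
    keep = (frac <= max_missing) & (maf >= min_maf) & ~on_excl
    logger.info("filter_markers: kept %d/%d", int(keep.sum()), gm.n_markers)
    return GenotypeMatrix(
        gm.genotypes[:, keep],
        list(gm.individual_ids),
        gm.markers.loc[keep].reset_index(drop=True),
    )


def extract_trios(
    gm: GenotypeMatrix, ped: PedigreeTable, check_mendelian: bool = True
) -> TrioSet:
    """Build the trio set: every genotyped child with both parents genotyped.

    The usability mask is marker-specific: a trio is usable at a marker only
    when all three members are non-missing there.  When ``check_mendelian``
    is set, trios whose child genotype is impossible given the parents at a
    marker are additionally masked there (and counted in the log), so a
    single genotyping error cannot force a zero expected probability onto an
    observed genotype.
    """
    idx = gm.individual_index()
    triples: list[tuple[int, int, int]] = []
    skipped = 0
    for _, row in ped.table.iterrows():
        c, f, m = row["individual_id"], row["father_id"], row["mother_id"]
        if f is None or m is None:
            continue
        if c not in idx:
            continue
        if f not in idx or m not in idx:
            skipped += 1
            continue
        triples.append((idx[c], idx[f], idx[m]))
    if skipped:
        logger.warning("extract_trios: %d children skipped (ungenotyped parent)", skipped)
    if not triples:
        raise ValueError("no usable trios: no genotyped child has both parents genotyped")
    trios = np.asarray(triples, dtype=np.intp)
    g = gm.genotypes
    cg, fg, mg = g[trios[:, 0]], g[trios[:, 1]], g[trios[:, 2]]
    usable = (cg != MISSING) & (fg != MISSING) & (mg != MISSING)
    if check_mendelian:
        ok = CONSISTENT[
            np.where(usable, fg, 0), np.where(usable, mg, 0), np.where(usable, cg, 0)
        ]
        n_bad = int((usable & ~ok).sum())
        if n_bad:
            logger.warning(
                "extract_trios: %d Mendelian-inconsistent (trio, marker) calls masked", n_bad
            )
        usable &= ok
    return TrioSet(trios, usable)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    pass


def read_map(path: str) -> pd.DataFrame:
    """Read a MAP file (``chrom id cM bp`` + optional ``major minor``)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) not in (4, 6):
                raise ParseError(f"{path}:{ln}: expected 4 or 6 columns, got {len(tok)}")
            major, minor = (tok[4], tok[5]) if len(tok) == 6 else ("A", "B")
            try:
                pos = int(tok[3])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: bad position {tok[3]!r}") from e
            rows.append((tok[1], tok[0], pos, major, minor))
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def write_map(markers: pd.DataFrame, path: str, alleles: bool = True) -> None:
    with open(path, "w") as fh:
        for _, r in markers.iterrows():
            cols = [str(r["chromosome"]), str(r["marker_id"]), "0", str(int(r["position"]))]
            if alleles:
                cols += [str(r["allele_major"]), str(r["allele_minor"])]
            fh.write("\t".join(cols) + "\n")


def read_ped_map(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into minor-allele dosage coding.

    The minor allele of each marker is the rarer allele among non-missing
    calls; ties are broken by taking the lexicographically later base as
    minor.  More than two distinct alleles at a marker is an error.
    """
    markers = read_map(map_path)
    m = len(markers)
    ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    n_half = 0
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} columns for {m} markers, got {len(tok)}"
                )
            ids.append(tok[1])
            allele_rows.append(np.array(tok[6:], dtype="U8").reshape(m, 2))
    if not allele_rows:
        raise ParseError(f"{ped_path}: no genotype rows")
    alleles = np.stack(allele_rows)  # (n, m, 2)
    n = alleles.shape[0]
    geno = np.full((n, m), MISSING, dtype=np.int8)
    major_l, minor_l = [], []
    for j in range(m):
        aj = alleles[:, j, :]
        called = ~(aj == "0").any(axis=1)  # half-missing treated as missing
        n_half += int(((aj == "0").sum(axis=1) == 1).sum())
        obs = aj[called].ravel()
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise ParseError(
                f"{ped_path}: marker {markers['marker_id'].iloc[j]!r} is not biallelic: {list(uniq)}"
            )
        if len(uniq) == 0:
            major, minor = "A", "B"
        elif len(uniq) == 1:
            major, minor = str(uniq[0]), "."
        else:
            # rarer allele is minor; tie -> lexicographically later base
            order = np.lexsort((uniq, counts))  # ascending count, then base
            if counts[0] == counts[1]:
                major, minor = sorted(uniq)
            else:
                minor, major = str(uniq[order[0]]), str(uniq[order[1]])
        major_l.append(major)
        minor_l.append(minor)
        if called.any():
            geno[called, j] = (aj[called] == minor).sum(axis=1)
    if n_half:
        logger.warning("read_ped_map: %d half-missing calls treated as missing", n_half)
    markers = markers.assign(allele_major=major_l, allele_minor=minor_l)
    return GenotypeMatrix.from_unsorted(geno, ids, markers)


def write_ped_map(
    gm: GenotypeMatrix,
    ped_path: str,
    map_path: str,
    pedigree: PedigreeTable | None = None,
) -> None:
    """Write PLINK text PED/MAP; parent columns come from ``pedigree`` if given."""
    write_map(gm.markers, map_path, alleles=False)
    parents: dict[str, tuple[str, str]] = {}
    sexes: dict[str, str] = {}
    if pedigree is not None:
        for _, r in pedigree.table.iterrows():
            parents[r["individual_id"]] = (r["father_id"] or "0", r["mother_id"] or "0")
            sexes[r["individual_id"]] = str(r["sex"]) if r["sex"] in ("1", "2", 1, 2) else "0"
    major = gm.markers["allele_major"].to_numpy()
    minor = gm.markers["allele_minor"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(gm.individual_ids):
            f, m = parents.get(iid, ("0", "0"))
            cols = ["FAM", iid, f, m, sexes.get(iid, "0"), "-9"]
            row = gm.genotypes[i]
            for j, g in enumerate(row):
                if g == MISSING:
                    cols += ["0", "0"]
                else:
                    cols += [minor[j]] * int(g) + [major[j]] * (2 - int(g))
            fh.write("\t".join(cols) + "\n")


def read_tsv(tsv_path: str, map_path: str | None = None) -> GenotypeMatrix:
    """Read the dosage TSV dialect (header of marker ids, cells 0/1/2/NA)."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{tsv_path}: need an id column plus >=1 marker column")
    ids = df.iloc[:, 0].astype(str).tolist()
    marker_ids = list(df.columns[1:])
    vals = df.iloc[:, 1:].to_numpy()
    geno = np.full(vals.shape, MISSING, dtype=np.int8)
    for code in ("0", "1", "2"):
        geno[vals == code] = int(code)
    bad = ~(np.isin(vals, ("0", "1", "2", "NA")) | pd.isna(vals))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{tsv_path}: line {i + 2}: bad genotype cell {vals[i, j]!r} for marker {marker_ids[j]!r}"
        )
    if map_path is not None:
        markers = read_map(map_path)
        order = {mid: k for k, mid in enumerate(marker_ids)}
        missing = [mid for mid in markers["marker_id"] if mid not in order]
        if missing or len(markers) != len(marker_ids):
            raise ParseError(f"{tsv_path}: marker ids do not match {map_path}")
        geno = geno[:, [order[mid] for mid in markers["marker_id"]]]
    else:
        markers = pd.DataFrame(
            {
                "marker_id": marker_ids,
                "chromosome": "1",
                "position": np.arange(1, len(marker_ids) + 1),
                "allele_major": "A",
                "allele_minor": "B",
            }
        )
    return GenotypeMatrix.from_unsorted(geno, ids, markers)


def write_tsv(gm: GenotypeMatrix, tsv_path: str, map_path: str | None = None) -> None:
    """Write the dosage TSV dialect plus (optionally) a 6-column map sidecar."""
    with open(tsv_path, "w") as fh:
        fh.write("individual_id\t" + "\t".join(gm.marker_ids) + "\n")
        for i, iid in enumerate(gm.individual_ids):
            cells = ["NA" if g == MISSING else str(int(g)) for g in gm.genotypes[i]]
            fh.write(iid + "\t" + "\t".join(cells) + "\n")
    if map_path is not None:
        write_map(gm.markers, map_path, alleles=True)


def read_genotypes(path: str, format: str = "ped_map", map_path: str | None = None) -> GenotypeMatrix:
    """Read genotypes from ``path`` in the named dialect.

    For ``ped_map``, ``path`` may be the ``.ped`` file or a prefix; the map
    defaults to the same prefix with ``.map``.  For ``tsv`` the map sidecar is
    used when present.
    """
    if format == "ped_map":
        ped = path if path.endswith(".ped") else path + ".ped"
        mp = map_path or os.path.splitext(ped)[0] + ".map"
        return read_ped_map(ped, mp)
    if format == "tsv":
        tsv = path if path.endswith(".tsv") else path + ".tsv"
        mp = map_path or os.path.splitext(tsv)[0] + ".map"
        return read_tsv(tsv, mp if os.path.exists(mp) else None)
    raise ValueError(f"unknown genotype format {format!r}")


def read_pedigree(path: str) -> PedigreeTable:
    """Read a whitespace pedigree table (3-column or FAM-like)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if len(tok) == 3:
                c, f, m, sex = tok[0], tok[1], tok[2], None
            elif len(tok) >= 4:
                c, f, m = tok[1], tok[2], tok[3]
                sex = tok[4] if len(tok) >= 5 else None
            else:
                raise ParseError(f"{path}:{ln}: expected 3 or >=4 columns, got {len(tok)}")
            rows.append({"individual_id": c, "father_id": f, "mother_id": m, "sex": sex})
    if not rows:
        raise ParseError(f"{path}: empty pedigree")
    return PedigreeTable(pd.DataFrame(rows))


def write_pedigree(ped: PedigreeTable, path: str) -> None:
    with open(path, "w") as fh:
        for _, r in ped.table.iterrows():
            sex = str(r["sex"]) if r["sex"] not in (None,) and not pd.isna(r["sex"]) else "0"
            fh.write(
                "\t".join(
                    ["FAM", r["individual_id"], r["father_id"] or "0", r["mother_id"] or "0", sex, "-9"]
                )
                + "\n"
            )


def chromosome_slices(markers: pd.DataFrame) -> dict[str, slice]:
    """Contiguous column slice per chromosome (markers are sorted)."""
    out: dict[str, slice] = {}
    chroms = markers["chromosome"].astype(str).to_numpy()
    start = 0
    for j in range(1, len(chroms) + 1):
        if j == len(chroms) or chroms[j] != chroms[start]:
            out[chroms[start]] = slice(start, j)
            start = j
    return out
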