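"""End-to-end runs: QC -> LD blocks -> screen -> fine map -> congruence.

All randomness flows from a single seed in :class:`RunConfig`; per-pair RNG
streams are derived from (seed, marker indices), so results are independent
of evaluation order.  Every output table carries a commented header with the
seed and package version, and each run writes a JSON manifest echoing the
configuration and the counts at every filter stage.
"""
from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__, block_mapping, congruence as congruence_mod, genotype_io, pedigree_sim
from .genotype_io import GenotypeMatrix, PedigreeTable, TrioSet

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full scan; file values can be overridden by flags."""

    genotypes: str = ""
    format: str = "ped_map"
    pedigree: str = ""
    out_dir: str = "imap_out"
    seed: int = 0
    # QC
    max_individual_missing: float = 0.10
    max_marker_missing: float = 0.10
    min_maf: float = 0.05
    exclude_chromosomes: list[str] = field(default_factory=list)
    # blocks / screening / fine mapping
    r2_threshold: float = 0.8
    B_screen: int = 1000
    B_finemap: int = 1000
    fdr_cutoff: float = 0.25
    p_cutoff: float = 0.001
    min_pair_trios: int = 20
    max_screen_pairs: int | None = None
    smoothed_pvalues: bool = True
    # congruence
    congruence_p_cutoff: float = 0.05

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("max_individual_missing", "max_marker_missing", "min_maf"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.B_screen < 1 or self.B_finemap < 1:
            raise ValueError("permutation counts must be >= 1")


def _write_table(df: pd.DataFrame, path: str, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# imap {__version__}\n# seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def load_inputs(config: RunConfig) -> tuple[GenotypeMatrix, PedigreeTable]:
    if not os.path.exists(_primary_path(config)):
        raise FileNotFoundError(f"genotype input not found: {_primary_path(config)}")
    gm = genotype_io.read_genotypes(config.genotypes, format=config.format)
    ped = genotype_io.read_pedigree(config.pedigree)
    return gm, ped


def _primary_path(config: RunConfig) -> str:
    p = config.genotypes
    ext = ".ped" if config.format == "ped_map" else ".tsv"
    return p if p.endswith(ext) else p + ext


def run_qc(config: RunConfig) -> tuple[GenotypeMatrix, TrioSet, dict]:
    """Load, filter, and extract trios; returns stage counts for the manifest."""
    config.validate()
    gm, ped = load_inputs(config)
    counts = {"individuals_in": gm.n_individuals, "markers_in": gm.n_markers}
    gm = genotype_io.filter_individuals(gm, config.max_individual_missing)
    counts["individuals_after_missing_filter"] = gm.n_individuals
    gm = genotype_io.filter_markers(
        gm, config.max_marker_missing, config.min_maf, config.exclude_chromosomes
    )
    counts["markers_after_filters"] = gm.n_markers
    trios = genotype_io.extract_trios(gm, ped)
    counts["trios"] = trios.n_trios
    return gm, trios, counts


def _blocks(config: RunConfig, gm: GenotypeMatrix, trios: TrioSet):
    part = block_mapping.partition_ld_blocks(
        gm, config.r2_threshold, individuals=block_mapping.parent_rows(trios)
    )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xB10C,)))
    part = block_mapping.choose_representatives(part, gm, rng)
    return part


def run_screen(config: RunConfig) -> pd.DataFrame:
    """Block-representative screen; writes screen.tsv and manifest.json."""
    gm, trios, counts = run_qc(config)
    part = _blocks(config, gm, trios)
    counts["ld_blocks"] = len(part.blocks)
    screen = block_mapping.screen_block_pairs(
        gm, trios, part,
        B=config.B_screen, fdr_cutoff=config.fdr_cutoff, seed=config.seed,
        min_pair_trios=config.min_pair_trios, max_pairs=config.max_screen_pairs,
        smoothed=config.smoothed_pvalues,
    )
    counts["screened_pairs"] = len(screen)
    counts["significant_block_pairs"] = int(screen["significant"].sum()) if len(screen) else 0
    os.makedirs(config.out_dir, exist_ok=True)
    _write_table(screen, os.path.join(config.out_dir, "screen.tsv"), config)
    _write_manifest(config, counts)
    return screen


def run_full(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Screen, fine-map significant block pairs, compute congruence scores."""
    gm, trios, counts = run_qc(config)
    part = _blocks(config, gm, trios)
    counts["ld_blocks"] = len(part.blocks)
    screen = block_mapping.screen_block_pairs(
        gm, trios, part,
        B=config.B_screen, fdr_cutoff=config.fdr_cutoff, seed=config.seed,
        min_pair_trios=config.min_pair_trios, max_pairs=config.max_screen_pairs,
        smoothed=config.smoothed_pvalues,
    )
    counts["screened_pairs"] = len(screen)
    counts["significant_block_pairs"] = int(screen["significant"].sum()) if len(screen) else 0
    fine = block_mapping.fine_map(
        gm, trios, part, screen,
        B=config.B_finemap, p_cutoff=config.p_cutoff, seed=config.seed,
        min_pair_trios=config.min_pair_trios, smoothed=config.smoothed_pvalues,
    )
    counts["fine_mapped_pairs"] = len(fine)
    if len(screen):
        profiles = congruence_mod.build_profiles(screen, config.congruence_p_cutoff)
        cong = congruence_mod.congruence_table(profiles)
    else:
        cong = congruence_mod.congruence_table({})
    counts["congruence_pairs"] = len(cong)

    os.makedirs(config.out_dir, exist_ok=True)
    _write_table(screen, os.path.join(config.out_dir, "screen.tsv"), config)
    _write_table(fine, os.path.join(config.out_dir, "finemap.tsv"), config)
    _write_table(cong, os.path.join(config.out_dir, "congruence.tsv"), config)
    _write_manifest(config, counts)
    return {"screen": screen, "finemap": fine, "congruence": cong}


def _write_manifest(config: RunConfig, counts: dict) -> None:
    manifest = {
        "imap_version": __version__,
        "config": asdict(config),
        "counts": counts,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_simulate(
    out_dir: str,
    seed: int,
    config: pedigree_sim.SimConfig | None = None,
    planted: bool = False,
    target_maf: float = 0.3,
    selection: float = 1.0,
) -> pedigree_sim.SimResult:
    """Simulate a dataset and write PED/MAP + pedigree + truth.json."""
    sim = pedigree_sim.simulate_dataset(
        seed, config=config,
        incompat="auto" if planted else None,
        target_maf=target_maf, selection=selection,
    )
    os.makedirs(out_dir, exist_ok=True)
    genotype_io.write_ped_map(
        sim.gm, os.path.join(out_dir, "sim.ped"), os.path.join(out_dir, "sim.map"), sim.ped
    )
    genotype_io.write_pedigree(sim.ped, os.path.join(out_dir, "sim.fam"))
    truth = dict(sim.truth, seed=seed)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
    return sim
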