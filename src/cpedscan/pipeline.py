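"""One-configuration orchestration of the whole analysis.

A :class:`RunConfig` (YAML-serializable) names the inputs and holds every
analysis constant; :func:`run_all` executes binning -> CPED band ->
periodicity scan (+ optional shuffled-genome null) -> orientation ->
regulon subsets -> contact association, writing one TSV per stage. Every
output carries the config's hash in its header, and the single run seed is
expanded into independent per-stage seeds with ``numpy.random.SeedSequence``
so each stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import binning, cped, hic, orientation, periodicity, regulon, synth
from .annotation import gene_table, load_gff
from .expression import ExpressionMatrix
from .grid import BinGrid

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

_STAGES = ("scan", "null", "orientation", "regulon", "hic")


@dataclass
class RunConfig:
    # inputs (counts TSV written by the fixture writer, or per-sample
    # alignment/coverage files plus a design table)
    counts_tsv: str | None = None
    sample_files: list[str] = field(default_factory=list)
    design_tsv: str | None = None
    gff: str | None = None
    regulators_tsv: str | None = None
    contacts_tsv: str | None = None
    out_dir: str = "cpedscan_out"

    # grid / normalization
    genome_length: int | None = None  # required for sample_files input
    bin_width: int = 500
    step: int | None = None
    circular: bool = True
    masked_in_denominator: bool = False

    # CPED / scan
    max_lag: int = 200_000
    window: int = 400_000
    slide: int = 5_000
    period_min: int = 10_000
    period_max: int = 70_000
    oversampling: float = 4.0
    n_randomizations: int = 400
    run_null: bool = False

    # regulon / hic
    flank: int = 500
    n_random_subsets: int = 100
    min_linear_distance: int = 20_000
    contact_bin_width: int = 5_000
    n_contact_groups: int = 8

    # misc
    forward_is_clockwise: bool = True
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def scan_config(self, seed: int | None = None) -> periodicity.ScanConfig:
        return periodicity.ScanConfig(
            window=self.window,
            slide=self.slide,
            period_min=self.period_min,
            period_max=self.period_max,
            oversampling=self.oversampling,
            n_randomizations=self.n_randomizations,
            seed=self.seed if seed is None else seed,
            max_lag=self.max_lag,
        )


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    # keep each derived seed below 2**31 so they can be re-used anywhere
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def _header(config: RunConfig, stage: str) -> list[str]:
    return [f"cpedscan stage={stage}", f"config_hash={config.config_hash}"]


def _load_matrix(config: RunConfig) -> ExpressionMatrix:
    if config.counts_tsv:
        raw, grid, samples = synth.read_counts_tsv(config.counts_tsv, circular=config.circular)
        if config.design_tsv:
            design = pd.read_csv(config.design_tsv, sep="\t")
        else:  # fall back: every sample its own phase
            design = pd.DataFrame({"sample": samples, "phase": samples, "replicate": 1})
    elif config.sample_files:
        if config.genome_length is None:
            raise ValueError("genome_length is required when counting from sample files")
        grid = BinGrid(config.genome_length, config.bin_width, config.step, config.circular)
        raw = np.column_stack([binning.count_bins(p, grid) for p in config.sample_files])
        if config.design_tsv is None:
            raise ValueError("design_tsv is required when counting from sample files")
        design = pd.read_csv(config.design_tsv, sep="\t")
    else:
        raise ValueError("config names no input: set counts_tsv or sample_files")
    if config.gff:
        mask = binning.mask_structural_rna(config.gff, grid)
    else:
        mask = np.zeros(grid.n_bins, dtype=bool)
    return binning.normalize_and_average(
        raw, mask, design, grid, masked_in_denominator=config.masked_in_denominator
    )


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns the in-memory results and
    writes one TSV per stage under ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    results: dict = {}

    matrix = _load_matrix(config)
    results["matrix"] = matrix
    matrix.to_tsv(
        os.path.join(config.out_dir, "expression_fpm.tsv"), _header(config, "binning")
    )

    band = cped.correlation_band(matrix, config.max_lag)
    results["band"] = band

    if "scan" in config.stages:
        pmap = periodicity.scan_genome(band, config.scan_config())
        pmap.to_tsv(os.path.join(config.out_dir, "period_map.tsv"), _header(config, "scan"))
        results["period_map"] = pmap

    if "null" in config.stages and config.run_null:
        null = periodicity.randomization_null(
            matrix, config.scan_config(seed=seeds[0]), seed=seeds[0]
        )
        pd.DataFrame({"pnmax": null.pnmax}).to_csv(
            os.path.join(config.out_dir, "null_pnmax.tsv"), sep="\t", index=False
        )
        results["null"] = null

    genes = None
    if config.gff:
        genes = gene_table(load_gff(config.gff))

    if "orientation" in config.stages and genes is not None and len(genes):
        table = orientation.assign_orientation(
            genes, matrix.grid, forward_is_clockwise=config.forward_is_clockwise
        )
        oriented_band = orientation.mirror_profiles(band, table)
        whole = (0, matrix.grid.genome_length)
        contrast = orientation.supercoiling_contrast(
            cped.average_profiles(oriented_band, whole), cped.average_profiles(band, whole)
        )
        pd.DataFrame(
            {
                "bin_start": matrix.grid.bin_starts,
                "orientation": table.calls,
            }
        ).to_csv(os.path.join(config.out_dir, "orientation.tsv"), sep="\t", index=False)
        results["orientation"] = table
        results["orientation_contrast"] = contrast

    if "regulon" in config.stages and config.regulators_tsv:
        targets = regulon.parse_targets(
            config.regulators_tsv, genes, matrix.grid, flank=config.flank
        )
        rows = []
        subsets = {}
        for rt in targets:
            sc = regulon.subset_distributions(
                band, rt, matrix.grid, n_random=config.n_random_subsets, seed=seeds[1]
            )
            subsets[rt.regulator] = sc
            for rec in sc.summary.to_dict("records"):
                rows.append({"regulator": rt.regulator, **rec})
        pd.DataFrame(rows).to_csv(
            os.path.join(config.out_dir, "regulon_subsets.tsv"), sep="\t", index=False
        )
        results["regulon"] = subsets

    if "hic" in config.stages and config.contacts_tsv:
        expr5k = hic.rebin_expression(matrix, config.contact_bin_width)
        cgrid = BinGrid(
            matrix.grid.genome_length,
            config.contact_bin_width,
            config.contact_bin_width,
            circular=config.circular,
        )
        contacts = hic.ContactMatrix.from_coo_tsv(config.contacts_tsv, cgrid)
        assoc = hic.build_pairs(expr5k, contacts, config.min_linear_distance)
        assoc = hic.group_and_test(assoc, n_groups=config.n_contact_groups)
        assoc.group_summary.to_csv(
            os.path.join(config.out_dir, "contact_groups.tsv"), sep="\t", index=False
        )
        results["hic"] = assoc

    config.to_yaml(os.path.join(config.out_dir, "run_config.yaml"))
    return results
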