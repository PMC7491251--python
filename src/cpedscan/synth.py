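"""Synthetic fixtures with planted distance-periodic co-expression.

The generator inverts the analysis' model of the data: within each genomic
region a single latent "spatial factor" varies across growth phases, and
every bin couples to it with a weight set by the bin's position relative to
a lattice of anchors spaced one planted period apart. Phase-to-phase
variation of the factor then induces pairwise correlations whose average
over a region is periodic in genomic lag with the planted period — the
structure the scan is supposed to recover. Counts are Poisson around the
exponentiated log-signal scaled to a library size; operon members share one
signal; structural-RNA intervals receive 100x inflated counts so that
masking failures are loud.

Coupling kernels (per bin position x relative to its region start, period P):

* ``cosine`` (default): w = cos(2*pi*x/P). Anchor-phase bins correlate +1
  and antiphase bins -1 in the noiseless limit, and the region-averaged
  correlation-vs-lag curve is periodic with maxima at multiples of P with
  the fundamental strongly dominant.
* ``triangular``: narrow tent of configurable half-width around each
  anchor; only anchor-proximal bins carry signal (a spike train — useful
  for planting periodicity that is *carried entirely* by a known bin set).
* ``sawtooth``: weight decays downstream (clockwise) from each anchor,
  giving a transcription-direction-asymmetric plant for orientation tests.

Contacts follow a circular distance-decay power law, modulated by the same
coupling field: contact(i,j) multiplied by boost**(w_i*w_j) for same-region
pairs, so spatial proximity and co-expression are coherently coupled
(boost = 1 recovers a pure distance-decay null).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binning import mask_structural_rna, normalize_and_average
from .expression import ExpressionMatrix
from .grid import BinGrid
from .hic import ContactMatrix

__all__ = [
    "SyntheticTruth",
    "SyntheticBundle",
    "SizingError",
    "make_truth",
    "simulate_expression",
    "simulate_contacts",
    "write_fixtures",
    "read_counts_tsv",
]

PHASE_LABELS = ["early_exp", "mid_exp", "early_stat", "mid_stat", "late_stat"]
STRUCTURAL_RNA_INFLATION = 100.0


class SizingError(ValueError):
    """Genome too short for the requested planted structure."""


@dataclass
class SyntheticTruth:
    genome_length: int
    regions: list[tuple[int, int, int, float]]  # (start, end, period, amplitude)
    operons: list[tuple[int, int, str]]  # (start, end, strand)
    structural_rna: list[tuple[int, int]]
    regulators: dict[str, list[int]]  # name -> target positions (bp)
    factor_seed: int
    kernel: str = "cosine"
    kernel_half_width: int | None = None  # triangular kernel only

    def __post_init__(self) -> None:
        for s, e, *_ in self.operons:
            if not (0 <= s < e <= self.genome_length):
                raise ValueError(f"operon ({s},{e}) outside [0, {self.genome_length})")
        for s, e in self.structural_rna:
            if not (0 <= s < e <= self.genome_length):
                raise ValueError(f"structural-RNA ({s},{e}) outside the genome")
        spans = sorted((s, e) for s, e, *_ in self.regions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("regions overlap")


@dataclass
class SyntheticBundle:
    truth: SyntheticTruth
    counts: np.ndarray  # n_bins x n_samples, non-negative
    design: pd.DataFrame  # sample, phase, replicate
    annotation: pd.DataFrame  # gene_id, name, start, end, strand
    grid: BinGrid
    contacts: ContactMatrix | None = None
    latent: np.ndarray | None = None  # n_bins x n_phases log-signal (no noise)

    def __post_init__(self) -> None:
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and >= 0")
        n_ph = self.design["phase"].nunique()
        n_rep = self.design["replicate"].nunique()
        if len(self.design) != n_ph * n_rep:
            raise ValueError("sample count must equal phases x replicates")

    def structural_mask(self) -> np.ndarray:
        return mask_structural_rna(self.truth.structural_rna, self.grid)

    def expression_matrix(self, masked_in_denominator: bool = False) -> ExpressionMatrix:
        return normalize_and_average(
            self.counts, self.structural_mask(), self.design, self.grid,
            masked_in_denominator=masked_in_denominator,
        )


def make_truth(
    genome_length: int,
    n_regions: int,
    period_choices: list[int],
    seed: int,
    coupling_amplitude: float = 1.0,
    kernel: str = "cosine",
    n_operons: int | None = None,
    n_structural_rna: int | None = None,
    period_range: tuple[int, int] = (10_000, 70_000),
) -> SyntheticTruth:
    """Deterministically build a planted truth: ``n_regions`` contiguous
    equal regions tiling the genome, each with one period drawn from
    ``period_choices``; random non-overlapping operons; a few structural-RNA
    intervals; and two regulators (one whose targets are the first region's
    anchors, one with uniformly random targets)."""
    rng = np.random.default_rng(seed)
    if not period_choices:
        raise ValueError("period_choices must be non-empty")
    for p in period_choices:
        if not (period_range[0] <= p <= period_range[1]):
            raise ValueError(f"planted period {p} outside the search range {period_range}")
    region_len = genome_length // n_regions
    if region_len < 4 * max(period_choices):
        raise SizingError(
            f"regions of {region_len} bp cannot hold 4 cycles of a "
            f"{max(period_choices)} bp period; enlarge the genome or drop regions"
        )
    regions = []
    for k in range(n_regions):
        period = int(rng.choice(period_choices)) if len(period_choices) > 1 else int(period_choices[0])
        regions.append((k * region_len, (k + 1) * region_len, period, float(coupling_amplitude)))

    # non-overlapping operons scattered along the genome
    n_ops = max(4, genome_length // 25_000) if n_operons is None else n_operons
    operons: list[tuple[int, int, str]] = []
    pos = int(rng.integers(0, 5_000))
    for _ in range(n_ops):
        length = int(rng.integers(1_500, 8_000))
        gap = int(rng.integers(2_000, 20_000))
        if pos + length >= genome_length:
            break
        operons.append((pos, pos + length, "+" if rng.random() < 0.5 else "-"))
        pos += length + gap

    n_rna = max(2, genome_length // 400_000) if n_structural_rna is None else n_structural_rna
    structural: list[tuple[int, int]] = []
    for _ in range(n_rna):
        s = int(rng.integers(0, genome_length - 4_000))
        structural.append((s, s + 3_000))

    anchors = list(range(regions[0][0], regions[0][1], regions[0][2]))
    uniform = sorted(int(x) for x in rng.integers(0, genome_length, size=max(8, len(anchors))))
    regulators = {"RegAnchor": anchors, "RegUniform": uniform}
    return SyntheticTruth(
        genome_length=genome_length,
        regions=regions,
        operons=operons,
        structural_rna=sorted(structural),
        regulators=regulators,
        factor_seed=int(seed),
        kernel=kernel,
    )


def coupling_weights(truth: SyntheticTruth, grid: BinGrid) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin coupling weight and region (factor-family) index (-1 outside
    any region), evaluated at bin centers (a bin's natural position)."""
    starts = grid.bin_starts
    centers = starts + grid.bin_width / 2.0
    w = np.zeros(grid.n_bins)
    fam = np.full(grid.n_bins, -1, dtype=int)
    half = truth.kernel_half_width or grid.bin_width
    for k, (s, e, period, _amp) in enumerate(truth.regions):
        sel = (starts >= s) & (starts < e)
        x = centers[sel] - s
        if truth.kernel == "cosine":
            w[sel] = np.cos(2 * np.pi * x / period)
        elif truth.kernel == "triangular":
            d = np.mod(x, period)
            d = np.minimum(d, period - d)
            w[sel] = np.maximum(0.0, 1.0 - d / half)
        elif truth.kernel == "sawtooth":
            w[sel] = 1.0 - np.mod(x, period) / period
        else:
            raise ValueError(f"unknown kernel {truth.kernel!r}")
        fam[sel] = k
    return w, fam


def simulate_expression(
    truth: SyntheticTruth,
    n_phases: int = 5,
    n_replicates: int = 2,
    noise_sd: float = 0.2,
    library_size: float = 2_000_000,
    seed: int = 0,
    bin_width: int = 500,
    poisson: bool = True,
) -> SyntheticBundle:
    """Draw binned counts for ``n_phases`` growth phases in ``n_replicates``
    biological replicates.

    Log-expression of bin b in phase p is ``a * w_b * f(k,p) + eps`` with
    f(k,p) ~ N(0,1) per (region, phase) drawn from ``truth.factor_seed``
    (replicates share f and differ only in eps and the Poisson draw), and
    eps ~ N(0, noise_sd) per bin/sample. ``poisson=False`` returns the
    continuous noiseless-count intensities (useful for exact oracles)."""
    if n_phases < 3:
        raise ValueError("correlation across phases needs n_phases >= 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    grid = BinGrid(truth.genome_length, bin_width, bin_width, circular=True)
    w, fam = coupling_weights(truth, grid)
    amp = np.zeros(grid.n_bins)
    for k, (_s, _e, _p, a) in enumerate(truth.regions):
        amp[fam == k] = a

    factor_rng = np.random.default_rng(truth.factor_seed)
    n_regions = len(truth.regions)
    f = factor_rng.standard_normal((n_regions, n_phases))

    # operon members share one signal: coupling of the operon's first bin
    operon_of = np.full(grid.n_bins, -1, dtype=int)
    for oi, (s, e, _strand) in enumerate(truth.operons):
        operon_of[grid.bins_overlapping(s, e)] = oi
    for oi, (s, e, _strand) in enumerate(truth.operons):
        members = np.flatnonzero(operon_of == oi)
        if members.size:
            lead = members[0]
            w[members] = w[lead]
            fam[members] = fam[lead]
            amp[members] = amp[lead]

    rng = np.random.default_rng(seed)
    phases = PHASE_LABELS[:n_phases] if n_phases <= len(PHASE_LABELS) else [
        f"phase{p + 1:02d}" for p in range(n_phases)
    ]
    signal = amp[:, None] * w[:, None] * np.where(fam[:, None] >= 0, f[fam, :], 0.0)

    rna_mask = mask_structural_rna(truth.structural_rna, grid)
    cols = []
    design_rows = []
    for p, phase in enumerate(phases):
        for rep in range(1, n_replicates + 1):
            eps = rng.standard_normal(grid.n_bins) * noise_sd if noise_sd > 0 else 0.0
            lam = np.exp(signal[:, p] + eps)
            lam[rna_mask] *= STRUCTURAL_RNA_INFLATION
            lam *= library_size / lam.sum()
            counts = rng.poisson(lam).astype(float) if poisson else lam
            cols.append(counts)
            design_rows.append({"sample": f"{phase}_r{rep}", "phase": phase, "replicate": rep})
    counts = np.column_stack(cols)
    design = pd.DataFrame(design_rows)

    genes = pd.DataFrame(
        [
            {
                "gene_id": f"operon_{oi:04d}",
                "name": f"operon_{oi:04d}",
                "start": s,
                "end": e,
                "strand": strand,
            }
            for oi, (s, e, strand) in enumerate(truth.operons)
        ],
        columns=["gene_id", "name", "start", "end", "strand"],
    )
    return SyntheticBundle(
        truth=truth, counts=counts, design=design, annotation=genes, grid=grid, latent=signal
    )


def simulate_contacts(
    truth: SyntheticTruth,
    bin_width: int = 5_000,
    decay_exponent: float = 1.0,
    coupling_boost: float = 5.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> ContactMatrix:
    """Symmetric contact map: circular distance-decay baseline
    ``(d/bin_width)^-decay_exponent`` times ``coupling_boost**(w_i*w_j)``
    for same-region pairs (boost 1 = pure distance decay). Optional
    multiplicative log-normal noise."""
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be > 0")
    grid = BinGrid(truth.genome_length, bin_width, bin_width, circular=True)
    n = grid.n_bins
    idx = np.arange(n)
    d = np.abs(grid.signed_lag(idx[:, None], idx[None, :])).astype(float)
    with np.errstate(divide="ignore"):
        freq = np.where(d > 0, (d / bin_width) ** (-decay_exponent), 0.0)
    if coupling_boost != 1.0:
        w, fam = coupling_weights(truth, grid)
        same = (fam[:, None] == fam[None, :]) & (fam[:, None] >= 0)
        rho = np.where(same, w[:, None] * w[None, :], 0.0)
        freq *= coupling_boost**rho
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.exp(rng.standard_normal((n, n)) * noise_sd)
        noise = np.sqrt(noise * noise.T)  # keep symmetry
        freq *= noise
    np.fill_diagonal(freq, 0.0)
    return ContactMatrix(grid=grid, freq=freq, normalization="synthetic")


# ---------------------------------------------------------------------------
# fixture I/O (plain-text, round-trips bit-identically through the readers)

_RNA_TYPES = ("rRNA", "tRNA", "tmRNA")


def write_fixtures(bundle: SyntheticBundle, out_dir) -> dict[str, str]:
    """Write counts TSV, per-sample bedGraphs, design TSV, GFF3 annotation,
    regulator-target TSV and (if present) a contact COO TSV."""
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    counts_path = os.path.join(out_dir, "counts.tsv")
    starts = bundle.grid.bin_starts
    df = pd.DataFrame({"bin_start": starts, "bin_end": starts + bundle.grid.bin_width})
    for k, name in enumerate(bundle.design["sample"]):
        df[name] = bundle.counts[:, k].astype(np.int64)
    df.to_csv(counts_path, sep="\t", index=False)
    paths["counts"] = counts_path

    design_path = os.path.join(out_dir, "design.tsv")
    bundle.design.to_csv(design_path, sep="\t", index=False)
    paths["design"] = design_path

    gff_path = os.path.join(out_dir, "annotation.gff3")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region chrom 1 {bundle.truth.genome_length}\n")
        for oi, (s, e, strand) in enumerate(bundle.truth.operons):
            gid = f"operon_{oi:04d}"
            fh.write(
                f"chrom\tcpedscan\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gid};Name={gid}\n"
            )
        for ri, (s, e) in enumerate(bundle.truth.structural_rna):
            ftype = _RNA_TYPES[ri % len(_RNA_TYPES)]
            fid = f"{ftype.lower()}_{ri:03d}"
            fh.write(
                f"chrom\tcpedscan\t{ftype}\t{s + 1}\t{e}\t.\t+\t.\tID={fid};Name={fid}\n"
            )
    paths["annotation"] = gff_path

    reg_path = os.path.join(out_dir, "regulators.tsv")
    rows = [
        {"regulator": name, "target_position": int(t)}
        for name, targets in bundle.truth.regulators.items()
        for t in targets
    ]
    pd.DataFrame(rows, columns=["regulator", "target_position"]).to_csv(
        reg_path, sep="\t", index=False
    )
    paths["regulators"] = reg_path

    for k, name in enumerate(bundle.design["sample"]):
        bg_path = os.path.join(out_dir, f"{name}.bedGraph")
        col = bundle.counts[:, k].astype(np.int64)
        mids = starts + bundle.grid.bin_width // 2
        nz = col > 0
        pd.DataFrame(
            {
                "chrom": "chrom",
                "start": mids[nz] % bundle.grid.genome_length,
                "end": mids[nz] % bundle.grid.genome_length + 1,
                "value": col[nz],
            }
        ).to_csv(bg_path, sep="\t", index=False, header=False)
        paths[f"bedgraph:{name}"] = bg_path

    if bundle.contacts is not None:
        contacts_path = os.path.join(out_dir, "contacts.tsv")
        bundle.contacts.to_coo_tsv(contacts_path)
        paths["contacts"] = contacts_path
    return paths


def read_counts_tsv(path, circular: bool = True) -> tuple[np.ndarray, BinGrid, list[str]]:
    """Round-trip reader for the counts TSV written by :func:`write_fixtures`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    samples = [c for c in df.columns if c not in ("bin_start", "bin_end")]
    starts = df["bin_start"].to_numpy()
    bin_width = int((df["bin_end"] - df["bin_start"]).iloc[0])
    step = int(starts[1] - starts[0]) if len(starts) > 1 else bin_width
    genome_length = int(starts[-1]) + step
    grid = BinGrid(genome_length, bin_width, step, circular=circular)
    return df[samples].to_numpy(dtype=np.int64), grid, samples
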