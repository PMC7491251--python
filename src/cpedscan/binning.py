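"""From alignments or coverage tracks to a masked, FPM-normalized,
replicate-averaged expression matrix.

The pipeline is: ``count_bins`` (per sample) -> ``mask_structural_rna`` ->
``normalize_and_average``. Counting assigns each sequenced *fragment* once,
by its midpoint, so that non-overlapping bins partition the fragments;
a coverage-sum mode is available for sliding (overlapping) bins.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd
import pysam

from .annotation import load_gff, structural_rna_intervals
from .expression import ExpressionMatrix
from .grid import BinGrid

__all__ = [
    "count_bins",
    "count_bam",
    "count_bedgraph",
    "mask_structural_rna",
    "normalize_and_average",
]


def _midpoint_counts(midpoints: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Histogram fragment midpoints onto the grid.

    For non-overlapping bins each midpoint lands in exactly one bin; for a
    sliding grid (step < bin_width) a midpoint is credited to every bin
    covering it.
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    if midpoints.size == 0:
        return counts
    mids = midpoints % grid.genome_length
    if grid.step == grid.bin_width:
        np.add.at(counts, grid.bin_of(mids), 1)
        return counts
    # sliding bins: bin i covers [i*step, i*step + bin_width)
    k_hi = mids // grid.step
    n_cover = grid.bin_width // grid.step
    for off in range(n_cover):
        idx = (k_hi - off) % grid.n_bins
        starts = idx * grid.step
        span = (mids - starts) % grid.genome_length
        ok = span < grid.bin_width
        np.add.at(counts, idx[ok], 1)
    return counts


def count_bam(path, grid: BinGrid) -> np.ndarray:
    """Per-bin fragment counts from a SAM/BAM file (single pass, no index).

    Paired reads are counted once per fragment, at the fragment midpoint
    (read with positive template length); unpaired reads at the alignment
    midpoint.
    """
    mode = "r" if str(path).endswith(".sam") else "rb"
    mids = []
    with pysam.AlignmentFile(str(path), mode) as bam:
        ref_len = bam.header.lengths[0] if bam.header.nreferences else None
        if ref_len is not None and ref_len != grid.genome_length:
            raise ValueError(
                f"reference length {ref_len} in {path} does not match "
                f"grid genome_length {grid.genome_length}"
            )
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired:
                if not read.is_proper_pair or read.template_length <= 0:
                    continue
                mid = read.reference_start + read.template_length // 2
            else:
                mid = (read.reference_start + read.reference_end) // 2
            mids.append(mid)
    return _midpoint_counts(np.asarray(mids, dtype=np.int64), grid)


def count_bedgraph(path, grid: BinGrid) -> np.ndarray:
    """Per-bin counts from a 4-column bedGraph (chrom, start, end, value).

    The track value is treated as a per-base signal and summed into each
    bin over the overlapped bases; a track holding fragment-midpoint counts
    therefore reproduces the BAM midpoint counting exactly.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"start": np.int64, "end": np.int64, "value": float},
    )
    if len(df) and df["end"].max() > grid.genome_length:
        raise ValueError(
            f"bedGraph interval end {df['end'].max()} exceeds grid "
            f"genome_length {grid.genome_length}"
        )
    counts = np.zeros(grid.n_bins, dtype=float)
    starts = grid.bin_starts
    ends = starts + grid.bin_width
    g = grid.genome_length
    for s, e, v in df[["start", "end", "value"]].itertuples(index=False):
        for i in grid.bins_overlapping(int(s), int(e)):
            ov = max(0, min(e, min(ends[i], g)) - max(s, starts[i]))
            if grid.circular and ends[i] > g:  # wrapped tail of the last bin
                ov += max(0, min(e, ends[i] - g) - s) if s < ends[i] - g else 0
            counts[i] += v * ov
    return np.rint(counts).astype(np.int64) if np.allclose(counts, np.rint(counts)) else counts


def count_bins(path, grid: BinGrid) -> np.ndarray:
    """Dispatch on file extension: .sam/.bam -> alignments, otherwise bedGraph."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".sam", ".bam"):
        return count_bam(path, grid)
    return count_bedgraph(path, grid)


def mask_structural_rna(annotation, grid: BinGrid) -> np.ndarray:
    """Boolean mask: True for every bin overlapping (>=1 bp) an rRNA, tRNA
    or tmRNA feature.

    ``annotation`` may be a GFF3 path, a gffutils database, or a list of
    (start, end) 0-based half-open intervals.
    """
    if isinstance(annotation, (str, os.PathLike)):
        intervals = structural_rna_intervals(load_gff(annotation))
    elif isinstance(annotation, (list, tuple)):
        intervals = list(annotation)
    else:  # gffutils.FeatureDB
        intervals = structural_rna_intervals(annotation)
    mask = np.zeros(grid.n_bins, dtype=bool)
    for start, end in intervals:
        mask[grid.bins_overlapping(int(start), int(end))] = True
    return mask


def normalize_and_average(
    raw: np.ndarray,
    mask: np.ndarray,
    design: pd.DataFrame,
    grid: BinGrid,
    masked_in_denominator: bool = False,
) -> ExpressionMatrix:
    """FPM-normalize each sample and average biological replicates per phase.

    Per sample, values = count * 1e6 / library_size. By default masked bins
    are nulled *before* the library size is computed (they are excluded from
    the per-million denominator, removing the depletion-efficiency bias that
    motivates the masking); set ``masked_in_denominator=True`` to keep them
    in the denominator. Replicates are arithmetic-averaged per phase after
    normalization.
    """
    raw = np.asarray(raw, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if raw.shape[0] != grid.n_bins:
        raise ValueError(f"raw has {raw.shape[0]} rows, grid has {grid.n_bins} bins")
    if raw.shape[1] != len(design):
        raise ValueError("one design row per sample column is required")
    if np.any(raw < 0) or not np.all(np.isfinite(raw)):
        raise ValueError("counts must be finite and non-negative")

    fpm = np.empty_like(raw)
    for s in range(raw.shape[1]):
        col = raw[:, s]
        denom = col.sum() if masked_in_denominator else col[~mask].sum()
        if denom <= 0:
            raise ValueError(f"sample {design['sample'].iloc[s]!r} has zero unmasked counts")
        fpm[:, s] = col * (1e6 / denom)
    fpm[mask, :] = np.nan

    phases = list(dict.fromkeys(design["phase"]))  # preserve order
    values = np.full((grid.n_bins, len(phases)), np.nan)
    for k, ph in enumerate(phases):
        cols = np.flatnonzero((design["phase"] == ph).to_numpy())
        values[:, k] = fpm[:, cols].mean(axis=1)
    return ExpressionMatrix(
        grid=grid,
        values=values,
        mask=mask,
        condition_labels=[str(p) for p in phases],
        raw_counts=np.asarray(raw),
        design=design.reset_index(drop=True),
        masked_in_denominator=masked_in_denominator,
    )
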