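"""Binned, normalized expression matrices.

The central container is :class:`ExpressionMatrix`: bins x conditions of
fragments-per-million values, with a boolean mask marking structural-RNA
(rRNA/tRNA/tmRNA) bins whose values are nulled (NaN). Raw per-sample counts
and the sample design are carried along when available so that the matrix
can be re-binned at a coarser width with the normalization rules reapplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import BinGrid

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    grid: BinGrid
    values: np.ndarray  # n_bins x n_conditions, FPM, NaN where masked
    mask: np.ndarray  # n_bins bool, True = structural-RNA / nulled
    condition_labels: list[str]
    # optional provenance for re-binning: raw counts per sample + design
    raw_counts: np.ndarray | None = None  # n_bins x n_samples
    design: pd.DataFrame | None = None  # columns: sample, phase, replicate
    masked_in_denominator: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (self.grid.n_bins, len(self.condition_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{self.grid.n_bins} bins x {len(self.condition_labels)} conditions"
            )
        if self.mask.shape != (self.grid.n_bins,):
            raise ValueError("mask length does not match bin count")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    def to_frame(self) -> pd.DataFrame:
        starts = self.grid.bin_starts
        df = pd.DataFrame(
            {
                "bin_start": starts,
                "bin_end": starts + self.grid.bin_width,
                "masked": self.mask.astype(int),
            }
        )
        for k, lab in enumerate(self.condition_labels):
            df[lab] = self.values[:, k]
        return df

    def to_tsv(self, path, header_comments: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_comments or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, circular: bool = True) -> "ExpressionMatrix":
        df = pd.read_csv(
            path, sep="\t", comment="#", na_values=["NA"], float_precision="round_trip"
        )
        cond = [c for c in df.columns if c not in ("bin_start", "bin_end", "masked")]
        starts = df["bin_start"].to_numpy()
        widths = (df["bin_end"] - df["bin_start"]).to_numpy()
        step = int(starts[1] - starts[0]) if len(starts) > 1 else int(widths[0])
        bin_width = int(widths[0])
        genome_length = int(starts[-1]) + step
        grid = BinGrid(genome_length, bin_width, step, circular=circular)
        return cls(
            grid=grid,
            values=df[cond].to_numpy(dtype=float),
            mask=df["masked"].to_numpy(dtype=bool),
            condition_labels=cond,
        )
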