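"""Fixed-width tiling of a (usually circular) bacterial chromosome.

All genomic coordinates inside the package are 0-based half-open; GFF3
input (1-based closed) is converted at the parsing boundary. The grid owns
every piece of coordinate arithmetic the rest of the pipeline needs, in
particular the *signed minimal wrap distance* between bins on a circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = ["BinGrid"]


@dataclass(frozen=True)
class BinGrid:
    """Tiling of a genome of ``genome_length`` bp into bins of ``bin_width``
    bp spaced ``step`` bp apart.

    With ``step == bin_width`` (the default) the bins are non-overlapping;
    ``step < bin_width`` gives a sliding tiling (e.g. 1000 bp bins sliding
    at 500 bp). Bin ``i`` covers ``[i*step, i*step + bin_width)``, truncated
    at ``genome_length`` for a linear genome and wrapped for a circular one.
    """

    genome_length: int
    bin_width: int = 500
    step: int | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if self.step is None:
            object.__setattr__(self, "step", self.bin_width)
        if self.genome_length <= 0:
            raise ValueError(f"genome_length must be positive, got {self.genome_length}")
        if not (0 < self.step <= self.bin_width <= self.genome_length):
            raise ValueError(
                "need 0 < step <= bin_width <= genome_length, got "
                f"step={self.step}, bin_width={self.bin_width}, "
                f"genome_length={self.genome_length}"
            )

    @property
    def n_bins(self) -> int:
        return math.ceil(self.genome_length / self.step)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.step

    def bin_interval(self, i: int) -> tuple[int, int]:
        """(start, end) of bin ``i``; end may exceed genome_length on a
        circular genome (the bin wraps) and is clipped on a linear one."""
        start = int(i) * self.step
        end = start + self.bin_width
        if not self.circular:
            end = min(end, self.genome_length)
        return start, end

    def bin_of(self, position: int | np.ndarray) -> np.ndarray:
        """Index of the *step-tile* containing ``position`` (the unique bin
        when bins are non-overlapping)."""
        pos = np.asarray(position, dtype=np.int64) % self.genome_length
        idx = pos // self.step
        return np.minimum(idx, self.n_bins - 1)

    def signed_lag(self, i: int | np.ndarray, j: int | np.ndarray) -> np.ndarray:
        """Signed genomic lag (bp) from bin ``i`` to bin ``j``.

        Circular grids use the minimal wrap distance in ``(-G/2, G/2]``;
        at the exact antipode of an even-sized circle both directions are
        G/2 and the positive sign is returned for either order.
        """
        d = (np.asarray(j, dtype=np.int64) - np.asarray(i, dtype=np.int64)) * self.step
        if not self.circular:
            return d
        g = self.genome_length
        w = d % g
        return np.where(w > g // 2, w - g, w)

    def circular_distance(self, i, j) -> np.ndarray:
        return np.abs(self.signed_lag(i, j))

    def bins_overlapping(self, start: int, end: int) -> np.ndarray:
        """Indices of all bins overlapping ``[start, end)`` by >= 1 bp.

        On a circular genome the query interval may wrap (``start > end``
        means the interval crosses the origin) and bins that themselves
        wrap past the origin are handled.
        """
        if end < start:
            if not self.circular:
                raise ValueError(f"inverted interval [{start}, {end}) on a linear grid")
            a = self.bins_overlapping(start, self.genome_length)
            b = self.bins_overlapping(0, end)
            return np.union1d(a, b)
        starts = self.bin_starts
        ends = starts + self.bin_width
        hit = (starts < end) & (ends > start)
        if self.circular:
            # wrapped tail of bins whose interval passes genome_length
            over = ends > self.genome_length
            hit |= over & ((ends - self.genome_length) > start)
        return np.flatnonzero(hit)

    def lag_grid(self, max_lag: int, include_zero: bool = False) -> np.ndarray:
        """Signed lags ``-max_lag .. +max_lag`` in steps of ``step``."""
        k = max_lag // self.step
        lags = np.arange(-k, k + 1, dtype=np.int64) * self.step
        if not include_zero:
            lags = lags[lags != 0]
        return lags
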