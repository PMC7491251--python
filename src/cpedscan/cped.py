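"""Correlation of Pairwise Expression relative to Distance (CPED).

For every genomic bin, the Pearson correlation of its expression changes
(across growth-phase conditions) with every neighbor out to ``max_lag`` bp
is computed, yielding a bins x signed-lags *band* — the per-bin CPED
profiles. Profiles are then averaged over bins inside a genomic region,
with a 95% confidence interval of the mean per lag.

The band, not a full n x n matrix, is the primary structure: at 500 bp bins
on a multi-Mbp genome a +/-200 kbp band holds every pair any profile
analysis needs at a fraction of the memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix
from .grid import BinGrid

__all__ = ["pearson", "correlation_band", "average_profiles", "CorrelationBand", "AveragedProfile"]


def pearson(x, y) -> float:
    """Pearson r on complete cases; NaN if < 3 complete pairs or either
    vector is constant (mirrors R's cor(use="complete.obs") degeneracies)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    xs, ys = x[ok] - x[ok].mean(), y[ok] - y[ok].mean()
    denom = np.sqrt((xs * xs).sum() * (ys * ys).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((xs * ys).sum() / denom, -1.0, 1.0))


@dataclass
class CorrelationBand:
    grid: BinGrid
    max_lag: int
    lags: np.ndarray  # signed bp, +/-max_lag in steps of grid.step, no 0
    r: np.ndarray  # n_bins x n_lags, NaN where missing
    mask: np.ndarray  # n_bins bool (structural-RNA bins)

    def lag_index(self, lag_bp: int) -> int:
        idx = np.flatnonzero(self.lags == lag_bp)
        if idx.size != 1:
            raise KeyError(f"lag {lag_bp} not on the band's lag grid")
        return int(idx[0])


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm, so the correlation of two
    bins is the dot product of their standardized rows. Rows that are
    constant or contain any missing value become all-NaN."""
    v = np.asarray(values, dtype=float)
    bad = ~np.all(np.isfinite(v), axis=1)
    v = np.where(np.isfinite(v), v, 0.0)
    z = v - v.mean(axis=1, keepdims=True)
    norm = np.sqrt(np.sum(z * z, axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = z / norm
    z[bad | (norm[:, 0] == 0)] = np.nan
    return z


def correlation_band(matrix: ExpressionMatrix, max_lag: int = 200_000) -> CorrelationBand:
    """Pearson correlation between every unmasked bin and the bin at each
    signed circular lag in [-max_lag, +max_lag] (step = grid.step, lag 0
    excluded). Entries touching a masked bin are NaN.
    """
    grid = matrix.grid
    if matrix.n_conditions < 3:
        raise ValueError("need >= 3 conditions for pairwise correlation")
    if grid.circular and max_lag > grid.genome_length // 2:
        raise ValueError(
            f"max_lag {max_lag} exceeds half the genome length "
            f"({grid.genome_length // 2}) on a circular grid"
        )
    z = _standardize_rows(matrix.values)
    lags = grid.lag_grid(max_lag)
    n = grid.n_bins
    r = np.full((n, lags.size), np.nan)
    for k, lag in enumerate(lags):
        shift = int(lag) // grid.step
        if grid.circular:
            zj = np.roll(z, -shift, axis=0)
            r[:, k] = np.einsum("ij,ij->i", z, zj)
        else:
            lo, hi = max(0, -shift), min(n, n - shift)
            r[lo:hi, k] = np.einsum("ij,ij->i", z[lo:hi], z[lo + shift : hi + shift])
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationBand(grid=grid, max_lag=max_lag, lags=lags, r=r, mask=matrix.mask.copy())


@dataclass
class AveragedProfile:
    region: tuple[int, int]
    lags: np.ndarray  # signed bp
    mean_r: np.ndarray
    ci95: np.ndarray  # half-width of the 95% CI of the mean
    n: np.ndarray  # contributing bins per lag

    def values_at(self, positive_only: bool = False):
        if positive_only:
            keep = self.lags > 0
            return self.lags[keep], self.mean_r[keep]
        return self.lags, self.mean_r


def average_profiles(
    band: CorrelationBand,
    region: tuple[int, int],
    exclude_bins: np.ndarray | None = None,
) -> AveragedProfile:
    """Average the per-bin CPED profiles over all unmasked bins whose start
    lies in ``region`` (0-based half-open; start > end wraps on a circular
    grid), ignoring missing entries. ``exclude_bins`` removes specific bin
    indices from the average (regulator-exclusion re-profiling)."""
    start, end = region
    starts = band.grid.bin_starts
    if end >= start:
        in_region = (starts >= start) & (starts < end)
    else:
        if not band.grid.circular:
            raise ValueError("wrapped region on a linear grid")
        in_region = (starts >= start) | (starts < end)
    in_region &= ~band.mask
    if exclude_bins is not None and len(exclude_bins):
        in_region[np.asarray(exclude_bins, dtype=int)] = False
    if not in_region.any():
        raise ValueError(f"region {region} contains no usable bins")
    sub = band.r[in_region]
    n = np.sum(np.isfinite(sub), axis=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(sub, axis=0)
        sd = np.nanstd(sub, axis=0, ddof=1)
    ci = np.where(n > 1, 1.96 * sd / np.sqrt(np.maximum(n, 1)), np.nan)
    mean[n == 0] = np.nan
    return AveragedProfile(region=(start, end), lags=band.lags.copy(), mean_r=mean, ci95=ci, n=n)
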