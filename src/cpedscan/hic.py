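"""Spatial proximity (3C contact frequency) versus pairwise co-expression.

Expression is re-binned to the contact map's resolution (5 kbp in the
reference dataset), every unordered bin pair with a circular linear
distance strictly greater than 20 kbp (to exclude operons and local
supercoiling effects) is joined to its contact frequency and its Pearson
correlation across conditions, and the pairs are grouped by increasing
contact frequency. Each group's mean correlation is compared to the
lowest-contact group with a two-sided rank-sum (Wilcoxon/Mann-Whitney)
test, Bonferroni-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binning import normalize_and_average
from .cped import _standardize_rows
from .expression import ExpressionMatrix
from .grid import BinGrid

__all__ = [
    "ContactMatrix",
    "PairAssociation",
    "rebin_expression",
    "build_pairs",
    "group_and_test",
]


@dataclass
class ContactMatrix:
    grid: BinGrid
    freq: np.ndarray  # n_bins x n_bins, symmetric, non-negative; diagonal ignored
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (self.grid.n_bins, self.grid.n_bins):
            raise ValueError("contact matrix shape does not match grid")
        if not np.allclose(self.freq, self.freq.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")

    def to_coo_tsv(self, path) -> None:
        iu = np.triu_indices(self.grid.n_bins, k=1)
        vals = self.freq[iu]
        keep = np.isfinite(vals) & (vals != 0)
        pd.DataFrame(
            {"bin_i": iu[0][keep], "bin_j": iu[1][keep], "frequency": vals[keep]}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_coo_tsv(cls, path, grid: BinGrid, normalization: str = "raw") -> "ContactMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
        freq = np.zeros((grid.n_bins, grid.n_bins))
        i = df["bin_i"].to_numpy(dtype=int)
        j = df["bin_j"].to_numpy(dtype=int)
        v = df["frequency"].to_numpy(dtype=float)
        freq[i, j] = v
        freq[j, i] = v
        return cls(grid=grid, freq=freq, normalization=normalization)

    @classmethod
    def from_dense_tsv(cls, path, grid: BinGrid, normalization: str = "raw") -> "ContactMatrix":
        freq = pd.read_csv(path, sep="\t", comment="#", header=None).to_numpy(dtype=float)
        return cls(grid=grid, freq=freq, normalization=normalization)


def rebin_expression(matrix: ExpressionMatrix, target_width: int) -> ExpressionMatrix:
    """Re-aggregate the matrix's raw counts at ``target_width`` (a multiple
    of the source step), then reapply normalization, masking and replicate
    averaging. A coarse bin is masked if any constituent fine bin was."""
    grid = matrix.grid
    if grid.step != grid.bin_width:
        raise ValueError("rebinning requires non-overlapping source bins")
    if target_width % grid.step != 0:
        raise ValueError(f"target width {target_width} is not a multiple of step {grid.step}")
    if matrix.raw_counts is None or matrix.design is None:
        raise ValueError("matrix carries no raw counts/design; cannot rebin")
    if target_width == grid.step:
        return matrix
    factor = target_width // grid.step
    n_coarse = int(np.ceil(grid.n_bins / factor))
    pad = n_coarse * factor - grid.n_bins
    raw = matrix.raw_counts
    if pad:
        raw = np.vstack([raw, np.zeros((pad, raw.shape[1]))])
    coarse_raw = raw.reshape(n_coarse, factor, -1).sum(axis=1)
    mask_pad = np.concatenate([matrix.mask, np.zeros(pad, dtype=bool)])
    coarse_mask = mask_pad.reshape(n_coarse, factor).any(axis=1)
    coarse_grid = BinGrid(grid.genome_length, target_width, target_width, circular=grid.circular)
    return normalize_and_average(
        coarse_raw,
        coarse_mask,
        matrix.design,
        coarse_grid,
        masked_in_denominator=matrix.masked_in_denominator,
    )


@dataclass
class PairAssociation:
    pairs: pd.DataFrame  # bin_i, bin_j, distance, contact, r [, group]
    min_linear_distance: int
    n_dropped_missing_contact: int = 0
    group_summary: pd.DataFrame | None = None
    tests: pd.DataFrame | None = None
    n_groups: int | None = None


def build_pairs(
    expr: ExpressionMatrix,
    contacts: ContactMatrix,
    min_linear_distance: int = 20_000,
) -> PairAssociation:
    """All unordered unmasked bin pairs (i < j) with circular linear
    distance strictly greater than ``min_linear_distance``, joined to the
    contact frequency and the pairwise expression correlation. Pairs with
    missing (NaN or zero) contact are dropped and counted."""
    if expr.grid.n_bins != contacts.grid.n_bins or expr.grid.step != contacts.grid.step:
        raise ValueError(
            f"expression grid ({expr.grid.n_bins} bins @ {expr.grid.step} bp) does not "
            f"match contact grid ({contacts.grid.n_bins} bins @ {contacts.grid.step} bp)"
        )
    grid = expr.grid
    z = _standardize_rows(expr.values)
    corr = z @ z.T  # NaN rows (masked/constant) propagate
    np.clip(corr, -1.0, 1.0, out=corr)
    iu, ju = np.triu_indices(grid.n_bins, k=1)
    dist = grid.circular_distance(iu, ju)
    keep = dist > min_linear_distance
    iu, ju, dist = iu[keep], ju[keep], dist[keep]
    r = corr[iu, ju]
    c = contacts.freq[iu, ju]
    ok = np.isfinite(r)
    have_contact = np.isfinite(c) & (c > 0)
    n_dropped = int(np.sum(ok & ~have_contact))
    sel = ok & have_contact
    pairs = pd.DataFrame(
        {
            "bin_i": iu[sel],
            "bin_j": ju[sel],
            "distance": dist[sel],
            "contact": c[sel],
            "r": r[sel],
        }
    )
    return PairAssociation(
        pairs=pairs,
        min_linear_distance=min_linear_distance,
        n_dropped_missing_contact=n_dropped,
    )


def group_and_test(
    assoc: PairAssociation, n_groups: int = 8, scheme: str = "logwidth"
) -> PairAssociation:
    """Group pairs by increasing contact frequency and test each group's
    correlation distribution against the lowest-contact group.

    ``scheme='logwidth'`` (default) uses equal-width intervals on
    log10(contact), which yields groups of unequal membership;
    ``'quantile'`` uses equal-count groups. Empty groups are merged into
    their lower neighbor with a warning. Rank-sum p-values are two-sided
    and Bonferroni-adjusted by (n_groups - 1), capped at 1."""
    pairs = assoc.pairs.copy()
    logc = np.log10(pairs["contact"].to_numpy())
    lo, hi = logc.min(), logc.max()
    if hi == lo:
        pairs["group"] = 1
        groups = [1]
    else:
        if scheme == "logwidth":
            edges = np.linspace(lo, hi, n_groups + 1)
            g = np.clip(np.searchsorted(edges, logc, side="right") - 1, 0, n_groups - 1) + 1
        elif scheme == "quantile":
            g = pd.qcut(logc, n_groups, labels=False, duplicates="drop") + 1
        else:
            raise ValueError(f"unknown grouping scheme {scheme!r}")
        g = np.asarray(g, dtype=int)
        present = np.unique(g)
        if len(present) < n_groups:
            warnings.warn(
                f"{n_groups - len(present)} empty contact group(s) merged into neighbors"
            )
        # relabel to consecutive 1..k preserving order
        relabel = {old: k + 1 for k, old in enumerate(present)}
        g = np.array([relabel[x] for x in g])
        pairs["group"] = g
        groups = sorted(relabel.values())
    if len(groups) < 2:
        assoc.pairs = pairs
        assoc.group_summary = _summary(pairs, groups)
        assoc.tests = pd.DataFrame(columns=["group", "p_raw", "p_bonferroni"])
        assoc.n_groups = len(groups)
        return assoc
    summary = _summary(pairs, groups)
    base = pairs.loc[pairs["group"] == groups[0], "r"].to_numpy()
    rows = []
    for gk in groups[1:]:
        vals = pairs.loc[pairs["group"] == gk, "r"].to_numpy()
        p = float(stats.mannwhitneyu(vals, base, alternative="two-sided").pvalue)
        rows.append(
            {"group": gk, "p_raw": p, "p_bonferroni": min(p * (len(groups) - 1), 1.0)}
        )
    assoc.pairs = pairs
    assoc.group_summary = summary
    assoc.tests = pd.DataFrame(rows)
    assoc.n_groups = len(groups)
    return assoc


def _summary(pairs: pd.DataFrame, groups) -> pd.DataFrame:
    rows = []
    for gk in groups:
        vals = pairs.loc[pairs["group"] == gk, "r"].to_numpy()
        n = len(vals)
        mean = float(vals.mean()) if n else np.nan
        ci = float(1.96 * vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            {
                "group": gk,
                "n": n,
                "mean_r": mean,
                "ci95": ci,
                "contact_min": float(pairs.loc[pairs["group"] == gk, "contact"].min()) if n else np.nan,
                "contact_max": float(pairs.loc[pairs["group"] == gk, "contact"].max()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
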