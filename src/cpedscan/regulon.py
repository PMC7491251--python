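"""Regulator-target subset analysis of co-expression.

Tests whether transcription factors, sigma factors or nucleoid-associated
proteins account for the observed co-expression by comparing correlation
coefficients within four bin subsets per regulator — *At* (bins within a
flank of a regulatory target), *Between* (mock sites at the circular
midpoints toward the clockwise successor site), *Random* (repeated
same-size uniform draws) and *Without* (every coefficient not touching an
At bin) — and by re-profiling regions with the regulator's bins excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cped import AveragedProfile, CorrelationBand, average_profiles
from .grid import BinGrid
from .periodicity import PeriodogramResult, ScanConfig, lomb_scargle

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatorTargets",
    "SubsetCorrelations",
    "parse_targets",
    "between_sites",
    "subset_distributions",
    "exclusion_reprofile",
]

MIN_AT_BINS = 20  # regulators with <= this many associated bins are dropped


@dataclass
class RegulatorTargets:
    regulator: str
    targets: np.ndarray  # sorted genomic positions (bp)
    flank: int
    at_bins: np.ndarray  # bin indices overlapping any [t-flank, t+flank]

    @classmethod
    def from_positions(
        cls, regulator: str, positions, grid: BinGrid, flank: int = 500
    ) -> "RegulatorTargets":
        pos = np.sort(np.asarray(positions, dtype=np.int64) % grid.genome_length)
        bins: set[int] = set()
        for t in pos:
            lo, hi = int(t) - flank, int(t) + flank
            lo_mod = lo % grid.genome_length
            hi_mod = hi % grid.genome_length
            if lo < 0 or hi > grid.genome_length:
                bins.update(grid.bins_overlapping(lo_mod, hi_mod).tolist())
            else:
                bins.update(grid.bins_overlapping(lo, hi).tolist())
        return cls(
            regulator=regulator,
            targets=pos,
            flank=flank,
            at_bins=np.array(sorted(bins), dtype=int),
        )


def parse_targets(
    path,
    annotation: pd.DataFrame | None,
    grid: BinGrid,
    flank: int = 500,
    min_bins: int = MIN_AT_BINS,
    position_mode: str = "tss",
) -> list[RegulatorTargets]:
    """Read a RegulonDB-style TSV mapping regulator -> target gene (or a
    direct ``target_position`` column) into per-regulator target sets.

    Columns accepted: ``regulator`` plus either ``target_gene`` (resolved
    through ``annotation``, a gene table) or ``target_position`` (bp).
    ``position_mode`` places gene targets at the strand-aware 5' end
    ("tss", where the regulated promoter sits) or the leftmost coordinate
    ("start"). Regulators with <= ``min_bins`` associated bins are dropped,
    unresolvable gene names skipped; if nothing resolves, that is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    if "regulator" not in df.columns:
        raise ValueError(f"{path}: expected a 'regulator' column, got {list(df.columns)}")
    by_name: dict[str, tuple[int, int, str]] = {}
    if annotation is not None:
        for rec in annotation.itertuples(index=False):
            by_name[str(rec.name)] = (int(rec.start), int(rec.end), rec.strand)
            by_name.setdefault(str(rec.gene_id), (int(rec.start), int(rec.end), rec.strand))

    out: list[RegulatorTargets] = []
    n_unresolved = 0
    any_resolved = False
    for reg, sub in df.groupby("regulator", sort=False):
        positions: list[int] = []
        if "target_position" in sub.columns and sub["target_position"].notna().any():
            positions = [int(p) for p in sub["target_position"].dropna()]
        else:
            for gene in sub.get("target_gene", pd.Series(dtype=str)).dropna():
                rec = by_name.get(str(gene))
                if rec is None:
                    n_unresolved += 1
                    logger.info("regulator %s: target gene %r not in annotation", reg, gene)
                    continue
                start, end, strand = rec
                if position_mode == "tss":
                    positions.append(start if strand == "+" else end - 1)
                else:
                    positions.append(start)
        if not positions:
            continue
        any_resolved = True
        rt = RegulatorTargets.from_positions(str(reg), positions, grid, flank)
        if len(rt.at_bins) <= min_bins:
            logger.info(
                "regulator %s dropped: %d associated bins (need > %d)",
                reg,
                len(rt.at_bins),
                min_bins,
            )
            continue
        out.append(rt)
    if not any_resolved:
        raise ValueError(f"{path}: no regulator target could be resolved")
    return out


def between_sites(targets: RegulatorTargets, grid: BinGrid) -> np.ndarray:
    """Mock binding sites: for each real site, the circular midpoint between
    it and its clockwise successor. Same cardinality as the real set."""
    pos = targets.targets
    if pos.size < 2:
        raise ValueError("between_sites needs >= 2 target positions")
    g = grid.genome_length
    succ = np.roll(pos, -1)
    gap = (succ - pos) % g
    return (pos + gap // 2) % g


def _band_pairs_r(band: CorrelationBand, bins: np.ndarray) -> np.ndarray:
    """Correlation coefficients for all unordered pairs among ``bins`` that
    fall inside the band (each pair once, via positive lags)."""
    bins = np.asarray(sorted(set(int(b) for b in bins)), dtype=int)
    inset = np.zeros(band.grid.n_bins, dtype=bool)
    inset[bins] = True
    pos = band.lags > 0
    shifts = (band.lags[pos] // band.grid.step).astype(int)
    out = []
    sub = band.r[bins][:, pos]
    for col, sh in enumerate(shifts):
        partners = (bins + sh) % band.grid.n_bins if band.grid.circular else bins + sh
        ok = (partners < band.grid.n_bins) & inset[partners % band.grid.n_bins]
        vals = sub[ok, col]
        out.append(vals[np.isfinite(vals)])
    return np.concatenate(out) if out else np.empty(0)


def _without_pairs_r(band: CorrelationBand, at_bins: np.ndarray) -> np.ndarray:
    """All band coefficients (each pair once) excluding any pair touching an
    At bin."""
    at = np.zeros(band.grid.n_bins, dtype=bool)
    at[np.asarray(at_bins, dtype=int)] = True
    pos = band.lags > 0
    shifts = (band.lags[pos] // band.grid.step).astype(int)
    idx = np.arange(band.grid.n_bins)
    out = []
    for col, sh in zip(np.flatnonzero(pos), shifts):
        partners = (idx + sh) % band.grid.n_bins if band.grid.circular else idx + sh
        ok = partners < band.grid.n_bins
        keep = ok & ~at & ~at[partners % band.grid.n_bins]
        vals = band.r[keep, col]
        out.append(vals[np.isfinite(vals)])
    return np.concatenate(out) if out else np.empty(0)


@dataclass
class SubsetCorrelations:
    regulator: str
    distributions: dict[str, np.ndarray]  # At / Between / Random / Without
    random_reps: int
    summary: pd.DataFrame  # subset, mean, n [, p_vs_at]

    def mean(self, subset: str) -> float:
        return float(np.mean(self.distributions[subset]))


def subset_distributions(
    band: CorrelationBand,
    targets: RegulatorTargets,
    grid: BinGrid,
    n_random: int = 100,
    seed: int = 0,
) -> SubsetCorrelations:
    """Correlation-coefficient distributions of the four subsets for one
    regulator, plus a two-sided rank-sum comparison of At against each of
    the others."""
    rng = np.random.default_rng(seed)
    at_bins = targets.at_bins
    if len(at_bins) < 2:
        raise ValueError("At subset has fewer than 2 bins")
    mock = RegulatorTargets.from_positions(
        targets.regulator, between_sites(targets, grid), grid, targets.flank
    )
    dists: dict[str, np.ndarray] = {
        "At": _band_pairs_r(band, at_bins),
        "Between": _band_pairs_r(band, mock.at_bins),
    }
    unmasked = np.flatnonzero(~band.mask)
    pools = []
    for _ in range(n_random):
        draw = rng.choice(unmasked, size=len(at_bins), replace=False)
        pools.append(_band_pairs_r(band, draw))
    dists["Random"] = np.concatenate(pools) if pools else np.empty(0)
    dists["Without"] = _without_pairs_r(band, at_bins)

    rows = []
    for name, vals in dists.items():
        row = {"subset": name, "mean": float(np.mean(vals)) if vals.size else np.nan, "n": vals.size}
        if name != "At" and vals.size and dists["At"].size:
            row["p_vs_at"] = float(
                stats.mannwhitneyu(dists["At"], vals, alternative="two-sided").pvalue
            )
        rows.append(row)
    return SubsetCorrelations(
        regulator=targets.regulator,
        distributions=dists,
        random_reps=n_random,
        summary=pd.DataFrame(rows),
    )


def exclusion_reprofile(
    band: CorrelationBand,
    region: tuple[int, int],
    at_bins: np.ndarray,
    config: ScanConfig = ScanConfig(),
    min_surviving_bins: int = 8,
) -> dict:
    """Averaged profile + periodogram of a region with and without the
    regulator-associated bins; reports the change in peak period and PNmax.

    If the periodic signal is carried by the excluded bins, the pattern
    (and its PNmax) should collapse; if not, it should be unchanged."""
    before_profile = average_profiles(band, region)
    starts = band.grid.bin_starts
    s, e = region
    in_region = (starts >= s) & (starts < e) if e >= s else (starts >= s) | (starts < e)
    surviving = in_region & ~band.mask
    surviving[np.asarray(at_bins, dtype=int)] = False
    if surviving.sum() < min_surviving_bins:
        raise ValueError(
            f"only {int(surviving.sum())} bins survive exclusion; need >= {min_surviving_bins}"
        )
    after_profile = average_profiles(band, region, exclude_bins=at_bins)
    before = lomb_scargle(before_profile, config)
    after = lomb_scargle(after_profile, config)
    return {
        "profile_before": before_profile,
        "profile_after": after_profile,
        "periodogram_before": before,
        "periodogram_after": after,
        "delta_peak_period": after.peak_period - before.peak_period,
        "delta_pnmax": after.pnmax - before.pnmax,
    }
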