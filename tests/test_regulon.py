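from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import cpedscan as cs
from cpedscan.regulon import RegulatorTargets, _band_pairs_r, _without_pairs_r
from conftest import random_matrix

GRID = cs.BinGrid(100_000, 500, 500, circular=True)


class TestParseTargets:
    def write(self, tmp_path, rows, columns=("regulator", "target_position")):
        path = tmp_path / "targets.tsv"
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)
        return path

    def test_threshold_is_strictly_greater_than_20(self, tmp_path):
        # mid-bin targets cover 3 bins each: 7 targets -> 21 bins (kept),
        # 6 targets -> 18 bins (dropped: the rule is strictly more than 20)
        keep = [("big", 250 + 5_000 * k) for k in range(7)]
        drop = [("small", 60_250 + 5_000 * k) for k in range(6)]
        path = self.write(tmp_path, keep + drop)
        out = cs.parse_targets(path, None, GRID, flank=500)
        assert [t.regulator for t in out] == ["big"]
        assert len(out[0].at_bins) == 21

    def test_overlapping_flanks_count_bins_once(self):
        rt = RegulatorTargets.from_positions("r", [10_000, 10_100], GRID, flank=500)
        # [9500,10500) and [9600,10600) overlap; union covers bins 19-21 once
        assert rt.at_bins.tolist() == [19, 20, 21]

    def test_gene_names_resolved_at_tss(self, tmp_path):
        genes = pd.DataFrame(
            [
                {"gene_id": "g1", "name": "araC", "start": 30_000, "end": 31_000, "strand": "+"},
                {"gene_id": "g2", "name": "lacZ", "start": 50_000, "end": 52_000, "strand": "-"},
            ]
        )
        path = self.write(
            tmp_path,
            [("tf", "araC"), ("tf", "lacZ"), ("tf", "missing")],
            columns=("regulator", "target_gene"),
        )
        out = cs.parse_targets(path, genes, GRID, flank=500, min_bins=0)
        assert sorted(out[0].targets.tolist()) == [30_000, 51_999]  # 5' ends

    def test_nothing_resolvable_is_error(self, tmp_path):
        path = self.write(tmp_path, [("tf", "ghost")], columns=("regulator", "target_gene"))
        with pytest.raises(ValueError, match="no regulator target"):
            cs.parse_targets(path, pd.DataFrame(columns=["gene_id", "name", "start", "end", "strand"]), GRID)


class TestBetweenSites:
    def test_circular_midpoints(self):
        grid = cs.BinGrid(10_000, 500, 500)
        rt = RegulatorTargets.from_positions("r", [1_000, 3_000], grid, flank=500)
        assert sorted(cs.between_sites(rt, grid).tolist()) == [2_000, 7_000]

    def test_equally_spaced_sites_shift_half_spacing(self):
        grid = cs.BinGrid(100_000, 500, 500)
        sites = list(range(0, 100_000, 20_000))
        rt = RegulatorTargets.from_positions("r", sites, grid, flank=500)
        mocks = sorted(cs.between_sites(rt, grid).tolist())
        assert mocks == [s + 10_000 for s in sites]

    def test_cardinality_preserved(self):
        rng = np.random.default_rng(5)
        sites = rng.choice(100_000, size=9, replace=False)
        rt = RegulatorTargets.from_positions("r", sites, GRID, flank=500)
        assert len(cs.between_sites(rt, GRID)) == len(rt.targets)

    def test_rotation_equivariance(self):
        grid = cs.BinGrid(100_000, 500, 500)
        sites = [4_000, 20_000, 57_000, 90_000]
        delta = 12_345
        rt = RegulatorTargets.from_positions("r", sites, grid, flank=500)
        rt2 = RegulatorTargets.from_positions(
            "r", [(s + delta) % 100_000 for s in sites], grid, flank=500
        )
        a = set((m + delta) % 100_000 for m in cs.between_sites(rt, grid))
        assert a == set(int(m) for m in cs.between_sites(rt2, grid))


class TestSubsetDistributions:
    def test_partition_exhaustive(self):
        matrix = random_matrix(n_bins=40, seed=1)
        band = cs.correlation_band(matrix, 5_000)
        at_bins = np.array([3, 9, 15, 21])
        n_at = len(_band_pairs_r(band, at_bins))
        n_without = len(_without_pairs_r(band, at_bins))
        touching = 0
        at = set(at_bins.tolist())
        for col, lag in enumerate(band.lags):
            if lag <= 0:
                continue
            for i in range(40):
                j = (i + lag // 500) % 40
                if np.isfinite(band.r[i, col]) and (i in at or j in at):
                    touching += 1
        total = np.isfinite(band.r[:, band.lags > 0]).sum()
        assert n_without + touching == total
        assert n_at <= touching

    def test_anchored_regulator_beats_random(self, small_bundle):
        band = cs.correlation_band(small_bundle.expression_matrix(), 40_000)
        rt = RegulatorTargets.from_positions(
            "RegA", small_bundle.truth.regulators["RegA"], small_bundle.grid, flank=500
        )
        sc = cs.subset_distributions(band, rt, small_bundle.grid, n_random=50, seed=3)
        assert sc.mean("At") > sc.mean("Random")
        assert sc.mean("At") > sc.mean("Without")

    def test_uniform_regulator_within_random_spread(self, small_bundle):
        band = cs.correlation_band(small_bundle.expression_matrix(), 40_000)
        rng = np.random.default_rng(11)
        rt = RegulatorTargets.from_positions(
            "null", rng.integers(0, 100_000, 5), small_bundle.grid, flank=500
        )
        sc = cs.subset_distributions(band, rt, small_bundle.grid, n_random=200, seed=4)
        # mean(At) of a random regulator behaves like one more random draw
        unmasked = np.flatnonzero(~band.mask)
        means = []
        for _ in range(200):
            draw = rng.choice(unmasked, size=len(rt.at_bins), replace=False)
            means.append(np.mean(_band_pairs_r(band, draw)))
        lo, hi = np.quantile(means, [0.025, 0.975])
        assert lo <= sc.mean("At") <= hi

    def test_random_draws_seed_deterministic(self, small_bundle):
        band = cs.correlation_band(small_bundle.expression_matrix(), 40_000)
        rt = RegulatorTargets.from_positions(
            "RegA", small_bundle.truth.regulators["RegA"], small_bundle.grid, flank=500
        )
        a = cs.subset_distributions(band, rt, small_bundle.grid, n_random=10, seed=9)
        b = cs.subset_distributions(band, rt, small_bundle.grid, n_random=10, seed=9)
        np.testing.assert_array_equal(a.distributions["Random"], b.distributions["Random"])


class TestExclusionReprofile:
    CFG = cs.ScanConfig(window=100_000, slide=5_000, period_min=10_000,
                        period_max=35_000, max_lag=40_000)

    @staticmethod
    def spiky_matrix(seed=2):
        """Periodicity carried entirely by a known bin set: bins around each
        20 kbp anchor share one phase-varying signal, all others are iid
        noise. Returns (matrix, anchor_bin_indices)."""
        rng = np.random.default_rng(seed)
        grid = cs.BinGrid(200_000, 500, 500, circular=True)
        values = rng.standard_normal((grid.n_bins, 5))
        f = rng.standard_normal(5) * 3
        anchor_bins = []
        for a in range(0, 200_000, 20_000):
            for off in range(-2, 3):
                b = (a // 500 + off) % grid.n_bins
                anchor_bins.append(b)
                values[b] = f + rng.standard_normal(5) * 0.1
        matrix = cs.ExpressionMatrix(
            grid, values + 10.0, np.zeros(grid.n_bins, bool), list("abcde")
        )
        return matrix, np.unique(anchor_bins)

    def test_excluding_nothing_is_identity(self, small_bundle, small_config):
        band = cs.correlation_band(small_bundle.expression_matrix(), 40_000)
        out = cs.exclusion_reprofile(band, (0, 100_000), np.array([], dtype=int),
                                     small_config)
        np.testing.assert_allclose(
            out["profile_before"].mean_r, out["profile_after"].mean_r, equal_nan=True
        )
        assert out["delta_pnmax"] == 0.0

    def test_exclusion_destroys_carried_periodicity(self):
        matrix, anchors = self.spiky_matrix()
        band = cs.correlation_band(matrix, 40_000)
        out = cs.exclusion_reprofile(band, (0, 200_000), anchors, self.CFG)
        assert out["periodogram_before"].pnmax > 3
        assert out["periodogram_after"].pnmax < 3

    def test_exclusion_spares_independent_periodicity(self, small_bundle, small_config):
        # cosine plant is carried by every bin; dropping anchor bins is harmless
        band = cs.correlation_band(small_bundle.expression_matrix(), 40_000)
        anchors = np.concatenate(
            [small_bundle.grid.bins_overlapping(a - 500, a + 500)
             for a in range(0, 100_000, 20_000)]
        )
        out = cs.exclusion_reprofile(band, (0, 100_000), anchors, small_config)
        span = 39_500 - 500
        one_step = 20_000**2 / (4 * span)
        assert abs(out["delta_peak_period"]) <= one_step
        assert out["periodogram_after"].pnmax > 3

    def test_too_few_survivors_is_error(self, small_bundle, small_config):
        band = cs.correlation_band(small_bundle.expression_matrix(), 40_000)
        with pytest.raises(ValueError, match="survive"):
            cs.exclusion_reprofile(band, (0, 5_000), np.arange(10), small_config)
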