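from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cpedscan as cs
from conftest import random_matrix


class TestRebinExpression:
    def fine_matrix(self, n_bins=20, masked=()):
        import pandas as pd

        grid = cs.BinGrid(n_bins * 500, 500, 500)
        rng = np.random.default_rng(1)
        raw = rng.integers(1, 50, size=(n_bins, 4)).astype(float)
        mask = np.zeros(n_bins, bool)
        mask[list(masked)] = True
        design = pd.DataFrame(
            {"sample": ["a1", "a2", "b1", "b2"], "phase": ["a", "a", "b", "b"],
             "replicate": [1, 2, 1, 2]}
        )
        return cs.normalize_and_average(raw, mask, design, grid)

    def test_counts_summed(self):
        m = self.fine_matrix()
        coarse = cs.rebin_expression(m, 5_000)
        expected = m.raw_counts.reshape(2, 10, -1).sum(axis=1)
        np.testing.assert_allclose(coarse.raw_counts, expected)

    def test_mask_propagates(self):
        coarse = cs.rebin_expression(self.fine_matrix(masked=(3,)), 5_000)
        assert coarse.mask.tolist() == [True, False]
        assert np.all(np.isnan(coarse.values[0]))

    def test_rebin_to_source_width_is_identity(self):
        m = self.fine_matrix()
        assert cs.rebin_expression(m, 500) is m

    def test_non_multiple_width_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            cs.rebin_expression(self.fine_matrix(), 750)

    def test_normalization_reapplied(self):
        coarse = cs.rebin_expression(self.fine_matrix(), 5_000)
        np.testing.assert_allclose(np.nansum(coarse.values, axis=0), 1e6, rtol=1e-9)


def make_assoc(n_bins=60, seed=4, min_dist=20_000, coupled=False):
    if coupled:
        truth = cs.make_truth(n_bins * 5_000, 1, [50_000], seed=seed)
        bundle = cs.simulate_expression(truth, bin_width=5_000, noise_sd=0.2, seed=seed)
        expr = bundle.expression_matrix()
        contacts = cs.simulate_contacts(truth, 5_000, decay_exponent=1.0,
                                        coupling_boost=5.0, seed=seed)
    else:
        expr = random_matrix(n_bins=n_bins, step=5_000, seed=seed)
        truth = cs.SyntheticTruth(n_bins * 5_000, [], [], [], {}, factor_seed=seed)
        contacts = cs.simulate_contacts(truth, 5_000, decay_exponent=1.0,
                                        coupling_boost=1.0, seed=seed)
    return expr, contacts, cs.build_pairs(expr, contacts, min_dist)


class TestBuildPairs:
    def test_strict_distance_exclusion(self):
        expr, contacts, assoc = make_assoc()
        assert (assoc.pairs["distance"] > 20_000).all()
        # a pair at exactly 20,000 bp must be excluded
        d = expr.grid.circular_distance(
            assoc.pairs["bin_i"].to_numpy(), assoc.pairs["bin_j"].to_numpy()
        )
        assert not np.any(d == 20_000)

    def test_pair_count_bound_and_uniqueness(self):
        expr, _, assoc = make_assoc(n_bins=60)
        assert len(assoc.pairs) <= 60 * 59 // 2
        keys = set(zip(assoc.pairs["bin_i"], assoc.pairs["bin_j"]))
        assert len(keys) == len(assoc.pairs)
        assert (assoc.pairs["bin_i"] < assoc.pairs["bin_j"]).all()

    def test_matches_brute_force_enumeration(self):
        expr, contacts, assoc = make_assoc(n_bins=30, seed=7)
        got = set(zip(assoc.pairs["bin_i"], assoc.pairs["bin_j"]))
        expected = set()
        for i, j in combinations(range(30), 2):
            d = abs(int(expr.grid.signed_lag(i, j)))
            if d > 20_000 and contacts.freq[i, j] > 0:
                expected.add((i, j))
        assert got == expected
        # and the correlations match pairwise scipy on the same rows
        for _, row in assoc.pairs.head(20).iterrows():
            i, j = int(row.bin_i), int(row.bin_j)
            ref = stats.pearsonr(expr.values[i], expr.values[j]).statistic
            assert row.r == pytest.approx(ref, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        expr, contacts, _ = make_assoc()
        other = random_matrix(n_bins=40, step=5_000, seed=1)
        with pytest.raises(ValueError, match="grid"):
            cs.build_pairs(other, contacts, 20_000)


class TestGroupAndTest:
    def test_ranksum_matches_exact_enumeration(self):
        """Two-sided rank-sum p for {1,2,3} vs {4,5,6} by brute force over
        all C(6,3)=20 rank assignments is 0.1."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
            1 for a in x for b in y if a == b
        )
        pooled = x + y
        stats_all = []
        for idx in combinations(range(6), 3):
            xs = [pooled[k] for k in idx]
            ys = [pooled[k] for k in range(6) if k not in idx]
            u = sum(1 for a in xs for b in ys if a > b)
            stats_all.append(u)
        mu = len(x) * len(y) / 2
        p_exact = np.mean([abs(u - mu) >= abs(u_obs - mu) for u in stats_all])
        assert p_exact == pytest.approx(0.1)
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p_scipy == pytest.approx(p_exact, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ranksum_oracle_random_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(3, 8)).round(2).tolist()
        y = rng.normal(size=rng.integers(3, 8)).round(2).tolist()
        pooled = np.array(x + y)
        nx = len(x)
        u_obs = sum(1 for a in x for b in y if a > b) + 0.5 * sum(
            1 for a in x for b in y if a == b
        )
        mu = nx * len(y) / 2
        devs = []
        for idx in combinations(range(len(pooled)), nx):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            u = sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
                1 for a in xs for b in ys if a == b
            )
            devs.append(abs(u - mu) >= abs(u_obs - mu) - 1e-12)
        p_exact = np.mean(devs)
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        if len(set(x + y)) == len(x + y):  # scipy exact assumes no ties
            assert p_scipy == pytest.approx(p_exact, rel=1e-9)

    def test_group_membership_monotone_in_contact(self):
        _, _, assoc = make_assoc(coupled=True)
        assoc = cs.group_and_test(assoc, n_groups=8)
        g = assoc.pairs.sort_values("contact")["group"].to_numpy()
        assert np.all(np.diff(g) >= 0)

    def test_same_pairs_for_8_and_21_groups(self):
        _, _, assoc = make_assoc(coupled=True)
        a8 = cs.group_and_test(assoc, n_groups=8)
        pairs8 = a8.pairs[["bin_i", "bin_j"]].copy()
        a21 = cs.group_and_test(assoc, n_groups=21)
        pd.testing.assert_frame_equal(pairs8, a21.pairs[["bin_i", "bin_j"]])

    def test_coupled_data_non_decreasing_group_means(self):
        _, _, assoc = make_assoc(coupled=True, n_bins=100)
        assoc = cs.group_and_test(assoc, n_groups=8)
        means = assoc.group_summary["mean_r"].to_numpy()
        assert np.all(np.diff(means) >= -0.02)  # monotone up to group noise
        assert means[-1] > means[0] + 0.2

    def test_null_coupling_no_trend(self):
        # with boost = 1 contacts are pure distance decay: correlation must
        # show no systematic increase across contact groups (individual
        # rank-sum p-values are anti-conservative here because pairs share
        # bins, so the null property is the absence of a trend)
        _, _, assoc = make_assoc(coupled=False)
        assoc = cs.group_and_test(assoc, n_groups=8)
        means = assoc.group_summary["mean_r"].to_numpy()
        assert abs(means[-1] - means[0]) < 0.1
        rho, p = stats.spearmanr(np.arange(len(means)), means)
        assert p > 0.05

    def test_all_equal_contacts_single_group(self):
        expr = random_matrix(n_bins=30, step=5_000, seed=2)
        freq = np.ones((30, 30)); np.fill_diagonal(freq, 0)
        contacts = cs.ContactMatrix(expr.grid, freq)
        assoc = cs.group_and_test(cs.build_pairs(expr, contacts, 20_000), n_groups=8)
        assert assoc.n_groups == 1
        assert len(assoc.tests) == 0


class TestContactMatrix:
    def test_simulated_contacts_symmetric_nonnegative(self, small_truth):
        cm = cs.simulate_contacts(small_truth, 5_000, seed=3, noise_sd=0.1)
        np.testing.assert_allclose(cm.freq, cm.freq.T)
        assert (cm.freq >= 0).all()

    def test_decay_exponent_contract(self, small_truth):
        with pytest.raises(ValueError, match="decay_exponent"):
            cs.simulate_contacts(small_truth, 5_000, decay_exponent=0.0)

    def test_coo_round_trip(self, small_truth, tmp_path):
        cm = cs.simulate_contacts(small_truth, 5_000, seed=3)
        path = tmp_path / "contacts.tsv"
        cm.to_coo_tsv(path)
        back = cs.ContactMatrix.from_coo_tsv(path, cm.grid)
        np.testing.assert_array_equal(back.freq, cm.freq)
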