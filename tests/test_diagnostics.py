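"""Heterogeneity, influence, stability and enrichment diagnostics."""

import itertools
import math

import numpy as np
import pytest

from lipidmr import pvalues
from lipidmr.diagnostics import (
    bonferroni_threshold,
    cochran_q,
    cooks_distances,
    count_significant,
    leave_subset_out,
    qq_statistics,
)
from lipidmr.summary_data import HarmonizedSet, harmonize
from lipidmr.synthetic import SyntheticTruth, generate_two_sample
from lipidmr.univariable import ivw
from lipidmr.datasets import table1


def make_hset(bx, by, sy, sx=None):
    J = len(bx)
    sx = sx if sx is not None else [0.01] * J
    return HarmonizedSet(
        variant_ids=[f"rs{j}" for j in range(J)],
        exposure_names=["e"],
        bx=np.asarray(bx, float)[:, None],
        sx=np.asarray(sx, float)[:, None],
        by=np.asarray(by, float),
        sy=np.asarray(sy, float),
        orientation_flags=np.zeros(J, bool),
    )


class TestCochranQ:
    def test_perfect_fit(self):
        bx = np.array([0.1, 0.2, 0.3])
        q, df, p = cochran_q((bx, None, 0.4 * bx, np.full(3, 0.02)), 0.4)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 2 and p == pytest.approx(1.0)

    def test_hand_computed_toy(self, ivw_toy):
        bx, sx, by, sy = ivw_toy
        theta = ivw((bx, sx, by, sy)).theta
        q, df, p = cochran_q((bx, sx, by, sy), theta)
        assert q == pytest.approx(2.8035714286, abs=1e-9)
        assert df == 2

    def test_q_minimized_at_ivw_estimate(self, random_toys):
        for bx, sx, by, sy in random_toys[:10]:
            theta_hat = ivw((bx, sx, by, sy)).theta
            q_hat, _, _ = cochran_q((bx, sx, by, sy), theta_hat)
            for t in np.linspace(theta_hat - 0.5, theta_hat + 0.5, 41):
                q_t, _, _ = cochran_q((bx, sx, by, sy), t)
                assert q_t >= q_hat - 1e-12


class TestCooks:
    def test_collinear_data_all_zero(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        d, flagged = cooks_distances((bx, None, 0.5 * bx, np.full(4, 0.02)))
        np.testing.assert_allclose(d, 0.0, atol=1e-20)
        assert flagged == []

    def test_displaced_variant_has_maximum_distance(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.5 * bx
        by[2] += 0.3
        d, flagged = cooks_distances((bx, None, by, np.full(5, 0.02)))
        assert d.argmax() == 2
        assert 2 in flagged

    @pytest.mark.parametrize("model,k", [("ivw", 1), ("egger", 2)])
    def test_matches_leave_one_out_oracle(self, model, k):
        """D_j = sum_i w_i (fit_i - fit_i(-j))^2 / (k s^2), via explicit refits."""
        rng = np.random.default_rng(21)
        bx = rng.normal(0.15, 0.05, 9)
        by = 0.4 * bx + rng.normal(0, 0.03, 9)
        sy = rng.uniform(0.01, 0.04, 9)
        w = sy ** -2.0
        flip = np.sign(bx)

        def fit(idx):
            if model == "ivw":
                th = np.sum(w[idx] * bx[idx] * by[idx]) / np.sum(w[idx] * bx[idx] ** 2)
                return th * bx  # fitted values for ALL points
            X = np.column_stack([np.ones(9), flip * bx])
            yy = flip * by
            Xi, yi, wi = X[idx], yy[idx], w[idx]
            beta = np.linalg.solve(Xi.T @ (wi[:, None] * Xi), Xi.T @ (wi * yi))
            return flip * (X @ beta)

        full_idx = np.arange(9)
        fit_full = fit(full_idx)
        resid = by - fit_full
        s2 = np.sum(w * resid ** 2) / (9 - k)
        oracle = np.empty(9)
        for j in range(9):
            fit_j = fit(np.delete(full_idx, j))
            oracle[j] = np.sum(w * (fit_full - fit_j) ** 2) / (k * s2)
        d, _ = cooks_distances((bx, None, by, sy), model=model)
        np.testing.assert_allclose(d, oracle, rtol=1e-9, atol=1e-12)


class TestLeaveSubsetOut:
    def test_all_positive_ratios_give_100_percent(self):
        hs = make_hset([0.1, 0.2, 0.3, 0.4], [0.05, 0.1, 0.15, 0.2],
                       [0.02] * 4)
        res = leave_subset_out(hs, fraction=0.3, n_iterations=50, seed=0)
        assert res.proportion_positive == 1.0

    def test_fraction_zero_returns_full_sample_estimate(self):
        truth = SyntheticTruth(J=20, seed=2)
        exps, out, _ = generate_two_sample(truth)
        hs = harmonize(exps, out)
        full = ivw(hs).theta
        res = leave_subset_out(hs, fraction=0.0, n_iterations=10, seed=0)
        np.testing.assert_allclose(res.estimates, full)

    def test_matches_exhaustive_enumeration_on_small_set(self):
        """J = 8, fraction 0.3 -> 2 removed; enumerate all C(8,2) subsets."""
        rng = np.random.default_rng(17)
        bx = rng.normal(0.2, 0.05, 8)
        by = 0.5 * bx + rng.normal(0, 0.15, 8)  # noisy: sign varies by subset
        sy = np.full(8, 0.05)
        hs = make_hset(bx, by, sy)
        exact = np.mean([
            ivw(hs.subset(np.setdiff1d(np.arange(8), list(drop)))).theta > 0
            for drop in itertools.combinations(range(8), 2)
        ])
        res = leave_subset_out(hs, fraction=0.3, n_iterations=4000, seed=5)
        assert res.n_removed == 2
        mc_se = math.sqrt(exact * (1 - exact) / 4000) if 0 < exact < 1 else 0.01
        assert abs(res.proportion_positive - exact) < 4 * mc_se + 0.01


class TestQQ:
    def test_unit_chi_square_point(self):
        df = qq_statistics([math.log10(0.3173)])
        assert df["observed"].iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_both_coordinates(self):
        rng = np.random.default_rng(4)
        lp = np.log10(rng.uniform(1e-12, 1, 200))
        df = qq_statistics(lp)
        assert (np.diff(df["expected"]) >= 0).all()
        assert (np.diff(df["observed"]) >= 0).all()

    def test_uniform_null_hugs_diagonal(self):
        rng = np.random.default_rng(6)
        lp = np.log10(rng.uniform(size=1000))
        df = qq_statistics(lp)
        # exclude the extreme tail where order statistics are noisy
        body = df.iloc[:990]
        assert np.max(np.abs(body["observed"] - body["expected"])) < 1.0

    def test_single_extreme_point_tops_the_plot(self):
        lp = list(np.log10(np.linspace(0.2, 0.9, 20))) + [-30.0]
        df = qq_statistics(lp)
        assert df["observed"].iloc[-1] > 100
        assert df["observed"].iloc[-1] > df["expected"].iloc[-1] + 50


class TestCounting:
    def test_printed_amd_pvalues_at_genome_wide(self):
        t1 = table1()
        amd = t1[t1["trait"] == "amd"]["log10_p"].tolist()
        counts = count_significant(amd, [5e-8, 0.05 / 182])
        assert counts[5e-8] == 3
        assert counts[0.05 / 182] == 9

    def test_threshold_one_counts_everything(self):
        lp = [-0.1, -1.0, -5.0]
        assert count_significant(lp, [1.0])[1.0] == 3

    def test_matches_direct_loop(self):
        rng = np.random.default_rng(9)
        lp = np.log10(rng.uniform(size=300))
        for thr in (0.001, 0.05):
            expected = sum(1 for v in lp if 10 ** v < thr)
            assert count_significant(lp, [thr])[thr] == expected

    def test_bonferroni_helper(self):
        assert bonferroni_threshold(0.05, 182) == pytest.approx(0.05 / 182)
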