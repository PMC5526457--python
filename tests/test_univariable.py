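"""Wald ratio, IVW, MR-Egger and weighted-median estimators."""

import numpy as np
import pytest
import statsmodels.api as sm

from lipidmr.univariable import (
    _weighted_median,
    egger,
    ivw,
    wald_ratio,
    weighted_median,
)


def rank_walk_median(ratios, weights):
    """Independent weighted-median oracle: explicit cumulative rank walk."""
    pairs = sorted(zip(ratios, weights), key=lambda t: t[0])
    total = sum(w for _, w in pairs)
    cum = 0.0
    pk = []
    for r, w in pairs:
        pk.append((cum + w / 2) / total)
        cum += w
    if 0.5 <= pk[0]:
        return pairs[0][0]
    if 0.5 >= pk[-1]:
        return pairs[-1][0]
    for i in range(len(pairs) - 1):
        if pk[i] <= 0.5 <= pk[i + 1]:
            frac = (0.5 - pk[i]) / (pk[i + 1] - pk[i])
            return pairs[i][0] + frac * (pairs[i + 1][0] - pairs[i][0])
    raise AssertionError("unreachable")


class TestWald:
    def test_zero_numerator(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.02).theta == 0.0

    def test_printed_cetp_variant(self):
        """HDL beta 0.147, AMD beta 0.109 (se from p = 3e-10)."""
        est = wald_ratio(0.147, None, 0.109, 0.017305)
        assert est.theta == pytest.approx(0.74150, abs=1e-4)
        assert est.se == pytest.approx(0.11772, abs=1e-4)
        assert est.odds_ratio[0] == pytest.approx(2.099, abs=0.005)

    def test_homogeneity_in_outcome_scale(self):
        a = wald_ratio(0.2, 0.01, 0.1, 0.02)
        b = wald_ratio(0.2, 0.01, 0.3, 0.06)
        assert b.theta == pytest.approx(3 * a.theta)
        assert b.se == pytest.approx(3 * a.se)

    def test_zero_denominator_errors(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_hand_computed_toy(self, ivw_toy):
        bx, sx, by, sy = ivw_toy
        est = ivw((bx, sx, by, sy), effects="fixed")
        assert est.theta == pytest.approx(0.5357142857, abs=1e-9)
        assert est.se == pytest.approx(0.0534522484, abs=1e-9)
        assert est.q_statistic == pytest.approx(2.8035714286, abs=1e-9)
        assert est.phi == pytest.approx(1.4017857143, abs=1e-9)

    def test_single_variant_reduces_to_wald(self):
        est = ivw(([0.15], [0.01], [0.09], [0.02]))
        ref = wald_ratio(0.15, 0.01, 0.09, 0.02)
        assert est.theta == pytest.approx(ref.theta, abs=1e-14)
        assert est.se == pytest.approx(ref.se, abs=1e-14)

    def test_perfect_fit(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = ivw((bx, bx * 0.1, 0.4 * bx, np.full(3, 0.03)))
        assert est.theta == pytest.approx(0.4, abs=1e-14)
        assert est.q_statistic == pytest.approx(0.0, abs=1e-20)
        assert est.phi == 1.0

    def test_random_effects_se_never_below_fixed(self, random_toys):
        for toy in random_toys:
            assert ivw(toy, "random").se >= ivw(toy, "fixed").se - 1e-15

    def test_matches_wls_oracle(self, random_toys):
        """Zero-intercept WLS via statsmodels agrees to 1e-10."""
        for bx, sx, by, sy in random_toys:
            fit = sm.WLS(by, bx, weights=sy ** -2.0).fit()
            est = ivw((bx, sx, by, sy))
            assert est.theta == pytest.approx(fit.params[0], abs=1e-10)
            # statsmodels scales by the residual mean square (no floor)
            se_fixed = float(fit.bse[0]) / np.sqrt(fit.scale)
            q = fit.scale * fit.df_resid
            assert est.q_statistic == pytest.approx(q, rel=1e-10)
            se_expected = se_fixed * np.sqrt(max(1.0, q / fit.df_resid))
            assert est.se == pytest.approx(se_expected, rel=1e-10)

    def test_invariance_to_reordering(self, ivw_toy):
        bx, sx, by, sy = ivw_toy
        perm = [2, 0, 1]
        a = ivw((bx, sx, by, sy))
        b = ivw((bx[perm], sx[perm], by[perm], sy[perm]))
        assert a.theta == pytest.approx(b.theta, abs=1e-14)


class TestEgger:
    def test_exact_affine_data(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.02 + 0.5 * bx
        est = egger((bx, bx * 0 + 0.01, by, np.full(3, 0.02)))
        assert est.theta == pytest.approx(0.5, abs=1e-12)
        assert est.intercept == pytest.approx(0.02, abs=1e-12)
        assert est.q_statistic == pytest.approx(0.0, abs=1e-20)

    def test_pre_flipped_row_gives_identical_output(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.02 + 0.5 * bx
        sy = np.full(3, 0.02)
        base = egger((bx, None, by, sy))
        bx2, by2 = bx.copy(), by.copy()
        bx2[1], by2[1] = -bx2[1], -by2[1]
        flipped = egger((bx2, None, by2, sy))
        assert flipped.theta == pytest.approx(base.theta, abs=1e-14)
        assert flipped.intercept == pytest.approx(base.intercept, abs=1e-14)

    def test_too_few_variants(self):
        with pytest.raises(ValueError, match="at least 3"):
            egger(([0.1, 0.2], None, [0.1, 0.1], [0.01, 0.01]))

    def test_matches_wls_oracle(self, random_toys):
        for bx, sx, by, sy in random_toys:
            flip = np.sign(bx)
            X = sm.add_constant(bx * flip)
            fit = sm.WLS(by * flip, X, weights=sy ** -2.0).fit()
            est = egger((bx, sx, by, sy))
            assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert est.theta == pytest.approx(fit.params[1], abs=1e-10)
            scale = max(1.0, fit.scale)
            assert est.se == pytest.approx(
                float(fit.bse[1]) / np.sqrt(fit.scale) * np.sqrt(scale), rel=1e-9
            )


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        ratios = np.array([0.4, 0.5, 0.6, 0.7, 0.8])
        assert _weighted_median(ratios, np.ones(5)) == pytest.approx(0.6)

    def test_hand_interpolated_toy(self, ivw_toy):
        bx, sx, by, sy = ivw_toy
        # ratios (0.5, 0.4, 0.6), weights (25, 100, 225)/350 -> estimate 0.55
        est = weighted_median((bx, sx, by, sy), n_boot=200, seed=0)
        assert est.theta == pytest.approx(0.55, abs=1e-12)

    def test_degenerate_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = 0.3 * bx
        est = weighted_median((bx, np.full(3, 1e-6), by, np.full(3, 0.01)),
                              n_boot=200, seed=1)
        assert est.theta == pytest.approx(0.3, abs=1e-12)
        assert est.se < 0.05

    def test_matches_rank_walk_oracle(self, random_toys):
        for bx, sx, by, sy in random_toys:
            small = slice(0, 7)
            bx, sx, by, sy = bx[small], sx[small], by[small], sy[small]
            ratios = by / bx
            weights = (bx / sy) ** 2
            assert _weighted_median(ratios, weights) == pytest.approx(
                rank_walk_median(list(ratios), list(weights)), abs=1e-12
            )

    def test_bootstrap_seed_reproducible(self, ivw_toy):
        a = weighted_median(ivw_toy, n_boot=200, seed=42)
        b = weighted_median(ivw_toy, n_boot=200, seed=42)
        assert a.se == b.se


class TestEstimateContainer:
    def test_ci_brackets_theta_and_or_scale_consistent(self, random_toys):
        for toy in random_toys[:20]:
            est = ivw(toy)
            assert est.ci_low < est.theta < est.ci_high
            orr, lo, hi = est.odds_ratio
            assert lo == pytest.approx(np.exp(est.ci_low))
            assert hi == pytest.approx(np.exp(est.ci_high))
            assert 0.0 <= est.p <= 1.0
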