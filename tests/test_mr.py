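"""Causal estimators: Wald ratio, IVW, Egger, medians, mode, OR transforms."""

import numpy as np
import pytest
from scipy import stats

from mrcoloc import (
    DomainError,
    HarmonizedSet,
    InsufficientInstrumentsError,
    ivw,
    mr_egger,
    run_all_methods,
    simple_median,
    to_odds_ratio,
    wald_p_from_or_ci,
    wald_ratio,
    weighted_median,
    weighted_mode,
)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,beta,se",
        [
            (1.0, 0.5, 0.1, 0.5, 0.1),     # unit denominator
            (0.2, 0.05, 0.02, 0.25, 0.1),  # hand arithmetic
        ],
    )
    def test_point_and_se(self, bx, by, sy, beta, se):
        est = wald_ratio(bx, 0.01, by, sy)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_null_outcome_effect(self):
        est = wald_ratio(1.0, 0.01, 0.0, 0.1)
        assert est.beta == 0.0
        assert est.pvalue == 1.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(DomainError):
            wald_ratio(0.0, 0.01, 0.1, 0.1)


class TestIvw:
    def test_single_pair_equals_wald_ratio(self):
        hs = HarmonizedSet.from_arrays([0.2], [0.01], [0.05], [0.02])
        est = ivw(hs)
        ref = wald_ratio(0.2, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)
        assert est.n_snps == 1

    def test_homogeneous_ratios_fixed_equals_random(self):
        hs = HarmonizedSet.from_arrays(
            [1.0, 2.0, 0.5], [0.01] * 3, [0.3, 0.6, 0.15], [0.1, 0.2, 0.05]
        )
        fixed = ivw(hs, mode="fixed")
        random = ivw(hs, mode="random_multiplicative")
        assert fixed.beta == pytest.approx(0.3)
        assert random.beta == pytest.approx(0.3)
        assert fixed.se == pytest.approx(random.se)  # Q = 0, no inflation

    def test_three_pair_weighted_mean_long_hand(self, three_pair_set):
        # ratios (.2,.3,.5), ratio ses (.1,.2,.1) -> w = (100,25,100)
        # beta = (100*.2 + 25*.3 + 100*.5)/225 = 77.5/225
        est = ivw(three_pair_set, mode="fixed")
        assert est.beta == pytest.approx(77.5 / 225, rel=1e-12)
        assert est.se == pytest.approx(225**-0.5, rel=1e-12)

    def test_random_mode_inflates_by_q_over_df(self, three_pair_set):
        # Q = 41/9 (see sensitivity tests), df = 2
        est = ivw(three_pair_set, mode="random_multiplicative")
        expected = (225**-0.5) * np.sqrt((41 / 9) / 2)
        assert est.se == pytest.approx(expected, rel=1e-9)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(7)
        k = 10
        bx = rng.normal(0.1, 0.02, k)
        by = 0.3 * bx + rng.normal(0, 0.01, k)
        hs = HarmonizedSet.from_arrays(bx, np.full(k, 0.01), by, np.full(k, 0.01))
        flip = rng.random(k) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        hs_f = HarmonizedSet.from_arrays(bx * sgn, np.full(k, 0.01), by * sgn, np.full(k, 0.01))
        assert ivw(hs).beta == pytest.approx(ivw(hs_f).beta, rel=1e-12)


class TestEgger:
    def _set(self, slope, intercept, bx=(0.1, 0.2, 0.3, 0.4), sy=(0.05, 0.04, 0.05, 0.06)):
        bx = np.asarray(bx)
        by = intercept + slope * bx
        return HarmonizedSet.from_arrays(bx, np.full(bx.size, 0.01), by, np.asarray(sy))

    def test_exact_line_recovered(self):
        res = mr_egger(self._set(0.4, 0.0))
        assert res.slope.beta == pytest.approx(0.4, abs=1e-12)
        assert res.intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_intercept_recovered(self):
        res = mr_egger(self._set(0.4, 0.02))
        assert res.intercept.beta == pytest.approx(0.02, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.4, abs=1e-12)

    def test_i2_gx_long_hand(self):
        # bx = (.1,.2,.3,.4), sx = .05: weighted mean .25,
        # Q_GX = (2*.15^2 + 2*.05^2)/.0025 = 20, I2 = (20-3)/20 = .85
        hs = HarmonizedSet.from_arrays(
            [0.1, 0.2, 0.3, 0.4], [0.05] * 4, [0.04, 0.08, 0.12, 0.16], [0.05] * 4
        )
        res = mr_egger(hs)
        assert res.i2_gx == pytest.approx(0.85, rel=1e-12)

    def test_orientation_standardization(self):
        """Sign-flipping a pair (both betas) must not change the fit."""
        base = self._set(0.4, 0.02)
        flipped_pairs = HarmonizedSet.from_arrays(
            -base.beta_exposure, base.se_exposure, -base.beta_outcome, base.se_outcome
        )
        a, b = mr_egger(base), mr_egger(flipped_pairs)
        assert a.slope.beta == pytest.approx(b.slope.beta)
        assert a.intercept.beta == pytest.approx(b.intercept.beta)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.05] * 2))


class TestMedians:
    def _ratio_set(self, ratios, ses):
        ratios = np.asarray(ratios, dtype=float)
        return HarmonizedSet.from_arrays(
            np.ones(ratios.size), np.full(ratios.size, 1e-4), ratios, np.asarray(ses)
        )

    def test_simple_median_odd_count(self):
        hs = self._ratio_set([0.1, 0.2, 0.9], [0.1, 0.1, 0.1])
        assert simple_median(hs, n_boot=50, seed=1).beta == pytest.approx(0.2)

    def test_weighted_median_interpolation_long_hand(self):
        # sorted ratios (.1,.2,.9) with normalized weights (.6,.2,.2):
        # cumulative-minus-half-weight = (.3,.7,.9); 0.5 falls between the
        # first two -> 0.1 + (0.5-0.3)/(0.7-0.3) * (0.2-0.1) = 0.15
        ses = 1.0 / np.sqrt(np.array([0.6, 0.2, 0.2]))
        hs = self._ratio_set([0.1, 0.2, 0.9], ses)
        est = weighted_median(hs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.15, rel=1e-9)

    def test_equal_ratios_tight_bootstrap(self):
        hs = self._ratio_set([0.3, 0.3, 0.3], [1e-6, 1e-6, 1e-6])
        est = weighted_median(hs, n_boot=200, seed=2)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 1e-5

    def test_bootstrap_reproducible(self):
        hs = self._ratio_set([0.1, 0.25, 0.4, 0.7], [0.1, 0.2, 0.1, 0.3])
        a = weighted_median(hs, n_boot=300, seed=9)
        b = weighted_median(hs, n_boot=300, seed=9)
        assert a.se == b.se
        assert a.beta == b.beta


class TestWeightedMode:
    def _ratio_set(self, ratios, ses):
        ratios = np.asarray(ratios, dtype=float)
        return HarmonizedSet.from_arrays(
            np.ones(ratios.size), np.full(ratios.size, 1e-4), ratios, np.asarray(ses)
        )

    def test_majority_cluster_dominates(self):
        hs = self._ratio_set([0.30, 0.30, 0.30, 1.5], [0.05] * 4)
        est = weighted_mode(hs, n_boot=50, seed=3)
        assert est.beta == pytest.approx(0.30, abs=0.01)

    def test_dominant_weight_ratio_wins(self):
        hs = self._ratio_set([0.1, 0.5, 0.9], [0.01, 1.0, 1.0])
        est = weighted_mode(hs, n_boot=50, seed=3)
        assert est.beta == pytest.approx(0.1, abs=0.02)

    def test_matches_grid_search_oracle(self):
        ratios = np.array([0.05, 0.12, 0.15, 0.35, 0.8])
        ses = np.array([0.05, 0.04, 0.06, 0.1, 0.3])
        hs = self._ratio_set(ratios, ses)
        est = weighted_mode(hs, bandwidth_phi=1.0, n_boot=10, seed=0)
        # independent brute-force maximization of the same weighted KDE
        w = 1.0 / ses**2
        sd = np.std(ratios, ddof=1)
        mad = stats.median_abs_deviation(ratios, scale="normal")
        h = 0.9 * min(sd, mad) * ratios.size ** (-1 / 5)
        grid = np.arange(ratios.min(), ratios.max() + 1e-4, 1e-4)
        dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(1)
        oracle = grid[np.argmax(dens)]
        assert est.beta == pytest.approx(oracle, abs=1e-4)


class TestOddsRatioTransforms:
    def test_null_beta_symmetric_ci(self):
        orv, lci, uci = to_odds_ratio(0.0, 0.1)
        assert orv == 1.0
        assert np.log(lci) == pytest.approx(-np.log(uci))

    def test_reported_row_round_trip(self):
        # published-style row: OR 0.0714, 95% CI roughly (0.0156, 0.3277)
        orv, lci, uci = to_odds_ratio(np.log(0.0714), 0.7766)
        assert orv == pytest.approx(0.0714, rel=1e-6)
        assert lci == pytest.approx(0.0156, rel=2e-3)
        assert uci == pytest.approx(0.3277, rel=2e-3)

    def test_p_from_ci_reproduces_wald_p(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            beta = rng.normal(0, 1)
            se = rng.uniform(0.05, 1.0)
            p_direct = 2 * stats.norm.sf(abs(beta) / se)
            assert wald_p_from_or_ci(*to_odds_ratio(beta, se)) == pytest.approx(
                p_direct, rel=1e-9
            )

    @pytest.mark.parametrize(
        "orv,lci,uci,expected,digits",
        [
            (0.0714, 0.0156, 0.3277, 0.0007, 4),
            (25.1309, 1.9890, 317.5326, 0.0127, 4),
        ],
    )
    def test_published_rows_reproduced(self, orv, lci, uci, expected, digits):
        assert round(wald_p_from_or_ci(orv, lci, uci), digits) == expected

    def test_unit_or_symmetric_ci_gives_p_one(self):
        assert wald_p_from_or_ci(1.0, np.exp(-0.2), np.exp(0.2)) == pytest.approx(1.0)

    def test_non_monotone_bounds_raise(self):
        with pytest.raises(DomainError):
            wald_p_from_or_ci(0.5, 0.6, 0.9)


class TestRunAllMethods:
    def test_all_methods_with_or_fields(self):
        rng = np.random.default_rng(5)
        k = 8
        bx = np.abs(rng.normal(0.1, 0.03, k))
        by = 0.2 * bx + rng.normal(0, 0.01, k)
        hs = HarmonizedSet.from_arrays(bx, np.full(k, 0.01), by, np.full(k, 0.012))
        estimates = run_all_methods(hs, binary_outcome=True, n_boot=100, seed=1)
        methods = {e.method for e in estimates}
        assert methods == {
            "ivw", "egger_slope", "egger_intercept",
            "weighted_median", "simple_median", "weighted_mode",
        }
        for e in estimates:
            if e.method == "egger_intercept":
                assert e.or_value is None
            else:
                assert e.or_lci < e.or_value < e.or_uci

    def test_homogeneous_ratios_agree_across_estimators(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        hs = HarmonizedSet.from_arrays(bx, np.full(5, 1e-4), 0.3 * bx, np.full(5, 1e-6))
        estimates = run_all_methods(hs, binary_outcome=False, n_boot=50, seed=2)
        for e in estimates:
            if e.method == "egger_intercept":
                assert e.beta == pytest.approx(0.0, abs=1e-9)
            else:
                assert e.beta == pytest.approx(0.3, abs=1e-3), e.method
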