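import math

import numpy as np
import pytest
from scipy import stats

from protmr import estimators as est
from protmr.errors import (
    ConfigurationError,
    InsufficientDataError,
    UndefinedRatioError,
)

from .conftest import mk_inst, mk_insts, scenario_instruments


class TestWaldRatio:
    def test_first_order_closed_form(self):
        r = est.wald_ratio(mk_inst(2.0, 0.0, 1.0, 0.2), order="first")
        assert r.theta_hat == pytest.approx(0.5)
        assert r.se_theta == pytest.approx(0.1)

    def test_null_outcome_gives_p_one(self):
        r = est.wald_ratio(mk_inst(2.0, 0.1, 0.0, 0.2))
        assert r.theta_hat == 0.0 and r.pvalue == pytest.approx(1.0)

    def test_second_order_matches_delta_expression(self):
        # sqrt(se_y^2/b_x^2 + b_y^2 se_x^2 / b_x^4) at (0.5, 0.05, 0.1, 0.05),
        # evaluated independently beforehand
        r = est.wald_ratio(mk_inst(0.5, 0.05, 0.1, 0.05), order="second")
        assert r.se_theta == pytest.approx(0.10198039027185569, abs=1e-15)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(UndefinedRatioError):
            est.wald_ratio(mk_inst(0.0, 0.1, 0.1, 0.1))


class TestIVW:
    def test_homogeneous_pair(self):
        insts = mk_insts([1.0, 1.0], [1e-12, 1e-12], [0.3, 0.3], [0.1, 0.1])
        r = est.ivw(insts, random_effects="multiplicative")
        single = est.wald_ratio(insts[0])
        assert r.theta_hat == pytest.approx(0.3)
        assert r.se_theta == pytest.approx(single.se_theta / math.sqrt(2))
        assert r.extras["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_equals_wls_oracle_with_first_order_weights(self):
        """IVW with first-order weights equals the through-origin WLS slope
        of beta_Y on beta_X with weights 1/se_Y^2, to 1e-10."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            j = int(rng.integers(3, 40))
            bx = rng.normal(0.2, 0.05, j)
            by = rng.normal(0.06, 0.03, j)
            sy = rng.uniform(0.01, 0.05, j)
            insts = mk_insts(bx, np.full(j, 0.01), by, sy)
            r = est.ivw(insts, random_effects="fixed", weights="first")
            slope = np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2)
            assert abs(r.theta_hat - slope) < 1e-10
            se = math.sqrt(1.0 / np.sum(bx**2 / sy**2))
            assert abs(r.se_theta - se) < 1e-10

    def test_permutation_leaves_output_bit_identical(self):
        rng = np.random.default_rng(5)
        insts = mk_insts(
            rng.normal(0.2, 0.05, 12), np.full(12, 0.01),
            rng.normal(0.06, 0.02, 12), rng.uniform(0.01, 0.05, 12),
        )
        a = est.ivw(insts)
        b = est.ivw(insts[::-1])
        assert (a.theta_hat, a.se_theta, a.pvalue) == (b.theta_hat, b.se_theta, b.pvalue)
        assert a.extras["Q"] == b.extras["Q"]

    def test_orientation_flip_invariance(self):
        insts = mk_insts([0.2, 0.3, -0.25], [0.01] * 3, [0.06, 0.1, -0.07], [0.02] * 3)
        flipped = [
            mk_inst(-i.beta_exposure, i.se_exposure, -i.beta_outcome, i.se_outcome,
                    vid=i.variant_id)
            for i in insts
        ]
        assert est.ivw(insts).theta_hat == pytest.approx(
            est.ivw(flipped).theta_hat, abs=1e-15
        )

    def test_multiplicative_inflation_never_deflates(self):
        insts = mk_insts([0.2, 0.21, 0.19, 0.2], [1e-9] * 4,
                         [0.060, 0.0631, 0.0569, 0.0601], [0.02] * 4)
        fixed = est.ivw(insts, random_effects="fixed")
        mult = est.ivw(insts, random_effects="multiplicative")
        assert mult.se_theta >= fixed.se_theta
        assert mult.extras["re_inflation"] >= 1.0

    def test_single_instrument_is_error(self):
        with pytest.raises(InsufficientDataError):
            est.ivw([mk_inst(0.2, 0.01, 0.06, 0.02)])


class TestIVWRobust:
    def test_agrees_with_ivw_on_clean_data(self):
        insts = scenario_instruments(
            theta=0.3, J=30, n_exposure=30_000, n_outcome=30_000, seed=1
        )
        plain = est.ivw(insts)
        robust = est.ivw_robust(insts)
        assert abs(robust.theta_hat - plain.theta_hat) < plain.se_theta

    def test_resists_gross_outlier(self):
        rng = np.random.default_rng(12)
        j = 30
        bx = rng.uniform(0.1, 0.3, j)
        by = 0.3 * bx + rng.normal(0, 0.005, j)
        by[0] = 10 * 0.3 * bx[0]  # planted 10x ratio
        insts = mk_insts(bx, np.full(j, 1e-8), by, np.full(j, 0.005))
        truth = 0.3
        assert abs(est.ivw_robust(insts).theta_hat - truth) < abs(
            est.ivw(insts, random_effects="fixed").theta_hat - truth
        )

    def test_zero_residuals_reduce_to_fixed_effect_ivw(self):
        insts = mk_insts([0.1, 0.2, 0.3], [1e-9] * 3, [0.05, 0.10, 0.15], [0.02] * 3)
        r = est.ivw_robust(insts)
        f = est.ivw(insts, random_effects="fixed", weights="first")
        assert r.theta_hat == pytest.approx(f.theta_hat, abs=1e-12)
        assert r.extras.get("degenerate_zero_residuals")


class TestEgger:
    def test_exact_line(self):
        insts = mk_insts([1.0, 2.0, 3.0], [1e-9] * 3, [0.6, 1.1, 1.6], [0.1] * 3)
        r = est.egger(insts)
        assert r.theta_hat == pytest.approx(0.5, abs=1e-12)
        assert r.extras["intercept"] == pytest.approx(0.1, abs=1e-12)

    def test_proportional_data_zero_intercept_p_one(self):
        insts = mk_insts([1.0, 2.0, 3.0], [1e-9] * 3, [0.5, 1.0, 1.5], [0.1] * 3)
        r = est.egger(insts)
        assert r.extras["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert r.extras["p_intercept"] == pytest.approx(1.0)

    def test_matches_textbook_weighted_regression(self):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.1, 0.4, 20)
        by = 0.05 + 0.3 * bx + rng.normal(0, 0.01, 20)
        sy = rng.uniform(0.01, 0.03, 20)
        insts = mk_insts(bx, np.full(20, 1e-9), by, sy)
        r = est.egger(insts)
        X = np.column_stack([np.ones(20), bx])
        W = np.diag(1 / sy**2)
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ by)
        assert r.extras["intercept"] == pytest.approx(coef[0], abs=1e-10)
        assert r.theta_hat == pytest.approx(coef[1], abs=1e-10)

    def test_flip_then_egger_equals_egger(self):
        rng = np.random.default_rng(9)
        bx = rng.normal(0, 0.2, 10)
        by = 0.3 * bx + rng.normal(0, 0.02, 10)
        insts = mk_insts(bx, np.full(10, 0.01), by, np.full(10, 0.02))
        flipped = [
            mk_inst(-i.beta_exposure, i.se_exposure, -i.beta_outcome, i.se_outcome,
                    vid=i.variant_id)
            for i in insts
        ]
        a, b = est.egger(insts), est.egger(flipped)
        assert a.theta_hat == pytest.approx(b.theta_hat, abs=1e-14)
        assert a.extras["intercept"] == pytest.approx(b.extras["intercept"], abs=1e-14)

    def test_directional_pleiotropy_intercept_recovery_smoke(self):
        ints = []
        for r in range(50):
            insts = scenario_instruments(
                theta=0.3, J=100, exposure_r2_total=0.25, n_exposure=30_000,
                n_outcome=30_000, pleiotropy="directional", pleiotropy_mean=0.05,
                pleiotropy_sd=0.01, prop_invalid=1.0, seed=1000 + r,
            )
            ints.append(est.egger(insts).extras["intercept"])
        assert np.mean(ints) == pytest.approx(0.05, abs=0.01)


class TestWeightedMedian:
    def test_equal_weights_pick_middle_ratio(self):
        insts = mk_insts([1.0, 1.0, 1.0], [1e-12] * 3, [0.2, 0.3, 10.0], [1.0] * 3)
        r = est.weighted_median(insts, n_boot=50, seed=0)
        assert r.theta_hat == pytest.approx(0.3)

    def test_degenerate_equal_ratios(self):
        insts = mk_insts([1.0, 2.0, 4.0], [1e-12] * 3, [0.25, 0.5, 1.0], [0.001] * 3)
        r = est.weighted_median(insts, n_boot=200, seed=0)
        assert r.theta_hat == pytest.approx(0.25, abs=1e-9)
        assert r.se_theta < 0.01

    def test_resists_30pct_directional_pleiotropy(self):
        bias_med, bias_ivw = [], []
        for r in range(60):
            insts = scenario_instruments(
                theta=0.3, J=50, exposure_r2_total=0.25, n_exposure=30_000,
                n_outcome=30_000, pleiotropy="directional", pleiotropy_mean=0.05,
                pleiotropy_sd=0.01, prop_invalid=0.3, seed=2000 + r,
            )
            bias_med.append(est.weighted_median(insts, n_boot=100, seed=r).theta_hat - 0.3)
            bias_ivw.append(est.ivw(insts).theta_hat - 0.3)
        assert abs(np.mean(bias_med)) < abs(np.mean(bias_ivw))

    def test_reordering_preserves_point_estimate(self):
        insts = scenario_instruments(theta=0.2, J=10, seed=3)
        a = est.weighted_median(insts, n_boot=50, seed=1)
        b = est.weighted_median(insts[::-1], n_boot=50, seed=1)
        assert a.theta_hat == b.theta_hat


class TestWeightedMode:
    def test_dominant_cluster_wins(self):
        insts = mk_insts([1.0] * 4, [1e-12] * 4, [0.3, 0.3, 0.3, 5.0], [0.5] * 4)
        r = est.weighted_mode(insts, n_boot=50, seed=0)
        assert r.theta_hat == pytest.approx(0.3, abs=r.extras["bandwidth"])

    def test_tight_cluster_center(self):
        insts = mk_insts([1.0] * 5, [1e-12] * 5,
                         [0.29, 0.30, 0.31, 0.30, 0.30], [0.05] * 5)
        r = est.weighted_mode(insts, n_boot=50, seed=0)
        assert r.theta_hat == pytest.approx(0.30, abs=0.02)

    def test_argmax_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(10)
        j = 15
        bx = rng.uniform(0.1, 0.3, j)
        by = 0.3 * bx + rng.normal(0, 0.01, j)
        sy = rng.uniform(0.01, 0.03, j)
        insts = mk_insts(bx, np.full(j, 0.005), by, sy)
        r = est.weighted_mode(insts, n_boot=10, seed=0)
        theta_j = by / bx
        var_j = sy**2 / bx**2 + by**2 * 0.005**2 / bx**4
        w = 1 / var_j
        w = w / w.sum()
        h = r.extras["bandwidth"]
        grid = np.arange(theta_j.min() - 3 * h, theta_j.max() + 3 * h, 1e-4)
        dens = np.exp(-0.5 * ((grid[:, None] - theta_j[None, :]) / h) ** 2) @ w
        oracle = grid[np.argmax(dens)]
        assert r.theta_hat == pytest.approx(oracle, abs=2e-4)


class TestConmix:
    def test_consistent_instruments_recover_theta(self):
        insts = scenario_instruments(
            theta=0.4, J=15, exposure_r2_total=0.2, maf_range=(0.3, 0.5),
            n_exposure=200_000, n_outcome=200_000, seed=6,
        )
        r = est.conmix(insts, psi=1.0, theta_grid=(-2.0, 2.0, 0.001))
        assert r.theta_hat == pytest.approx(0.4, abs=0.02)
        assert r.extras["n_valid"] == len(insts)

    def test_planted_contamination_excluded_from_valid_set(self):
        j = 12
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.2, 0.4, j)
        by = 0.4 * bx
        wild = [1, 4, 7, 10]
        for i, s in zip(wild, [5, -5, 5, -5]):
            by[i] = s * bx[i]
        insts = mk_insts(bx, np.full(j, 1e-6), by, np.full(j, 0.01))
        r = est.conmix(insts)
        valid = set(r.extras["valid_set"])
        assert valid == {f"rs{i}" for i in range(j) if i not in wild}
        assert r.theta_hat == pytest.approx(0.4, abs=0.02)

    def test_ci_contains_estimate(self):
        insts = scenario_instruments(theta=0.1, J=10, seed=2)
        r = est.conmix(insts)
        assert r.ci_low <= r.theta_hat <= r.ci_high


class TestMRPresso:
    def test_planted_outlier_flagged_and_corrected(self):
        insts = scenario_instruments(
            theta=0.3, J=20, exposure_r2_total=0.2, maf_range=(0.3, 0.5),
            n_exposure=100_000, n_outcome=100_000, seed=3,
        )
        bad = insts[5]
        bad.beta_outcome = 10 * bad.beta_outcome
        r = est.mr_presso(insts, n_sim=1000, seed=3)
        assert bad.variant_id in r.extras["outliers"]
        assert abs(r.theta_hat - 0.3) < abs(r.extras["raw_theta"] - 0.3)
        assert r.extras["global_p"] < 0.05

    def test_exchangeable_duplicates_produce_no_outliers(self):
        insts = mk_insts([0.2] * 8, [0.01] * 8, [0.06] * 8, [0.02] * 8)
        r = est.mr_presso(insts, n_sim=500, seed=1)
        assert r.extras["outliers"] == []
        assert math.isnan(r.extras["distortion_p"])

    def test_low_simulation_count_rejected(self):
        insts = mk_insts([0.2] * 4, [0.01] * 4, [0.06] * 4, [0.02] * 4)
        with pytest.raises(ConfigurationError):
            est.mr_presso(insts, n_sim=50, seed=0)


class TestMRcML:
    def test_all_valid_selects_k0_and_matches_ivw(self):
        insts = scenario_instruments(
            theta=0.3, J=15, n_exposure=30_000, n_outcome=30_000, seed=5
        )
        r = est.mr_cml(insts, n=30_000)
        assert r.extras["K_selected"] == 0
        f = est.ivw(insts, random_effects="fixed", weights="first")
        assert r.theta_hat == pytest.approx(f.theta_hat, abs=1e-12)

    def test_two_planted_invalid_flagged(self):
        j = 12
        rng = np.random.default_rng(13)
        bx = rng.uniform(0.2, 0.4, j)
        by = 0.3 * bx + rng.normal(0, 0.004, j)
        by[2] += 0.5
        by[9] -= 0.5
        insts = mk_insts(bx, np.full(j, 1e-6), by, np.full(j, 0.004))
        r = est.mr_cml(insts, n=100_000)
        assert r.extras["K_selected"] == 2
        assert set(r.extras["invalid_set"]) == {"rs2", "rs9"}

    def test_bic_selection_matches_exhaustive_enumeration_at_j3(self):
        rng = np.random.default_rng(14)
        for trial in range(20):
            bx = rng.uniform(0.1, 0.4, 3)
            by = 0.3 * bx + rng.normal(0, 0.05, 3)
            sy = rng.uniform(0.01, 0.05, 3)
            insts = mk_insts(bx, np.full(3, 1e-9), by, sy)
            r = est.mr_cml(insts, k_max=1)
            w = 1 / sy**2
            # brute force: K=0 uses all, K=1 tries each single invalid set
            def nll_of(valid):
                th = np.sum(w[valid] * bx[valid] * by[valid]) / np.sum(
                    w[valid] * bx[valid] ** 2
                )
                return 0.5 * np.sum(((by[valid] - th * bx[valid]) / sy[valid]) ** 2)

            bics = {0: 2 * nll_of(np.arange(3))}
            best1 = min(
                nll_of(np.array([a for a in range(3) if a != drop]))
                for drop in range(3)
            )
            bics[1] = 2 * best1 + math.log(3)
            assert r.extras["K_selected"] == min(bics, key=bics.get)


class TestCochranQ:
    def test_homogeneous_is_zero(self):
        insts = mk_insts([1.0, 2.0], [1e-12] * 2, [0.3, 0.6], [0.01, 0.02])
        q, df, p = est.cochran_q(insts, 0.3)
        assert q == pytest.approx(0.0, abs=1e-18) and df == 1 and p == pytest.approx(1.0)

    def test_two_instrument_closed_form(self):
        # Q = w1 w2 (t1 - t2)^2 / (w1 + w2) at the weighted mean
        insts = mk_insts([1.0, 1.0], [1e-12] * 2, [0.2, 0.5], [0.1, 0.2])
        t = np.array([0.2, 0.5])
        w = np.array([1 / 0.01, 1 / 0.04])
        ref = float(np.sum(w * t) / np.sum(w))
        q, df, _ = est.cochran_q(insts, ref)
        expected = w[0] * w[1] * (t[0] - t[1]) ** 2 / (w[0] + w[1])
        assert q == pytest.approx(expected, rel=1e-10)

    def test_chi_square_moment_under_homogeneity(self):
        # strong instruments (mean F ~ 250) so the delta-method ratio
        # variance is accurate and Q ~ chi-square(J-1)
        qs = []
        for r in range(1000):
            insts = scenario_instruments(
                theta=0.3, J=30, exposure_r2_total=0.25, n_exposure=30_000,
                n_outcome=30_000, seed=9000 + r,
            )
            theta = est.ivw(insts, random_effects="fixed").theta_hat
            q, df, _ = est.cochran_q(insts, theta)
            qs.append(q)
        assert np.mean(qs) == pytest.approx(29, rel=0.05)


class TestSteiger:
    def test_strong_exposure_side_wins(self):
        insts = scenario_instruments(
            theta=0.1, J=30, exposure_r2_total=0.05, n_exposure=30_000,
            n_outcome=30_000, seed=4,
        )
        r = est.steiger_direction(insts, 30_000, 30_000)
        assert r.direction == "exposure_to_outcome"
        assert r.pvalue < 1e-6
        # z formula evaluated independently from the returned r2 values
        z = (math.atanh(math.sqrt(r.r2_exposure)) - math.atanh(math.sqrt(r.r2_outcome))) / math.sqrt(
            1 / (30_000 - 3) + 1 / (30_000 - 3)
        )
        assert r.z == pytest.approx(z, rel=1e-12)
        assert r.pvalue == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-9)

    def test_symmetric_sides_give_z_zero(self):
        insts = mk_insts([0.1], [0.01], [0.1], [0.01], eaf=[0.3])
        r = est.steiger_direction(insts, 20_000, 20_000)
        assert r.z == pytest.approx(0.0) and r.pvalue == pytest.approx(1.0)

    def test_swapping_sides_flips_direction_and_negates_z(self):
        insts = mk_insts([0.2, 0.15], [0.01] * 2, [0.05, 0.04], [0.01] * 2)
        fwd = est.steiger_direction(insts, 30_000, 40_000)
        swapped = [
            mk_inst(i.beta_outcome, i.se_outcome, i.beta_exposure, i.se_exposure,
                    vid=i.variant_id, eaf=i.eaf)
            for i in insts
        ]
        rev = est.steiger_direction(swapped, 40_000, 30_000)
        assert rev.z == pytest.approx(-fwd.z, rel=1e-12)
        assert fwd.direction == "exposure_to_outcome"
        assert rev.direction == "outcome_to_exposure"

    def test_missing_eaf_names_variant(self):
        insts = [mk_inst(0.1, 0.01, 0.05, 0.01, vid="rs77", eaf=None)]
        from protmr.errors import PreconditionError

        with pytest.raises(PreconditionError, match="rs77"):
            est.steiger_direction(insts, 1000, 1000)


class TestOrientationInvariance:
    """Simultaneous sign-flip of (beta_X, beta_Y) on any instrument leaves
    every point estimate unchanged (Egger re-orients internally)."""

    @pytest.mark.parametrize(
        "fn",
        [
            lambda ii: est.ivw(ii).theta_hat,
            lambda ii: est.ivw_robust(ii).theta_hat,
            lambda ii: est.egger(ii).theta_hat,
            lambda ii: est.weighted_median(ii, n_boot=20, seed=0).theta_hat,
            lambda ii: est.weighted_mode(ii, n_boot=5, seed=0).theta_hat,
            lambda ii: est.conmix(ii).theta_hat,
            lambda ii: est.mr_cml(ii).theta_hat,
        ],
    )
    def test_flip_one_instrument(self, fn):
        insts = scenario_instruments(theta=0.25, J=8, seed=17)
        flipped = [
            mk_inst(-i.beta_exposure, i.se_exposure, -i.beta_outcome, i.se_outcome,
                    vid=i.variant_id, eaf=i.eaf)
            if k == 3
            else i
            for k, i in enumerate(insts)
        ]
        assert fn(insts) == pytest.approx(fn(flipped), abs=1e-10)
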