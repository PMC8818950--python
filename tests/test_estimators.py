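import math

import numpy as np
import pytest
from scipy import stats

from tsmr.estimators import (
    egger,
    ivw,
    mode_estimate,
    or_from_beta,
    ratio_estimates,
    wald_ratio,
    weighted_median,
)
from tsmr.exceptions import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from tsmr.harmonization import HarmonizedInstrument
from tsmr.synthetic import SyntheticScenario, generate_pair
from tsmr.harmonization import harmonize_all

from conftest import make_instruments


def flip(inst: HarmonizedInstrument) -> HarmonizedInstrument:
    import dataclasses

    return dataclasses.replace(inst, beta_exp=-inst.beta_exp, beta_out=-inst.beta_out)


class TestWaldRatio:
    def test_single_snp(self):
        (inst,) = make_instruments([0.1], [0.2], [0.05])
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_zero_exposure_effect(self):
        (inst,) = make_instruments([0.0], [0.2], [0.05])
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(inst)


class TestIVW:
    def test_single_snp_delegates_to_wald(self):
        insts = make_instruments([0.1], [0.2], [0.05])
        est = ivw(insts)
        assert est.method == "ivw"
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_two_identical_snps_closed_form(self):
        # closed form: theta = 0.5, se = 1/sqrt(2)
        insts = make_instruments([1.0, 1.0], [0.5, 0.5], [1.0, 1.0])
        est = ivw(insts)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(1 / math.sqrt(2))

    def test_equals_wls_through_origin_oracle(self, rng):
        # oracle: weighted least squares of by on bx through the origin
        for _ in range(100):
            n = rng.integers(2, 30)
            bx = rng.normal(0.1, 0.05, n)
            bx[bx == 0] = 0.01
            by = rng.normal(0.0, 0.1, n)
            sy = rng.uniform(0.01, 0.2, n)
            w = sy**-2.0
            theta_wls = np.sum(w * bx * by) / np.sum(w * bx**2)
            se_wls = np.sum(w * bx**2) ** -0.5
            est = ivw(make_instruments(bx, by, sy))
            assert est.beta == pytest.approx(theta_wls, abs=1e-10)
            assert est.se == pytest.approx(se_wls, abs=1e-10)

    def test_or_and_ci_consistent(self):
        insts = make_instruments([1.0, 1.0], [0.5, 0.5], [1.0, 1.0])
        est = ivw(insts)
        assert est.or_value == pytest.approx(math.exp(est.beta))
        assert est.ci_low <= est.beta <= est.ci_high

    def test_multiplicative_variant_inflates_only(self, rng):
        bx = rng.normal(0.1, 0.02, 20)
        by = 0.5 * bx + rng.normal(0, 0.3, 20)  # gross over-dispersion
        sy = np.full(20, 0.05)
        fixed = ivw(make_instruments(bx, by, sy), variant="fixed")
        mre = ivw(make_instruments(bx, by, sy), variant="multiplicative")
        assert mre.beta == pytest.approx(fixed.beta)
        assert mre.se >= fixed.se

    def test_multiplicative_floor_at_one(self):
        # exact fit: residual sd 0 -> scale floored at 1, se equals fixed
        bx = np.array([0.1, 0.2, 0.3])
        insts = make_instruments(bx, 0.5 * bx, [0.05] * 3)
        assert ivw(insts, variant="multiplicative").se == pytest.approx(
            ivw(insts, variant="fixed").se
        )

    def test_zero_exposure_effect_named(self):
        insts = make_instruments([0.1, 0.0], [0.2, 0.1], [0.05, 0.05])
        with pytest.raises(DegenerateInstrumentError, match="rs1"):
            ivw(insts)

    def test_sign_flip_invariance(self, rng):
        bx = rng.normal(0.1, 0.05, 10)
        by = rng.normal(0.05, 0.05, 10)
        sy = rng.uniform(0.01, 0.1, 10)
        insts = make_instruments(bx, by, sy)
        flipped = [flip(i) if k % 2 else i for k, i in enumerate(insts)]
        assert ivw(flipped).beta == pytest.approx(ivw(insts).beta)
        assert ivw(flipped).se == pytest.approx(ivw(insts).se)


class TestEgger:
    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.3 + 0.8 * bx
        est = egger(make_instruments(bx, by, [0.05] * 4))
        assert est.beta == pytest.approx(0.8, abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(0.3, abs=1e-10)
        assert est.extra["q_rucker"] == pytest.approx(0.0, abs=1e-18)

    def test_collinear_exposure_effects(self):
        insts = make_instruments([0.2, 0.2, 0.2], [0.1, 0.2, 0.3], [0.05] * 3)
        with pytest.raises(CollinearityError):
            egger(insts)

    def test_too_few_instruments(self):
        insts = make_instruments([0.1, 0.2], [0.1, 0.2], [0.05] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(insts)

    def test_directional_pleiotropy_simulation(self):
        # alpha = 0.1, theta = 0: intercept recovers alpha, slope near 0
        intercepts, slopes = [], []
        for seed in range(500):
            sc = SyntheticScenario(
                nsnp=50, theta=0.0, pleiotropy_mean=0.1, pleiotropy_sd=0.02,
                beta_x_sd=0.1, seed=40_000 + seed,
            )
            e, o, _ = generate_pair(sc)
            est = egger(harmonize_all(e, o).kept)
            intercepts.append(est.extra["intercept"])
            slopes.append(est.beta)
        assert np.mean(intercepts) == pytest.approx(0.1, abs=0.01)
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.05)

    def test_sign_flip_invariance(self, rng):
        bx = rng.normal(0.1, 0.05, 10)
        by = rng.normal(0.05, 0.05, 10)
        sy = rng.uniform(0.01, 0.1, 10)
        insts = make_instruments(bx, by, sy)
        flipped = [flip(i) if k % 3 == 0 else i for k, i in enumerate(insts)]
        assert egger(flipped).beta == pytest.approx(egger(insts).beta)
        assert egger(flipped).extra["intercept"] == pytest.approx(
            egger(insts).extra["intercept"]
        )


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.4])
        insts = make_instruments(bx, 3.0 * bx, [0.05, 0.01, 0.2])
        est = weighted_median(insts, n_boot=50, seed=1)
        assert est.beta == pytest.approx(3.0)

    def test_equal_weights_interpolation_oracle(self):
        # ratios {1, 2, 10}, equal weights: p2 = 0.5 exactly -> estimate 2
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([1.0, 2.0, 10.0])
        est = weighted_median(make_instruments(bx, by, [1.0] * 3), n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_brute_force_cumulative_weight_oracle(self, rng):
        # oracle: scan the cumulative standardized weights and interpolate
        for _ in range(20):
            n = int(rng.integers(3, 12))
            bx = rng.uniform(0.05, 0.3, n)
            by = rng.normal(0.1, 0.2, n)
            sy = rng.uniform(0.01, 0.2, n)
            ratios = by / bx
            w = bx**2 / sy**2
            order = np.argsort(ratios)
            r_s, w_s = ratios[order], w[order]
            p = (np.cumsum(w_s) - w_s / 2) / w_s.sum()
            if 0.5 <= p[0]:
                expected = r_s[0]
            elif 0.5 >= p[-1]:
                expected = r_s[-1]
            else:
                k = np.searchsorted(p, 0.5)
                frac = (0.5 - p[k - 1]) / (p[k] - p[k - 1])
                expected = r_s[k - 1] + frac * (r_s[k] - r_s[k - 1])
            est = weighted_median(make_instruments(bx, by, sy), n_boot=2, seed=0)
            assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_within_ratio_range_and_odd_n_median(self, rng):
        bx = np.full(5, 1.0)
        by = rng.normal(0.2, 0.5, 5)
        insts = make_instruments(bx, by, np.full(5, 0.1))
        est = weighted_median(insts, n_boot=20, seed=3)
        ratios = by / bx
        assert ratios.min() <= est.beta <= ratios.max()
        assert est.beta == pytest.approx(np.median(ratios))

    def test_bootstrap_seeded_reproducible(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.05, 0.12, 0.14])
        insts = make_instruments(bx, by, [0.02] * 3)
        a = weighted_median(insts, n_boot=100, seed=7)
        b = weighted_median(insts, n_boot=100, seed=7)
        assert a.se == b.se


class TestModeEstimate:
    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.4])
        insts = make_instruments(bx, 2.5 * bx, [0.05] * 3)
        est = mode_estimate(insts, weighted=True, n_boot=20, seed=1)
        assert est.beta == pytest.approx(2.5)

    def test_majority_cluster_wins(self):
        # {1.00, 1.02, 0.98, 3.0} equal weights: mode near 1
        bx = np.full(4, 1.0)
        by = np.array([1.00, 1.02, 0.98, 3.0])
        insts = make_instruments(bx, by, np.full(4, 0.1))
        est = mode_estimate(insts, weighted=False, n_boot=20, seed=1)
        assert 0.9 < est.beta < 1.1

    def test_dense_grid_density_argmax_oracle(self, rng):
        # independent weighted-KDE argmax on a much denser grid
        from tsmr.estimators import _mode_bandwidth

        for _ in range(10):
            n = int(rng.integers(4, 15))
            bx = rng.uniform(0.05, 0.3, n)
            by = rng.normal(0.1, 0.2, n)
            sy = rng.uniform(0.01, 0.2, n)
            insts = make_instruments(bx, by, sy)
            ratios = by / bx
            w = bx**2 / sy**2
            h = _mode_bandwidth(ratios, 1.0)
            grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 20001)
            dens = np.zeros_like(grid)
            for rj, wj in zip(ratios, w):
                dens += wj * stats.norm.pdf((grid - rj) / h)
            expected = grid[np.argmax(dens)]
            est = mode_estimate(insts, weighted=True, n_boot=2, seed=0)
            grid_step = (np.ptp(ratios) + 6 * h) / 511
            assert est.beta == pytest.approx(expected, abs=grid_step)

    def test_weighted_vs_simple_mode(self):
        # heavy weights pin the weighted mode inside the [1.0, 1.05] cluster
        bx = np.full(3, 1.0)
        by = np.array([1.0, 1.05, 3.0])
        sy = np.array([1 / math.sqrt(10), 1 / math.sqrt(10), 1 / math.sqrt(0.1)])
        insts = make_instruments(bx, by, sy)
        wm = mode_estimate(insts, weighted=True, n_boot=20, seed=1)
        assert 1.0 - 1e-6 <= wm.beta <= 1.05 + 1e-6

    def test_needs_three(self):
        insts = make_instruments([0.1, 0.2], [0.1, 0.2], [0.05] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mode_estimate(insts)


class TestOrFromBeta:
    def test_null(self):
        assert or_from_beta(0.0) == 1.0

    def test_published_rounding(self):
        assert round(or_from_beta(1.074), 2) == 2.93

    def test_negative(self):
        assert or_from_beta(-0.053) == pytest.approx(0.948, abs=5e-4)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            or_from_beta(float("inf"))


class TestRatioEstimates:
    def test_first_order_variance(self):
        insts = make_instruments([0.5], [0.2], [0.1])
        re = ratio_estimates(insts)
        assert re.ratios[0] == pytest.approx(0.4)
        assert re.variances[0] == pytest.approx(0.1**2 / 0.5**2)

    def test_second_order_adds_exposure_term(self):
        insts = make_instruments([0.5], [0.2], [0.1], sx=[0.05])
        re1 = ratio_estimates(insts)
        re2 = ratio_estimates(insts, second_order=True)
        extra = 0.2**2 * 0.05**2 / 0.5**4
        assert re2.variances[0] == pytest.approx(re1.variances[0] + extra)


class TestParameterRecovery:
    def test_all_estimators_recover_theta_without_pleiotropy(self):
        theta = 0.4
        results = {m: [] for m in ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")}
        n_rep = 200
        for seed in range(n_rep):
            sc = SyntheticScenario(
                nsnp=100, theta=theta, beta_x_sd=0.08, seed=50_000 + seed
            )
            e, o, _ = generate_pair(sc)
            kept = harmonize_all(e, o).kept
            results["ivw"].append(ivw(kept).beta)
            results["egger"].append(egger(kept).beta)
            results["weighted_median"].append(
                weighted_median(kept, n_boot=1, seed=seed).beta
            )
            results["simple_mode"].append(
                mode_estimate(kept, weighted=False, n_boot=1, seed=seed).beta
            )
            results["weighted_mode"].append(
                mode_estimate(kept, weighted=True, n_boot=1, seed=seed).beta
            )
        for method, vals in results.items():
            mc_se = np.std(vals, ddof=1) / math.sqrt(n_rep)
            assert abs(np.mean(vals) - theta) < 2 * mc_se + 1e-3, method

    def test_egger_robust_to_directional_pleiotropy_where_ivw_drifts(self):
        ivw_bias, egger_bias = [], []
        for seed in range(100):
            sc = SyntheticScenario(
                nsnp=80, theta=0.0, pleiotropy_mean=0.05, pleiotropy_sd=0.02,
                beta_x_sd=0.1, seed=60_000 + seed,
            )
            e, o, _ = generate_pair(sc)
            kept = harmonize_all(e, o).kept
            ivw_bias.append(ivw(kept).beta)
            egger_bias.append(egger(kept).beta)
        assert abs(np.mean(egger_bias)) < abs(np.mean(ivw_bias))
        assert abs(np.mean(ivw_bias)) > 0.1  # IVW visibly pulled by pleiotropy
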