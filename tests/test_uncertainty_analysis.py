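"""LHS sampling, Monte Carlo propagation and SRC sensitivity."""

import numpy as np
import pytest
from scipy.special import ndtr

from granudiff.model_system import UncertaintySpec
from granudiff.uncertainty_analysis import (
    ParameterDraws,
    lhs_sample,
    run_monte_carlo,
    src_sensitivity,
)

D_TRUE = 1.2e-9


class TestLHS:
    def test_zero_rsd_column_is_degenerate(self):
        spec = UncertaintySpec(rsd={"V_T": 0.0, "r_g": 0.1})
        draws = lhs_sample(spec, {"V_T": 5e-5, "r_g": 1.5e-3}, 100, seed=1)
        assert np.allclose(draws.column("V_T"), 5e-5)
        assert draws.column("r_g").std() > 0

    def test_exactly_one_sample_per_quantile_bin(self):
        n = 256
        spec = UncertaintySpec(rsd={"r_g": 0.1})
        draws = lhs_sample(spec, {"r_g": 1.0}, n, seed=3)
        u = ndtr((draws.column("r_g") - 1.0) / 0.1)
        bins = np.floor(u * n).astype(int)
        assert sorted(bins) == list(range(n))

    def test_sample_statistics_match_target(self):
        spec = UncertaintySpec(rsd={"r_g": 0.10})
        draws = lhs_sample(spec, {"r_g": 1.0}, 1000, seed=5)
        x = draws.column("r_g")
        # chi-square-style band for the sample RSD at n=1000 (LHS is tighter
        # than i.i.d. sampling, so the i.i.d. band is conservative)
        assert 0.093 <= x.std(ddof=1) / x.mean() <= 0.107
        assert abs(x.mean() - 1.0) < 3.0 * 0.1 / np.sqrt(1000)

    def test_matches_scipy_qmc_marginals(self):
        # independent oracle: scipy's own Latin hypercube, same marginal law
        from scipy.stats import qmc
        from scipy.special import ndtri

        n = 2000
        sampler = qmc.LatinHypercube(d=1, seed=11)
        oracle = 1.0 + 0.1 * ndtri(sampler.random(n)[:, 0])
        spec = UncertaintySpec(rsd={"r_g": 0.1})
        ours = lhs_sample(spec, {"r_g": 1.0}, n, seed=11).column("r_g")
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert np.quantile(ours, q) == pytest.approx(
                np.quantile(oracle, q), abs=0.01
            )

    def test_large_rsd_truncation_rejected(self):
        spec = UncertaintySpec(rsd={"K": 0.9})
        with pytest.raises(ValueError, match="truncates"):
            lhs_sample(spec, {"K": 0.2}, 200, seed=1)

    def test_positive_values_even_at_half_rsd(self):
        spec = UncertaintySpec(rsd={"K": 0.5})
        draws = lhs_sample(spec, {"K": 0.2}, 500, seed=2)
        assert np.all(draws.column("K") > 0)


class TestMonteCarlo:
    def test_no_uncertainty_means_no_spread(self, system, designs):
        spec = UncertaintySpec(rsd={"r_g": 0.0})
        res = run_monte_carlo(2, system, designs[2], spec, n=50, seed=1)
        assert res.rsd == pytest.approx(0.0, abs=1e-6)
        assert res.inherent_inaccuracy == pytest.approx(0.0, abs=0.5)

    def test_radius_amplification_for_ficks_second_law(self, system, designs):
        spec = UncertaintySpec(rsd={"r_g": 0.10})
        res = run_monte_carlo(2, system, designs[2], spec, n=400, seed=9)
        assert res.rsd == pytest.approx(20.0, abs=2.5)

    def test_radius_linearity_for_method5(self, system, designs):
        spec = UncertaintySpec(rsd={"r_g": 0.10})
        res = run_monte_carlo(5, system, designs[5], spec, n=400, seed=9)
        assert res.rsd == pytest.approx(10.0, abs=1.5)

    def test_doubling_n_is_stable(self, system, designs):
        spec = UncertaintySpec(rsd={"r_g": 0.10})
        r1 = run_monte_carlo(3, system, designs[3], spec, n=400, seed=21).rsd
        r2 = run_monte_carlo(3, system, designs[3], spec, n=800, seed=22).rsd
        assert abs(r2 - r1) / r1 < 0.10

    def test_amplification_scales_with_input_rsd(self, system, designs):
        # output RSD ~ 2x input RSD across the 5-15% range
        for rsd_in in (0.05, 0.15):
            spec = UncertaintySpec(rsd={"r_g": rsd_in})
            res = run_monte_carlo(6, system, designs[6], spec, n=300, seed=4)
            assert res.rsd == pytest.approx(200.0 * rsd_in, rel=0.15)


class TestSRC:
    def test_recovers_analytic_betas_on_linear_model(self):
        rng = np.random.default_rng(0)
        n = 400
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = 2.0 * x1 + x2
        draws = ParameterDraws(
            matrix=np.column_stack([x1, x2]), names=["x1", "x2"], seed=0
        )
        sens = src_sensitivity(draws, y)
        assert sens.r_squared == pytest.approx(1.0, abs=1e-10)
        ratio = sens.beta2_share["x1"] / sens.beta2_share["x2"]
        assert ratio == pytest.approx(4.0, rel=0.05)
        assert sens.linear

    def test_pure_noise_is_insignificant(self):
        rng = np.random.default_rng(1)
        n = 2000
        X = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        draws = ParameterDraws(matrix=X, names=["a", "b", "c"], seed=1)
        sens = src_sensitivity(draws, y)
        assert not sens.linear
        assert all(not v for v in sens.significant.values())

    def test_per_point_aggregation(self):
        rng = np.random.default_rng(2)
        n = 300
        pts = rng.standard_normal((n, 5))
        x = rng.standard_normal(n)
        y = x + pts.sum(axis=1)
        names = ["r_g"] + [f"C_B_points[{i}]" for i in range(5)]
        draws = ParameterDraws(
            matrix=np.column_stack([x, pts]), names=names, seed=2
        )
        sens = src_sensitivity(draws, y)
        # five unit-variance point channels vs one parameter: 5/6 vs 1/6
        assert sens.beta2_share["C_B_points"] == pytest.approx(100 * 5 / 6, rel=0.05)
        assert "C_B_points[0]" not in sens.beta
        assert "r_g" in sens.beta

    def test_rank_deficiency_rejected(self):
        draws = ParameterDraws(matrix=np.ones((5, 7)), names=list("abcdefg"), seed=0)
        with pytest.raises(ValueError, match="samples"):
            src_sensitivity(draws, np.arange(5.0))
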