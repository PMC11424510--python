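"""Tests for the GCM statistic and test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from comets import (
    DegenerateStatisticError,
    RegressorSpec,
    gcm_statistic,
    gcm_statistic_multivariate,
    gcm_test,
    generate,
    DGPConfig,
)


def brute_force_statistic(eps, xi):
    """Direct transcription of the standardized residual-product form."""
    eps, xi = np.asarray(eps, float), np.asarray(xi, float)
    n = len(eps)
    num = (np.sum(eps * xi) / np.sqrt(n)) ** 2
    den = np.sum(eps**2 * xi**2) / n - (np.sum(eps * xi) / n) ** 2
    return num / den


class TestUnivariateStatistic:
    def test_hand_evaluated_example(self):
        T, p = gcm_statistic(eps=[1, 2, -1, 0], xi=[1, 1, 1, 1])
        assert T == pytest.approx(0.8, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(0.8, 1), abs=1e-10)
        assert p == pytest.approx(0.3711, abs=5e-4)

    def test_zero_numerator_gives_p_one(self):
        T, p = gcm_statistic(eps=[1, -1, 1, -1], xi=[1, 1, -1, -1])
        assert T == 0.0
        assert p == 1.0

    def test_constant_products_raise_degenerate(self):
        with pytest.raises(DegenerateStatisticError, match="degenerate residual products"):
            gcm_statistic(eps=[1, 1, 1, 1], xi=[1, 1, 1, 1])

    def test_too_few_observations(self):
        from comets import RegressionError

        with pytest.raises(RegressionError):
            gcm_statistic(eps=[1.0], xi=[1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        eps, xi = rng.standard_normal(200), rng.standard_normal(200)
        T, _ = gcm_statistic(eps=eps, xi=xi)
        assert T == pytest.approx(brute_force_statistic(eps, xi), rel=1e-12)

    @given(
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        seed=st.integers(0, 100),
    )
    def test_scale_invariance_and_symmetry(self, a, b, seed):
        rng = np.random.default_rng(seed)
        eps, xi = rng.standard_normal(50), rng.standard_normal(50)
        T, p = gcm_statistic(eps=eps, xi=xi)
        T_scaled, _ = gcm_statistic(eps=a * eps, xi=b * xi)
        T_swapped, _ = gcm_statistic(eps=xi, xi=eps)
        assert T >= 0 and 0 <= p <= 1
        assert T_scaled == pytest.approx(T, rel=1e-9)
        assert T_swapped == pytest.approx(T, rel=1e-12)


class TestMultivariateStatistic:
    def test_d1_quadratic_reduces_to_univariate(self, rng):
        eps, xi = rng.standard_normal(100), rng.standard_normal(100)
        T1, p1 = gcm_statistic(eps=eps, xi=xi)
        Tm, desc, pm = gcm_statistic_multivariate(eps, xi[:, None], "quadratic")
        assert Tm == T1 and pm == p1 and desc["df"] == 1

    def test_duplicated_column_uses_rank_df(self, rng, caplog):
        eps = rng.standard_normal(100)
        col = rng.standard_normal(100)
        with caplog.at_level("WARNING"):
            T, desc, p = gcm_statistic_multivariate(eps, np.column_stack([col, col]), "quadratic")
        assert desc["rank_deficient"] and desc["df"] == 1
        assert "pseudo-inverse" in caplog.text
        T1, p1 = gcm_statistic(eps=eps, xi=col)
        assert T == pytest.approx(T1, rel=1e-6)

    def test_high_dimensional_quadratic_refused(self, rng):
        from comets import RegressionError

        with pytest.raises(RegressionError, match="PCM"):
            gcm_statistic_multivariate(rng.standard_normal(10), rng.standard_normal((10, 12)), "quadratic")

    def test_max_type_is_seed_deterministic(self, rng):
        eps, xi = rng.standard_normal(100), rng.standard_normal((100, 30))
        out1 = gcm_statistic_multivariate(eps, xi, "max", seed=5)
        out2 = gcm_statistic_multivariate(eps, xi, "max", seed=5)
        assert out1[0] == out2[0] and out1[2] == out2[2]
        assert 0 <= out1[2] <= 1

    def test_p_decreases_as_statistic_increases(self):
        ps = [stats.chi2.sf(t, 3) for t in (0.5, 2.0, 8.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_quadratic_chi2_calibration_under_independence(self):
        # eps, xi iid N(0,1), n=2000, d=3: rejection at the chi2_3 0.95
        # quantile should be close to 5%
        rng = np.random.default_rng(2024)
        crit = stats.chi2.ppf(0.95, 3)
        rejections = 0
        reps = 500
        for _ in range(reps):
            eps = rng.standard_normal(2000)
            xi = rng.standard_normal((2000, 3))
            T, _, _ = gcm_statistic_multivariate(eps, xi, "quadratic")
            rejections += T > crit
        assert 0.03 <= rejections / reps <= 0.07


class TestGCMTest:
    def test_empty_z_degrades_to_mean_centering(self, rng):
        y = rng.standard_normal(60)
        x = rng.standard_normal(60)
        res = gcm_test(y, x, None, RegressorSpec("linear"), RegressorSpec("linear"))
        T, p = gcm_statistic(eps=y - y.mean(), xi=x - x.mean())
        assert res.statistic == pytest.approx(T, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_binary_x_residualized_on_probability_scale(self, rng):
        z = rng.standard_normal(120)
        x = (z + rng.standard_normal(120) > 0).astype(float)
        y = z + rng.standard_normal(120)
        res = gcm_test(y, x, z, RegressorSpec("linear"), RegressorSpec("linear"))
        assert 0 <= res.p_value <= 1
        assert res.residual_correlation is not None

    def test_result_serializable(self, rng):
        z = rng.standard_normal(60)
        res = gcm_test(rng.standard_normal(60), rng.standard_normal(60), z,
                       RegressorSpec("linear"), RegressorSpec("linear"))
        d = res.to_dict()
        assert d["method"] == "gcm" and 0 <= d["p_value"] <= 1 and d["df"] == 1

    def test_partially_linear_null_pvalues_uniform(self):
        # theta = 0 with an exactly linear E[X|Z]: p-values should look
        # Uniform(0,1) across replicates
        lin = RegressorSpec("linear")
        pvals = []
        for s in range(200):
            ds = generate(DGPConfig("partially_linear", n=500, theta=0.0, seed=s))
            pvals.append(gcm_test(ds.Y, ds.X, ds.Z, lin, lin).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_partially_linear_alternative_power(self):
        lin = RegressorSpec("linear")
        rej = 0
        for s in range(200):
            ds = generate(DGPConfig("partially_linear", n=500, theta=0.5, seed=s))
            rej += gcm_test(ds.Y, ds.X, ds.Z, lin, lin).p_value <= 0.05
        assert rej / 200 >= 0.9
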