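"""Tests for sample splitting, the PCM projection and the PCM test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from comets import (
    DGPConfig,
    DegenerateStatisticError,
    RegressorSpec,
    fit_projection,
    generate,
    make_splits,
    pcm_single_split,
    pcm_statistic,
    pcm_test,
    register_learner,
)

LIN = RegressorSpec("linear")
MEAN = RegressorSpec("mean_only")


class TestSplits:
    def test_even_and_odd_half_sizes(self):
        (p,) = make_splits(20, 1, 0)
        assert len(p.indices_d1) == len(p.indices_d2) == 10
        (p,) = make_splits(21, 1, 0)
        assert len(p.indices_d1) == 11 and len(p.indices_d2) == 10

    def test_seeded_determinism(self):
        a = make_splits(50, 3, 7)
        b = make_splits(50, 3, 7)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.indices_d1, pb.indices_d1)
            assert np.array_equal(pa.indices_d2, pb.indices_d2)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least 20"):
            make_splits(19, 1, 0)

    @given(n=st.integers(20, 200), K=st.integers(1, 5), seed=st.integers(0, 50))
    def test_splits_partition_all_rows(self, n, K, seed):
        for plan in make_splits(n, K, seed):
            plan.validate(n)


class TestStatistic:
    def test_hand_evaluated_example(self):
        T, p, cov = pcm_statistic([1, 0, -1], [1, 0, -1])
        assert T == pytest.approx(np.sqrt(6), abs=1e-10)  # 2/sqrt(3) / sqrt(2/9)
        assert T == pytest.approx(2.449489, abs=1e-6)
        assert p == pytest.approx(stats.norm.sf(np.sqrt(6)), abs=1e-12)
        assert p == pytest.approx(0.0072, abs=2e-4)
        assert cov == pytest.approx(2 / 3, abs=1e-12)

    def test_zero_mean_product_gives_half(self):
        T, p, _ = pcm_statistic([1, -1, 1, -1], [1, 1, -1, -1])
        assert T == 0.0 and p == 0.5

    def test_constant_zero_projection_degenerate(self):
        with pytest.raises(DegenerateStatisticError, match="degenerate"):
            pcm_statistic([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])


class TestProjection:
    def test_constant_response_gives_zero_projection(self, rng):
        X = rng.standard_normal(40)
        Z = rng.standard_normal(40)
        proj = fit_projection(X, Z, np.full(40, 2.5), MEAN, MEAN)
        f = proj.evaluate(X, Z[:, None])
        assert np.allclose(f, 0.0)
        with pytest.raises(DegenerateStatisticError):
            pcm_single_split(np.full(40, 2.5), X, Z, proj, MEAN, MEAN)

    def test_linear_gaussian_projection_is_x_centered(self, rng):
        # Y = X + Z + N(0,1) with X indep Z: f(x,z) = (x - E[X|Z]) / Var(Y|X,Z) = x
        n = 5000
        X = rng.standard_normal(n)
        Z = rng.standard_normal(n)
        Y = X + Z + rng.standard_normal(n)
        proj = fit_projection(X, Z, Y, LIN, LIN)
        f = proj.evaluate(X, Z[:, None])
        slope = np.polyfit(X, f, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)
        assert abs(np.corrcoef(f, X)[0, 1]) > 0.95

    def test_homoskedastic_variance_estimate(self, rng):
        n = 5000
        X = rng.standard_normal(n)
        Z = rng.standard_normal(n)
        Y = X + Z + rng.standard_normal(n)
        proj = fit_projection(X, Z, Y, LIN, LIN, spec_var=MEAN)
        v = proj.v_hat.predict(np.column_stack([X, Z]))
        assert np.ptp(v) == 0.0  # constant estimate
        assert v[0] == pytest.approx(1.0, abs=0.1)

    def test_variance_floor_applies_to_nonpositive_vhat(self, rng, caplog):
        class NegVar:
            def fit(self, X, y):
                return self

            def predict(self, X):
                return np.full(X.shape[0], -1.0)

        register_learner("negative_var", lambda spec, p: NegVar())
        n = 60
        X, Z = rng.standard_normal(n), rng.standard_normal(n)
        Y = X + Z + rng.standard_normal(n)
        proj = fit_projection(X, Z, Y, LIN, LIN, spec_var=RegressorSpec("negative_var"))
        with caplog.at_level("WARNING"):
            f = proj.evaluate(X, Z[:, None])
        assert np.all(np.isfinite(f))
        assert proj.floor_hits == n
        assert "variance floor" in caplog.text


class TestPCMTest:
    def test_k1_equals_single_split_computation(self, rng):
        n = 100
        Z = rng.standard_normal(n)
        X = Z + rng.standard_normal(n)
        Y = X + Z + rng.standard_normal(n)
        res = pcm_test(Y, X, Z, LIN, LIN, K=1, seed=9)
        (plan,) = make_splits(n, 1, 9)
        i1, i2 = plan.indices_d1, plan.indices_d2
        proj = fit_projection(X[i2], Z[i2], Y[i2], LIN, LIN)
        T, cov, _ = pcm_single_split(Y[i1], X[i1], Z[i1], proj, LIN, LIN)
        assert res.statistic == pytest.approx(T, rel=1e-12)
        assert res.p_value == pytest.approx(stats.norm.sf(T), rel=1e-12)

    def test_reproducibility(self, rng):
        n = 120
        Z = rng.standard_normal(n)
        X = Z + rng.standard_normal(n)
        Y = 0.5 * X + Z + rng.standard_normal(n)
        r1 = pcm_test(Y, X, Z, LIN, LIN, K=3, seed=4)
        r2 = pcm_test(Y, X, Z, LIN, LIN, K=3, seed=4)
        assert r1.statistic == r2.statistic and r1.p_value == r2.p_value
        assert [d.get("T") for d in r1.per_split] == [d.get("T") for d in r2.per_split]

    def test_swap_halves_doubles_split_records(self, rng):
        n = 80
        Z = rng.standard_normal(n)
        X = Z + rng.standard_normal(n)
        Y = X + Z + rng.standard_normal(n)
        res = pcm_test(Y, X, Z, LIN, LIN, K=2, seed=1, swap_halves=True)
        assert len(res.per_split) == 4

    def test_x_never_used_as_response_high_dimensional_block(self, rng):
        # d_x >> n would break any X-on-Z regression; the PCM must not care
        n, d = 60, 300
        Z = rng.standard_normal(n)
        X = rng.standard_normal((n, d))
        Y = Z + rng.standard_normal(n)
        res = pcm_test(Y, X, Z, RegressorSpec("lasso_cv", hyperparameters={"cv_folds": 5}),
                       LIN, K=1, seed=2)
        assert 0 <= res.p_value <= 1

    def test_oracle_null_statistic_is_standard_normal(self):
        # inject population residuals for a fixed direction f(X,Z) = X under
        # a null DGP: T should be N(0,1) across replicates
        Ts = []
        for s in range(1000):
            ds = generate(DGPConfig("pure_null", n=500, seed=s))
            T, _, _ = pcm_statistic(ds.oracle.eps, ds.oracle.xi[:, 0])
            Ts.append(T)
        Ts = np.asarray(Ts)
        assert abs(Ts.mean()) < 0.1
        assert 0.85 < Ts.var() < 1.15

    def test_cov_estimate_positive_under_alternative(self):
        # empirical tau estimates should be positive in expectation when X helps
        covs = []
        for s in range(30):
            ds = generate(DGPConfig("partially_linear", n=400, theta=0.5, seed=s))
            res = pcm_test(ds.Y, ds.X, ds.Z, LIN, LIN, K=1, seed=s)
            covs.append([d["cov_estimate"] for d in res.per_split if "cov_estimate" in d])
        assert np.mean(np.concatenate(covs)) > 0

    def test_multi_split_average_is_mean_of_per_split_stats(self, rng):
        n = 150
        Z = rng.standard_normal(n)
        X = Z + rng.standard_normal(n)
        Y = 0.3 * X + Z + rng.standard_normal(n)
        res = pcm_test(Y, X, Z, LIN, LIN, K=5, seed=0)
        Ts = [d["T"] for d in res.per_split if "T" in d]
        assert res.statistic == pytest.approx(np.mean(Ts), rel=1e-12)
        assert res.p_value == pytest.approx(stats.norm.sf(np.mean(Ts)), rel=1e-12)

    def test_serializable(self, rng):
        n = 80
        Z = rng.standard_normal(n)
        X = Z + rng.standard_normal(n)
        Y = X + Z + rng.standard_normal(n)
        d = pcm_test(Y, X, Z, LIN, LIN, K=2, seed=1).to_dict()
        assert d["method"] == "pcm" and d["K"] == 2 and len(d["per_split"]) == 2
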