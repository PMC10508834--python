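import numpy as np
import pytest

import pulmflow as pf
from pulmflow.parameters import PARAMETER_BOUNDS
from pulmflow.uq import (
    SobolIndices,
    build_basis,
    fit_pce_ols,
    generalized_sobol,
    sample_prior,
    sobol_from_pce,
    surrogate_moments,
    validation_mse,
)

UNIT3 = {"x1": (-np.pi, np.pi), "x2": (-np.pi, np.pi), "x3": (-np.pi, np.pi)}


def ishigami(X, a=7.0, b=0.1):
    return (
        np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2 + b * X[:, 2] ** 4 * np.sin(X[:, 0])
    )


def ishigami_exact(a=7.0, b=0.1):
    V = a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18 + 0.5
    V1 = 0.5 * (1 + b * np.pi**4 / 5) ** 2
    V2 = a**2 / 8
    ST1 = V1 + 8 * b**2 * np.pi**8 / 225
    ST3 = 8 * b**2 * np.pi**8 / 225
    return {
        "S": np.array([V1 / V, V2 / V, 0.0]),
        "ST": np.array([ST1 / V, V2 / V, ST3 / V]),
        "V": V,
    }


class TestSampling:
    def test_within_bounds(self):
        X = sample_prior(200, seed=1)
        for i, (lo, hi) in enumerate(PARAMETER_BOUNDS.values()):
            assert X[:, i].min() >= lo and X[:, i].max() <= hi

    def test_marginal_means(self):
        X = sample_prior(500, seed=4)
        for i, (lo, hi) in enumerate(PARAMETER_BOUNDS.values()):
            mid = 0.5 * (lo + hi)
            assert abs(X[:, i].mean() - mid) < 0.02 * (hi - lo) + 1e-12

    def test_deterministic(self):
        assert np.array_equal(sample_prior(50, seed=9), sample_prior(50, seed=9))

    def test_invalid_bounds(self):
        with pytest.raises(ValueError, match="bounds"):
            sample_prior(10, {"x": (1.0, 0.0)}, seed=0)


class TestBasis:
    def test_term_counts(self):
        assert build_basis(8, 4).n_terms == 495
        assert build_basis(8, 2).n_terms == 45
        assert build_basis(3, 9).n_terms == 220

    def test_empirical_orthonormality(self):
        basis = build_basis(4, 3)
        rng = np.random.default_rng(0)
        xi = rng.uniform(-1, 1, size=(100_000, 4))
        Psi = basis.evaluate(xi) / np.sqrt(basis.gammas)
        G = Psi.T @ Psi / xi.shape[0]
        assert np.abs(G - np.eye(basis.n_terms)).max() < 0.02


class TestOLSFit:
    def test_exact_polynomial_recovery(self):
        X = sample_prior(600, seed=2)
        z = (
            1.5
            + 2.0 * X[:, 0] / 1e6
            + 30.0 * (X[:, 3] - 0.86) ** 2
            + 4.0 * X[:, 3] * X[:, 4]
        )
        s = fit_pce_ols(X, z, 2)
        Xt = sample_prior(150, seed=12)
        zt = (
            1.5
            + 2.0 * Xt[:, 0] / 1e6
            + 30.0 * (Xt[:, 3] - 0.86) ** 2
            + 4.0 * Xt[:, 3] * Xt[:, 4]
        )
        assert np.abs(s(Xt)[:, 0] - zt).max() < 1e-8 * np.abs(zt).max()

    def test_constant_target(self):
        X = sample_prior(200, seed=3)
        s = fit_pce_ols(X, np.full(200, 6.25), 2)
        mean, var = surrogate_moments(s)
        assert mean[0] == pytest.approx(6.25, rel=1e-12)
        assert var[0] == pytest.approx(0.0, abs=1e-18)

    def test_underdetermined_rejected(self):
        X = sample_prior(20, seed=5)
        with pytest.raises(ValueError, match="at least"):
            fit_pce_ols(X, np.zeros(20), 2)

    def test_mse_decreases_with_degree(self):
        """Smooth non-polynomial target: held-out error falls as K = 2, 3, 4."""
        bounds = {"x1": (0.0, 1.0), "x2": (0.0, 1.0), "x3": (0.0, 1.0)}
        f = lambda X: np.exp(X[:, 0]) * np.sin(2.5 * X[:, 1]) + 1.0 / (
            1.5 + X[:, 2]
        )
        Xtr = sample_prior(300, bounds, seed=6)
        Xva = sample_prior(100, bounds, seed=7)
        mses = []
        for K in (2, 3, 4):
            s = fit_pce_ols(Xtr, f(Xtr), K, bounds)
            _, m = validation_mse(s, Xva, f(Xva))
            mses.append(m)
        assert mses[1] < mses[0] and mses[2] < mses[1]


class TestMoments:
    def test_uniform_variance(self):
        bounds = {"x": (2.0, 5.0)}
        X = sample_prior(300, bounds, seed=8)
        s = fit_pce_ols(X, X[:, 0], 2, bounds)
        _, var = surrogate_moments(s)
        assert var[0] == pytest.approx(3.0**2 / 12.0, rel=1e-10)

    def test_moments_match_monte_carlo(self):
        Xtr = sample_prior(3000, UNIT3, seed=10)
        s = fit_pce_ols(Xtr, ishigami(Xtr), 7, UNIT3)
        mean, var = surrogate_moments(s)
        Xmc = sample_prior(100_000, UNIT3, seed=11)
        zs = s(Xmc)[:, 0]
        assert mean[0] == pytest.approx(zs.mean(), abs=0.01 * np.sqrt(var[0]))
        assert var[0] == pytest.approx(zs.var(), rel=0.01)


class TestSobol:
    def test_single_parameter_target(self):
        X = sample_prior(400, seed=13)
        s = fit_pce_ols(X, X[:, 2], 2)
        idx = sobol_from_pce(s)
        assert idx.first[2, 0] == pytest.approx(1.0, abs=1e-10)
        assert idx.total[2, 0] == pytest.approx(1.0, abs=1e-10)
        others = np.delete(np.arange(8), 2)
        assert np.abs(idx.first[others, 0]).max() < 1e-10

    def test_additive_two_parameter(self):
        bounds = {"x1": (0.0, 1.0), "x2": (0.0, 1.0)}
        X = sample_prior(300, bounds, seed=14)
        s = fit_pce_ols(X, X[:, 0] + 2.0 * X[:, 1], 2, bounds)
        idx = sobol_from_pce(s, list(bounds))
        assert idx.first[:, 0] == pytest.approx([0.2, 0.8], abs=1e-10)
        assert idx.total[:, 0] == pytest.approx([0.2, 0.8], abs=1e-10)

    def test_ishigami_analytic(self):
        Xtr = sample_prior(4000, UNIT3, seed=15)
        s = fit_pce_ols(Xtr, ishigami(Xtr), 9, UNIT3)
        idx = sobol_from_pce(s, list(UNIT3))
        exact = ishigami_exact()
        assert np.abs(idx.first[:, 0] - exact["S"]).max() < 0.02
        assert np.abs(idx.total[:, 0] - exact["ST"]).max() < 0.02

    def test_matches_pick_freeze_on_surrogate(self):
        """PCE coefficient indices agree with a pick-freeze Monte-Carlo
        estimator applied to the surrogate itself."""
        Xtr = sample_prior(3000, UNIT3, seed=16)
        s = fit_pce_ols(Xtr, ishigami(Xtr), 7, UNIT3)
        idx = sobol_from_pce(s, list(UNIT3))

        rng = np.random.default_rng(17)
        n = 60_000
        lo = np.array([b[0] for b in UNIT3.values()])
        hi = np.array([b[1] for b in UNIT3.values()])
        A = lo + rng.random((n, 3)) * (hi - lo)
        B = lo + rng.random((n, 3)) * (hi - lo)
        fA = s(A)[:, 0]
        var = fA.var()
        for i in range(3):
            ABi = A.copy()
            ABi[:, i] = B[:, i]
            fABi = s(ABi)[:, 0]
            fB = s(B)[:, 0]
            Si = np.mean(fB * (fABi - fA)) / var        # Saltelli estimator
            STi = 0.5 * np.mean((fA - fABi) ** 2) / var
            assert abs(Si - idx.first[i, 0]) < 0.02
            assert abs(STi - idx.total[i, 0]) < 0.02

    def test_index_invariants_on_fitted_surrogates(self):
        Xtr = sample_prior(2000, UNIT3, seed=18)
        s = fit_pce_ols(Xtr, ishigami(Xtr), 6, UNIT3)
        idx = sobol_from_pce(s, list(UNIT3))
        assert np.all(idx.first >= -1e-12)
        assert np.all(idx.first <= idx.total + 1e-9)
        assert np.all(idx.total <= 1.0 + 1e-6)
        assert idx.first[:, 0].sum() <= 1.0 + 1e-6

    def test_zero_variance_flagged(self):
        X = sample_prior(200, seed=19)
        s = fit_pce_ols(X, np.full(200, 3.0), 2)
        idx = sobol_from_pce(s)
        assert idx.degenerate[0]
        assert np.all(idx.first[:, 0] == 0.0)


class TestGeneralizedSobol:
    def _indices(self, S, var):
        S = np.asarray(S, dtype=float)
        var = np.asarray(var, dtype=float)
        return SobolIndices(
            names=["x"], first=S[None, :], total=S[None, :], variance=var
        )

    def test_constant_in_time(self):
        t = np.linspace(0.01, 1.0, 50)
        idx = self._indices(np.full(50, 0.37), np.full(50, 2.0))
        GS, _ = generalized_sobol(idx, t)
        assert GS[0, 1:] == pytest.approx(0.37, rel=1e-12)

    def test_convex_combination_bound(self):
        t = np.linspace(0.01, 1.0, 200)
        rng = np.random.default_rng(20)
        S = rng.uniform(0.1, 0.9, size=200)
        var = rng.uniform(0.5, 2.0, size=200)
        GS, _ = generalized_sobol(self._indices(S, var), t)
        assert S.min() - 1e-9 <= GS[0, -1] <= S.max() + 1e-9

    def test_variance_concentration(self):
        """If variance lives in the late segment, GS(T) approaches the late
        segment's index."""
        t = np.linspace(0.01, 1.0, 400)
        S = np.where(t < 0.5, 0.9, 0.1)
        var = np.where(t < 0.5, 1e-6, 10.0)
        GS, _ = generalized_sobol(self._indices(S, var), t)
        assert abs(GS[0, -1] - 0.1) < 1e-3

    def test_zero_variance_rejected(self):
        t = np.linspace(0.01, 1.0, 10)
        with pytest.raises(ValueError, match="variance"):
            generalized_sobol(self._indices(np.ones(10), np.zeros(10)), t)


class TestValidationMSE:
    def test_exact_target_near_zero(self):
        X = sample_prior(300, seed=21)
        z = X[:, 0] / 1e6 + X[:, 3]
        s = fit_pce_ols(X, z, 2)
        Xv = sample_prior(80, seed=22)
        zv = Xv[:, 0] / 1e6 + Xv[:, 3]
        _, m = validation_mse(s, Xv, zv)
        assert m < 1e-20

    def test_zero_surrogate_gives_variance(self):
        X = sample_prior(100, seed=23)
        s = fit_pce_ols(X, np.zeros(100), 1)
        Xv = sample_prior(5000, seed=24)
        zv = Xv[:, 3] - PARAMETER_BOUNDS["alpha"][0]
        zv = zv - zv.mean()
        _, m = validation_mse(s, Xv, zv)
        assert m == pytest.approx(zv.var(), rel=1e-10)

    def test_empty_validation_rejected(self):
        X = sample_prior(100, seed=25)
        s = fit_pce_ols(X, np.zeros(100), 1)
        with pytest.raises(ValueError, match="empty"):
            validation_mse(s, X[:0], np.zeros(0))


class TestStudySmoke:
    def test_toy_study_satisfies_invariants(self, waveforms):
        """End-to-end pipeline on a miniature network."""
        from pulmflow.uq import UQStudyConfig, run_uq_study

        net = pf.make_toy_network(2)
        res = run_uq_study(
            net, waveforms,
            study=UQStudyConfig(degrees=(2,), n_train=60, n_val=8, seed=42),
        )
        assert res.n_failed == 0
        idx = res.sobol
        assert np.all(idx.first <= idx.total + 1e-9)
        assert np.all(idx.total <= 1.0 + 1e-6)
        assert np.all(idx.first.sum(axis=0) <= 1.0 + 1e-6)
        assert np.all((res.gs_pressure >= -1e-9) & (res.gs_pressure <= 1 + 1e-6))
        assert 2 in res.surrogates and 2 in res.val_mse
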