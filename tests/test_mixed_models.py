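import numpy as np
import pandas as pd
import pytest

from hetdom.io_formats import PhenotypeRecord
from hetdom.mixed_models import (
    MixedModelSpec,
    design_from_phenotypes,
    fit_lmm,
    het_association,
    loglik_at,
    model_aic,
    vif,
)
from hetdom.pedigree_coefficients import PedigreeModel

from conftest import make_genotypes


def reml_oracle(y, X, K, sigma_a2, sigma_e2):
    """Direct dense-matrix restricted log-likelihood (Patterson-Thompson)."""
    n, p = X.shape
    V = sigma_a2 * K + sigma_e2 * np.eye(n)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    r = y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    _, logdetX = np.linalg.slogdet(XtVinvX)
    return -0.5 * (
        logdetV + logdetX + r @ Vinv @ r + (n - p) * np.log(2 * np.pi)
    )


def simulate_gblup(rng, n, h2, K=None):
    if K is None:
        M = rng.standard_normal((n, 4 * n))
        K = M @ M.T / (4 * n)
    d, U = np.linalg.eigh(K)
    a = U @ (np.sqrt(np.clip(d, 0, None)) * rng.standard_normal(n))
    scale = np.sqrt(h2 / max(np.diag(K).mean(), 1e-12)) if h2 else 0.0
    y = 1.0 + a * scale + rng.standard_normal(n) * np.sqrt(1 - h2)
    return y, K


class TestFitLMM:
    def test_zero_kinship_reduces_to_ols(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = X @ np.array([1.0, 2.0, -0.5]) + rng.standard_normal(n)
        fit = fit_lmm(MixedModelSpec(y=y, X=X, K=np.zeros((n, n))))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-10)
        np.testing.assert_allclose(fit.blup, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loglik_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        y, K = simulate_gblup(rng, n, 0.5)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        for sa2, se2 in [(0.3, 0.7), (1.0, 1.0), (0.05, 2.0)]:
            got = loglik_at(y, X, K, sa2, se2, reml=True)
            assert got == pytest.approx(reml_oracle(y, X, K, sa2, se2), abs=1e-8)

    def test_reml_optimum_beats_random_ratios(self, rng):
        n = 60
        y, K = simulate_gblup(rng, n, 0.4)
        X = np.ones((n, 1))
        fit = fit_lmm(MixedModelSpec(y=y, X=X, K=K))
        best = loglik_at(y, X, K, fit.sigma_a2, fit.sigma_e2)
        for lam in 10 ** rng.uniform(-4, 4, size=20):
            assert loglik_at(y, X, K, lam, 1.0) <= best + 1e-6

    def test_h2_recovery_short(self):
        h2s = []
        for rep in range(25):
            rng = np.random.default_rng(500 + rep)
            y, K = simulate_gblup(rng, 300, 0.4)
            fit = fit_lmm(MixedModelSpec(y=y, X=np.ones((300, 1)), K=K))
            h2s.append(fit.h2)
        assert np.mean(h2s) == pytest.approx(0.4, abs=0.08)

    def test_row_permutation_invariance(self, rng):
        n = 50
        y, K = simulate_gblup(rng, n, 0.3)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fit = fit_lmm(MixedModelSpec(y=y, X=X, K=K))
        perm = rng.permutation(n)
        fit_p = fit_lmm(MixedModelSpec(y=y[perm], X=X[perm], K=K[np.ix_(perm, perm)]))
        np.testing.assert_allclose(fit.beta, fit_p.beta, atol=1e-6)
        np.testing.assert_allclose(fit.residuals[perm], fit_p.residuals, atol=1e-6)

    def test_residuals_gls_orthogonal_to_design(self, rng):
        n = 80
        y, K = simulate_gblup(rng, n, 0.5)
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        fit = fit_lmm(MixedModelSpec(y=y, X=X, K=K))
        # X' V^{-1} (y - X beta) = 0 at the GLS solution
        V = fit.sigma_a2 * K + fit.sigma_e2 * np.eye(n)
        r_fixed = y - X @ fit.beta
        np.testing.assert_allclose(X.T @ np.linalg.solve(V, r_fixed), 0.0, atol=1e-6)

    def test_non_psd_kinship_rejected(self, rng):
        n = 10
        K = -np.eye(n)
        with pytest.raises(ValueError, match="PSD"):
            fit_lmm(MixedModelSpec(y=rng.standard_normal(n), X=np.ones((n, 1)), K=K))

    def test_pure_noise_boundary_flag(self, rng):
        n = 120
        y = rng.standard_normal(n)
        M = rng.standard_normal((n, 300))
        K = M @ M.T / 300
        fit = fit_lmm(MixedModelSpec(y=y, X=np.ones((n, 1)), K=K))
        assert fit.sigma_a2 <= 0.2  # little to no spurious genetic variance


class TestVif:
    def test_orthogonal_covariates_unity(self):
        X = np.eye(6)[:, :3] - 1.0 / 6
        out = vif(X)
        np.testing.assert_allclose(out.values, 1.0, atol=0.3)

    def test_known_correlation_closed_form(self, rng):
        n = 20_000
        x1 = rng.standard_normal(n)
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        out = vif(np.column_stack([x1, x2]))
        assert out.iloc[0] == pytest.approx(1 / (1 - 0.81), rel=0.05)

    def test_duplicated_covariate_flagged_infinite(self, rng):
        x = rng.standard_normal(30)
        out = vif(np.column_stack([x, x]))
        assert np.isinf(out).all()

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            vif(np.column_stack([np.ones(10), rng.standard_normal(10)]))


class TestAic:
    def test_identical_refit_identical_aic(self, rng):
        y, K = simulate_gblup(rng, 50, 0.4)
        spec = MixedModelSpec(y=y, X=np.ones((50, 1)), K=K)
        assert model_aic(fit_lmm(spec)) == model_aic(fit_lmm(spec))

    def test_noise_covariate_usually_raises_aic(self):
        worse = 0
        n = 150
        for rep in range(100):
            rng = np.random.default_rng(900 + rep)
            y, K = simulate_gblup(rng, n, 0.3)
            X0 = np.ones((n, 1))
            X1 = np.column_stack([X0, rng.standard_normal(n)])
            a0 = fit_lmm(MixedModelSpec(y=y, X=X0, K=K)).aic
            a1 = fit_lmm(MixedModelSpec(y=y, X=X1, K=K)).aic
            worse += a1 > a0
        assert worse >= 80


def _toy_cohort(rng, n=120, coef_oh=2.0):
    """Phenotypes driven by a known OH coefficient on unrelated animals."""
    oh = rng.uniform(0.2, 0.5, size=n)
    het = np.clip(oh * 2 - 0.3 + rng.normal(0, 0.05, n), 0, 1)
    y = 3.0 + coef_oh * oh + rng.standard_normal(n) * 0.5
    records = [
        PhenotypeRecord(
            f"a{i}", float(y[i]),
            dam_parity=str(rng.integers(1, 4)),
            contemporary_group=f"cg{i % 6}",
        )
        for i in range(n)
    ]
    cov = pd.DataFrame({"oh": oh, "het": het}, index=[f"a{i}" for i in range(n)])
    pm = PedigreeModel(
        animals=[f"a{i}" for i in range(n)],
        A=np.eye(n),
        Q=np.ones((n, 1)),
        group_labels=["all"],
    )
    return records, cov, pm


class TestHetAssociation:
    def test_recovers_known_oh_coefficient(self):
        covered = 0
        for rep in range(30):
            rng = np.random.default_rng(40 + rep)
            records, cov, pm = _toy_cohort(rng, coef_oh=2.0)
            out = het_association(records, cov, pm, ["oh"])
            b, se = out.iloc[0]["coefficient"], out.iloc[0]["se"]
            covered += abs(b - 2.0) <= 2 * se
        assert covered >= 24

    def test_oh_hl_together_refused(self, rng):
        records, cov, pm = _toy_cohort(rng)
        cov["hl"] = 1 - cov["oh"]
        with pytest.raises(ValueError, match="collinear"):
            het_association(records, cov, pm, ["oh", "hl"])

    def test_zero_variance_covariate_rejected(self, rng):
        records, cov, pm = _toy_cohort(rng)
        cov["flat"] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            het_association(records, cov, pm, ["flat", "oh"])

    def test_covariate_order_invariance(self, rng):
        records, cov, pm = _toy_cohort(rng)
        a = het_association(records, cov, pm, ["het", "oh"]).set_index("measure")
        b = het_association(records, cov, pm, ["oh", "het"]).set_index("measure")
        for m in ("het", "oh"):
            assert a.loc[m, "coefficient"] == pytest.approx(
                b.loc[m, "coefficient"], abs=1e-8
            )


class TestDesignBuilder:
    def test_rare_levels_merged(self):
        records = [
            PhenotypeRecord(f"a{i}", float(i), dam_parity="1" if i < 9 else "5+")
            for i in range(10)
        ]
        y, X, names, animals = design_from_phenotypes(records, factors=("dam_parity",))
        assert not any("5+" in c for c in names)

    def test_design_shapes(self):
        records = [
            PhenotypeRecord(
                f"a{i}", float(i), dam_parity=str(1 + i % 3),
                birth_herd="beef" if i % 2 else "dairy",
                contemporary_group=f"g{i % 2}",
            )
            for i in range(12)
        ]
        y, X, names, animals = design_from_phenotypes(records)
        assert X.shape == (12, len(names))
        assert names[0] == "intercept"
        assert len(animals) == 12
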