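import numpy as np
import pytest

from gspanel.gwas import VarianceComponents, fit_null_lmm
from gspanel.linmodels import (
    BayesPrior,
    McmcConfig,
    aireml,
    bayes_sample,
    gblup_predict,
    marker_gebv,
)
from gspanel.popstruct import GRM, compute_grm

from conftest import make_geno


def _unrelated(n, m, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.5, m)
    return make_geno(rng.binomial(2, p, size=(n, m)).astype(float))


def _centered(geno):
    d = geno.dosages.astype(float)
    return d - d.mean(axis=0)


class TestAireml:
    def test_scale_equivariance(self):
        geno = _unrelated(200, 300, 0)
        grm = compute_grm(geno)
        rng = np.random.default_rng(1)
        z = _centered(geno)
        y = z @ rng.standard_normal(300) * 0.05 + rng.standard_normal(200)
        vc1 = aireml(y, grm)
        vc2 = aireml(10.0 * y, grm)
        assert vc2.sigma_a2 == pytest.approx(100 * vc1.sigma_a2, rel=1e-4)
        assert vc2.sigma_e2 == pytest.approx(100 * vc1.sigma_e2, rel=1e-4)
        assert vc2.h2 == pytest.approx(vc1.h2, abs=1e-6)

    def test_pure_noise_bounded(self):
        h2s = []
        for seed in range(20):
            geno = _unrelated(300, 200, 50 + seed)
            y = np.random.default_rng(900 + seed).standard_normal(300)
            h2s.append(aireml(y, compute_grm(geno)).h2)
        assert np.mean(h2s) < 0.1

    def test_agrees_with_spectral_reml(self):
        # independent optimizer for the same REML objective
        geno = _unrelated(250, 400, 2)
        grm = compute_grm(geno)
        rng = np.random.default_rng(3)
        y = _centered(geno) @ rng.standard_normal(400) * 0.04 + rng.standard_normal(250)
        vc_ai = aireml(y, grm)
        vc_sp = fit_null_lmm(y, np.ones((250, 1)), grm)
        assert vc_ai.h2 == pytest.approx(vc_sp.h2, abs=0.01)

    def test_small_n_rejected(self):
        geno = _unrelated(10, 20, 4)
        with pytest.raises(ValueError):
            aireml(np.zeros(10), compute_grm(geno))


class TestGblup:
    def test_complete_shrinkage_limit(self):
        geno = _unrelated(60, 50, 5)
        grm = compute_grm(geno)
        y = np.random.default_rng(6).standard_normal(40)
        vc = VarianceComponents(1e-12, 1.0)  # lambda -> infinity
        fit = gblup_predict(y, grm, np.arange(40), np.arange(40, 60), vc)
        assert np.abs(fit.gebv).max() < 1e-6

    def test_snp_blup_equivalence(self):
        # GBLUP with G = ZZ'/c equals ridge on markers with lambda_m = c*lambda
        rng = np.random.default_rng(7)
        n, m = 50, 30
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        p = d.mean(axis=0) / 2
        z = d - 2 * p
        c = 2 * np.sum(p * (1 - p))
        grm = GRM(z @ z.T / c, [f"s{i}" for i in range(n)], m)
        y = z @ rng.standard_normal(m) * 0.2 + rng.standard_normal(n)
        vc = VarianceComponents(0.6, 0.8)
        tr, te = np.arange(40), np.arange(40, 50)
        fit = gblup_predict(y[tr], grm, tr, te, vc)
        lam_m = c * vc.sigma_e2 / vc.sigma_a2
        a = np.linalg.solve(z[tr].T @ z[tr] + lam_m * np.eye(m), z[tr].T @ (y[tr] - fit.mu))
        np.testing.assert_allclose(fit.gebv, z @ a, atol=1e-6)

    def test_duplicated_training_individual_stays_finite(self):
        geno = _unrelated(50, 60, 8)
        d = geno.dosages.copy()
        d[1] = d[0]
        grm = compute_grm(make_geno(d))
        rng = np.random.default_rng(9)
        y = rng.standard_normal(40)
        y[1] = y[0]
        vc = VarianceComponents(0.5, 0.5)
        fit = gblup_predict(y, grm, np.arange(40), np.arange(40, 50), vc)
        assert np.isfinite(fit.gebv).all()

    def test_overlapping_train_test_rejected(self):
        geno = _unrelated(30, 40, 10)
        grm = compute_grm(geno)
        with pytest.raises(ValueError, match="overlap"):
            gblup_predict(np.zeros(20), grm, np.arange(20), np.arange(19, 25),
                          VarianceComponents(1, 1))


class TestBayesSamplers:
    def test_single_marker_matches_ridge_closed_form(self):
        rng = np.random.default_rng(11)
        n = 200
        x = rng.binomial(2, 0.4, n).astype(float)
        x -= x.mean()
        y = 0.4 * x + rng.standard_normal(n)
        se2, sg2 = 1.0, 0.25
        prior = BayesPrior(model="A", fixed_sigma_e2=se2, fixed_sigma_g2=sg2, S=sg2)
        fit = bayes_sample(y, x[:, None], prior, McmcConfig(18_000, 3_000, 1, seed=13))
        ridge = float(x @ (y - fit.mu)) / (x @ x + se2 / sg2)
        draws = fit.draws[:, 0]
        nb = 50
        batches = draws[: (draws.size // nb) * nb].reshape(nb, -1).mean(axis=1)
        mc_se = batches.std(ddof=1) / np.sqrt(nb)
        assert abs(fit.effects[0] - ridge) < 3 * mc_se

    def test_chains_bit_reproducible(self):
        geno = _unrelated(100, 80, 12)
        z = _centered(geno)
        rng = np.random.default_rng(13)
        y = z @ rng.standard_normal(80) * 0.1 + rng.standard_normal(100)
        for model in ("A", "B", "Cpi", "Lasso"):
            a = bayes_sample(y, z, BayesPrior(model=model), McmcConfig(500, 100, 5, seed=7))
            b = bayes_sample(y, z, BayesPrior(model=model), McmcConfig(500, 100, 5, seed=7))
            assert np.array_equal(a.effects, b.effects), model
            assert a.mu == b.mu

    @pytest.mark.parametrize("model", ["A", "B", "Cpi", "Lasso"])
    def test_null_shrinkage_below_ols(self, model):
        # permuted phenotype: posterior means shrink below per-marker OLS
        geno = _unrelated(150, 60, 14)
        z = _centered(geno)
        rng = np.random.default_rng(15)
        y = z @ rng.standard_normal(60) * 0.2 + rng.standard_normal(150)
        y_perm = rng.permutation(y)
        fit = bayes_sample(y_perm, z, BayesPrior(model=model), McmcConfig(2000, 500, 5, seed=1))
        ols = np.array([z[:, j] @ y_perm / (z[:, j] @ z[:, j]) for j in range(60)])
        assert np.abs(fit.effects).max() < np.abs(ols).max()

    def test_bayescpi_sparse_recovery(self):
        rng = np.random.default_rng(16)
        n, m = 300, 1000
        p = rng.uniform(0.1, 0.5, m)
        d = rng.binomial(2, p, size=(n, m)).astype(float)
        z = d - d.mean(axis=0)
        qtl = np.array([100, 300, 500, 700, 900])
        beta = np.array([1.0, -1.0, 0.8, -0.8, 1.2])
        g = z[:, qtl] @ beta
        y = g + rng.standard_normal(n) * g.std() * 0.5  # h2 = 0.8
        fit = bayes_sample(y, z, BayesPrior(model="Cpi"), McmcConfig(3000, 1000, 5, seed=2))
        assert fit.pi_mean > 0.9
        top20 = np.argsort(-np.abs(fit.effects))[:20]
        assert set(qtl).issubset(set(top20))

    def test_wgs_scale_refused(self):
        with pytest.raises(ValueError, match="panel-scale"):
            bayes_sample(np.zeros(10), np.zeros((10, 60_000)), BayesPrior())


class TestMarkerGebv:
    def test_linearity_and_oracle(self):
        geno = _unrelated(50, 30, 17)
        z = _centered(geno)
        rng = np.random.default_rng(18)
        y = z @ rng.standard_normal(30) * 0.3 + rng.standard_normal(50)
        fit = bayes_sample(y, z, BayesPrior(model="A"), McmcConfig(500, 100, 5, seed=3))
        gebv = marker_gebv(fit, z)
        oracle = np.array([float(np.dot(z[i], fit.effects)) for i in range(50)])
        np.testing.assert_allclose(gebv, oracle, atol=1e-12)
        np.testing.assert_allclose(marker_gebv(fit, 2 * z), 2 * gebv, atol=1e-12)
        fit.effects = np.zeros_like(fit.effects)
        assert np.all(marker_gebv(fit, z) == 0)

    def test_misaligned_markers_rejected(self):
        geno = _unrelated(40, 20, 19)
        z = _centered(geno)
        fit = bayes_sample(np.random.default_rng(0).standard_normal(40), z,
                           BayesPrior(model="A"), McmcConfig(200, 50, 5, seed=4))
        with pytest.raises(ValueError):
            marker_gebv(fit, z[:, :10])
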