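import numpy as np
import pandas as pd
import pytest

from pevsim.lmm import (GBLUP, MultiLocationLMM, StageOneLMM,
                        backsolve_marker_effects, blup_and_pev, fit_k_model)
from pevsim.relmat import (CovStructure, InvalidInputError, center_columns,
                           identity_structure, normalize_gn,
                           recode_minor_allele, vanraden_g)
from pevsim.simkit import TrialDesign


def _balanced_table(rng, n_g=20, n_loc=2, n_blk=3, loc_sd=(1.0, 1.0)):
    lay = TrialDesign(n_g, n_loc, n_blk).layout()
    g = rng.normal(0, 1, n_g)
    L = rng.normal(0, 1, n_loc)
    B = rng.normal(0, 0.5, (n_loc, n_blk))
    eps = rng.standard_normal(len(lay)) * np.array(loc_sd)[lay["li"]]
    lay["value"] = g[lay["gi"]] + L[lay["li"]] + B[lay["li"], lay["bi"]] + eps
    return lay[["genotype", "location", "block", "value"]], g


class TestStageOne:
    def test_homogeneous_case_matches_ols(self, rng):
        """With a single residual variance FGLS equals OLS genotype means."""
        pheno, g = _balanced_table(rng, n_loc=1)
        res = StageOneLMM(pheno).fit()
        # balanced design: centered BLUEs are centered genotype means
        means = pheno.groupby("genotype", sort=False)["value"].mean()
        expected = means - means.mean()
        np.testing.assert_allclose(
            res.g_hat.loc[expected.index], expected, atol=1e-8)

    def test_centered_blues_recover_truth_without_noise(self, rng):
        pheno, g = _balanced_table(rng, loc_sd=(0.0, 0.0))
        with pytest.warns(RuntimeWarning):  # zero residual variance
            res = StageOneLMM(pheno).fit()
        order = [f"g{i}" for i in range(20)]
        np.testing.assert_allclose(res.g_hat.loc[order], g - g.mean(), atol=1e-8)

    def test_duplicate_rows_flagged_degenerate(self, rng):
        pheno, _ = _balanced_table(rng, loc_sd=(0.0, 0.0))
        with pytest.warns(RuntimeWarning):
            res = StageOneLMM(pheno).fit()
        assert res.degenerate

    def test_two_location_variance_recovery(self):
        """Per-location residual variances (1, 4) recovered on average."""
        rng = np.random.default_rng(99)
        reps = 30
        est = np.zeros((reps, 2))
        for r in range(reps):
            pheno, _ = _balanced_table(rng, n_g=40, loc_sd=(1.0, 2.0))
            res = StageOneLMM(pheno).fit()
            est[r] = [res.residual_variances["L0"], res.residual_variances["L1"]]
        for j, truth in enumerate((1.0, 4.0)):
            mc_se = est[:, j].std(ddof=1) / np.sqrt(reps)
            assert abs(est[:, j].mean() - truth) < 3 * mc_se


class TestGBLUPReml:
    def test_null_variance_hits_boundary(self):
        """Pure-noise responses push the additive variance to ~zero."""
        rng = np.random.default_rng(11)
        ratios = []
        for _ in range(20):
            A = rng.standard_normal((200, 80))
            K = CovStructure(A @ A.T / 80)
            y = rng.standard_normal(200)
            fit = GBLUP(y, K).fit()
            ratios.append(fit.sigma2_a_star / fit.sigma2_eps)
        assert np.mean(ratios) <= 0.05

    def test_estimates_maximize_over_grid(self, ld_markers):
        """REML optimum beats every point of a 50 x 50 variance grid."""
        rng = np.random.default_rng(3)
        GN = normalize_gn(vanraden_g(ld_markers))
        idx = np.arange(30)
        K = GN.subset(idx)
        F = np.linalg.cholesky(K.matrix + 1e-8 * np.eye(30))
        y = F @ rng.standard_normal(30) + rng.standard_normal(30)
        model = GBLUP(y, K)
        fit = model.fit()
        best = model.loglik(fit.sigma2_a_star, fit.sigma2_eps)
        s2a_grid = np.linspace(1e-4, 4.0, 50)
        s2e_grid = np.linspace(1e-4, 4.0, 50)
        grid_max = max(model.loglik(a, e) for a in s2a_grid for e in s2e_grid)
        assert best >= grid_max - 1e-6

    def test_identity_kernel_is_confounded(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(50)
        with pytest.warns(RuntimeWarning):
            fit = GBLUP(y, identity_structure(50)).fit()
        assert fit.boundary
        total = fit.sigma2_a_star + fit.sigma2_eps
        assert total == pytest.approx(y.var(ddof=1), abs=1e-6)

    def test_kernel_scaling_moves_only_the_scaler(self, ld_markers):
        rng = np.random.default_rng(5)
        G = vanraden_g(ld_markers)
        F = np.linalg.cholesky(G.matrix + 1e-6 * np.eye(G.n))
        y = F @ rng.standard_normal(G.n) + rng.standard_normal(G.n)
        c = 3.5
        f1 = GBLUP(y, G).fit()
        f2 = GBLUP(y, CovStructure(c * G.matrix, kind="G")).fit()
        assert f2.sigma2_a_star == pytest.approx(f1.sigma2_a_star / c, rel=1e-6)
        assert f2.sigma2_eps == pytest.approx(f1.sigma2_eps, rel=1e-8)

    def test_invariant_to_constant_shift(self, ld_markers):
        rng = np.random.default_rng(6)
        G = vanraden_g(ld_markers)
        y = rng.standard_normal(G.n)
        f1 = GBLUP(y, G).fit()
        f2 = GBLUP(y + 57.0, G).fit()
        assert f2.sigma2_a_star == pytest.approx(f1.sigma2_a_star, abs=1e-8)
        assert f2.sigma2_eps == pytest.approx(f1.sigma2_eps, abs=1e-8)

    def test_asymmetric_kernel_rejected(self):
        K = np.eye(12)
        K[0, 1] = 0.5
        with pytest.raises(InvalidInputError):
            GBLUP(np.zeros(12), K)


class TestBlupAndPev:
    def test_hand_built_mme_inverse(self):
        """3-genotype instance checked against the explicit 4x4 MME solve."""
        y = np.array([1.0, -0.5, 2.0])
        n = 3
        K = np.eye(n)
        s2a = s2e = 1.0
        X = np.ones((n, 1))
        Z = np.eye(n)
        C = np.block([[X.T @ X / s2e, X.T @ Z / s2e],
                      [Z.T @ X / s2e, Z.T @ Z / s2e + np.linalg.inv(K) / s2a]])
        rhs = np.concatenate([X.T @ y / s2e, Z.T @ y / s2e])
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        a_mme = sol[1:]
        pev_mme = Cinv[1:, 1:]
        model = GBLUP(y, CovStructure(K), min_n=3)
        a_hat, pev = model._blup_pev(s2a, s2e)
        np.testing.assert_allclose(a_hat, a_mme - a_mme.mean(), atol=1e-10)
        np.testing.assert_allclose(pev, pev_mme, atol=1e-10)

    def test_zero_additive_variance_gives_zero_blups(self):
        model = GBLUP(np.arange(12.0), identity_structure(12))
        a_hat, pev = model._blup_pev(0.0, 1.0)
        assert np.all(a_hat == 0.0) and np.all(pev == 0.0)

    def test_vanishing_residual_removes_shrinkage(self):
        """No residual noise: BLUPs equal the centered response and the
        PEV of the centered effects vanishes (the raw Henderson PEV keeps
        one unit of uncertainty for the mean, confounded with the
        intercept, in its 11'/n component)."""
        n = 15
        rng = np.random.default_rng(8)
        y = rng.standard_normal(n)
        model = GBLUP(y, identity_structure(n), min_n=10)
        a_hat, pev = model._blup_pev(1.0, 1e-10)
        np.testing.assert_allclose(a_hat, y - y.mean(), atol=1e-4)
        Q = np.eye(n) - np.ones((n, n)) / n
        assert np.trace(Q @ pev @ Q) / n < 1e-6

    def test_henderson_identity_psd(self, ld_markers):
        """Cov(a_hat) = K s2a - PEV must be PSD with non-negative diagonal."""
        rng = np.random.default_rng(9)
        GN = normalize_gn(vanraden_g(ld_markers))
        y = rng.standard_normal(GN.n)
        fit = GBLUP(y, GN).fit()
        cov_ahat = fit.sigma2_a_star * GN.matrix - fit.pev()
        assert np.min(np.diag(cov_ahat)) >= -1e-8
        w = np.linalg.eigvalsh(0.5 * (cov_ahat + cov_ahat.T))
        assert w.min() >= -1e-8 * max(w.max(), 1.0)
        assert np.all(np.diag(fit.pev()) <= fit.sigma2_a_star
                      * np.diag(GN.matrix) + 1e-8)

    def test_more_information_shrinks_pev(self, ld_markers):
        """Halving the residual variance (doubling replication) cannot
        increase the average prediction error variance."""
        rng = np.random.default_rng(10)
        GN = normalize_gn(vanraden_g(ld_markers))
        y = rng.standard_normal(GN.n)
        model = GBLUP(y, GN)
        _, pev1 = model._blup_pev(1.0, 1.0)
        _, pev2 = model._blup_pev(1.0, 0.5)
        assert np.trace(pev2) <= np.trace(pev1) + 1e-8

    def test_accessor_rejects_unknown_term(self, ld_markers):
        rng = np.random.default_rng(12)
        fit = GBLUP(rng.standard_normal(ld_markers.n),
                    vanraden_g(ld_markers)).fit()
        with pytest.raises(InvalidInputError):
            blup_and_pev(fit, "dominance")


class TestBacksolve:
    def test_square_identity(self):
        a = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(backsolve_marker_effects(np.eye(3), a), a)

    def test_row_space_identity(self, rng):
        Z = rng.standard_normal((15, 40))
        w = rng.standard_normal(40)
        a = Z @ w
        beta = backsolve_marker_effects(Z, a)
        np.testing.assert_allclose(Z @ beta, a, atol=1e-8)

    def test_gblup_solutions_live_in_row_space(self, ld_markers):
        rng = np.random.default_rng(13)
        M = recode_minor_allele(ld_markers)
        Z = center_columns(M)
        G = vanraden_g(ld_markers)
        y = rng.standard_normal(G.n)
        fit = GBLUP(y, G).fit()
        a_hat = fit.blups()
        beta = backsolve_marker_effects(Z, a_hat)
        scale = np.linalg.norm(a_hat)
        assert np.linalg.norm(Z.values @ beta - a_hat) <= 1e-6 * max(scale, 1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidInputError):
            backsolve_marker_effects(np.eye(3), np.zeros(4))


class TestMultiLocation:
    def test_single_location_rejected(self, rng):
        lay = TrialDesign(10, 1, 3).layout()
        lay["value"] = rng.standard_normal(len(lay))
        with pytest.raises(InvalidInputError):
            MultiLocationLMM(lay, identity_structure(10))

    def test_parameter_recovery_identity_kernel(self):
        """Known (s2a=1, s2aL=0.5, s2eL=(1,2)) recovered within 3 MC SEs."""
        rng = np.random.default_rng(77)
        reps = 12
        des = TrialDesign(100, 2, 2)
        lay = des.layout()
        out = []
        for _ in range(reps):
            a = rng.normal(0, 1, 100)
            aL = rng.normal(0, np.sqrt(0.5), (100, 2))
            sd = np.where(lay["li"] == 0, 1.0, np.sqrt(2.0))
            lay2 = lay[["genotype", "location", "block"]].copy()
            lay2["value"] = (a[lay["gi"]] + aL[lay["gi"], lay["li"]]
                             + rng.standard_normal(len(lay)) * sd)
            fit = MultiLocationLMM(lay2, identity_structure(100)).fit()
            out.append([fit.reml_scalers["additive"],
                        fit.reml_scalers["axl:L0"], fit.reml_scalers["axl:L1"],
                        fit.residual_variances["L0"], fit.residual_variances["L1"]])
        out = np.asarray(out)
        for j, truth in enumerate((1.0, 0.5, 0.5, 1.0, 2.0)):
            mc_se = out[:, j].std(ddof=1) / np.sqrt(reps)
            assert abs(out[:, j].mean() - truth) < 3 * max(mc_se, 1e-3)

    def test_null_interaction_collapses_to_boundary(self):
        """With zero simulated interaction the aL scalers collapse to (or
        near) the zero boundary: a negligible share of the additive
        scaler in at least 80% of repetitions."""
        rng = np.random.default_rng(78)
        des = TrialDesign(60, 2, 3)
        lay = des.layout()
        at_boundary = 0
        reps = 8
        for _ in range(reps):
            a = rng.normal(0, 1, 60)
            lay2 = lay[["genotype", "location", "block"]].copy()
            lay2["value"] = a[lay["gi"]] + rng.standard_normal(len(lay))
            fit = MultiLocationLMM(lay2, identity_structure(60)).fit()
            axl = max(fit.reml_scalers["axl:L0"], fit.reml_scalers["axl:L1"])
            if axl < 0.15 * fit.reml_scalers["additive"]:
                at_boundary += 1
        assert at_boundary >= 0.8 * reps

    def test_blups_centered_and_pev_psd(self, ld_markers):
        rng = np.random.default_rng(79)
        n = ld_markers.n
        GN = normalize_gn(vanraden_g(ld_markers))
        des = TrialDesign(n, 2, 2)
        lay = des.layout()
        F = np.linalg.cholesky(GN.matrix + 1e-8 * np.eye(n))
        a = F @ rng.standard_normal(n)
        lay2 = lay[["genotype", "location", "block"]].copy()
        lay2["value"] = a[lay["gi"]] + rng.standard_normal(len(lay))
        fit = MultiLocationLMM(lay2, GN).fit()
        a_hat, pev = blup_and_pev(fit, "additive")
        assert abs(a_hat.mean()) < 1e-8
        assert np.min(np.diag(pev)) >= -1e-8
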