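import numpy as np
import pytest

from pevsim.esstats import MVNSpec, expected_sample_variance, generalized_sev
from pevsim.relmat import (CovStructure, InvalidInputError, compound_symmetry,
                           identity_structure, normalize_gn, vanraden_g)
from pevsim.simkit import (TargetVariances, TrialDesign, ess_term_sevs,
                           location_effects_from_axl, sample_marker_effects,
                           sample_variance_gamma, scale_to_target, simulate_axl,
                           simulate_ess, simulate_fixed, simulate_mvn)

TERMS = ("location", "block", "additive", "axl", "residual")


class TestTrialDesign:
    def test_layout_is_complete_rcbd(self):
        d = TrialDesign(4, 2, 3)
        lay = d.layout()
        assert len(lay) == d.n_plots == 24
        counts = lay.groupby(["location", "block"])["genotype"].nunique()
        assert (counts == 4).all()


class TestMarkerEffects:
    def test_gamma_magnitude_and_sign_moments(self):
        eff = sample_marker_effects(100_000, seed=0)
        assert np.abs(eff).mean() == pytest.approx(0.4 * 1.66, rel=0.02)
        sign_se = 1.0 / np.sqrt(100_000)
        assert abs(np.sign(eff).mean()) < 3 * sign_se

    def test_deterministic_under_seed(self):
        np.testing.assert_array_equal(sample_marker_effects(50, seed=9),
                                      sample_marker_effects(50, seed=9))

    def test_invalid_gamma_parameters(self):
        with pytest.raises(InvalidInputError):
            sample_marker_effects(10, shape=-1.0)


class TestScaleToTarget:
    def test_exact_sd(self):
        out = scale_to_target(np.array([1.0, 2.0, 3.0]), 2.0)
        assert np.std(out, ddof=1) == pytest.approx(2.0, abs=1e-12)

    def test_zero_target_gives_zero(self):
        np.testing.assert_array_equal(scale_to_target(np.arange(5.0), 0.0),
                                      np.zeros(5))

    def test_matrix_input_scaled_over_all_elements(self, rng):
        A = rng.standard_normal((6, 4))
        out = scale_to_target(A, 1.7)
        assert np.std(out, ddof=1) == pytest.approx(1.7, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(InvalidInputError):
            scale_to_target(np.ones(4), 1.0)


class TestAxL:
    def test_double_centered_output(self, rng, ke5):
        Ma = rng.standard_normal((10, 30))
        out = simulate_axl(Ma, 20, ke5, seed=rng)
        assert out.shape == (10, 5)
        assert np.max(np.abs(out.mean(axis=0))) < 1e-10
        assert np.max(np.abs(out.mean(axis=1))) < 1e-10

    def test_zero_marker_matrix(self, ke5):
        out = simulate_axl(np.zeros((8, 12)), 10, ke5, seed=0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_location_effects_are_column_means(self):
        raw = np.array([[1.0, 4.0], [1.0, 4.0], [1.0, 4.0]])
        np.testing.assert_allclose(location_effects_from_axl(raw), [1.0, 4.0])

    def test_centered_input_flagged_degenerate(self):
        with pytest.warns(RuntimeWarning):
            out = location_effects_from_axl(np.zeros((3, 2)))
        np.testing.assert_allclose(out, 0.0)


class TestGammaVarianceSampler:
    def test_zero_sev_is_degenerate(self):
        assert sample_variance_gamma(1.3, 0.0, seed=0) == 1.3

    def test_parameter_identities(self):
        sigma2, sev = 1.0, 0.3
        theta = sev**2 / sigma2
        k = sigma2**2 / sev**2
        assert theta * k == pytest.approx(sigma2)
        assert theta**2 * k == pytest.approx(sev**2)

    def test_moments(self):
        rng = np.random.default_rng(1)
        draws = np.array([sample_variance_gamma(1.0, 0.3, rng)
                          for _ in range(20_000)])
        mc = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 3 * mc
        # sd of the sd estimate via the fourth moment
        sd_se = draws.std() / np.sqrt(2 * draws.size) * np.sqrt(
            max(((draws - draws.mean())**4).mean() / draws.var()**2 - 1, 1.0))
        assert abs(draws.std(ddof=1) - 0.3) < 3 * max(sd_se, 5e-3)


class TestFixedStrategy:
    def test_realized_variances_equal_targets_exactly(self, ld_markers, targets):
        des = TrialDesign(ld_markers.n, 5, 3)
        ke = compound_symmetry(5, 0.3)
        sim = simulate_fixed(targets, ld_markers, ke, des, n_qtl=200, seed=4)
        for term in TERMS:
            assert sim.realized_variances[term] == pytest.approx(
                targets.target(term), abs=1e-10)

    def test_phenotype_is_sum_of_mapped_effects(self, ld_markers, targets):
        des = TrialDesign(ld_markers.n, 3, 2)
        ke = compound_symmetry(3, 0.3)
        sim = simulate_fixed(targets, ld_markers, ke, des, n_qtl=150, seed=5)
        lay = des.layout()
        gi, li, bi = (lay[c].to_numpy() for c in ("gi", "li", "bi"))
        y = (sim.effects["location"][li] + sim.effects["block"][li, bi]
             + sim.effects["additive"][gi] + sim.effects["axl"][gi, li]
             + sim.effects["residual"])
        np.testing.assert_allclose(sim.phenotype_vector(), y, atol=1e-12)

    def test_additive_values_are_marker_built(self, ld_markers, targets):
        des = TrialDesign(ld_markers.n, 2, 2)
        ke = compound_symmetry(2, 0.3)
        sim = simulate_fixed(targets, ld_markers, ke, des, n_qtl=100, seed=6)
        Mq = ld_markers.dosages[:, sim.effects["qtl"]].astype(float)
        np.testing.assert_allclose(Mq @ sim.effects["beta"],
                                   sim.effects["additive"], atol=1e-10)
        assert np.std(sim.effects["additive"], ddof=1) == pytest.approx(
            np.sqrt(targets.sigma2_a), abs=1e-10)

    def test_same_seed_reproduces_phenotypes(self, ld_markers, targets):
        des = TrialDesign(ld_markers.n, 2, 2)
        ke = compound_symmetry(2, 0.3)
        a = simulate_fixed(targets, ld_markers, ke, des, seed=7, n_qtl=100)
        b = simulate_fixed(targets, ld_markers, ke, des, seed=7, n_qtl=100)
        np.testing.assert_array_equal(a.phenotype_vector(), b.phenotype_vector())


class TestMVNStrategy:
    def test_all_zero_scalers_give_zero_phenotype(self, ld_markers):
        tg = TargetVariances(0.0, 0.0, 0.0, 0.0, 0.0)
        des = TrialDesign(ld_markers.n, 2, 2)
        sim = simulate_mvn(tg, vanraden_g(ld_markers),
                           compound_symmetry(2, 0.3), des, seed=1)
        np.testing.assert_allclose(sim.phenotype_vector(), 0.0, atol=1e-12)

    def test_identity_kernel_mean_realized_variance(self):
        """Realized additive variance under Sigma = I averages to the
        closed-form expected sample variance (= 1)."""
        rng = np.random.default_rng(2)
        n = 40
        tg = TargetVariances(0.0, 0.0, 1.0, 0.0, 0.0)
        des = TrialDesign(n, 2, 2)
        G = identity_structure(n)
        ke = compound_symmetry(2, 0.3)
        vals = [simulate_mvn(tg, G, ke, des, seed=rng).realized_variances["additive"]
                for _ in range(400)]
        vals = np.asarray(vals)
        mc = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 1.0) < 3 * mc

    def test_misscaled_kernel_misses_target(self, ld_markers):
        """With Sigma = G sigma2_a* the mean realized variance matches the
        closed form tr(centered Sigma)/(n-1), not the nominal target."""
        rng = np.random.default_rng(3)
        G = vanraden_g(ld_markers)
        n = G.n
        tg = TargetVariances(0.0, 0.0, 1.0, 0.0, 0.0)
        des = TrialDesign(n, 2, 2)
        ke = compound_symmetry(2, 0.3)
        vals = np.asarray(
            [simulate_mvn(tg, G, ke, des, seed=rng).realized_variances["additive"]
             for _ in range(400)])
        expect = expected_sample_variance(G.matrix)
        mc = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - expect) < 3 * mc
        assert abs(expect - 1.0) > 0.1  # the scaling mismatch being reproduced


class TestESSStrategy:
    def test_gn_based_sev_inputs(self, ld_markers, targets, ke5):
        GN = normalize_gn(vanraden_g(ld_markers))
        des = TrialDesign(ld_markers.n, 5, 3)
        sev = ess_term_sevs(targets, GN, ke5, des)
        direct = generalized_sev(MVNSpec.zero_mean(GN.matrix * targets.sigma2_a))
        assert sev["additive"] == pytest.approx(direct, rel=1e-12)
        # iid terms use the classical formula
        assert sev["block"] == pytest.approx(
            np.sqrt(2) * targets.sigma2_Block / np.sqrt(des.n_blocks - 1))

    def test_realized_variance_equals_sampled_target(self, ld_markers, targets, ke5):
        GN = normalize_gn(vanraden_g(ld_markers))
        des = TrialDesign(ld_markers.n, 5, 3)
        sim = simulate_ess(targets, ld_markers, GN, ke5, des, n_qtl=150, seed=8)
        assert sim.realized_variances["additive"] == pytest.approx(
            sim.sampled_targets["additive"], abs=1e-10)
        assert sim.realized_variances["axl"] == pytest.approx(
            sim.sampled_targets["axl"], abs=1e-10)

    def test_moments_across_reps(self, ld_markers, ke5):
        """Mean of realized additive variances ~ target; sd ~ SEV."""
        rng = np.random.default_rng(9)
        targets = TargetVariances()
        GN = normalize_gn(vanraden_g(ld_markers))
        des = TrialDesign(ld_markers.n, 5, 3)
        sevs = ess_term_sevs(targets, GN, ke5, des)
        vals = np.asarray([
            simulate_ess(targets, ld_markers, GN, ke5, des, n_qtl=150,
                         seed=rng, sevs=sevs).realized_variances["additive"]
            for _ in range(300)])
        mc = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - targets.sigma2_a) < 3 * mc
        # dispersion check against the intended SEV (batch MC SE)
        batches = vals.reshape(10, 30).std(ddof=1, axis=1)
        mc_sd = batches.std(ddof=1) / np.sqrt(10)
        assert abs(vals.std(ddof=1) - sevs["additive"]) < 4 * mc_sd

    def test_perfect_correlation_falls_back_to_fixed(self, ld_markers, targets):
        ones = CovStructure(np.ones((ld_markers.n, ld_markers.n)), kind="GN")
        des = TrialDesign(ld_markers.n, 2, 3)
        ke = compound_symmetry(2, 0.3)
        with pytest.warns(RuntimeWarning):
            sim = simulate_ess(targets, ld_markers, ones, ke, des,
                               n_qtl=150, seed=10)
        assert sim.sampled_targets["additive"] == targets.sigma2_a
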