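import numpy as np
import pytest

from straindecon import Hyperparameters, ModelParams, apply_error, predict_allele_freq
from straindecon.distributions import betabinom_log_pmf, betabinom_log_pmf_raw
from straindecon.model import (
    ParamTransform,
    PosteriorObjective,
    community_prior,
    error_prior,
    genotype_prior,
    log_likelihood,
    log_posterior,
    metacommunity_prior,
)
from straindecon.simulate import simulate


def random_params(rng, N, S, G) -> ModelParams:
    return ModelParams(
        pi=rng.dirichlet(np.ones(S), size=N),
        gamma=rng.uniform(0.05, 0.95, size=(S, G)),
        rho=rng.dirichlet(np.ones(S)),
        epsilon=rng.uniform(0.005, 0.1, size=N),
    )


class TestDeterministicStructure:
    def test_single_strain_passes_genotype_through(self):
        gamma = np.array([[0.1, 0.9, 0.5]])
        P = predict_allele_freq(np.array([[1.0]]), gamma)
        np.testing.assert_allclose(P, gamma)

    def test_even_mixture_of_opposite_alleles(self):
        P = predict_allele_freq(np.array([[0.5, 0.5]]), np.array([[0.0], [1.0]]))
        assert P[0, 0] == pytest.approx(0.5)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(4), size=3)
        gamma = rng.uniform(size=(4, 5))
        P = predict_allele_freq(pi, gamma)
        for i in range(3):
            for g in range(5):
                assert P[i, g] == pytest.approx(
                    sum(pi[i, s] * gamma[s, g] for s in range(4))
                )

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            predict_allele_freq(np.ones((2, 3)) / 3, np.ones((4, 5)))

    @pytest.mark.parametrize(
        "p,eps,expected", [(1.0, 0.01, 0.995), (0.5, 0.37, 0.5), (0.0, 0.01, 0.005)]
    )
    def test_error_transform_values(self, p, eps, expected):
        assert apply_error(np.array([[p]]), eps)[0, 0] == pytest.approx(expected)

    def test_error_transform_range(self):
        p = np.linspace(0, 1, 11)[None, :]
        out = apply_error(p, np.array([0.2]))
        assert out.min() >= 0.1 and out.max() <= 0.9


class TestLogPosterior:
    def test_equals_sum_of_component_terms(self, small_world):
        rng = np.random.default_rng(1)
        params = random_params(rng, 12, 3, 40)
        hyper = Hyperparameters()
        total = log_posterior(params, small_world.metagenotype, hyper)
        parts = (
            log_likelihood(params, small_world.metagenotype, hyper)
            + genotype_prior(params.gamma, hyper.gamma_star)
            + community_prior(params.pi, params.rho, hyper.pi_star)
            + metacommunity_prior(params.rho, hyper.rho_star)
            + error_prior(params.epsilon, hyper)
        )
        assert total == pytest.approx(parts)

    def test_likelihood_term_uses_betabinomial(self, small_world):
        # the model's raw lgamma expression agrees with the scipy-backed pmf
        rng = np.random.default_rng(2)
        params = random_params(rng, 12, 3, 40)
        hyper = Hyperparameters()
        mgt = small_world.metagenotype
        ptil = apply_error(predict_allele_freq(params.pi, params.gamma), params.epsilon)
        mask = mgt.total > 0
        expected = betabinom_log_pmf(
            mgt.alt[mask], mgt.total[mask], ptil[mask], hyper.alpha_star
        ).sum()
        raw = betabinom_log_pmf_raw(
            mgt.alt.astype(float), mgt.total.astype(float), ptil, hyper.alpha_star
        )[mask].sum()
        assert raw == pytest.approx(expected)
        assert log_likelihood(params, mgt, hyper) == pytest.approx(expected)

    def test_sparsity_direction_of_genotype_prior(self):
        # with gamma* < 1, ambiguous genotypes are less probable than sharp ones
        assert genotype_prior(np.array([[0.5]]), 0.1) < genotype_prior(
            np.array([[0.01]]), 0.1
        )

    def test_zero_depth_data_reduces_to_priors(self):
        from straindecon.metagenotype import Metagenotype

        mgt = Metagenotype(
            ["a", "b"], ["g1", "g2"], np.zeros((2, 2), int), np.zeros((2, 2), int)
        )
        rng = np.random.default_rng(3)
        params = random_params(rng, 2, 2, 2)
        hyper = Hyperparameters()
        assert log_likelihood(params, mgt, hyper) == 0.0
        assert log_posterior(params, mgt, hyper) == pytest.approx(
            genotype_prior(params.gamma, hyper.gamma_star)
            + community_prior(params.pi, params.rho, hyper.pi_star)
            + metacommunity_prior(params.rho, hyper.rho_star)
            + error_prior(params.epsilon, hyper)
        )

    def test_boundary_params_give_minus_inf(self, small_world):
        params = ModelParams(
            pi=np.full((12, 3), 1 / 3),
            gamma=np.zeros((3, 40)),  # boundary
            rho=np.ones(3) / 3,
            epsilon=np.full(12, 0.01),
        )
        assert log_posterior(params, small_world.metagenotype, Hyperparameters()) == -np.inf

    def test_likelihood_invariant_to_joint_strain_relabeling(self, small_world):
        rng = np.random.default_rng(4)
        params = random_params(rng, 12, 3, 40)
        hyper = Hyperparameters()
        perm = params.permute_strains([2, 0, 1])
        assert log_likelihood(params, small_world.metagenotype, hyper) == pytest.approx(
            log_likelihood(perm, small_world.metagenotype, hyper)
        )

    def test_large_concentration_approaches_binomial(self, small_world):
        from scipy.stats import binom

        rng = np.random.default_rng(5)
        params = random_params(rng, 12, 3, 40)
        mgt = small_world.metagenotype
        ptil = apply_error(predict_allele_freq(params.pi, params.gamma), params.epsilon)
        mask = mgt.total > 0
        ll = log_likelihood(params, mgt, Hyperparameters(alpha_star=1e8))
        ll_binom = binom.logpmf(mgt.alt[mask], mgt.total[mask], ptil[mask]).sum()
        assert ll == pytest.approx(ll_binom, rel=1e-4)


class TestParamTransform:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(6)
        params = random_params(rng, 5, 4, 7)
        tr = ParamTransform(5, 4, 7)
        back = tr.constrain(tr.unconstrain(params))
        np.testing.assert_allclose(back.pi, params.pi, atol=1e-8)
        np.testing.assert_allclose(back.gamma, params.gamma, atol=1e-8)
        np.testing.assert_allclose(back.rho, params.rho, atol=1e-8)
        np.testing.assert_allclose(back.epsilon, params.epsilon, atol=1e-8)

    def test_zero_vector_is_the_uniform_anchor(self):
        tr = ParamTransform(3, 4, 2)
        params = tr.constrain(np.zeros(tr.size))
        np.testing.assert_allclose(params.pi, 1 / 4)
        np.testing.assert_allclose(params.rho, 1 / 4)
        np.testing.assert_allclose(params.gamma, 0.5)
        np.testing.assert_allclose(params.epsilon, 0.5)

    def test_non_interior_params_rejected(self):
        tr = ParamTransform(2, 2, 2)
        params = ModelParams(
            pi=np.array([[1.0, 0.0], [0.5, 0.5]]),
            gamma=np.full((2, 2), 0.5),
            rho=np.array([0.5, 0.5]),
            epsilon=np.array([0.5, 0.5]),
        )
        with pytest.raises(ValueError):
            tr.unconstrain(params)

    def test_objective_gradient_matches_finite_differences(self):
        world = simulate(3, 5, 8, seed=2)
        hyper = Hyperparameters()
        obj = PosteriorObjective(world.metagenotype, hyper, 3)
        rng = np.random.default_rng(0)
        theta = rng.normal(scale=0.5, size=obj.transform.size)
        _, grad = obj.value_and_grad(theta, hyper.gamma_star, hyper.rho_star)
        h = 1e-6
        fd = np.empty_like(theta)
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd[i] = (
                obj.value_and_grad(tp, hyper.gamma_star, hyper.rho_star)[0]
                - obj.value_and_grad(tm, hyper.gamma_star, hyper.rho_star)[0]
            ) / (2 * h)
        rel = np.abs(grad - fd) / np.maximum(1e-8, np.abs(grad) + np.abs(fd))
        assert rel.max() < 1e-4

    def test_objective_is_deterministic(self, small_world):
        hyper = Hyperparameters()
        obj = PosteriorObjective(small_world.metagenotype, hyper, 3)
        theta = np.random.default_rng(8).normal(size=obj.transform.size)
        l1, g1 = obj.value_and_grad(theta, 0.5, 1.0)
        l2, g2 = obj.value_and_grad(theta, 0.5, 1.0)
        assert l1 == l2
        np.testing.assert_array_equal(g1, g2)


class TestHyperparameters:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            Hyperparameters(gamma_star=0.0)

    def test_epsilon_prior_orientations(self):
        default = Hyperparameters()
        a, b = default.epsilon_shapes()
        assert (a, b) == (1.5 * 0.01, 1.5)  # small-mean error-rate prior
        rev = Hyperparameters(epsilon_prior_orientation="reversed")
        assert rev.epsilon_shapes() == (1.5, 1.5 * 0.01)

    def test_simplex_tolerance_renormalizes_silently(self):
        pi = np.array([[0.5 + 4e-7, 0.5]])  # inside 1e-6 tolerance
        params = ModelParams(
            pi=pi, gamma=np.full((2, 3), 0.5), rho=np.array([0.5, 0.5]), epsilon=np.array([0.5])
        )
        assert params.pi.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            ModelParams(
                pi=np.array([[0.6, 0.5]]),
                gamma=np.full((2, 3), 0.5),
                rho=np.array([0.5, 0.5]),
                epsilon=np.array([0.5]),
            )
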