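"""Hierarchical likelihood, priors and the sampler target: oracles are direct
scipy density evaluations and central finite differences."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import binom, halfnorm, norm

import psifit as pf
from psifit.model import HierarchicalModel, batches_to_arrays


def make_coefs(**over):
    base = dict(
        coef_alpha_AT=-0.4, coef_alpha_AT_minus_T=-0.3, coef_alpha_AT_minus_A=-0.5,
        coef_beta_AT=0.3, coef_beta_AT_minus_T=-0.1, coef_beta_AT_minus_A=-0.35,
        coef_lambda=-4.0,
    )
    base.update(over)
    return pf.SubjectCoefficients(**base)


class TestAggregation:
    def test_same_key_collapses(self):
        df = pd.DataFrame(
            {"subject": [1, 1, 1], "condition": ["AT"] * 3, "x_cm": [0.5] * 3, "response": [1, 0, 1]}
        )
        (b,) = pf.aggregate_trials(df)
        assert (b.n, b.y) == (3, 2)

    def test_distinct_keys_pass_through(self):
        df = pd.DataFrame(
            {"subject": [1, 2, 1], "condition": ["AT", "T", "A"], "x_cm": [0.0, 0.5, 1.0], "response": [1, 0, 1]}
        )
        batches = pf.aggregate_trials(df)
        assert len(batches) == 3 and all(b.n == 1 for b in batches)

    def test_trial_count_preserved_against_recount(self, small_experiment):
        trials, _, _ = small_experiment
        batches = pf.aggregate_trials(trials)
        # independent recount with a hash map
        counts = {}
        for row in trials.itertuples(index=False):
            counts[(row.subject, row.condition, row.x_cm)] = counts.get(
                (row.subject, row.condition, row.x_cm), 0
            ) + 1
        assert len(batches) == len(counts) < len(trials)
        assert sum(b.n for b in batches) == len(trials)

    def test_mixed_experiments_rejected(self):
        df = pd.DataFrame(
            {"subject": [1, 1], "condition": ["AT", "AT"], "x_cm": [0, 0], "response": [1, 0],
             "experiment": [1, 2]}
        )
        with pytest.raises(ValueError, match="experiment"):
            pf.aggregate_trials(df)


class TestLogLikelihood:
    def test_single_bernoulli(self):
        b = pf.StimulusBatch(0, pf.ConditionFlags.from_label("AT"), x=-0.4, n=1, y=1)
        # at x == alpha the response probability is exactly 0.5
        assert pf.log_likelihood([b], [make_coefs()]) == pytest.approx(np.log(0.5))

    def test_binomial_pmf_oracle(self):
        coefs = make_coefs()
        params = pf.assemble_params(coefs, pf.ConditionFlags.from_label("T"))
        x = 0.8
        p = pf.response_probability(params, x)
        b = pf.StimulusBatch(0, pf.ConditionFlags.from_label("T"), x=x, n=10, y=3)
        assert pf.log_likelihood([b], [coefs]) == pytest.approx(binom.logpmf(3, 10, p), rel=1e-12)

    def test_empty_batches(self):
        assert pf.log_likelihood([], [make_coefs()]) == 0.0

    def test_aggregated_equals_trial_level(self, small_experiment):
        trials, truth, _ = small_experiment
        coefs = np.array(
            [[truth["subjects"][str(k)][f] for f in pf.FAMILIES] for k in range(4)]
        )
        agg = pf.aggregate_trials(trials)
        subj_order = {s: i for i, s in enumerate(pd.unique(trials["subject"]))}
        flat = [
            pf.StimulusBatch(
                subject_index=subj_order[row.subject],
                flags=pf.ConditionFlags.from_label(row.condition),
                x=float(row.x_cm), n=1, y=int(row.response),
            )
            for row in trials.itertuples(index=False)
        ]
        assert all(b.n == 1 for b in flat)
        from scipy.special import gammaln

        def binom_const(bs):
            return sum(
                float(gammaln(b.n + 1) - gammaln(b.y + 1) - gammaln(b.n - b.y + 1)) for b in bs
            )

        ll_agg = pf.log_likelihood(agg, coefs) - binom_const(agg)
        ll_flat = pf.log_likelihood(flat, coefs) - binom_const(flat)
        assert ll_agg == pytest.approx(ll_flat, abs=1e-10)


class TestLogPrior:
    def spec(self):
        return pf.HyperpriorSpec.for_experiment(1)

    def test_no_subjects_leaves_hyperprior_terms(self):
        spec = self.spec()
        pop = pf.PopulationParams(mu=spec.mu_loc, sigma=0.5 * spec.sigma_scale)
        expected = float(
            np.sum(norm.logpdf(pop.mu, spec.mu_loc, spec.mu_scale))
            + np.sum(halfnorm.logpdf(pop.sigma, scale=spec.sigma_scale))
        )
        assert pf.log_prior(pop, np.empty((0, 7)), spec) == pytest.approx(expected, rel=1e-12)

    def test_subject_at_population_mean(self):
        spec = self.spec()
        sigma = np.full(7, 0.5)
        pop = pf.PopulationParams(mu=spec.mu_loc, sigma=sigma)
        base = pf.log_prior(pop, np.empty((0, 7)), spec)
        lp = pf.log_prior(pop, spec.mu_loc[None, :], spec)
        # each coefficient at its mean contributes the normal mode density
        assert lp - base == pytest.approx(float(np.sum(-np.log(sigma * np.sqrt(2 * np.pi)))), rel=1e-12)

    def test_full_density_sum_oracle(self):
        spec = self.spec()
        rng = np.random.default_rng(3)
        pop = pf.PopulationParams(mu=rng.normal(size=7), sigma=rng.uniform(0.2, 1.0, 7))
        C = rng.normal(size=(3, 7))
        expected = float(
            np.sum(norm.logpdf(pop.mu, spec.mu_loc, spec.mu_scale))
            + np.sum(halfnorm.logpdf(pop.sigma, scale=spec.sigma_scale))
            + np.sum(norm.logpdf(C, pop.mu[None], pop.sigma[None]))
        )
        assert pf.log_prior(pop, C, spec) == pytest.approx(expected, rel=1e-12)

    def test_hyperprior_is_proper(self):
        """Each family's hyperprior density integrates to 1 (normal x half-normal)."""
        spec = self.spec()
        for i in (0, 3, 6):
            zmu, _ = integrate.quad(
                lambda v: np.exp(norm.logpdf(v, spec.mu_loc[i], spec.mu_scale[i])), -30, 30
            )
            zsd, _ = integrate.quad(
                lambda v: np.exp(halfnorm.logpdf(v, scale=spec.sigma_scale[i])), 0, 30
            )
            assert zmu == pytest.approx(1.0, abs=1e-8)
            assert zsd == pytest.approx(1.0, abs=1e-8)

    def test_experiment_specs_differ_only_in_range(self):
        d1 = pf.HyperpriorSpec.for_experiment(1).to_dict()
        d2 = pf.HyperpriorSpec.for_experiment(2).to_dict()
        assert d1.pop("stimulus_range_cm") == 2.0 and d2.pop("stimulus_range_cm") == 3.0
        assert d1.pop("experiment") == 1 and d2.pop("experiment") == 2
        assert d1 == d2  # the hyperprior table itself is identical


class TestLogPosterior:
    def test_sum_of_parts_and_support(self, small_experiment):
        trials, truth, _ = small_experiment
        spec = pf.HyperpriorSpec.for_experiment(2)
        batches = pf.aggregate_trials(trials)
        C = np.array([[truth["subjects"][str(k)][f] for f in pf.FAMILIES] for k in range(4)])
        pop = pf.PopulationParams(
            mu=np.array([truth["population"]["mu"][f] for f in pf.FAMILIES]),
            sigma=np.array([truth["population"]["sigma"][f] for f in pf.FAMILIES]),
        )
        lp = pf.log_posterior(batches, pop, C, spec)
        assert lp == pytest.approx(pf.log_prior(pop, C, spec) + pf.log_likelihood(batches, C))
        bad = pf.PopulationParams(mu=pop.mu, sigma=pop.sigma.copy())
        object.__setattr__(bad, "sigma", pop.sigma * np.array([1, 1, 1, 1, 1, 1, 0]))
        assert pf.log_prior(bad, C, spec) == -np.inf

    def test_gradient_matches_finite_differences(self, small_experiment):
        trials, _, _ = small_experiment
        spec = pf.HyperpriorSpec.for_experiment(2)
        model = HierarchicalModel(pf.aggregate_trials(trials), spec)
        rng = np.random.default_rng(0)
        q = model.initial_point(rng) + 0.3 * rng.standard_normal(model.dim)
        _, g = model.logp_grad(q)
        eps = 1e-6
        for i in rng.choice(model.dim, size=20, replace=False):
            e = np.zeros(model.dim)
            e[i] = eps
            gn = (model.logp(q + e) - model.logp(q - e)) / (2 * eps)
            assert g[i] == pytest.approx(gn, rel=1e-5, abs=1e-7)

    def test_noncentered_matches_centered_density_up_to_reparam(self, small_experiment):
        """The sampler target equals the centered joint plus the exact change-of-variables terms."""
        trials, _, _ = small_experiment
        spec = pf.HyperpriorSpec.for_experiment(2)
        batches = pf.aggregate_trials(trials)
        model = HierarchicalModel(batches, spec)
        rng = np.random.default_rng(1)
        q = model.initial_point(rng) + 0.2 * rng.standard_normal(model.dim)
        mu, log_sigma, z = model.unpack(q)
        sigma = np.exp(log_sigma)
        C = model.coefs(q)
        pop = pf.PopulationParams(mu=mu, sigma=sigma)
        lp_centered = pf.log_posterior(batches, pop, C, spec)
        # z-density vs coef-density: N(z; 0, 1) = N(coef; mu, sigma) * sigma per coordinate
        jac_z = model.K * float(np.sum(np.log(sigma)))
        # sampling log sigma adds the + log sigma change-of-variables term per family
        jac_s = float(np.sum(log_sigma))
        lp_model, _ = model.logp_grad(q)
        assert lp_model == pytest.approx(lp_centered + jac_z + jac_s, rel=1e-10)
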