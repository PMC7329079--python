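"""Mirror-Metropolis and TMVN Gibbs samplers against closed forms and oracles."""

import numpy as np
import pytest
from scipy import stats

import fluxpolytope as fp
from fluxpolytope.stochastic_samplers import (
    MeasurementSet,
    TMVNSpec,
    _mirror_into,
    build_tmvn_posterior,
    default_jump_lengths,
    gibbs_tmvn_sample,
    mirror_sample,
)
from fluxpolytope.synthetic_data import make_box_polytope, rejection_tmvn


def _spec(mu, C, lb, ub):
    C = np.atleast_2d(np.asarray(C, float))
    return TMVNSpec(
        mu=np.atleast_1d(np.asarray(mu, float)),
        C=C,
        L=np.linalg.cholesky(C),
        v_lb=np.atleast_1d(np.asarray(lb, float)),
        v_ub=np.atleast_1d(np.asarray(ub, float)),
    )


class TestMirror:
    def test_single_reflection_exact(self):
        # violating u <= 1 by 0.3 mirrors to 0.7
        A = np.array([[1.0], [-1.0]])
        b = np.array([1.0, 0.0])
        out = _mirror_into(A, b, np.array([1.3]))
        assert out[0] == pytest.approx(0.7)

    def test_double_reflection_sequence(self):
        A = np.array([[1.0], [-1.0]])
        b = np.array([1.0, 0.0])
        # 2.5 -> mirror at 1 gives -0.5 -> mirror at 0 gives 0.5
        out = _mirror_into(A, b, np.array([2.5]))
        assert out[0] == pytest.approx(0.5)

    def test_uniform_moments_without_measurements(self):
        poly, truth = make_box_polytope([1.0, 1.0])
        chain = mirror_sample(poly, meas=None, M=8000, thinning=2, seed=13)
        se_mean = np.sqrt(1.0 / 12 / 8000)
        assert np.all(np.abs(chain.samples.mean(0) - truth.mean) < 4 * se_mean)
        np.testing.assert_allclose(chain.samples.var(0, ddof=1), truth.var, rtol=0.1)

    def test_truncated_normal_target_matches_closed_form(self):
        # 1-D u on [-1, 1], one measurement v = u with value b and noise sigma
        poly, _ = make_box_polytope([2.0])
        # shift box [0,2] to represent u in [-1,1] via measurement on the flux itself
        meas = MeasurementSet(a=np.array([1.0]), b=np.array([1.2]), sigma2=np.array([0.25]))
        chain = mirror_sample(poly, meas=meas, jump=0.8, M=20000, thinning=2, seed=17)
        a, bnd = (0.0 - 1.2) / 0.5, (2.0 - 1.2) / 0.5
        target_mean = stats.truncnorm.mean(a, bnd, loc=1.2, scale=0.5)
        target_sd = stats.truncnorm.std(a, bnd, loc=1.2, scale=0.5)
        se = target_sd / np.sqrt(fp.ess(chain.samples[:, 0]))
        assert abs(chain.samples[:, 0].mean() - target_mean) < 3.5 * se

    def test_agrees_with_hr_when_uniform(self):
        poly, _ = make_box_polytope([1.0, 3.0])
        mirror = mirror_sample(poly, M=5000, thinning=2, seed=19)
        hr = fp.hr_sample(poly, M=5000, thinning=2, seed=20)
        for j in range(2):
            _, p = stats.ks_2samp(mirror.samples[:, j], hr.samples[:, j])
            assert p > 0.01

    def test_reflection_cap_abort(self):
        poly, _ = make_box_polytope([1e-6])
        with pytest.raises(RuntimeError, match="jump lengths"):
            mirror_sample(poly, jump=1e6, M=200, thinning=1, seed=23)

    def test_seed_reproducibility(self):
        poly, _ = make_box_polytope([1.0, 1.0])
        a = mirror_sample(poly, M=100, seed=3)
        b = mirror_sample(poly, M=100, seed=3)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_default_jump_lengths(self):
        lengths = default_jump_lengths(np.array([0.0, -2.0]), np.array([4.0, 2.0]))
        np.testing.assert_allclose(lengths, [2.0, 2.0])
        np.testing.assert_allclose(
            default_jump_lengths(np.zeros(2), np.ones(2), scale=0.01), [0.01, 0.01]
        )


class TestPosterior:
    def test_prior_only_scalar(self):
        model = fp.MetabolicModel(
            S=np.zeros((1, 1)),
            v_lb=np.array([-np.inf]),
            v_ub=np.array([np.inf]),
            reaction_ids=["r"],
            metabolite_ids=["m"],
        )
        spec = build_tmvn_posterior(model, gamma=1.0, prior_var=np.array([1.0]))
        assert spec.mu[0] == pytest.approx(0.0)
        assert spec.C[0, 0] == pytest.approx(1.0)

    def test_two_flux_closed_form(self, two_flux_model):
        # 2x2 inverse of diag(1/p) + S' S / gamma for S = [1, -1]
        g, p = 1e-4, 25.0
        spec = build_tmvn_posterior(two_flux_model, gamma=g, prior_var=np.full(2, p))
        prec = np.array([[1 / p + 1 / g, -1 / g], [-1 / g, 1 / p + 1 / g]])
        np.testing.assert_allclose(spec.C, np.linalg.inv(prec), rtol=1e-10)
        np.testing.assert_allclose(spec.mu, 0.0, atol=1e-12)
        corr = spec.C[0, 1] / np.sqrt(spec.C[0, 0] * spec.C[1, 1])
        assert corr > 0.999

    def test_correlation_tightens_as_gamma_shrinks(self, two_flux_model):
        corrs = []
        for g in (1e-2, 1e-4, 1e-6):
            spec = build_tmvn_posterior(two_flux_model, gamma=g, prior_var=np.full(2, 25.0))
            corrs.append(spec.C[0, 1] / np.sqrt(spec.C[0, 0] * spec.C[1, 1]))
        assert corrs[0] < corrs[1] < corrs[2]

    def test_prior_mean_closest_to_zero_in_bounds(self):
        model = fp.synthetic_data.make_two_flux_model(lb=(2.0, 2.0), ub=(10.0, 10.0))
        spec = build_tmvn_posterior(model, gamma=1e6, prior_var=np.full(2, 1e-6))
        # with a dominant prior, the posterior mean sits at the prior mean = 2
        np.testing.assert_allclose(spec.mu, 2.0, atol=1e-3)

    def test_measurement_shifts_mean(self, two_flux_model):
        meas = MeasurementSet(
            a=np.array([1.0, 0.0]), b=np.array([5.0, 0.0]), sigma2=np.array([0.01, 1.0])
        )
        spec = build_tmvn_posterior(two_flux_model, meas=meas, gamma=1e-4, prior_var=np.full(2, 1e4))
        assert spec.mu[0] == pytest.approx(5.0, abs=0.1)
        assert spec.mu[1] == pytest.approx(5.0, abs=0.1)  # coupled through Sv~0


class TestGibbs:
    def test_unconstrained_standard_normal(self):
        spec = _spec(0.0, 1.0, -np.inf, np.inf)
        chain = gibbs_tmvn_sample(spec, M=5000, seed=29)
        x = chain.samples[:, 0]
        assert abs(x.mean()) < 3 * (1 / np.sqrt(5000))
        assert abs(x.var(ddof=1) - 1.0) < 3 * np.sqrt(2 / 5000)

    def test_half_normal_mean(self):
        spec = _spec(0.0, 1.0, 0.0, np.inf)
        chain = gibbs_tmvn_sample(spec, M=8000, seed=31)
        x = chain.samples[:, 0]
        target = np.sqrt(2 / np.pi)
        sd = np.sqrt(1 - 2 / np.pi)
        assert abs(x.mean() - target) < 3 * sd / np.sqrt(8000)

    def test_correlated_2d_matches_rejection_oracle(self):
        C = np.array([[1.0, 0.6], [0.6, 1.0]])
        spec = _spec([0.2, -0.1], C, [-1.0, -1.5], [1.5, 1.0])
        gibbs = gibbs_tmvn_sample(spec, M=12000, seed=37)
        oracle = rejection_tmvn(spec, M=50000, seed=38)
        for j in range(2):
            se = oracle[:, j].std() / np.sqrt(12000 / 3)  # sweeps are correlated
            assert abs(gibbs.samples[:, j].mean() - oracle[:, j].mean()) < 3.5 * se
            assert abs(gibbs.samples[:, j].std() - oracle[:, j].std()) < 0.05

    def test_samples_respect_bounds_exactly(self):
        spec = _spec([0.0, 0.0], np.eye(2), [-0.5, -0.5], [0.5, 0.5])
        chain = gibbs_tmvn_sample(spec, M=2000, seed=41)
        assert chain.samples.min() >= -0.5 and chain.samples.max() <= 0.5

    def test_steady_state_concentration_as_gamma_vanishes(self, two_flux_model):
        g = 1e-8
        spec = build_tmvn_posterior(two_flux_model, gamma=g, prior_var=np.full(2, 25.0))
        chain = gibbs_tmvn_sample(spec, M=3000, seed=43)
        diff_sd = np.std(chain.samples[:, 0] - chain.samples[:, 1])
        assert diff_sd < 10 * np.sqrt(g)

    def test_shrinkage_monotone_in_prior_variance(self):
        # informative prior at m0=0 pulls the mean of a measured flux toward 0
        model = fp.MetabolicModel(
            S=np.zeros((1, 1)),
            v_lb=np.array([-100.0]),
            v_ub=np.array([100.0]),
            reaction_ids=["r"],
            metabolite_ids=["m"],
        )
        meas = MeasurementSet(a=np.array([1.0]), b=np.array([4.0]), sigma2=np.array([1.0]))
        means = []
        for pv in (8.0, 4.0, 2.0, 1.0):
            spec = build_tmvn_posterior(model, meas=meas, gamma=1.0, prior_var=np.array([pv]))
            chain = gibbs_tmvn_sample(spec, M=4000, seed=47)
            means.append(abs(chain.samples.mean()))
        assert means[0] > means[1] > means[2] > means[3]

    def test_seed_reproducibility(self):
        spec = _spec([0.0, 0.0], np.eye(2), [-1.0, -1.0], [1.0, 1.0])
        a = gibbs_tmvn_sample(spec, M=100, seed=7)
        b = gibbs_tmvn_sample(spec, M=100, seed=7)
        np.testing.assert_array_equal(a.samples, b.samples)
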