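"""Tests of the SMMALA + Gibbs sampler and the Raftery-Lewis diagnostic."""

import numpy as np
import pytest
from scipy import stats

from pkdeconv.inference import (
    Dataset,
    NoiseModel,
    PosteriorEval,
    assemble_posterior,
    likelihood_eval,
)
from pkdeconv.input_prior import build_kl_basis, penalty_energy
from pkdeconv.sampler import (
    RafteryLewisError,
    SamplerConfig,
    gibbs_update_lambda,
    raftery_lewis,
    run_mcmc,
    smmala_step,
    split_rhat,
)
from pkdeconv.synthetic_data import generate_dataset, make_schedule


def gaussian_target(cov_inv):
    """PosteriorEval factory for a zero-mean Gaussian with precision cov_inv."""

    def eval_fn(x):
        grad = -cov_inv @ x
        value = 0.5 * float(x @ grad)
        return PosteriorEval(value, grad, cov_inv, value, np.empty(0))

    return eval_fn


def run_chain(eval_fn, x0, n, eps, rng):
    x = np.asarray(x0, dtype=float)
    ev = eval_fn(x)
    out = np.empty((n, x.size))
    n_acc = 0
    for i in range(n):
        x, ev, acc = smmala_step(x, ev, eval_fn, eps, rng)
        out[i] = x
        n_acc += acc
    return out, n_acc / n


class TestSmmalaStep:
    def test_standard_gaussian_moments(self, rng):
        """On a standard Gaussian target with the identity metric the chain
        must recover mean 0 and identity covariance."""
        dim = 5
        eval_fn = gaussian_target(np.eye(dim))
        draws, acc = run_chain(eval_fn, np.zeros(dim), 50_000, 1.4, rng)
        assert 0.3 < acc < 0.95
        # Monte-Carlo standard error via batch means (100 batches)
        batches = draws.reshape(100, -1, dim).mean(axis=1)
        mc_se = batches.std(axis=0, ddof=1) / np.sqrt(100)
        assert np.all(np.abs(draws.mean(axis=0)) < 3 * mc_se)
        cov = np.cov(draws.T)
        assert np.max(np.abs(cov - np.eye(dim))) < 0.05

    def test_correlated_gaussian_uses_metric(self, rng):
        """With the exact precision as metric, a strongly correlated target
        is still sampled with near-unit efficiency per dimension."""
        prec = np.array([[2.0, 1.8], [1.8, 2.0]])
        eval_fn = gaussian_target(prec)
        draws, acc = run_chain(eval_fn, np.zeros(2), 30_000, 1.4, rng)
        target_cov = np.linalg.inv(prec)
        assert np.max(np.abs(np.cov(draws.T) - target_cov)
                      / np.abs(target_cov)) < 0.10

    def test_small_step_accepts_almost_always(self, rng):
        eval_fn = gaussian_target(np.eye(3))
        _, acc = run_chain(eval_fn, np.ones(3), 300, 1e-3, rng)
        assert acc > 0.98

    def test_deterministic_replay(self):
        eval_fn = gaussian_target(np.eye(3))
        d1, _ = run_chain(eval_fn, np.zeros(3), 200, 0.8,
                          np.random.default_rng(7))
        d2, _ = run_chain(eval_fn, np.zeros(3), 200, 0.8,
                          np.random.default_rng(7))
        np.testing.assert_array_equal(d1, d2)

    def test_nonfinite_proposal_value_rejected(self, rng):
        calls = {"n": 0}

        def eval_fn(x):
            calls["n"] += 1
            if calls["n"] > 1:
                return PosteriorEval(-np.inf, np.zeros(2), np.eye(2), -np.inf,
                                     np.empty(0))
            return PosteriorEval(0.0, np.zeros(2), np.eye(2), 0.0, np.empty(0))

        x0 = np.zeros(2)
        ev = eval_fn(x0)
        x, ev_out, acc = smmala_step(x0, ev, eval_fn, 0.5, rng)
        assert not acc
        np.testing.assert_array_equal(x, x0)


class TestGibbsLambda:
    def test_null_space_coefficients_give_prior_conditional(self, long_basis,
                                                            rng):
        """c confined to the null space: the conditional is Gamma(alpha +
        r/2, beta) exactly (zero penalty energy)."""
        alpha, beta = 1e-3, 1e-3
        r = long_basis.n_basis - long_basis.n_null
        c = np.zeros(long_basis.n_basis)
        c[0], c[1] = 30.0, -5.0
        draws = np.array([
            gibbs_update_lambda(c, long_basis, alpha, beta, rng)
            for _ in range(10_000)
        ])
        ks = stats.kstest(draws, stats.gamma(a=alpha + r / 2,
                                             scale=1 / beta).cdf)
        assert ks.pvalue > 0.01

    def test_conditional_mean_and_distribution(self, long_basis, rng):
        """At fixed c the draws must match Gamma(alpha + r/2, beta +
        energy/2): mean within 2% at 10k draws and KS p > 0.01."""
        alpha, beta = 1e-3, 1e-3
        r = long_basis.n_basis - long_basis.n_null
        c = rng.standard_normal(long_basis.n_basis) * 1e-3
        energy = penalty_energy(long_basis, c)
        shape, rate = alpha + r / 2, beta + energy / 2
        draws = np.array([
            gibbs_update_lambda(c, long_basis, alpha, beta, rng)
            for _ in range(10_000)
        ])
        assert draws.mean() == pytest.approx(shape / rate, rel=0.02)
        ks = stats.kstest(draws, stats.gamma(a=shape, scale=1 / rate).cdf)
        assert ks.pvalue > 0.01


class TestRafteryLewis:
    def test_iid_chain_matches_analytic_floor(self, rng):
        """For an iid chain the required N equals the closed-form floor
        N_min = ceil(z^2 q(1-q)/r^2); q=0.025, r=0.02, s=0.95 gives 235."""
        chain = rng.standard_normal(20_000)
        res = raftery_lewis(chain, q=[0.025], r=[0.02], s=0.95)
        entry = res["q=0.025"]
        assert entry["n_min"] == 235
        assert abs(entry["required_n"] - entry["n_min"]) \
            < 0.2 * entry["n_min"]

    def test_constant_chain_is_degenerate(self):
        with pytest.raises(RafteryLewisError):
            raftery_lewis(np.full(5000, 3.14), q=[0.5], r=[0.06])

    def test_short_chain_rejected(self, rng):
        with pytest.raises(RafteryLewisError, match="pilot"):
            raftery_lewis(rng.standard_normal(50), q=[0.025], r=[0.02])

    def test_thinned_correlated_chain_near_iid_floor(self, rng):
        """An AR(1) chain thinned to independence must require close to the
        iid floor."""
        n = 200_000
        rho = 0.8
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * eps[i]
        thinned = x[::30]  # autocorrelation 0.8^30 ~ 1e-3
        res = raftery_lewis(thinned, q=[0.025], r=[0.02], s=0.95)
        entry = res["q=0.025"]
        assert abs(entry["required_n"] - entry["n_min"]) \
            < 0.2 * entry["n_min"]

    def test_default_quantile_battery(self, rng):
        res = raftery_lewis(rng.standard_normal(20_000))
        assert set(k for k in res if k.startswith("q=")) == {
            "q=0.025", "q=0.25", "q=0.5", "q=0.75", "q=0.975"}
        assert res["max_required_n"] > 0


@pytest.fixture(scope="module")
def sparse_long_run(pk_params, input_params):
    ds, _ = generate_dataset(input_params, make_schedule("long", "sparse"),
                             pk_params, noise=None, seed=11)
    basis = build_kl_basis(ds.times[0], ds.times[-1], 120, 20)
    cfg = SamplerConfig(n_samples=1200, seed=5)
    return ds, basis, run_mcmc(ds, basis, pk_params, NoiseModel(), cfg)


class TestRunMcmc:
    def test_shapes_and_metadata(self, sparse_long_run):
        ds, basis, samples = sparse_long_run
        assert samples.coeff.shape == (960, 20)   # 1200 minus 20% burn-in
        assert samples.lam.shape == (960,)
        assert np.all(samples.lam > 0)
        assert samples.mode == "steady_state"
        assert 0.01 < samples.acceptance_rate <= 1.0

    def test_posterior_tracks_truth(self, sparse_long_run, input_params):
        """The posterior mean input must lie close to the truth on the bulk
        of the grid for clean sparse data (loose end-to-end sanity check)."""
        from pkdeconv.postprocess import rmse_vs_truth
        from pkdeconv.synthetic_data import test_input as true_input

        ds, basis, samples = sparse_long_run
        rmse = rmse_vs_truth(samples, basis,
                             lambda t: true_input(t, input_params),
                             units="pmol/week")
        assert rmse < 150.0  # truth peaks at ~540 pmol/week

    def test_deterministic_replay(self, pk_params, input_params):
        ds, _ = generate_dataset(input_params, make_schedule("long", "sparse"),
                                 pk_params, noise=None, seed=11)
        basis = build_kl_basis(ds.times[0], ds.times[-1], 80, 12)
        cfg = SamplerConfig(n_samples=150, seed=42, compute_raftery=False)
        s1 = run_mcmc(ds, basis, pk_params, NoiseModel(), cfg)
        s2 = run_mcmc(ds, basis, pk_params, NoiseModel(), cfg)
        np.testing.assert_array_equal(s1.coeff, s2.coeff)
        np.testing.assert_array_equal(s1.lam, s2.lam)

    def test_prior_only_chain_energy(self, pk_params, long_basis):
        """With no data and lam fixed, the chain samples the prior: the
        penalized second-derivative energy averages r/lam."""
        empty = Dataset(times=np.empty(0), conc=np.empty(0), timescale="long")
        lam = 2.0
        cfg = SamplerConfig(n_samples=6000, seed=3, sample_lambda=False,
                            lam_init=lam, step_size=1.0,
                            compute_raftery=False)
        samples = run_mcmc(empty, long_basis, pk_params, NoiseModel(), cfg)
        energies = np.array([penalty_energy(long_basis, c)
                             for c in samples.coeff])
        r = long_basis.n_basis - long_basis.n_null
        # mean of chi2_r/lam is r/lam; allow generous MCMC error
        assert energies.mean() == pytest.approx(r / lam, rel=0.25)

    def test_conjugate_linear_model_posterior(self, rng):
        """Quadratic log-target = Bayesian linear model with known noise and
        known lam: the SMMALA chain must reproduce the analytic Gaussian
        posterior moments."""
        n_obs, dim = 30, 4
        x = rng.standard_normal((n_obs, dim))
        beta_true = np.array([1.0, -0.5, 0.2, 0.0])
        sigma = 0.3
        y = x @ beta_true + sigma * rng.standard_normal(n_obs)
        lam = 2.0
        prec = x.T @ x / sigma ** 2 + lam * np.eye(dim)
        mean = np.linalg.solve(prec, x.T @ y / sigma ** 2)

        def eval_fn(b):
            resid = b - mean
            grad = -prec @ resid
            value = 0.5 * float(resid @ grad)
            return PosteriorEval(value, grad, prec, value, np.empty(0))

        draws, acc = run_chain(eval_fn, mean.copy(), 40_000, 1.4, rng)
        batches = draws.reshape(100, -1, dim).mean(axis=1)
        mc_se = batches.std(axis=0, ddof=1) / np.sqrt(100)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 3 * mc_se)
        cov = np.cov(draws.T)
        target_cov = np.linalg.inv(prec)
        assert np.max(np.abs(cov - target_cov)) < 0.10 * np.max(target_cov)

    def test_robustness_to_gross_outlier(self, pk_params, input_params):
        """One gross outlier in the data: the t4 likelihood must give a fit
        closer to the clean-data truth than the Gaussian likelihood."""
        from pkdeconv.postprocess import rmse_vs_truth
        from pkdeconv.synthetic_data import test_input as true_input

        ds, _ = generate_dataset(input_params, make_schedule("long", "sparse"),
                                 pk_params, noise=None, seed=21)
        conc = ds.conc.copy()
        conc[4] *= 5.0  # gross outlier at week 4
        ds_out = Dataset(times=ds.times, conc=conc, timescale="long")
        basis = build_kl_basis(ds.times[0], ds.times[-1], 120, 20)
        truth = lambda t: true_input(t, input_params)
        rmses = {}
        for family in ("student_t", "gaussian"):
            cfg = SamplerConfig(n_samples=1500, seed=9,
                                compute_raftery=False)
            samples = run_mcmc(ds_out, basis, pk_params,
                               NoiseModel(family=family), cfg)
            rmses[family] = rmse_vs_truth(samples, basis, truth,
                                          units="pmol/week")
        assert rmses["student_t"] < rmses["gaussian"]

    def test_basis_column_permutation_equivariance(self, pk_params,
                                                   input_params, rng):
        """Permuting basis columns (with their eigenvalues) permutes the
        gradient and conjugates the metric, leaving the posterior value
        unchanged -- the sampler's target is ordering-independent."""
        from pkdeconv.input_prior import InputBasis

        ds, _ = generate_dataset(input_params, make_schedule("long", "sparse"),
                                 pk_params, noise=None, seed=11)
        basis = build_kl_basis(ds.times[0], ds.times[-1], 120, 20)
        perm = rng.permutation(20)
        basis_p = InputBasis(grid=basis.grid, B=basis.B[:, perm],
                             d=basis.d[perm], n_null=basis.n_null)
        c = rng.standard_normal(20) * 0.1
        c[0] = -60.0
        noise = NoiseModel()
        c_p = c[perm]   # same reconstructed function in the permuted basis
        ev = assemble_posterior(
            likelihood_eval(ds, basis, c, pk_params, noise, "steady_state"),
            basis, c, 1.3, null_precision=0.0)
        ev_p = assemble_posterior(
            likelihood_eval(ds, basis_p, c_p, pk_params, noise,
                            "steady_state"),
            basis_p, c_p, 1.3, null_precision=0.0)
        assert ev_p.value == pytest.approx(ev.value, rel=1e-10)
        np.testing.assert_allclose(ev_p.grad, ev.grad[perm], rtol=1e-8)
        np.testing.assert_allclose(ev_p.metric, ev.metric[perm][:, perm],
                                   rtol=1e-8)


class TestSplitRhat:
    def test_well_mixed_chain_near_one(self, rng):
        assert abs(split_rhat(rng.standard_normal(4000)) - 1.0) < 0.02
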