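"""GP kernel, posterior conditioning, sampling and hyperparameter fitting."""

import numpy as np
import pytest

from gdose.gp import (
    GPHyperparams,
    GPTrainingSet,
    confidence_band,
    fit_hyperparams,
    kernel_matrix,
    log_marginal_likelihood,
    posterior,
    sample_realizations,
    sampling_covariance,
)

HYP = GPHyperparams(lengthscale=1.0, signal_var=2.0, noise_var=0.01)


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        k = kernel_matrix(np.array([1.3]), np.array([1.3]), HYP)
        assert k[0, 0] == pytest.approx(2.0, rel=1e-14)

    def test_decay_to_zero_at_large_distance(self):
        k = kernel_matrix(np.array([0.0]), np.array([50.0]), HYP)
        assert k[0, 0] < 1e-300 or k[0, 0] == 0.0

    def test_matches_elementwise_oracle(self):
        x = np.array([0.0, 1.0, 2.0])
        k = kernel_matrix(x, x, HYP)
        for i in range(3):
            for j in range(3):
                expect = 2.0 * np.exp(-0.5 * (x[i] - x[j]) ** 2)
                assert k[i, j] == pytest.approx(expect, rel=1e-12)
        assert np.allclose(k, k.T)


def _random_case(rng, n_train, n_query):
    x = np.sort(rng.uniform(0.0, 3.0, n_train))
    y = np.sin(2.0 * x) + rng.normal(0, 0.1, n_train)
    xq = rng.uniform(0.0, 3.0, n_query)
    hyper = GPHyperparams(
        lengthscale=rng.uniform(0.2, 1.5),
        signal_var=rng.uniform(0.5, 3.0),
        noise_var=rng.uniform(1e-3, 0.1),
        jitter=0.0,
    )
    return GPTrainingSet(x=x, y=y), hyper, xq


def _brute_force_conditioning(train, hyper, xq):
    """Condition the explicit joint Gaussian of (y_train, f_query) directly."""
    ys = (train.y - train.y.mean()) / train.y.std()
    ktt = kernel_matrix(train.x, train.x, hyper) + hyper.noise_var * np.eye(train.n)
    ktq = kernel_matrix(train.x, xq, hyper)
    kqq = kernel_matrix(xq, xq, hyper)
    inv = np.linalg.inv(ktt)
    mean_s = ktq.T @ inv @ ys
    cov_s = kqq - ktq.T @ inv @ ktq
    sc = train.y.std()
    return train.y.mean() + sc * mean_s, sc**2 * cov_s


class TestPosterior:
    def test_matches_brute_force_joint_conditioning(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            train, hyper, xq = _random_case(rng, rng.integers(3, 11), 5)
            post = posterior(train, hyper, xq)
            mean_o, cov_o = _brute_force_conditioning(train, hyper, xq)
            scale = max(np.abs(mean_o).max(), 1.0)
            assert np.max(np.abs(post.mean - mean_o)) / scale < 1e-8
            cscale = max(np.abs(cov_o).max(), 1.0)
            assert np.max(np.abs(post.cov - cov_o)) / cscale < 1e-8

    def test_matches_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(5)
        train, hyper, xq = _random_case(rng, 12, 6)
        ys = (train.y - train.y.mean()) / train.y.std()
        gpr = GaussianProcessRegressor(
            kernel=ConstantKernel(hyper.signal_var, "fixed")
            * RBF(hyper.lengthscale, "fixed"),
            alpha=hyper.noise_var,
            optimizer=None,
        ).fit(train.x[:, None], ys)
        mean_ref, sd_ref = gpr.predict(xq[:, None], return_std=True)
        mean_ref = train.y.mean() + train.y.std() * mean_ref
        sd_ref = train.y.std() * sd_ref
        post = posterior(train, hyper, xq)
        assert np.allclose(post.mean, mean_ref, rtol=1e-8, atol=1e-10)
        assert np.allclose(post.sd, sd_ref, rtol=1e-6, atol=1e-8)

    def test_noise_free_interpolation(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.3, -0.2, 0.7])
        train = GPTrainingSet(x=x, y=y)
        hyper = GPHyperparams(lengthscale=0.8, signal_var=1.0, noise_var=1e-12)
        post = posterior(train, hyper, x)
        assert np.allclose(post.mean, y, atol=1e-5)
        assert np.all(post.sd < 1e-3 * np.std(y))

    def test_posterior_variance_bounded_by_prior(self):
        rng = np.random.default_rng(3)
        train, hyper, xq = _random_case(rng, 8, 5)
        post = posterior(train, hyper, xq)
        prior_var = hyper.signal_var * train.y.std() ** 2
        assert np.all(np.diag(post.cov) <= prior_var * (1 + 1e-9))


class TestSampling:
    def test_zero_covariance_returns_the_mean(self):
        train = GPTrainingSet(x=np.array([0.0, 1.0]), y=np.array([1.0, 2.0]))
        hyper = GPHyperparams(lengthscale=1.0, signal_var=1.0, noise_var=1e-10)
        post = posterior(train, hyper, np.array([0.0, 1.0]))
        post.cov[:] = 0.0
        draws = sample_realizations(post, 50, seed=0, noise="none")
        assert np.allclose(draws, post.mean[None, :], atol=1e-12)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(9)
        train, hyper, xq = _random_case(rng, 10, 6)
        post = posterior(train, hyper, xq)
        a = sample_realizations(post, 20, seed=123, noise="correlated")
        b = sample_realizations(post, 20, seed=123, noise="correlated")
        assert np.array_equal(a, b)
        c = sample_realizations(post, 20, seed=124, noise="correlated")
        assert not np.array_equal(a, c)

    def test_empirical_moments_match_target_covariance(self):
        rng = np.random.default_rng(2)
        train, hyper, xq = _random_case(rng, 10, 5)
        post = posterior(train, hyper, xq)
        for noise in ("none", "correlated"):
            cov = sampling_covariance(post, noise)
            draws = sample_realizations(post, 10_000, seed=1, noise=noise)
            emp_mean = draws.mean(axis=0)
            sd = np.sqrt(np.diag(cov))
            se_mean = sd / np.sqrt(draws.shape[0])
            assert np.all(np.abs(emp_mean - post.mean) < 4.0 * (se_mean + 1e-12))

    def test_band_percentiles_match_analytic_band(self):
        rng = np.random.default_rng(4)
        train, hyper, xq = _random_case(rng, 10, 4)
        post = posterior(train, hyper, xq)
        draws = sample_realizations(post, 20_000, seed=3, noise="none")
        lo_emp = np.percentile(draws, 2.5, axis=0)
        hi_emp = np.percentile(draws, 97.5, axis=0)
        lo, hi = confidence_band(post)
        tol = 4.0 * np.sqrt(np.diag(post.cov)) / np.sqrt(20_000) * 3.0 + 1e-9
        assert np.all(np.abs(lo_emp - lo) < np.maximum(tol, 0.05 * post.sd + 1e-9))
        assert np.all(np.abs(hi_emp - hi) < np.maximum(tol, 0.05 * post.sd + 1e-9))


class TestConfidenceBand:
    def test_zero_variance_band_collapses(self):
        train = GPTrainingSet(x=np.array([0.0, 1.0]), y=np.array([1.0, 2.0]))
        hyper = GPHyperparams(lengthscale=1.0, signal_var=1.0, noise_var=1e-10)
        post = posterior(train, hyper, np.array([0.5]))
        post.cov[:] = 0.0
        lo, hi = confidence_band(post)
        assert np.allclose(lo, post.mean) and np.allclose(hi, post.mean)

    def test_width_monotone_in_signal_variance(self):
        x = np.array([0.0, 2.0])
        y = np.array([0.0, 1.0])
        widths = []
        for sf2 in (0.5, 1.0, 2.0, 4.0):
            hyper = GPHyperparams(lengthscale=0.5, signal_var=sf2, noise_var=0.01)
            post = posterior(GPTrainingSet(x=x, y=y), hyper, np.array([1.0]))
            lo, hi = confidence_band(post)
            widths.append(hi[0] - lo[0])
        assert np.all(np.diff(widths) > 0)

    def test_near_zero_width_at_noise_free_training_point(self):
        x = np.linspace(0, 2, 5)
        y = np.sin(x)
        hyper = GPHyperparams(lengthscale=0.7, signal_var=1.0, noise_var=1e-10)
        post = posterior(GPTrainingSet(x=x, y=y), hyper, x[2:3])
        lo, hi = confidence_band(post)
        assert hi[0] - lo[0] < 1e-3 * np.std(y)


class TestHyperparamFit:
    def test_recovers_lengthscale_from_known_gp(self):
        """Parameter recovery: data generated from a known GP must give a
        lengthscale within a factor of two, in each of several replicates."""
        true = GPHyperparams(lengthscale=0.3, signal_var=1.0, noise_var=0.01)
        for rep in range(3):
            rng = np.random.default_rng(100 + rep)
            x = np.sort(rng.uniform(0, 3, 200))
            k = kernel_matrix(x, x, true) + true.noise_var * np.eye(200)
            y = np.linalg.cholesky(k) @ rng.standard_normal(200)
            fitted = fit_hyperparams(GPTrainingSet(x=x, y=y), seed=rep, n_starts=4)
            assert 0.15 <= fitted.lengthscale <= 0.6

    def test_noise_free_data_drives_noise_to_lower_bound(self):
        x = np.linspace(0, 3, 40)
        y = np.sin(x)
        fitted = fit_hyperparams(
            GPTrainingSet(x=x, y=y),
            bounds={"noise_var": (1e-8, 1.0)},
            seed=0, n_starts=4,
        )
        assert fitted.noise_var < 1e-5

    def test_duplicated_x_with_spread_forces_noise(self):
        x = np.repeat(np.linspace(0, 3, 10), 2)
        rng = np.random.default_rng(0)
        y = np.sin(x) + np.where(np.arange(20) % 2 == 0, 0.3, -0.3)
        fitted = fit_hyperparams(GPTrainingSet(x=x, y=y), seed=0, n_starts=4)
        assert fitted.noise_var > 1e-3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_hyperparams(GPTrainingSet(x=np.ones(10), y=np.arange(10.0)))
        with pytest.raises(ValueError):
            fit_hyperparams(
                GPTrainingSet(x=np.array([0.0, 1.0]), y=np.array([1.0, 2.0]))
            )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 3, 60))
        y = np.sin(2 * x) + rng.normal(0, 0.1, 60)
        a = fit_hyperparams(GPTrainingSet(x=x, y=y), seed=7, n_starts=4)
        b = fit_hyperparams(GPTrainingSet(x=x, y=y), seed=7, n_starts=4)
        assert a == b

    def test_lml_finite_and_peaks_near_fit(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 3, 50))
        y = np.sin(2 * x) + rng.normal(0, 0.1, 50)
        train = GPTrainingSet(x=x, y=y)
        fitted = fit_hyperparams(train, seed=0, n_starts=4)
        lml_fit = log_marginal_likelihood(train, fitted)
        worse = GPHyperparams(
            lengthscale=fitted.lengthscale * 10.0,
            signal_var=fitted.signal_var,
            noise_var=fitted.noise_var,
        )
        assert np.isfinite(lml_fit)
        assert lml_fit >= log_marginal_likelihood(train, worse)
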