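"""Gaussian-process model over pooled G(E) data from several geometries.

The GP treats the geometry-specific G(E) functions as noisy observations of
one latent conversion function of x = log10(energy):

    y = f(x) + eps,   eps ~ N(0, sigma_eps^2),   f ~ GP(0, k)

with a radial-basis-function kernel ``k(x, x') = sigma_f^2 *
exp(-(x-x')^2 / (2 l^2))``.  The "noise" here is not counting noise: it is
the disagreement between G(E) functions calibrated under different
irradiation geometries, which is exactly the uncertainty the model is meant
to propagate into the dose rate.  Outputs are standardised (zero mean, unit
variance over the training y) before fitting; the zero-mean prior then
refers to the standardised scale.

The posterior over query points follows the usual conditioning formulas

    m(x*)  = K(x*, X) [K(X, X) + sigma_eps^2 I]^-1 y
    C(x*,x*') = K(x*,x*') - K(x*, X) [K(X, X) + sigma_eps^2 I]^-1 K(X, x*')

computed via Cholesky factorisation (never an explicit inverse).

Realizations ("G(E)GPR functions") can be drawn from the latent posterior
(``noise="none"``), with independent per-channel noise (``"iid"``), or with
a smooth correlated noise component sharing the kernel's correlation
structure (``"correlated"``).  The pipeline uses the correlated option:
a geometry mismatch shifts G(E) coherently across neighbouring energies,
not channel by channel, and only a coherent deviation survives the
summation over the spectrum that produces a dose rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "GPTrainingSet",
    "GPHyperparams",
    "GPPosterior",
    "kernel_matrix",
    "log_marginal_likelihood",
    "fit_hyperparams",
    "posterior",
    "sample_realizations",
    "confidence_band",
]


@dataclass
class GPTrainingSet:
    """Pooled (log10-energy, G-value) pairs with per-point geometry tags."""

    x: np.ndarray
    y: np.ndarray
    tags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.size != self.y.size or self.x.size < 2:
            raise ValueError("x and y must have equal length >= 2")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("training data must be finite")
        if self.tags is not None:
            self.tags = np.asarray(self.tags)
            if self.tags.size != self.x.size:
                raise ValueError("tags must match the number of points")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class GPHyperparams:
    """RBF kernel hyperparameters on the standardised-output scale."""

    lengthscale: float
    signal_var: float
    noise_var: float
    jitter: float = 1e-10  # relative diagonal inflation for factorisation

    def __post_init__(self) -> None:
        if min(self.lengthscale, self.signal_var, self.noise_var) <= 0:
            raise ValueError("lengthscale, signal_var and noise_var must be > 0")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def kernel_matrix(
    xa: np.ndarray, xb: np.ndarray, hyper: GPHyperparams
) -> np.ndarray:
    """RBF covariance sigma_f^2 exp(-(xa_i - xb_j)^2 / (2 l^2))."""
    xa = np.asarray(xa, dtype=float).ravel()
    xb = np.asarray(xb, dtype=float).ravel()
    d = xa[:, None] - xb[None, :]
    return hyper.signal_var * np.exp(-0.5 * (d / hyper.lengthscale) ** 2)


def _chol_with_jitter(k: np.ndarray, hyper: GPHyperparams) -> np.ndarray:
    """Lower Cholesky factor of ``k``, escalating jitter 10x up to 1e-6."""
    mean_diag = float(np.mean(np.diag(k)))
    jit = hyper.jitter
    while True:
        try:
            return linalg.cholesky(k + jit * mean_diag * np.eye(k.shape[0]), lower=True)
        except linalg.LinAlgError:
            if jit == 0.0:
                jit = 1e-12
            jit *= 10.0
            if jit > 1e-6:
                raise linalg.LinAlgError(
                    "kernel matrix not positive definite even with jitter 1e-6"
                ) from None


def _standardize(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(y))
    scale = float(np.std(y))
    if scale == 0.0:
        scale = 1.0
    return (y - mu) / scale, mu, scale


def log_marginal_likelihood(train: GPTrainingSet, hyper: GPHyperparams) -> float:
    """Standard GP log marginal likelihood of the standardised outputs."""
    ys, _, _ = _standardize(train.y)
    k = kernel_matrix(train.x, train.x, hyper) + hyper.noise_var * np.eye(train.n)
    low = _chol_with_jitter(k, hyper)
    alpha = linalg.cho_solve((low, True), ys)
    return float(
        -0.5 * ys @ alpha
        - np.sum(np.log(np.diag(low)))
        - 0.5 * train.n * np.log(2.0 * np.pi)
    )


_DEFAULT_BOUNDS = {
    "lengthscale": (0.02, 3.0),
    "signal_var": (1e-3, 1e3),
    "noise_var": (1e-8, 10.0),
}


def fit_hyperparams(
    train: GPTrainingSet,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 8,
) -> GPHyperparams:
    """Maximum-marginal-likelihood hyperparameters by multi-start L-BFGS-B.

    Optimisation runs over the logs of (lengthscale, signal_var, noise_var)
    within ``bounds``; starts are drawn log-uniformly with ``seed``, so the
    result is deterministic given (data, bounds, seed, n_starts).
    """
    if train.n < 5:
        raise ValueError("need at least 5 training points to fit hyperparameters")
    if np.ptp(train.x) == 0.0:
        raise ValueError("all x equal: lengthscale is unidentifiable")
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    names = ("lengthscale", "signal_var", "noise_var")
    log_bounds = [(np.log(b[k][0]), np.log(b[k][1])) for k in names]

    ys, _, _ = _standardize(train.y)
    n = train.n
    eye = np.eye(n)
    d2 = (train.x[:, None] - train.x[None, :]) ** 2

    def nll(log_theta: np.ndarray) -> float:
        ell, sf2, se2 = np.exp(log_theta)
        k = sf2 * np.exp(-0.5 * d2 / ell**2) + se2 * eye
        try:
            low = linalg.cholesky(k + 1e-10 * sf2 * eye, lower=True)
        except linalg.LinAlgError:
            return 1e12
        alpha = linalg.cho_solve((low, True), ys)
        return float(0.5 * ys @ alpha + np.sum(np.log(np.diag(low))))

    rng = np.random.default_rng(seed)
    starts = [np.array([np.log(0.3), np.log(1.0), np.log(0.01)])]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            np.array([rng.uniform(lo, hi) for lo, hi in log_bounds])
        )
    best, best_val = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=log_bounds,
            options={"maxiter": 200},
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    ell, sf2, se2 = np.exp(best)
    return GPHyperparams(lengthscale=float(ell), signal_var=float(sf2), noise_var=float(se2))


@dataclass
class GPPosterior:
    """Posterior mean and covariance on a set of query points.

    ``mean`` and ``cov`` are de-standardised (original G units); the
    standardisation constants and hyperparameters are retained so noise
    terms can be added consistently when sampling.
    """

    x_train: np.ndarray
    x_query: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    hyper: GPHyperparams
    y_mean: float
    y_scale: float

    def __post_init__(self) -> None:
        m = self.x_query.size
        if self.mean.shape != (m,) or self.cov.shape != (m, m):
            raise ValueError("mean/cov shapes must match the query points")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("posterior covariance must be symmetric")

    @property
    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    @property
    def noise_sd(self) -> float:
        """De-standardised observation noise sigma_eps."""
        return float(np.sqrt(self.hyper.noise_var) * self.y_scale)


def posterior(
    train: GPTrainingSet, hyper: GPHyperparams, x_query: np.ndarray
) -> GPPosterior:
    """Exact GP posterior on ``x_query`` via Cholesky conditioning."""
    xq = np.asarray(x_query, dtype=float).ravel()
    ys, y_mu, y_sc = _standardize(train.y)
    k_tt = kernel_matrix(train.x, train.x, hyper) + hyper.noise_var * np.eye(train.n)
    low = _chol_with_jitter(k_tt, hyper)
    k_tq = kernel_matrix(train.x, xq, hyper)
    alpha = linalg.cho_solve((low, True), ys)
    mean_s = k_tq.T @ alpha
    v = linalg.solve_triangular(low, k_tq, lower=True)
    cov_s = kernel_matrix(xq, xq, hyper) - v.T @ v
    cov_s = 0.5 * (cov_s + cov_s.T)
    return GPPosterior(
        x_train=train.x.copy(),
        x_query=xq,
        mean=y_mu + y_sc * mean_s,
        cov=y_sc**2 * cov_s,
        hyper=hyper,
        y_mean=y_mu,
        y_scale=y_sc,
    )


def sampling_covariance(post: GPPosterior, noise: str = "none") -> np.ndarray:
    """Covariance used for drawing realizations, in original G units."""
    if noise == "none":
        return post.cov
    noise_var = post.hyper.noise_var * post.y_scale**2
    if noise == "iid":
        return post.cov + noise_var * np.eye(post.x_query.size)
    if noise == "correlated":
        corr = kernel_matrix(
            post.x_query, post.x_query, post.hyper
        ) / post.hyper.signal_var
        return post.cov + noise_var * corr
    raise ValueError(f"unknown noise option {noise!r}")


def sample_realizations(
    post: GPPosterior, n_samples: int, seed: int | None = None, noise: str = "none"
) -> np.ndarray:
    """Draw ``n_samples`` G(E)GPR realizations on the query grid.

    Returns an array of shape (n_samples, n_query).  ``noise`` selects the
    sampling covariance (see module docstring); draws are reproducible for
    a given (seed, n_samples, noise).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cov = sampling_covariance(post, noise)
    scale = max(float(np.max(np.diag(cov))), 1e-300)
    # eigen factorisation tolerates the exactly singular case (zero cov)
    vals, vecs = np.linalg.eigh(cov + post.hyper.jitter * scale * np.eye(cov.shape[0]))
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, cov.shape[0]))
    return post.mean[None, :] + z @ root.T


def confidence_band(
    post: GPPosterior, include_noise: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """95% band: mean -/+ 1.96 posterior SD (optionally plus noise SD)."""
    var = np.clip(np.diag(post.cov), 0.0, None)
    if include_noise:
        var = var + post.hyper.noise_var * post.y_scale**2
    half = 1.96 * np.sqrt(var)
    return post.mean - half, post.mean + half
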