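"""Gaussian-process regression over the discrete task space.

A zero-mean GP with an anisotropic squared-exponential kernel models the
per-subject FPN>DMN contrast surface. Hyperparameters are fixed in advance
(never optimized within a run): the closed loop and all permutation refits use
the same configuration, mirroring real-time operation where there is no time
for marginal-likelihood optimization.

The posterior is the exact conjugate solution

    mu    = K*^T (K + sigma_n^2 I)^{-1} y
    sigma^2 = k** - K*^T (K + sigma_n^2 I)^{-1} K*

computed with a Cholesky factorization (jitter added if the Gram matrix is
numerically singular). With ``standardize_y`` the observations are centred and
scaled before fitting and the mean de-standardized afterwards, so the noise
variance is interpreted on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .task_space import Condition, TaskSpace

__all__ = [
    "GPConfig",
    "Observation",
    "GPPosterior",
    "kernel",
    "kernel_matrix",
    "gp_fit",
    "posterior_mean_operator",
    "ucb_select",
]


@dataclass(frozen=True)
class GPConfig:
    """Fixed GP and acquisition hyperparameters (grid units / contrast units).

    Defaults: task lengthscale 1.5 and difficulty lengthscale 1.0 grid units,
    unit signal variance, noise variance 0.25 (on the standardized scale when
    ``standardize_y`` is on), UCB exploration weight kappa = 2.
    """

    lengthscale_task: float = 1.5
    lengthscale_difficulty: float = 1.0
    signal_variance: float = 1.0
    noise_variance: float = 0.25
    ucb_kappa: float = 2.0
    standardize_y: bool = True

    def __post_init__(self) -> None:
        if self.lengthscale_task <= 0 or self.lengthscale_difficulty <= 0:
            raise ValueError("lengthscales must be positive")
        if self.signal_variance <= 0:
            raise ValueError("signal_variance must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.ucb_kappa < 0:
            raise ValueError("ucb_kappa must be >= 0")

    @property
    def lengthscales(self) -> np.ndarray:
        return np.array([self.lengthscale_task, self.lengthscale_difficulty])


@dataclass(frozen=True)
class Observation:
    """One sampled (condition, FPN>DMN contrast) pair from a loop iteration."""

    subject_id: str
    run: int
    iteration: int
    condition: Condition
    value: float
    burn_in: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite contrast value at iteration {self.iteration}")


@dataclass(frozen=True)
class GPPosterior:
    """Posterior mean and sd at every grid point, in enumeration order."""

    mean: np.ndarray
    sd: np.ndarray
    config: GPConfig
    n_obs: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have the same shape")
        if np.any(self.sd < 0):
            raise ValueError("posterior sd must be non-negative")


def kernel(c1, c2, config: GPConfig) -> float:
    """Squared-exponential covariance between two coordinate pairs.

    k(c1, c2) = sigma_f^2 * exp(-sum_d (c1_d - c2_d)^2 / (2 l_d^2)).
    """
    d = (np.asarray(c1, dtype=float) - np.asarray(c2, dtype=float)) / config.lengthscales
    return float(config.signal_variance * np.exp(-0.5 * np.dot(d, d)))


def kernel_matrix(x1: np.ndarray, x2: np.ndarray, config: GPConfig) -> np.ndarray:
    """Cross-covariance matrix between two coordinate sets (n1, 2) x (n2, 2)."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float)) / config.lengthscales
    x2 = np.atleast_2d(np.asarray(x2, dtype=float)) / config.lengthscales
    sq = ((x1[:, None, :] - x2[None, :, :]) ** 2).sum(axis=-1)
    return config.signal_variance * np.exp(-0.5 * sq)


def _obs_arrays(
    observations, space: TaskSpace
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (n, 2) and values (n,) from a list of observations.

    Accepts ``Observation`` objects or bare ``(Condition, value)`` pairs.
    """
    xs, ys = [], []
    for obs in observations:
        if isinstance(obs, Observation):
            cond, val = obs.condition, obs.value
        else:
            cond, val = obs
        xs.append(space.coordinates(cond))
        ys.append(float(val))
    x = np.asarray(xs, dtype=float).reshape(-1, 2)
    y = np.asarray(ys, dtype=float)
    if y.size and not np.all(np.isfinite(y)):
        raise ValueError("observations contain non-finite values")
    return x, y


def _chol_gram(k_mat: np.ndarray, noise_variance: float):
    """Cholesky of K + sigma_n^2 I, adding jitter on numerical failure."""
    n = k_mat.shape[0]
    gram = k_mat + noise_variance * np.eye(n)
    jitter = 0.0
    for _ in range(6):
        try:
            return cho_factor(gram + jitter * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10)
    raise np.linalg.LinAlgError("Gram matrix numerically singular even with jitter")


def gp_fit(observations, space: TaskSpace, config: GPConfig) -> GPPosterior:
    """Exact GP posterior over all grid points given the observations.

    With zero observations the prior is returned: mean 0 everywhere, sd equal
    to the prior sd at every grid point. Hyperparameters are taken from
    ``config`` as-is and never optimized.
    """
    grid = space.coordinate_array()
    x, y = _obs_arrays(observations, space)
    n = y.size
    if n == 0:
        prior_sd = np.sqrt(config.signal_variance)
        return GPPosterior(
            mean=np.zeros(space.n_conditions),
            sd=np.full(space.n_conditions, prior_sd),
            config=config,
            n_obs=0,
        )

    y_mean, y_scale = 0.0, 1.0
    if config.standardize_y:
        y_mean = float(np.mean(y))
        sd = float(np.std(y))
        y_scale = sd if sd > 0 else 1.0
    y_fit = (y - y_mean) / y_scale

    k_xx = kernel_matrix(x, x, config)
    k_sx = kernel_matrix(grid, x, config)  # (n_grid, n)
    cf = _chol_gram(k_xx, config.noise_variance)
    alpha = cho_solve(cf, y_fit)
    mu = k_sx @ alpha

    lower = solve_triangular(cf[0], k_sx.T, lower=True)  # L^{-1} K_x*
    var = config.signal_variance - (lower**2).sum(axis=0)
    var = np.clip(var, 0.0, None)

    mean = y_mean + y_scale * mu
    sd = y_scale * np.sqrt(var)
    return GPPosterior(mean=mean, sd=sd, config=config, n_obs=n)


def posterior_mean_operator(
    conditions: list[Condition], space: TaskSpace, config: GPConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Affine map (B, b0-builder) from observed values to posterior means.

    Returns ``B`` (n_grid, n) and the ones-weight vector ``w = B @ 1`` such
    that for values y sampled at the given conditions,

        mean = ybar * (1 - w) + B @ y        (standardize_y on)
        mean = B @ y                          (standardize_y off)

    where ybar is the sample mean of y. The scale of the standardization
    cancels in the de-standardized mean, so B does not depend on y. This is
    the exact ``gp_fit`` mean and is used to vectorize permutation refits in
    which only the value-to-condition assignment changes.
    """
    x = np.asarray([space.coordinates(c) for c in conditions], dtype=float)
    grid = space.coordinate_array()
    k_xx = kernel_matrix(x, x, config)
    k_sx = kernel_matrix(grid, x, config)
    cf = _chol_gram(k_xx, config.noise_variance)
    b = cho_solve(cf, k_sx.T).T  # (n_grid, n)
    return b, b.sum(axis=1)


def ucb_select_index(posterior: GPPosterior, config: GPConfig, rng) -> int:
    """GP-UCB acquisition: argmax over the grid of mu(c) + kappa * sd(c).

    Favours conditions with a high predicted contrast but equally values
    conditions whose response is still uncertain. Returns the row-major grid
    index; exact ties are broken uniformly at random with the supplied
    generator.
    """
    rng = np.random.default_rng(rng)
    acq = posterior.mean + config.ucb_kappa * posterior.sd
    best = np.flatnonzero(acq == acq.max())
    return int(best[0]) if best.size == 1 else int(rng.choice(best))


def ucb_select(
    posterior: GPPosterior, space: TaskSpace, config: GPConfig, rng
) -> Condition:
    """Condition variant of :func:`ucb_select_index`."""
    return space.condition_at(ucb_select_index(posterior, config, rng))
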