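"""Observation model, log-posterior, gradient and SMMALA metric.

Observations follow a proportional-error model y_i = f_i (1 + sigma eps_i)
with eps_i standard normal or standard Student-t. The t family with few
degrees of freedom is the robust default: it keeps single gross outliers
from dominating the fit.

Two prediction modes are available, mirroring the timescale split:

* ``dynamic`` integrates the TMDD ODEs with the reconstructed input and is
  required on short timescales (hours to days);
* ``steady_state`` applies the algebraic concentration-input relation
  pointwise and is valid on long timescales (weeks), where it is orders of
  magnitude cheaper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .input_prior import InputBasis, InputCoefficients, log_prior_density
from .pk_model import (
    PKParameters,
    simulate_dynamic,
    simulate_with_sensitivities,
    steady_state_concentration,
    RTOL_DEFAULT,
    ATOL_DEFAULT,
)

__all__ = [
    "NoiseModel",
    "Dataset",
    "predict",
    "log_likelihood",
    "likelihood_eval",
    "log_posterior_and_gradient",
    "PosteriorEval",
]

#: column names used in every CSV this package reads or writes; loud units
#: guard against silent hour/week mix-ups
TIME_COLUMN = "time_min"
CONC_COLUMN = "conc_pM"


@dataclass(frozen=True)
class NoiseModel:
    """Proportional-error observation model.

    family : 'gaussian' or 'student_t'
    sigma : proportional scale (default 0.10, i.e. 10% error)
    df : Student-t degrees of freedom (default 4; 6 is a common alternative)
    """

    family: str = "student_t"
    sigma: float = 0.10
    df: float = 4.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "student_t"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.family == "student_t" and not self.df > 2:
            raise ValueError("student_t df must be > 2")

    @property
    def fisher_weight(self) -> float:
        """Fisher-information factor of the standardized location family:
        1 for Gaussian, (df+1)/(df+3) for Student-t."""
        if self.family == "gaussian":
            return 1.0
        return (self.df + 1.0) / (self.df + 3.0)

    def log_density(self, z: np.ndarray) -> np.ndarray:
        """Log density of the standardized residual."""
        if self.family == "gaussian":
            return -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)
        nu = self.df
        const = (gammaln((nu + 1.0) / 2.0) - gammaln(nu / 2.0)
                 - 0.5 * np.log(nu * np.pi))
        return const - 0.5 * (nu + 1.0) * np.log1p(z * z / nu)

    def score(self, z: np.ndarray) -> np.ndarray:
        """d/dz log density of the standardized residual."""
        if self.family == "gaussian":
            return -z
        nu = self.df
        return -(nu + 1.0) * z / (nu + z * z)


@dataclass
class Dataset:
    """A single-subject time-concentration dataset.

    times in minutes (strictly increasing), concentrations in pM (> 0).
    ``timescale`` ('short' or 'long') selects the default prediction mode.
    """

    times: np.ndarray
    conc: np.ndarray
    timescale: str = "long"
    dose_mg: Optional[float] = None
    bodyweight_kg: float = 90.0

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.conc = np.atleast_1d(np.asarray(self.conc, dtype=float))
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have the same length")
        if self.times.size and (np.any(np.diff(self.times) <= 0)
                                or np.any(self.times < 0)):
            raise ValueError("times must be non-negative, strictly increasing")
        if np.any(self.conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if self.timescale not in ("short", "long"):
            raise ValueError("timescale must be 'short' or 'long'")

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path) -> None:
        pd.DataFrame({TIME_COLUMN: self.times, CONC_COLUMN: self.conc}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, timescale: str = "long",
                 dose_mg: Optional[float] = None,
                 bodyweight_kg: float = 90.0) -> "Dataset":
        df = pd.read_csv(path)
        for col in (TIME_COLUMN, CONC_COLUMN):
            if col not in df.columns:
                raise ValueError(
                    f"{path}: missing required column {col!r} "
                    f"(found {list(df.columns)})"
                )
        bad = df.index[~np.isfinite(df[TIME_COLUMN]) | ~np.isfinite(df[CONC_COLUMN])]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value at row {bad[0] + 2}")
        return cls(times=df[TIME_COLUMN].to_numpy(),
                   conc=df[CONC_COLUMN].to_numpy(),
                   timescale=timescale, dose_mg=dose_mg,
                   bodyweight_kg=bodyweight_kg)


def default_mode(timescale: str) -> str:
    """Long timescales use the cheap algebraic model; short ones need ODEs."""
    return "steady_state" if timescale == "long" else "dynamic"


def _check_mode(dataset: Dataset, mode: str, on_mismatch: str) -> None:
    if mode not in ("dynamic", "steady_state"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    if mode == "steady_state" and dataset.timescale == "short":
        msg = ("steady-state predictions are not valid on the short "
               "timescale: the PK transients have not settled")
        if on_mismatch == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=3)


def predict(dataset: Dataset, basis: InputBasis, coeffs, params: PKParameters,
            mode: Optional[str] = None, on_mismatch: str = "warn",
            rtol: float = RTOL_DEFAULT, atol: float = ATOL_DEFAULT) -> np.ndarray:
    """Predicted concentrations at the dataset's observation times."""
    c = coeffs.c if isinstance(coeffs, InputCoefficients) else np.asarray(coeffs)
    if mode is None:
        mode = default_mode(dataset.timescale)
    _check_mode(dataset, mode, on_mismatch)
    if len(dataset) == 0:
        return np.empty(0)
    if mode == "steady_state":
        u = np.exp(np.minimum(basis.rows_at(dataset.times, "clamp") @ c, 500.0))
        return steady_state_concentration(u, params)

    def input_fn(t):
        w = basis.rows_at(t, "clamp") @ c
        return np.exp(np.minimum(w, 500.0))

    return simulate_dynamic(input_fn, params, dataset.times, rtol=rtol,
                            atol=atol, check_input=False)


def log_likelihood(obs: np.ndarray, pred: np.ndarray,
                   noise: NoiseModel) -> float:
    """Proportional-error log likelihood sum_i log p((y_i-f_i)/(sigma f_i))
    - log(sigma f_i). Returns -inf if any prediction is non-positive."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.size == 0:
        return 0.0
    if np.any(pred <= 0) or not np.all(np.isfinite(pred)):
        return -np.inf
    scale = noise.sigma * pred
    z = (obs - pred) / scale
    return float(np.sum(noise.log_density(z) - np.log(scale)))


class LikelihoodEval(NamedTuple):
    """Likelihood value plus the pieces of the gradient/metric that do not
    depend on the regularization parameter (cached across Gibbs updates)."""

    loglik: float
    grad: np.ndarray       # d loglik / d c, shape (m,)
    fisher: np.ndarray     # J^T W J Gauss-Newton information, shape (m, m)
    pred: np.ndarray


class PosteriorEval(NamedTuple):
    value: float           # log posterior (likelihood + prior)
    grad: np.ndarray       # gradient in c at fixed lam
    metric: np.ndarray     # SMMALA metric G (positive definite)
    loglik: float
    pred: np.ndarray


def likelihood_eval(dataset: Dataset, basis: InputBasis, c: np.ndarray,
                    params: PKParameters, noise: NoiseModel, mode: str,
                    rtol: float = RTOL_DEFAULT,
                    atol: float = ATOL_DEFAULT) -> LikelihoodEval:
    """Likelihood, its gradient in c, and the Gauss-Newton information.

    The prediction Jacobian dC/dc comes from forward sensitivity ODEs in
    dynamic mode and from the analytic chain rule dC/du * u * B(t) in
    steady-state mode.
    """
    c = np.asarray(c, dtype=float)
    m = basis.n_basis
    if len(dataset) == 0:
        return LikelihoodEval(0.0, np.zeros(m), np.zeros((m, m)), np.empty(0))
    if mode == "steady_state":
        rows = basis.rows_at(dataset.times, "clamp")
        u = np.exp(np.minimum(rows @ c, 500.0))
        pred, dcdu = steady_state_concentration(u, params, grad=True)
        jac = (dcdu * u)[:, None] * rows
    else:
        pred, jac = simulate_with_sensitivities(basis, c, params,
                                                dataset.times, rtol, atol)
    ll = log_likelihood(dataset.conc, pred, noise)
    if not np.isfinite(ll):
        return LikelihoodEval(-np.inf, np.zeros(m), np.zeros((m, m)), pred)
    y = dataset.conc
    sigma = noise.sigma
    z = (y - pred) / (sigma * pred)
    # d/df of [log p(z(f)) - log(sigma f)]; dz/df = -y/(sigma f^2)
    dll_df = noise.score(z) * (-y / (sigma * pred ** 2)) - 1.0 / pred
    grad = jac.T @ dll_df
    w = noise.fisher_weight / (sigma * pred) ** 2
    fisher = (jac * w[:, None]).T @ jac
    return LikelihoodEval(ll, grad, fisher, pred)


def assemble_posterior(lik: LikelihoodEval, basis: InputBasis, c: np.ndarray,
                       lam: float, alpha: float = 1e-3, beta: float = 1e-3,
                       null_precision: float = 1e-8) -> PosteriorEval:
    """Combine a cached likelihood evaluation with the prior at a given lam."""
    coeffs = InputCoefficients(c=c, lam=lam)
    value = lik.loglik + log_prior_density(coeffs, basis, alpha, beta)
    grad = lik.grad - lam * basis.d * coeffs.c
    prior_prec = lam * basis.d.copy()
    prior_prec[: basis.n_null] += null_precision
    metric = lik.fisher + np.diag(prior_prec)
    return PosteriorEval(value, grad, metric, lik.loglik, lik.pred)


def log_posterior_and_gradient(dataset: Dataset, basis: InputBasis,
                               coeffs: InputCoefficients, params: PKParameters,
                               noise: NoiseModel, mode: Optional[str] = None,
                               alpha: float = 1e-3, beta: float = 1e-3,
                               null_precision: float = 1e-8,
                               rtol: float = RTOL_DEFAULT,
                               atol: float = ATOL_DEFAULT) -> PosteriorEval:
    """Log posterior over (c, lam), its gradient in c, and the SMMALA metric.

    The metric is the Gauss-Newton information J^T W J (W the Fisher weight
    of the noise family over the squared proportional scale) plus the prior
    precision lam * diag(d), with a small diffuse precision on the flat
    null-space directions to keep it positive definite.
    """
    if mode is None:
        mode = default_mode(dataset.timescale)
    _check_mode(dataset, mode, "warn")
    lik = likelihood_eval(dataset, basis, coeffs.c, params, noise, mode,
                          rtol, atol)
    return assemble_posterior(lik, basis, coeffs.c, coeffs.lam, alpha, beta,
                              null_precision)
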