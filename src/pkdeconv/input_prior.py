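"""Log-domain representation of the input function and its smoothness prior.

The unknown absorption rate is written as u(t) = exp(w(t)), which enforces
non-negativity by construction, and w is discretized on a uniform grid of N
nodes. Smoothness is imposed through a Gaussian prior penalizing the L2 norm
of the second derivative of w:

    -log p(w | lam) = (lam / 2) * integral (w'')^2 dt + const,

discretized as w^T K w with K = D2^T D2 / dt^3 (D2 the second-difference
operator). Inside :func:`build_kl_basis` the curvature is measured on the
time axis rescaled to [0, 1], so that lam is dimensionless and directly
comparable between the hours-scale and weeks-scale problems. The prior
leaves constants and linear trends unpenalized: K has a two-dimensional
null space, which receives a flat improper prior.

To keep the estimation problem low-dimensional, w is truncated onto the m
leading eigenvectors of K (the Karhunen-Loeve basis of the prior): the two
orthonormalized null-space functions followed by the m - 2 eigenvectors with
smallest positive eigenvalue, i.e. the smoothest directions. In that basis
the penalty is diagonal, w = B c and w^T K w = sum_j d_j c_j^2.

The regularization parameter lam is given a Gamma(alpha, beta) hyperprior
(alpha = beta = 1e-3 by default) and sampled alongside the coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputBasis",
    "InputCoefficients",
    "build_kl_basis",
    "second_derivative_penalty",
    "evaluate_input",
    "log_prior_density",
    "sample_prior_coefficients",
]


@dataclass
class InputBasis:
    """Discretization grid and Karhunen-Loeve basis of the smoothness prior.

    Attributes
    ----------
    grid : ndarray, shape (N,)
        Uniform time grid in minutes.
    B : ndarray, shape (N, m)
        Orthonormal basis matrix (columns are basis functions at the nodes).
    d : ndarray, shape (m,)
        Penalty eigenvalues; exactly zero for the n_null null-space functions,
        ascending thereafter.
    n_null : int
        Number of unpenalized (constant + linear) basis functions.
    """

    grid: np.ndarray
    B: np.ndarray
    d: np.ndarray
    n_null: int = 2

    @property
    def n_grid(self) -> int:
        return self.grid.size

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]

    @property
    def dt(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def rows_at(self, t, extrapolate: str = "error") -> np.ndarray:
        """Interpolated basis rows B(t), shape (len(t), m).

        extrapolate='clamp' holds the first/last row constant outside the
        grid (used when reporting the short-timescale reconstruction from
        t = 0, and inside the ODE right-hand side).
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.grid[0], self.grid[-1]
        if extrapolate == "error":
            if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
                raise ValueError(
                    f"time outside the basis support [{lo:g}, {hi:g}] min"
                )
        elif extrapolate != "clamp":
            raise ValueError("extrapolate must be 'error' or 'clamp'")
        s = np.clip((t - lo) / self.dt, 0.0, self.n_grid - 1.0)
        i = np.minimum(s.astype(int), self.n_grid - 2)
        th = (s - i)[:, None]
        return (1.0 - th) * self.B[i] + th * self.B[i + 1]

    def to_json(self, path) -> None:
        payload = {
            "grid": self.grid.tolist(),
            "B": self.B.tolist(),
            "d": self.d.tolist(),
            "n_null": self.n_null,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "InputBasis":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            grid=np.asarray(payload["grid"], dtype=float),
            B=np.asarray(payload["B"], dtype=float),
            d=np.asarray(payload["d"], dtype=float),
            n_null=int(payload["n_null"]),
        )


@dataclass
class InputCoefficients:
    """Basis coefficients (log-domain, dimensionless) and the regularization
    parameter lam (> 0)."""

    c: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if not self.lam > 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")


def second_derivative_penalty(grid: np.ndarray) -> np.ndarray:
    """Discrete penalty matrix K with v^T K v ~= integral (v'')^2 dt.

    K = D2^T D2 / dt^3, where D2 is the (N-2) x N second-difference operator.
    The dt^-3 scaling (two powers from squaring the dt^-2 in the second
    difference, minus one from the quadrature weight) makes lam comparable
    across timescales.
    """
    grid = np.asarray(grid, dtype=float)
    n = grid.size
    if n < 3:
        raise ValueError("grid must have at least 3 nodes")
    dt = np.diff(grid)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8):
        raise ValueError("grid must be uniform and strictly increasing")
    d2 = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    d2[idx, idx] = 1.0
    d2[idx, idx + 1] = -2.0
    d2[idx, idx + 2] = 1.0
    return d2.T @ d2 / dt[0] ** 3


def build_kl_basis(t_min: float, t_end: float, n_grid: int = 200,
                   n_basis: int = 20) -> InputBasis:
    """Build the truncated Karhunen-Loeve basis of the smoothness prior.

    Parameters
    ----------
    t_min, t_end : float
        Support of the reconstruction in minutes (typically first and last
        observation time).
    n_grid : int
        Number of uniform grid nodes N (default 200, chosen >> n_basis so
        that discretization error is dominated by the basis truncation).
    n_basis : int
        Number of basis functions m (default 20).
    """
    if not (t_end > t_min >= 0):
        raise ValueError("need t_end > t_min >= 0")
    if n_basis < 3:
        raise ValueError("need at least 3 basis functions")
    if n_grid < n_basis:
        raise ValueError(f"n_grid ({n_grid}) must be >= n_basis ({n_basis})")
    grid = np.linspace(t_min, t_end, n_grid)
    # curvature is measured on the normalized coordinate (t - t_min)/(t_end -
    # t_min): the penalty eigenvalues, and hence lam, are then dimensionless
    # and comparable across timescales, and the Gamma(1e-3, 1e-3) hyperprior
    # stays weakly informative (raw-minute energies would be ~1e-15 on the
    # 12-week window, which the hyperprior's rate would dominate)
    k = second_derivative_penalty(np.linspace(0.0, 1.0, n_grid))
    vals, vecs = np.linalg.eigh(k)
    # explicit orthonormal null space: constant and (centered) linear
    q0 = np.full(n_grid, 1.0 / np.sqrt(n_grid))
    x = grid - grid.mean()
    q1 = x / np.linalg.norm(x)
    b = np.column_stack([q0, q1, vecs[:, 2:n_basis]])
    # eigh's positive eigenvectors carry O(eps * cond) null-space components;
    # a QR pass (which leaves q0, q1 untouched) restores orthonormality
    q, r = np.linalg.qr(b)
    b = q * np.sign(np.diag(r))
    d = np.einsum("ij,ik,kj->j", b, k, b)
    d[:2] = 0.0
    return InputBasis(grid=grid, B=b, d=d, n_null=2)


def evaluate_input(basis: InputBasis, coeffs: InputCoefficients, t,
                   extrapolate: str = "error") -> np.ndarray:
    """Reconstruct u(t) = exp(B(t) c) at arbitrary times (pmol min^-1 kg^-1).

    Basis rows are linearly interpolated between grid nodes; the result is
    strictly positive by construction.
    """
    c = coeffs.c if isinstance(coeffs, InputCoefficients) else np.asarray(coeffs)
    w = basis.rows_at(t, extrapolate=extrapolate) @ c
    return np.exp(np.minimum(w, 500.0))


def penalty_energy(basis: InputBasis, c: np.ndarray) -> float:
    """Second-derivative energy sum_j d_j c_j^2 of a coefficient vector."""
    c = np.asarray(c, dtype=float)
    return float(np.sum(basis.d * c * c))


def log_prior_density(coeffs: InputCoefficients, basis: InputBasis,
                      alpha: float = 1e-3, beta: float = 1e-3) -> float:
    """Joint log prior density of (c, lam) up to an additive constant.

    (r/2) log lam - (lam/2) sum_{j > n_null} d_j c_j^2
        + (alpha - 1) log lam - beta lam,

    with r = m - n_null penalized coefficients; the null-space coefficients
    carry a flat improper prior.
    """
    r = basis.n_basis - basis.n_null
    lam = coeffs.lam
    energy = penalty_energy(basis, coeffs.c)
    return (0.5 * r + alpha - 1.0) * np.log(lam) - 0.5 * lam * energy - beta * lam


def sample_prior_coefficients(basis: InputBasis, lam: float,
                              rng: np.random.Generator,
                              null_values=(0.0, 0.0)) -> np.ndarray:
    """Draw c from the conditional prior c_j ~ N(0, 1/(lam d_j)) for the
    penalized coefficients; the (improper-flat) null-space coefficients are
    set to ``null_values``."""
    c = np.zeros(basis.n_basis)
    c[: basis.n_null] = null_values
    pen = slice(basis.n_null, None)
    c[pen] = rng.standard_normal(basis.n_basis - basis.n_null) / np.sqrt(
        lam * basis.d[pen]
    )
    return c
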