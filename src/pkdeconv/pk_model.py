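"""Target-mediated drug disposition (TMDD) pharmacokinetic model.

The system tracks the central drug concentration C (pM), the peripheral drug
amount A_T (pmol/kg) and the drug-receptor complex concentration RC (pM):

    dC/dt  = u(t)/V_c - (k_el + k_pt) C + k_tp A_T / V_c
             - k_on (R_tot - RC) C + k_off RC
    dA_T/dt = k_pt C V_c - k_tp A_T
    dRC/dt = k_on (R_tot - RC) C - (k_off + k_int) RC

where u(t) is the (unknown) absorption rate in pmol min^-1 kg^-1. All rate
constants are per minute; V_c is carried in ml/kg as published and converted
to L/kg internally so that u/V_c has units of pM/min.

When the input varies much more slowly than the PK dynamics (weeks vs.
minutes), setting the derivatives to zero yields an algebraic steady-state
concentration-input relation that is far cheaper than integrating the ODEs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Callable, NamedTuple

import numpy as np
from scipy.integrate import odeint

from . import _ode

__all__ = [
    "PKParameters",
    "SimulationResult",
    "simulate_dynamic",
    "simulate_with_sensitivities",
    "steady_state_concentration",
    "steady_state_input",
    "IntegrationError",
]

#: default stiff-solver tolerances; the binding kinetics (k_off ~ 0.6/min)
#: are fast relative to week-long horizons, which makes the system stiff
RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the stiff ODE solver fails to meet its tolerances."""


@dataclass(frozen=True)
class PKParameters:
    """TMDD model constants for exenatide (defaults from Gao & Jusko).

    Attributes
    ----------
    k_el : float
        First-order elimination rate constant, 1/min.
    k_pt, k_tp : float
        Intercompartmental distribution rate constants, 1/min.
    v_c_ml_per_kg : float
        Central volume of distribution per bodyweight, ml/kg.
    k_on : float
        Second-order receptor binding constant, 1/(pM min).
    k_off : float
        First-order dissociation constant, 1/min.
    k_int : float
        Internalization rate of the drug-receptor complex, 1/min.
    r_tot : float
        Total receptor concentration, pM.
    """

    k_el: float = 0.013
    k_pt: float = 0.0685
    k_tp: float = 0.0846
    v_c_ml_per_kg: float = 111.0
    k_on: float = 4.11e-4
    k_off: float = 0.566
    k_int: float = 0.00342
    r_tot: float = 1240.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"PK parameter {name} must be > 0, got {value}")

    @property
    def v_c(self) -> float:
        """Central volume in L/kg, so that pmol/kg / (L/kg) = pmol/L = pM."""
        return self.v_c_ml_per_kg / 1000.0

    def with_(self, **kwargs) -> "PKParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PKParameters":
        return cls(**d)

    def _rate_tuple(self):
        return (self.k_el, self.k_pt, self.k_tp, self.v_c,
                self.k_on, self.k_off, self.k_int, self.r_tot)


class SimulationResult(NamedTuple):
    """Full trajectory plus the quadrature states used for mass balance."""

    conc: np.ndarray      # C(t), pM
    a_t: np.ndarray       # A_T(t), pmol/kg
    rc: np.ndarray        # RC(t), pM
    int_c: np.ndarray     # cumulative integral of C, pM min
    int_rc: np.ndarray    # cumulative integral of RC, pM min
    int_u: np.ndarray     # cumulative input, pmol/kg


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-d array")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be non-negative and strictly increasing")
    return times


def _check_input_nonneg(input_fn: Callable, t_max: float) -> None:
    probe = np.linspace(0.0, t_max, 513)
    u = np.asarray(input_fn(probe), dtype=float)
    if u.shape != probe.shape:  # scalar-only callables
        u = np.array([float(input_fn(t)) for t in probe])
    if np.any(u < 0):
        t_bad = probe[np.argmin(u)]
        raise ValueError(f"input function is negative (u({t_bad:g}) = {u.min():g})")


def simulate_dynamic(
    input_fn: Callable[[np.ndarray], np.ndarray],
    params: PKParameters,
    times: np.ndarray,
    initial=(0.0, 0.0, 0.0),
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
    full_output: bool = False,
    check_input: bool = True,
):
    """Integrate the TMDD system for an arbitrary input function.

    Parameters
    ----------
    input_fn : callable
        Absorption rate u(t) in pmol min^-1 kg^-1; must be non-negative.
    params : PKParameters
    times : array
        Strictly increasing observation times in minutes.
    initial : tuple
        State (C, A_T, RC) at t = 0; default is the drug-naive state.
    full_output : bool
        If True return a :class:`SimulationResult` including the quadrature
        states needed for mass-balance checks; otherwise return C(t) only.

    Returns
    -------
    ndarray of C(t_i) in pM, or :class:`SimulationResult`.
    """
    times = _check_times(times)
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (3,) or np.any(initial < 0):
        raise ValueError("initial state must be three non-negative values")
    if initial[2] > params.r_tot:
        raise ValueError("initial RC exceeds R_tot")
    if check_input:
        _check_input_nonneg(input_fn, float(times[-1]))

    kel, kpt, ktp, vc, kon, koff, kint, rtot = params._rate_tuple()

    def rhs(y, t):
        u = float(np.asarray(input_fn(t)).reshape(()))  # scalar or 1-element
        c_, at, rc = y[0], y[1], y[2]
        free = rtot - rc
        dc = u / vc - (kel + kpt) * c_ + ktp * at / vc - kon * free * c_ + koff * rc
        dat = kpt * c_ * vc - ktp * at
        drc = kon * free * c_ - (koff + kint) * rc
        if y.size == 3:
            return [dc, dat, drc]
        return [dc, dat, drc, c_, rc, u]

    def jac(y, t):
        j3 = _ode.tmdd_jac(y[:3], t, kel, kpt, ktp, vc, kon, koff, kint, rtot)
        if y.size == 3:
            return j3
        j = np.zeros((6, 6))
        j[:3, :3] = j3
        j[3, 0] = 1.0
        j[4, 2] = 1.0
        return j

    y0 = initial if not full_output else np.concatenate([initial, [0.0, 0.0, 0.0]])
    ts = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    sol, info = odeint(rhs, y0, ts, Dfun=jac, rtol=rtol, atol=atol,
                       full_output=True, mxstep=100_000)
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"stiff integration failed near t = {info.get('tcur', [np.nan])[-1]:g} min: "
            f"{info['message']}"
        )
    if times[0] != 0.0:
        sol = sol[1:]
    if full_output:
        return SimulationResult(sol[:, 0], sol[:, 1], sol[:, 2],
                                sol[:, 3], sol[:, 4], sol[:, 5])
    return sol[:, 0]


def simulate_with_sensitivities(
    basis,
    coeffs: np.ndarray,
    params: PKParameters,
    times: np.ndarray,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
):
    """Integrate the TMDD system plus forward sensitivities dC/dc_j.

    The input is the log-domain basis reconstruction
    u(t) = exp(sum_j c_j B_j(t)) with linear interpolation of the basis rows
    between grid nodes and constant extrapolation outside the grid.

    Parameters
    ----------
    basis : InputBasis
        Provides the uniform grid and the N x m orthonormal basis matrix.
    coeffs : array, shape (m,)
        Basis coefficients (log-domain).

    Returns
    -------
    (conc, jac) : tuple
        conc[i] = C(t_i) in pM and jac[i, j] = dC(t_i)/dc_j.
    """
    times = _check_times(times)
    coeffs = np.asarray(coeffs, dtype=float)
    grid = np.asarray(basis.grid, dtype=float)
    bmat = np.ascontiguousarray(basis.B, dtype=float)
    if coeffs.shape != (bmat.shape[1],):
        raise ValueError("coefficient vector does not match the basis")
    wnode = bmat @ coeffs
    m = bmat.shape[1]
    grid0 = grid[0]
    dt = grid[1] - grid[0]
    n = grid.size
    args = (grid0, dt, n, wnode, bmat) + params._rate_tuple()

    y0 = np.zeros(3 + 3 * m)
    ts = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    sol, info = odeint(_ode.aug_rhs, y0, ts, Dfun=_ode.aug_jac, args=args,
                       rtol=rtol, atol=atol, full_output=True, mxstep=100_000)
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"sensitivity integration failed near t = "
            f"{info.get('tcur', [np.nan])[-1]:g} min: {info['message']}"
        )
    if times[0] != 0.0:
        sol = sol[1:]
    conc = sol[:, 0]
    jac = sol[:, 3::3]
    return conc, jac


def steady_state_concentration(u, params: PKParameters, grad: bool = False):
    """Algebraic steady-state concentration for a (slowly varying) input rate.

    Setting all derivatives of the TMDD system to zero and eliminating the
    bound-complex concentration gives a quadratic in C whose non-negative
    root is returned:

        k_el k_on C^2 + b(u) C - u (k_off + k_int)/V_c = 0,
        b(u) = k_el (k_off + k_int) + k_int k_on R_tot - u k_on / V_c.

    Continuous and strictly increasing in u, with C(0) = 0.

    Parameters
    ----------
    u : scalar or array
        Input rate in pmol min^-1 kg^-1; must be non-negative.
    grad : bool
        If True also return dC/du (via the inverse closed form u(C)).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("steady-state input rate must be non-negative")
    kel, kpt, ktp, vc, kon, koff, kint, rtot = params._rate_tuple()
    ke = koff + kint
    a = kel * kon
    b = kel * ke + kint * kon * rtot - u * kon / vc
    q = u * ke / vc
    disc = np.sqrt(b * b + 4.0 * a * q)
    # branch on sign(b) for a cancellation-free root
    conc = np.where(b >= 0, 2.0 * q / (b + disc), (disc - b) / (2.0 * a))
    if not grad:
        return conc
    dudc = vc * (kel + kint * kon * rtot * ke / (kon * conc + ke) ** 2)
    return conc, 1.0 / dudc


def steady_state_input(conc, params: PKParameters):
    """Inverse of :func:`steady_state_concentration`: the input rate that
    sustains a given steady-state concentration.

    From the stationarity conditions, u = V_c (k_el C + k_int RC_ss(C)) with
    RC_ss(C) = k_on R_tot C / (k_on C + k_off + k_int).
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    p = params
    ke = p.k_off + p.k_int
    rc = p.k_on * p.r_tot * conc / (p.k_on * conc + ke)
    return p.v_c * (p.k_el * conc + p.k_int * rc)
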