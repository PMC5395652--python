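"""Numba kernels for the TMDD right-hand sides and forward-sensitivity system.

The hot path of the dynamic-mode posterior is one stiff integration of the
state + sensitivity system per MCMC proposal, so these kernels are compiled.
The input function is the log-domain basis reconstruction: piecewise-linear
interpolation of the node values w = B c on a uniform grid, u(t) = exp(w(t)),
with constant extrapolation outside the grid.
"""

import numpy as np
from numba import njit

# exp argument clamp: keeps wild proposals from overflowing; the posterior
# assigns them ~zero probability anyway
_W_MAX = 500.0


@njit(cache=False)
def _interp_w(t, grid0, dt, n, wnode):
    s = (t - grid0) / dt
    if s <= 0.0:
        return wnode[0], 0, 0.0
    if s >= n - 1:
        return wnode[n - 1], n - 2, 1.0
    i = int(s)
    th = s - i
    return (1.0 - th) * wnode[i] + th * wnode[i + 1], i, th


@njit(cache=False)
def tmdd_rhs_basis(y, t, grid0, dt, n, wnode,
                   kel, kpt, ktp, vc, kon, koff, kint, rtot):
    """3-state TMDD right-hand side with basis-reconstructed input."""
    w, _, _ = _interp_w(t, grid0, dt, n, wnode)
    if w > _W_MAX:
        w = _W_MAX
    u = np.exp(w)
    out = np.empty(3)
    c_, at, rc = y[0], y[1], y[2]
    free = rtot - rc
    out[0] = u / vc - (kel + kpt) * c_ + ktp * at / vc - kon * free * c_ + koff * rc
    out[1] = kpt * c_ * vc - ktp * at
    out[2] = kon * free * c_ - (koff + kint) * rc
    return out


@njit(cache=False)
def tmdd_jac(y, t, kel, kpt, ktp, vc, kon, koff, kint, rtot):
    """State Jacobian of the TMDD system (input-independent)."""
    c_, rc = y[0], y[2]
    free = rtot - rc
    jac = np.zeros((3, 3))
    jac[0, 0] = -(kel + kpt) - kon * free
    jac[0, 1] = ktp / vc
    jac[0, 2] = kon * c_ + koff
    jac[1, 0] = kpt * vc
    jac[1, 1] = -ktp
    jac[2, 0] = kon * free
    jac[2, 2] = -(kon * c_ + koff + kint)
    return jac


@njit(cache=False)
def aug_rhs(y, t, grid0, dt, n, wnode, bmat,
            kel, kpt, ktp, vc, kon, koff, kint, rtot):
    """State + forward-sensitivity right-hand side.

    y = [C, A_T, RC, S_1(3), ..., S_m(3)] with S_j = d(state)/d(c_j).
    dS_j/dt = J_x S_j + (u(t)/V_c) b_j(t) e_1, since du/dc_j = u b_j.
    """
    m = bmat.shape[1]
    w, i, th = _interp_w(t, grid0, dt, n, wnode)
    if w > _W_MAX:
        w = _W_MAX
    u = np.exp(w)
    out = np.empty(3 + 3 * m)
    c_, at, rc = y[0], y[1], y[2]
    free = rtot - rc
    out[0] = u / vc - (kel + kpt) * c_ + ktp * at / vc - kon * free * c_ + koff * rc
    out[1] = kpt * c_ * vc - ktp * at
    out[2] = kon * free * c_ - (koff + kint) * rc
    j00 = -(kel + kpt) - kon * free
    j01 = ktp / vc
    j02 = kon * c_ + koff
    j10 = kpt * vc
    j20 = kon * free
    j22 = -(kon * c_ + koff + kint)
    uvc = u / vc
    for jj in range(m):
        b = (1.0 - th) * bmat[i, jj] + th * bmat[i + 1, jj]
        r = 3 + 3 * jj
        s0, s1, s2 = y[r], y[r + 1], y[r + 2]
        out[r] = j00 * s0 + j01 * s1 + j02 * s2 + uvc * b
        out[r + 1] = j10 * s0 - ktp * s1
        out[r + 2] = j20 * s0 + j22 * s2
    return out


@njit(cache=False)
def aug_jac(y, t, grid0, dt, n, wnode, bmat,
            kel, kpt, ktp, vc, kon, koff, kint, rtot):
    """Exact Jacobian of :func:`aug_rhs` with respect to the full state."""
    m = bmat.shape[1]
    nn = 3 + 3 * m
    c_, rc = y[0], y[2]
    free = rtot - rc
    j00 = -(kel + kpt) - kon * free
    j01 = ktp / vc
    j02 = kon * c_ + koff
    j10 = kpt * vc
    j20 = kon * free
    j22 = -(kon * c_ + koff + kint)
    jac = np.zeros((nn, nn))
    jac[0, 0] = j00
    jac[0, 1] = j01
    jac[0, 2] = j02
    jac[1, 0] = j10
    jac[1, 1] = -ktp
    jac[2, 0] = j20
    jac[2, 2] = j22
    for jj in range(m):
        r = 3 + 3 * jj
        s0, s2 = y[r], y[r + 2]
        # d(J_x S_j)/dx: J_x depends on C (via j02, j22) and RC (via j00, j20)
        jac[r, 0] = kon * s2
        jac[r, 2] = kon * s0
        jac[r + 2, 0] = -kon * s2
        jac[r + 2, 2] = -kon * s0
        jac[r, r] = j00
        jac[r, r + 1] = j01
        jac[r, r + 2] = j02
        jac[r + 1, r] = j10
        jac[r + 1, r + 1] = -ktp
        jac[r + 2, r] = j20
        jac[r + 2, r + 2] = j22
    return jac
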