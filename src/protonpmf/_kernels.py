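"""Numba-compiled Metropolis sweep loops.

The kernels operate on flat parameter vectors produced by
``Surface1D.kernel_params`` / ``Surface2D.kernel_params`` so the hot loop
carries no Python objects.  The wall constants are baked in at compile time
from :mod:`protonpmf.constants`.
"""

import numpy as np
from numba import njit

from .constants import WALL_K, WALL_ONSET

_DOMAIN_HI = 2.0


@njit(cache=True)
def _u1d(p, d):
    u = (
        -p[0] * np.exp(-((d - p[1]) ** 2) / (2.0 * p[2] * p[2]))
        - p[3] * np.exp(-((d - p[4]) ** 2) / (2.0 * p[5] * p[5]))
        + p[6] * d
        + p[7]
    )
    ax = abs(d)
    if ax > WALL_ONSET:
        u += WALL_K * (ax - WALL_ONSET) ** 2
    return u


@njit(cache=True)
def p9_mu(p, d1):
    """Channel centre mu(D1) of the 2D surface parameter vector."""
    return p[9] * np.tanh(d1 / p[10])


@njit(cache=True)
def _u2d(p, d1, d2):
    # p[0:8] -> D1 double-well term, p[8] kappa, p[9] mu amplitude, p[10] mu steepness
    mu = p[9] * np.tanh(d1 / p[10])
    u = _u1d(p[:8], d1) + 0.5 * p[8] * (d2 - mu) ** 2
    ax = abs(d2)
    if ax > WALL_ONSET:
        u += WALL_K * (ax - WALL_ONSET) ** 2
    return u


@njit(cache=True)
def mc_window_1d(
    params,
    k_bias,
    d_ref,
    d_start,
    n_equil,
    n_prod,
    sigma,
    kt,
    seed,
    restr_k,
    restr_ref,
    restr_interval,
    restr_decrement,
):
    """Metropolis chain on U(D) + harmonic bias; returns (production D, final D, accepted)."""
    np.random.seed(seed)
    out = np.empty(n_prod)
    d = d_start
    accepted = 0
    total = n_equil + n_prod
    for sweep in range(total):
        prop = d + sigma * np.random.normal()
        if abs(prop) <= _DOMAIN_HI:
            du = _u1d(params, prop) - _u1d(params, d)
            du += 0.5 * k_bias * ((prop - d_ref) ** 2 - (d - d_ref) ** 2)
            if restr_k > 0.0 and sweep < n_equil:
                pf = 1.0 - restr_decrement * (sweep // restr_interval)
                if pf > 0.0:
                    du += pf * restr_k * ((prop - restr_ref) ** 2 - (d - restr_ref) ** 2)
            if du <= 0.0 or np.random.random() < np.exp(-du / kt):
                d = prop
                accepted += 1
        if sweep >= n_equil:
            out[sweep - n_equil] = d
    return out, d, accepted


@njit(cache=True)
def mc_window_2d(
    params,
    k_bias,
    d_ref,
    d1_start,
    d2_start,
    n_equil,
    n_prod,
    sigma,
    kt,
    seed,
    restr_k,
    restr_ref,
    restr_interval,
    restr_decrement,
):
    """Metropolis chain on U(D1, D2) with the harmonic bias acting on D1 only.

    One sweep = one single-coordinate update of D1 followed by one of D2.
    Records the biased coordinate D1 every production sweep; returns
    (production D1, final D1, final D2, accepted moves).
    """
    np.random.seed(seed)
    out = np.empty(n_prod)
    d1 = d1_start
    d2 = d2_start
    accepted = 0
    total = n_equil + n_prod
    for sweep in range(total):
        # D1 move, sheared along the channel centre: D2 is co-displaced by
        # mu(D1') - mu(D1) so the channel deviation D2 - mu(D1) is invariant.
        # The map (d1, d2) -> (d1 + delta, d2 + mu(d1+delta) - mu(d1)) has
        # unit Jacobian and is its own inverse under delta -> -delta, so the
        # Gaussian proposal stays symmetric and plain Metropolis acceptance
        # applies.  Without the shear, D1 mixing is throttled by D2 having to
        # diffuse along the curved channel.
        prop = d1 + sigma * np.random.normal()
        prop2 = d2 + p9_mu(params, prop) - p9_mu(params, d1)
        if abs(prop) <= _DOMAIN_HI and abs(prop2) <= _DOMAIN_HI:
            du = _u2d(params, prop, prop2) - _u2d(params, d1, d2)
            du += 0.5 * k_bias * ((prop - d_ref) ** 2 - (d1 - d_ref) ** 2)
            if restr_k > 0.0 and sweep < n_equil:
                pf = 1.0 - restr_decrement * (sweep // restr_interval)
                if pf > 0.0:
                    du += pf * restr_k * ((prop - restr_ref) ** 2 - (d1 - restr_ref) ** 2)
            if du <= 0.0 or np.random.random() < np.exp(-du / kt):
                d1 = prop
                d2 = prop2
                accepted += 1
        # D2 move (free coordinate)
        prop = d2 + sigma * np.random.normal()
        if abs(prop) <= _DOMAIN_HI:
            du = _u2d(params, d1, prop) - _u2d(params, d1, d2)
            if du <= 0.0 or np.random.random() < np.exp(-du / kt):
                d2 = prop
                accepted += 1
        if sweep >= n_equil:
            out[sweep - n_equil] = d1
    return out, d1, d2, accepted
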