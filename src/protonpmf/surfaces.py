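"""Analytic free-energy surfaces standing in for the proton-transfer active site.

The QM/MM potential of mean force (PMF) along the proton-transfer coordinate
D = d_DH - d_AH is emulated by smooth analytic landscapes: a double-well
``Surface1D`` for direct (Type 1) transfer, and a coupled two-coordinate
``Surface2D`` for water-mediated (Type 2) transfer in which the biased
coordinate D1 (donor -> water proton) drags a freely relaxing coordinate D2
(water -> acceptor proton).

A surface is the *ground truth* of the pipeline: its exact PMF is available
through :func:`analytic_pmf` (directly in 1D, by quadrature marginalization in
2D), which serves as the oracle against which the umbrella-sampling + WHAM
chain is validated.  :func:`calibrate_surface` solves for surface parameters
so that the exact PMF reproduces a target (reaction energy, barrier height)
pair with the reactant and product minima at prescribed positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import minimize_scalar, root

from .constants import DOMAIN, TEMPERATURE, WALL_K, WALL_ONSET
from .pmf import PMFProfile


class DomainError(ValueError):
    """Raised when a reaction-coordinate value lies outside the surface domain."""


class CalibrationError(RuntimeError):
    """Raised when no surface can reproduce the requested energetics."""


@dataclass(frozen=True)
class EnergeticsTarget:
    """Target energetics for surface calibration.

    Parameters
    ----------
    reaction_energy : float
        F(product) - F(reactant), kcal/mol.
    barrier_height : float
        F(barrier) - F(reactant), kcal/mol.  Must be >= max(0, reaction_energy).
    reactant_position, product_position : float
        Reaction-coordinate positions (Å) of the two minima; must lie in
        [-1.7, +1.7] with reactant_position < product_position.
    """

    reaction_energy: float
    barrier_height: float
    reactant_position: float = -1.2
    product_position: float = 1.2

    def __post_init__(self) -> None:
        if self.barrier_height < max(0.0, self.reaction_energy):
            raise CalibrationError(
                f"infeasible target: barrier {self.barrier_height} < "
                f"max(0, reaction energy {self.reaction_energy})"
            )
        for pos in (self.reactant_position, self.product_position):
            if not -1.7 <= pos <= 1.7:
                raise CalibrationError(f"minimum position {pos} outside [-1.7, 1.7]")
        if self.reactant_position >= self.product_position:
            raise CalibrationError("reactant must lie left of product")


def _wall(x: np.ndarray | float) -> np.ndarray | float:
    """Quadratic confinement outside +/- WALL_ONSET, zero inside."""
    excess = np.maximum(np.abs(x) - WALL_ONSET, 0.0)
    return WALL_K * excess * excess


@dataclass(frozen=True)
class Surface1D:
    """Double-well landscape: two negative Gaussians on a linear ramp.

    U(D) = -A1 exp(-(D-p1)^2 / 2 w1^2) - A2 exp(-(D-p2)^2 / 2 w2^2)
           + slope * D + barrier_offset + wall(D)

    ``barrier_offset`` is the additive gauge constant; after calibration it is
    chosen so the reactant minimum sits at zero energy.
    """

    well_positions: tuple[float, float]
    well_depths: tuple[float, float]
    well_widths: tuple[float, float] = (0.30, 0.30)
    slope: float = 0.0
    barrier_offset: float = 0.0
    form: str = "double_gaussian_ramp"

    def energy(self, d: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(d, dtype=float)
        (p1, p2), (a1, a2), (w1, w2) = (
            self.well_positions,
            self.well_depths,
            self.well_widths,
        )
        u = (
            -a1 * np.exp(-((d - p1) ** 2) / (2.0 * w1 * w1))
            - a2 * np.exp(-((d - p2) ** 2) / (2.0 * w2 * w2))
            + self.slope * d
            + self.barrier_offset
            + _wall(d)
        )
        return u if u.ndim else float(u)

    def kernel_params(self) -> np.ndarray:
        """Flat parameter vector consumed by the numba MC kernels."""
        (p1, p2), (a1, a2), (w1, w2) = (
            self.well_positions,
            self.well_depths,
            self.well_widths,
        )
        return np.array(
            [a1, p1, w1, a2, p2, w2, self.slope, self.barrier_offset], dtype=float
        )


MuFunction = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class Surface2D:
    """Coupled landscape for water-mediated transfer.

    U(D1, D2) = g(D1) + 1/2 kappa(D1) (D2 - mu(D1))^2 + wall(D2)

    where g is a :class:`Surface1D` term along the biased coordinate D1 and the
    harmonic D2 channel tracks a logistic centre

        mu(D1) = mu_amplitude * tanh(D1 / mu_steepness)

    so that driving the first proton hop (D1: - -> +) lets the second hop
    relax spontaneously from the donor side to the acceptor side.  With a
    D1-independent kappa the marginal free energy along D1 equals g(D1) up to
    an additive constant; a callable ``kappa`` is supported for validating the
    marginalization quadrature against the closed-form Gaussian integral.
    """

    d1_term: Surface1D
    kappa: Union[float, Callable[[np.ndarray], np.ndarray]] = 100.0
    mu_amplitude: float = 1.0
    mu_steepness: float = 0.25

    def mu(self, d1: np.ndarray | float) -> np.ndarray | float:
        return self.mu_amplitude * np.tanh(np.asarray(d1, dtype=float) / self.mu_steepness)

    def _kappa_at(self, d1: np.ndarray | float) -> np.ndarray | float:
        if callable(self.kappa):
            return self.kappa(np.asarray(d1, dtype=float))
        return self.kappa

    def energy(self, d1: np.ndarray | float, d2: np.ndarray | float) -> np.ndarray | float:
        d1 = np.asarray(d1, dtype=float)
        d2 = np.asarray(d2, dtype=float)
        u = (
            self.d1_term.energy(d1)
            + 0.5 * self._kappa_at(d1) * (d2 - self.mu(d1)) ** 2
            + _wall(d2)
        )
        return u if np.ndim(u) else float(u)

    def kernel_params(self) -> np.ndarray:
        if callable(self.kappa):
            raise ValueError("MC sampling supports constant-kappa surfaces only")
        return np.concatenate(
            [
                self.d1_term.kernel_params(),
                [float(self.kappa), self.mu_amplitude, self.mu_steepness],
            ]
        )


Surface = Union[Surface1D, Surface2D]


def _check_domain(coords: np.ndarray) -> None:
    lo, hi = DOMAIN
    c = np.asarray(coords, dtype=float)
    if np.any(c < lo) or np.any(c > hi):
        raise DomainError(f"coordinates outside domain [{lo}, {hi}] Å")


def evaluate_surface(surface: Surface, coords) -> float | np.ndarray:
    """Energy (kcal/mol) of a surface at a reaction-coordinate point.

    For :class:`Surface1D` pass a scalar or array D; for :class:`Surface2D`
    pass a (D1, D2) pair (or arrays).
    """
    if isinstance(surface, Surface1D):
        _check_domain(np.asarray(coords))
        return surface.energy(coords)
    if isinstance(surface, Surface2D):
        d1, d2 = coords
        _check_domain(np.asarray(d1))
        _check_domain(np.asarray(d2))
        return surface.energy(d1, d2)
    raise TypeError(f"not a surface: {surface!r}")


def default_grid(step: float = 0.005) -> np.ndarray:
    """Dense reaction-coordinate grid covering the window range [-1.7, +1.7]."""
    n = int(round(3.4 / step)) + 1
    return np.linspace(-1.7, 1.7, n)


def _marginal_free_energy(
    surface: Surface2D,
    d1_grid: np.ndarray,
    temperature: float,
    n_d2: int = 4001,
) -> np.ndarray:
    """F(D1) = -kT ln Integral exp(-U(D1, D2)/kT) dD2 by Simpson quadrature."""
    kt = 0.0019872041 * temperature
    d2 = np.linspace(DOMAIN[0], DOMAIN[1], n_d2)
    u = surface.energy(d1_grid[:, None], d2[None, :])
    u_min = u.min(axis=1, keepdims=True)
    boltz = np.exp(-(u - u_min) / kt)
    integral = simpson(boltz, x=d2, axis=1)
    if np.any(~np.isfinite(integral)) or np.any(integral <= 0.0):
        raise FloatingPointError("non-integrable surface: marginalization failed")
    return u_min[:, 0] - kt * np.log(integral)


def _refine_minimum(f: Callable[[float], float], x0: float, half_width: float = 0.3) -> float:
    res = minimize_scalar(
        f, bounds=(x0 - half_width, x0 + half_width), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def analytic_pmf(
    surface: Surface,
    grid: np.ndarray | None = None,
    temperature: float = TEMPERATURE,
) -> PMFProfile:
    """Exact PMF of a surface, re-zeroed at the reactant (D < 0) minimum.

    For ``Surface1D`` the PMF is the potential itself minus its reactant-
    minimum value (temperature enters only through the gauge search).  For
    ``Surface2D`` the D2 coordinate is marginalized by dense quadrature.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    _check_domain(grid)

    if isinstance(surface, Surface1D):
        f_grid = surface.energy(grid)
        func = lambda x: float(surface.energy(x))  # noqa: E731
    elif isinstance(surface, Surface2D):
        f_grid = _marginal_free_energy(surface, grid, temperature)
        func = lambda x: float(
            _marginal_free_energy(surface, np.array([x]), temperature)[0]
        )  # noqa: E731
    else:
        raise TypeError(f"not a surface: {surface!r}")

    neg = grid < 0
    if not np.any(neg):
        raise ValueError("grid must cover the reactant (D < 0) region")
    x0 = float(grid[neg][np.argmin(f_grid[neg])])
    x_min = _refine_minimum(func, x0)
    gauge = func(x_min)
    return PMFProfile(
        grid=grid,
        free_energy=f_grid - gauge,
        temperature=temperature,
        window_free_energies=None,
        iterations=0,
        residual=0.0,
        source="analytic",
    )


def _extrema(surface1d: Surface1D, r_guess: float, p_guess: float):
    """Locate (reactant min, interior max, product min) positions and energies."""
    f = lambda x: float(surface1d.energy(x))  # noqa: E731
    x_r = _refine_minimum(f, r_guess)
    x_p = _refine_minimum(f, p_guess)
    res = minimize_scalar(
        lambda x: -f(x), bounds=(x_r + 0.05, x_p - 0.05), method="bounded",
        options={"xatol": 1e-10},
    )
    x_b = float(res.x)
    return (x_r, x_b, x_p), (f(x_r), f(x_b), f(x_p))


def calibrate_surface(
    target: EnergeticsTarget,
    kind: str = "direct",
    well_width: float = 0.30,
    kappa: float = 100.0,
) -> Surface:
    """Solve for a surface whose exact PMF reproduces a Table-style target.

    ``kind='direct'`` returns a :class:`Surface1D`; ``kind='water_mediated'``
    returns a :class:`Surface2D` whose *marginal* PMF along D1 matches the
    target (exact for the constant-stiffness D2 channel used here).

    The five free parameters (two well depths, two well centres, ramp slope)
    are found by root finding on five residuals: both minima at the target
    positions, the interior maximum at their midpoint, and the two energy
    differences.  Raises :class:`CalibrationError` on infeasible targets or
    non-convergence.
    """
    if kind not in ("direct", "water_mediated"):
        raise ValueError(f"unknown pathway kind: {kind!r}")

    r_pos, p_pos = target.reactant_position, target.product_position
    b_pos = 0.5 * (r_pos + p_pos)
    dg, dgb = target.reaction_energy, target.barrier_height
    if dgb - dg < 0.15 or dgb < 0.15:
        raise CalibrationError(
            "target too shallow for a clear product valley "
            f"(barrier - reaction energy = {dgb - dg:.3f} kcal/mol)"
        )

    w2 = well_width * well_width

    def _u_and_du(x, d):
        a1, a2, p1, p2, s = x
        g1 = np.exp(-((d - p1) ** 2) / (2.0 * w2))
        g2 = np.exp(-((d - p2) ** 2) / (2.0 * w2))
        u = -a1 * g1 - a2 * g2 + s * d
        du = a1 * (d - p1) / w2 * g1 + a2 * (d - p2) / w2 * g2 + s
        return u, du

    def residuals(x):
        u_r, du_r = _u_and_du(x, r_pos)
        u_p, du_p = _u_and_du(x, p_pos)
        u_b, du_b = _u_and_du(x, b_pos)
        return [du_r, du_p, du_b, (u_p - u_r) - dg, (u_b - u_r) - dgb]

    x0 = np.array([dgb, max(dgb - dg, 0.3), r_pos, p_pos, 0.0])
    sol = root(residuals, x0, method="hybr", options={"xtol": 1e-13})
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise CalibrationError(f"calibration did not converge: {sol.message}")
    a1, a2, p1, p2, s = sol.x
    if a1 <= 0 or a2 <= 0:
        raise CalibrationError("calibration produced non-well (positive) depths")

    surf = Surface1D(
        well_positions=(p1, p2),
        well_depths=(a1, a2),
        well_widths=(well_width, well_width),
        slope=s,
    )
    # shape check: exactly two minima and one interior maximum on the window range
    dense = np.linspace(-1.7, 1.7, 3401)
    du = np.gradient(surf.energy(dense), dense)
    signs = np.sign(du)
    signs = signs[signs != 0]  # exact zeros (e.g. a symmetric barrier top) are crossings
    n_crit = int(np.sum(signs[:-1] != signs[1:]))
    if n_crit != 3:
        raise CalibrationError(
            f"calibrated surface has {n_crit} interior critical points, expected 3"
        )

    # gauge: zero energy at the reactant minimum
    x_r = _refine_minimum(lambda x: float(surf.energy(x)), r_pos)
    surf = dataclasses.replace(surf, barrier_offset=-float(surf.energy(x_r)))

    if kind == "direct":
        return surf
    return Surface2D(d1_term=surf, kappa=kappa)


def extract_energetics_from_surface(
    surface: Surface, target_positions: tuple[float, float] = (-1.2, 1.2)
) -> tuple[float, float]:
    """(reaction energy, barrier height) of a surface's exact PMF.

    Convenience used by calibration round-trip checks; works on the analytic
    (marginal) PMF, independent of any sampling.
    """
    r_pos, p_pos = target_positions
    if isinstance(surface, Surface1D):
        (_, _, _), (f_r, f_b, f_p) = _extrema(surface, r_pos, p_pos)
        return f_p - f_r, f_b - f_r
    prof = analytic_pmf(surface)
    g = prof.grid
    fe = prof.free_energy

    def marg(x: float) -> float:
        return float(_marginal_free_energy(surface, np.array([x]), prof.temperature)[0])

    x_r = _refine_minimum(marg, float(g[np.argmin(np.where(g < 0, fe, np.inf))]))
    x_p = _refine_minimum(marg, float(g[np.argmin(np.where(g > 0, fe, np.inf))]))
    res = minimize_scalar(
        lambda x: -marg(x), bounds=(x_r + 0.05, x_p - 0.05), method="bounded",
        options={"xatol": 1e-8},
    )
    f_r, f_b, f_p = marg(x_r), marg(float(res.x)), marg(x_p)
    return f_p - f_r, f_b - f_r
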