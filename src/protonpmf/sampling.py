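"""Umbrella sampling along the proton-transfer coordinate.

The reaction coordinate is D = d_DH - d_AH (donor-hydrogen distance minus
acceptor-hydrogen distance), restrained per window by E = 1/2 k (D - D_ref)^2
with k = 150 kcal/mol/Å².  Windows are produced by the dragging/restart
protocol: starting at D_ref,0 (-1.2 Å for amino-acid acceptors, -1.0 Å for a
water acceptor) the restraint centre is stepped by 0.1 Å down to -1.7 Å and,
in a second run from the initial coordinates, up to +1.7 Å, saving a restart
configuration after a short equilibration at each step; the union is exactly
35 windows.  Each window is then equilibrated and sampled by Metropolis
Monte-Carlo on the surrogate surface, which is all a potential of mean force
requires (the engine samples equilibrium, not dynamics).

Time mapping: 1 ps of the original molecular dynamics corresponds to 500 MC
sweeps, so the paper-protocol 2.5 ps drag equilibration, 100 ps window run
and final 50 ps of production become 1 250, 50 000 and 25 000 sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .constants import (
    DEFAULT_FORCE_CONSTANT,
    KB,
    SWEEPS_PER_PS,
    TEMPERATURE,
    WINDOW_MAX,
    WINDOW_MIN,
    WINDOW_STEP,
)
from .surfaces import Surface, Surface1D, Surface2D


class SamplerStuckError(RuntimeError):
    """Raised when a window's Metropolis acceptance collapses below 1%."""


class EmptySeriesError(ValueError):
    """Raised when a window run is requested with zero production sweeps."""


def reaction_coordinate(d_dh: float, d_ah: float) -> float:
    """D = d_DH - d_AH (Å); negative while the proton sits on the donor."""
    if d_dh <= 0 or d_ah <= 0:
        raise ValueError("interatomic distances must be positive")
    return d_dh - d_ah


@dataclass(frozen=True)
class BiasWindow:
    """Harmonic umbrella restraint E = 1/2 k (D - D_ref)^2 for one window."""

    d_ref: float
    k: float = DEFAULT_FORCE_CONSTANT
    equil_sweeps: int = 25_000
    prod_sweeps: int = 25_000
    label: int = 0
    parent: int | None = None  # restart-parent window label; None = initial coords

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant must be nonnegative")
        if not WINDOW_MIN - 1e-9 <= self.d_ref <= WINDOW_MAX + 1e-9:
            raise ValueError(f"D_ref {self.d_ref} outside [{WINDOW_MIN}, {WINDOW_MAX}]")


def bias_energy(window: BiasWindow, d: float | np.ndarray) -> float | np.ndarray:
    """Harmonic restraint energy 1/2 k (D - D_ref)^2 in kcal/mol."""
    d = np.asarray(d, dtype=float)
    e = 0.5 * window.k * (d - window.d_ref) ** 2
    return e if e.ndim else float(e)


@dataclass(frozen=True)
class PositionalRestraint:
    """Mass-scaled positional constraint U(x) = p sum_i k_i m_i (x_i - x_ref,i)^2.

    The pre-factor p starts at 1.0 and drops by ``decrement`` every
    ``interval_sweeps`` sweeps until it reaches 0, releasing the system
    gradually during equilibration.
    """

    force_constants: np.ndarray
    masses: np.ndarray
    reference: np.ndarray
    decrement: float = 0.25
    interval_sweeps: int = 10 * SWEEPS_PER_PS

    def __post_init__(self) -> None:
        for name in ("force_constants", "masses", "reference"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not (len(self.force_constants) == len(self.masses) == len(self.reference)):
            raise ValueError("force_constants, masses and reference must have equal length")

    def prefactor(self, sweep_index: int) -> float:
        return max(0.0, 1.0 - self.decrement * (sweep_index // self.interval_sweeps))


def positional_restraint_energy(
    restraint: PositionalRestraint, coords, sweep_index: int
) -> float:
    """Restraint energy at a sweep, following the decaying pre-factor schedule."""
    x = np.atleast_1d(np.asarray(coords, dtype=float))
    if x.shape != restraint.reference.shape:
        raise ValueError(
            f"coordinate shape {x.shape} does not match reference {restraint.reference.shape}"
        )
    p = restraint.prefactor(sweep_index)
    return float(
        p
        * np.sum(
            restraint.force_constants
            * restraint.masses
            * (x - restraint.reference) ** 2
        )
    )


@dataclass(frozen=True)
class WindowProtocol:
    """The dragging/restart window-generation protocol.

    ``acceptor_kind`` selects the starting restraint centre: -1.2 Å for an
    amino-acid acceptor, -1.0 Å for a water acceptor.
    """

    acceptor_kind: str = "amino_acid"
    step: float = WINDOW_STEP
    d_min: float = WINDOW_MIN
    d_max: float = WINDOW_MAX
    force_constant: float = DEFAULT_FORCE_CONSTANT
    drag_equil_sweeps: int = int(2.5 * SWEEPS_PER_PS)
    window_equil_sweeps: int = 25_000
    prod_sweeps: int = 25_000
    proposal_sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.acceptor_kind not in ("amino_acid", "water"):
            raise ValueError(f"unknown acceptor kind: {self.acceptor_kind!r}")

    @property
    def d_ref0(self) -> float:
        return -1.2 if self.acceptor_kind == "amino_acid" else -1.0


@dataclass
class WindowTimeseries:
    """Biased samples of D from one window: one value per production sweep."""

    window: BiasWindow
    samples: np.ndarray
    seed: int
    discarded: int = 0
    acceptance_rate: float = float("nan")
    final_coords: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def generate_window_sequence(protocol: WindowProtocol) -> list[BiasWindow]:
    """Windows in dragging order with restart-parent labels.

    Downward leg from D_ref,0 to the lower endpoint (chained window to
    window), then upward leg from D_ref,0 + step to the upper endpoint, the
    first upward window restarting from the initial coordinates
    (``parent=None``).  The union covers every 0.1 Å step in [-1.7, +1.7]:
    35 distinct windows.
    """
    d0 = round(protocol.d_ref0, 10)
    step = protocol.step
    n_down = int(round((d0 - protocol.d_min) / step))
    n_up = int(round((protocol.d_max - d0) / step))
    windows: list[BiasWindow] = []
    parent: int | None = None
    for i in range(n_down + 1):
        d_ref = round(d0 - i * step, 10)
        windows.append(
            BiasWindow(
                d_ref=d_ref,
                k=protocol.force_constant,
                equil_sweeps=protocol.window_equil_sweeps,
                prod_sweeps=protocol.prod_sweeps,
                label=len(windows),
                parent=parent,
            )
        )
        parent = windows[-1].label
    parent = None  # the upward leg restarts from the initial coordinates
    for i in range(1, n_up + 1):
        d_ref = round(d0 + i * step, 10)
        windows.append(
            BiasWindow(
                d_ref=d_ref,
                k=protocol.force_constant,
                equil_sweeps=protocol.window_equil_sweeps,
                prod_sweeps=protocol.prod_sweeps,
                label=len(windows),
                parent=parent,
            )
        )
        parent = windows[-1].label
    return windows


def _restraint_kernel_args(restraint: PositionalRestraint | None):
    if restraint is None:
        return 0.0, 0.0, 1, 0.25
    if len(restraint.force_constants) != 1:
        raise ValueError("the MC kernels restrain a single surrogate coordinate")
    combined = float(restraint.force_constants[0] * restraint.masses[0])
    return combined, float(restraint.reference[0]), int(restraint.interval_sweeps), float(
        restraint.decrement
    )


def run_window(
    surface: Surface,
    window: BiasWindow,
    start,
    restraint: PositionalRestraint | None = None,
    seed: int = 0,
    proposal_sigma: float = 0.05,
    temperature: float = TEMPERATURE,
) -> WindowTimeseries:
    """Metropolis run of one umbrella window.

    ``start`` is a scalar D for a 1D surface or a (D1, D2) pair for a 2D
    surface; the restraint (if any) acts during equilibration sweeps only.
    Identical seeds give identical output.
    """
    if window.prod_sweeps <= 0:
        raise EmptySeriesError("window has zero production sweeps")
    kt = KB * temperature
    rk, rref, rint, rdec = _restraint_kernel_args(restraint)
    seed32 = int(seed) % (2**32)
    if isinstance(surface, Surface1D):
        samples, d_final, accepted = _kernels.mc_window_1d(
            surface.kernel_params(),
            window.k,
            window.d_ref,
            float(np.atleast_1d(start)[0]),
            window.equil_sweeps,
            window.prod_sweeps,
            proposal_sigma,
            kt,
            seed32,
            rk,
            rref,
            rint,
            rdec,
        )
        n_moves = window.equil_sweeps + window.prod_sweeps
        final = (float(d_final),)
    elif isinstance(surface, Surface2D):
        d1, d2 = (float(start[0]), float(start[1]))
        samples, d1_final, d2_final, accepted = _kernels.mc_window_2d(
            surface.kernel_params(),
            window.k,
            window.d_ref,
            d1,
            d2,
            window.equil_sweeps,
            window.prod_sweeps,
            proposal_sigma,
            kt,
            seed32,
            rk,
            rref,
            rint,
            rdec,
        )
        n_moves = 2 * (window.equil_sweeps + window.prod_sweeps)
        final = (float(d1_final), float(d2_final))
    else:
        raise TypeError(f"not a surface: {surface!r}")

    rate = accepted / n_moves
    if rate < 0.01:
        raise SamplerStuckError(
            f"window D_ref={window.d_ref}: acceptance {rate:.2%} below 1%"
        )
    return WindowTimeseries(
        window=window,
        samples=samples,
        seed=seed32,
        discarded=window.equil_sweeps,
        acceptance_rate=rate,
        final_coords=final,
    )


def _window_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-window seed table derived from the master seed."""
    ss = np.random.SeedSequence(int(master_seed))
    return ss.generate_state(2 * n, dtype=np.uint32)


def run_umbrella_protocol(
    surface: Surface,
    protocol: WindowProtocol,
    seed: int,
    restraint: PositionalRestraint | None = None,
) -> list[WindowTimeseries]:
    """Full dragging + per-window sampling protocol; returns 35 time series.

    Dragging: each window in :func:`generate_window_sequence` order is given a
    short equilibration started from its restart parent's final coordinates
    (or the initial coordinates), and its final configuration is stored as
    the restart point.  Production: each window then runs its own
    equilibration + production from its restart point.  All per-window seeds
    derive deterministically from ``seed``.
    """
    windows = generate_window_sequence(protocol)
    seeds = _window_seeds(seed, len(windows))

    if isinstance(surface, Surface2D):
        initial = (protocol.d_ref0, float(surface.mu(protocol.d_ref0)))
    else:
        initial = (protocol.d_ref0,)

    # dragging pass: build the restart table
    restarts: dict[int, tuple[float, ...]] = {}
    for w in windows:
        start = initial if w.parent is None else restarts[w.parent]
        drag = replace(w, equil_sweeps=0, prod_sweeps=protocol.drag_equil_sweeps)
        ts = run_window(
            surface,
            drag,
            start,
            restraint=restraint,
            seed=int(seeds[2 * w.label]),
            proposal_sigma=protocol.proposal_sigma,
        )
        restarts[w.label] = ts.final_coords

    # production pass
    out: list[WindowTimeseries] = []
    for w in windows:
        ts = run_window(
            surface,
            w,
            restarts[w.label],
            restraint=restraint,
            seed=int(seeds[2 * w.label + 1]),
            proposal_sigma=protocol.proposal_sigma,
        )
        out.append(ts)
    return out
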