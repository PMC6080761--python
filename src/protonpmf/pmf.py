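"""Potential-of-mean-force profile container shared by the oracle and WHAM."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PMFProfile:
    """Free-energy profile F(D) along the proton-transfer coordinate.

    Attributes
    ----------
    grid : ndarray
        Reaction-coordinate values D (Å); bin centres for WHAM output,
        arbitrary dense grids for analytic profiles.
    free_energy : ndarray
        F(D) in kcal/mol, gauge-fixed to zero at the reactant-region (D < 0)
        minimum.  Bins with no pooled samples are NaN (undefined, never
        silently interpolated).
    temperature : float
        Temperature (K) used for the reconstruction.
    window_free_energies : ndarray or None
        Per-window free-energy constants F_i from WHAM (None for analytic
        profiles).
    iterations : int
        WHAM iterations performed (0 for analytic profiles).
    residual : float
        Final max |dF_i| residual (0 for analytic profiles).
    source : str
        "analytic" or "wham".
    """

    grid: np.ndarray
    free_energy: np.ndarray
    temperature: float
    window_free_energies: np.ndarray | None = None
    iterations: int = 0
    residual: float = 0.0
    source: str = "wham"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.grid.shape != self.free_energy.shape:
            raise ValueError("grid and free_energy must have identical shape")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of grid points where the PMF is defined."""
        return np.isfinite(self.free_energy)

    def rezeroed(self) -> "PMFProfile":
        """Copy gauge-fixed to zero at the reactant-region (D < 0) minimum.

        The gauge value is the parabolic vertex through the lowest defined
        D < 0 grid point and its two neighbours (when available and convex),
        not the raw grid value: with stiff wells the true minimum can fall
        between grid points, and zeroing on the nearest grid value would
        shift the whole profile by the within-bin rise of the well.
        """
        mask = self.defined & (self.grid < 0)
        if not np.any(mask):
            raise ValueError("no defined PMF values in the reactant (D < 0) region")
        candidates = np.flatnonzero(mask)
        i = candidates[np.argmin(self.free_energy[candidates])]
        gauge = float(self.free_energy[i])
        if 0 < i < len(self.grid) - 1 and self.defined[i - 1] and self.defined[i + 1]:
            y0, y1, y2 = self.free_energy[i - 1 : i + 2]
            curv = y0 - 2.0 * y1 + y2
            if curv > 0:
                # vertex of the parabola through three equally spaced points
                gauge = float(y1 - (y2 - y0) ** 2 / (8.0 * curv))
        return PMFProfile(
            grid=self.grid.copy(),
            free_energy=self.free_energy - gauge,
            temperature=self.temperature,
            window_free_energies=self.window_free_energies,
            iterations=self.iterations,
            residual=self.residual,
            source=self.source,
            metadata=dict(self.metadata),
        )
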