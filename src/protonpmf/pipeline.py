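"""End-to-end convenience chain: calibrate → umbrella sample → WHAM → energetics."""

from __future__ import annotations

from dataclasses import dataclass

from .energetics import PathwayEnergetics, pathway_energetics
from .io import RunConfig
from .pmf import PMFProfile
from .sampling import WindowProtocol, WindowTimeseries, run_umbrella_protocol
from .surfaces import EnergeticsTarget, Surface, calibrate_surface
from .wham import HistogramSet, build_histograms, solve_wham


@dataclass
class PathwayResult:
    surface: Surface
    series: list[WindowTimeseries]
    histograms: HistogramSet
    pmf: PMFProfile
    energetics: PathwayEnergetics


def run_pathway(config: RunConfig, seed: int | None = None) -> PathwayResult:
    """Run the full inference chain for one proton-transfer pathway.

    Calibrates a surrogate surface to the configured (reaction energy,
    barrier height) target, executes the 35-window dragging + sampling
    protocol, reconstructs the PMF with WHAM and extracts the pathway
    energetics.  ``seed`` overrides the config seed when given.
    """
    target = EnergeticsTarget(
        reaction_energy=config.reaction_energy,
        barrier_height=config.barrier_height,
        reactant_position=config.reactant_position,
        product_position=config.product_position,
    )
    surface = calibrate_surface(target, kind=config.kind)
    protocol = WindowProtocol(
        acceptor_kind=config.acceptor_kind,
        force_constant=config.force_constant,
        window_equil_sweeps=config.window_equil_sweeps,
        prod_sweeps=config.prod_sweeps,
        proposal_sigma=config.proposal_sigma,
    )
    series = run_umbrella_protocol(
        surface, protocol, seed=config.seed if seed is None else seed
    )
    hist = build_histograms(series, bin_width=config.bin_width)
    pmf = solve_wham(hist, tol=config.tolerance, max_iter=config.max_iterations)
    return PathwayResult(
        surface=surface,
        series=series,
        histograms=hist,
        pmf=pmf,
        energetics=pathway_energetics(pmf),
    )
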