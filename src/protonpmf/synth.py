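"""Synthetic inputs with known ground truth.

Every generator is deterministic under a fixed seed and returns (or writes)
its own parameters alongside the data, so parameter-recovery tests can be
asserted automatically:

* Ornstein–Uhlenbeck distance series with prescribed stationary mean/SD and
  relaxation time (emulating interatomic distance fluctuations);
* correlated (distance, integer water-count) pairs with a calibrated
  population Pearson correlation;
* two-state Markov hydrogen-bond event chains with prescribed stationary
  occupancy and mean dwell time;
* i.i.d. Boltzmann draws from a biased window density (the exact-sampling
  oracle that bypasses the Metropolis sampler in WHAM tests);
* small multi-model Cα-only structure fixtures with per-region jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DOMAIN, KB, TEMPERATURE
from .sampling import BiasWindow, WindowTimeseries
from .surfaces import Surface1D
from .trajectory import StructureModel


@dataclass(frozen=True)
class OUParams:
    """Stationary Ornstein–Uhlenbeck parameters for a distance channel."""

    mean: float
    sd: float
    relaxation_frames: float = 2.0
    length: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("stationary SD must be nonnegative")
        if self.relaxation_frames < 1:
            raise ValueError("relaxation time must be at least one frame")


def gen_ou_series(params: OUParams) -> np.ndarray:
    """Exact-discretization OU updates started from the stationary law.

    x_{t+1} = mu + a (x_t - mu) + sd sqrt(1 - a^2) eps,  a = exp(-1/tau),
    which leaves the stationary N(mu, sd^2) invariant at every step and has
    lag-1 autocorrelation exactly a.
    """
    rng = np.random.default_rng(params.seed)
    a = np.exp(-1.0 / params.relaxation_frames)
    noise_scale = params.sd * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(params.length)
    x = np.empty(params.length)
    x[0] = params.mean + params.sd * eps[0]
    for t in range(1, params.length):
        x[t] = params.mean + a * (x[t - 1] - params.mean) + noise_scale * eps[t]
    return x


@dataclass(frozen=True)
class EventChainParams:
    """Two-state Markov chain parameters for a hydrogen-bond event channel."""

    occupancy: float
    mean_dwell_frames: float = 20.0
    length: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.mean_dwell_frames < 1:
            raise ValueError("mean dwell must be at least one frame")


def event_chain_rates(params: EventChainParams) -> tuple[float, float]:
    """(P(on->off), P(off->on)) realizing the stationary occupancy and dwell.

    The on-state dwell is geometric with mean ``mean_dwell_frames`` so
    q_off = 1/dwell; stationarity pi_on q_off = pi_off q_on fixes q_on.
    Raises when the implied q_on exceeds 1.
    """
    pi = params.occupancy
    if pi in (0.0, 1.0):
        return 0.0, 0.0
    q_off = 1.0 / params.mean_dwell_frames
    q_on = pi * q_off / (1.0 - pi)
    if q_on > 1.0:
        raise ValueError(
            f"occupancy {pi} with mean dwell {params.mean_dwell_frames} "
            f"requires off->on rate {q_on:.3f} > 1"
        )
    return q_off, q_on


def gen_event_chain(params: EventChainParams) -> np.ndarray:
    """Boolean series from the two-state chain, started from stationarity."""
    if params.occupancy == 1.0:
        return np.ones(params.length, dtype=bool)
    if params.occupancy == 0.0:
        return np.zeros(params.length, dtype=bool)
    q_off, q_on = event_chain_rates(params)
    rng = np.random.default_rng(params.seed)
    u = rng.random(params.length)
    out = np.empty(params.length, dtype=bool)
    state = u[0] < params.occupancy
    out[0] = state
    for t in range(1, params.length):
        if state:
            state = u[t] >= q_off
        else:
            state = u[t] < q_on
        out[t] = state
    return out


def _count_transform_population_corr(
    rho: float, count_mean: float, count_sd: float, n_quad: int = 4001
) -> float:
    """Population corr of (X, g(Y)) for standard bivariate normal (X, Y).

    g(y) = max(0, round(count_mean + count_sd * y)).  Using
    Cov(X, g(Y)) = rho * Cov(Y, g(Y)) (Gaussian conditioning), the result is
    rho * Cov(Y, g(Y)) / SD(g(Y)), evaluated by quadrature over the
    standard-normal density.
    """
    y = np.linspace(-8.0, 8.0, n_quad)
    phi = np.exp(-0.5 * y * y) / np.sqrt(2.0 * np.pi)
    g = np.maximum(np.rint(count_mean + count_sd * y), 0.0)
    w = phi / phi.sum()
    eg = np.sum(w * g)
    var_g = np.sum(w * (g - eg) ** 2)
    if var_g <= 0:
        raise ValueError("count transform is degenerate (zero variance)")
    cov_yg = np.sum(w * y * (g - eg))
    return float(rho * cov_yg / np.sqrt(var_g))


def gen_correlated_pair(
    r_target: float,
    distance_params: OUParams,
    count_mean: float,
    count_sd: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance series and integer count series with population corr = r_target.

    A latent standardized OU pair (z_d, z_c) with per-frame correlation rho*
    drives both channels; the count channel is the clipped rounding of an
    affine transform of z_c.  rho* is found by monotone bisection so the
    *population* correlation of the emitted pair equals ``r_target`` within
    0.002 (rounding/clipping attenuates the latent correlation).
    """
    if not abs(r_target) < 1:
        raise ValueError("|r_target| must be below 1")
    if count_sd <= 0 and r_target != 0:
        raise ValueError("count_sd = 0 cannot realize a nonzero correlation")

    if r_target == 0.0:
        rho = 0.0
    else:
        # population corr is monotone and odd in rho; bisect on |rho|
        lo, hi = 0.0, 1.0
        sign = np.sign(r_target)
        if _count_transform_population_corr(1.0, count_mean, count_sd) < abs(r_target):
            raise ValueError(
                "requested correlation infeasible for this count discretization"
            )
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _count_transform_population_corr(mid, count_mean, count_sd) < abs(
                r_target
            ):
                lo = mid
            else:
                hi = mid
        rho = sign * 0.5 * (lo + hi)

    rng = np.random.default_rng(seed)
    n = distance_params.length
    tau = distance_params.relaxation_frames
    a = np.exp(-1.0 / tau)
    sq = np.sqrt(1.0 - a * a)

    def standardized_ou(eps):
        z = np.empty(n)
        z[0] = eps[0]
        for t in range(1, n):
            z[t] = a * z[t - 1] + sq * eps[t]
        return z

    z_d = standardized_ou(rng.standard_normal(n))
    z_ind = standardized_ou(rng.standard_normal(n))
    z_c = rho * z_d + np.sqrt(1.0 - rho * rho) * z_ind

    distance = distance_params.mean + distance_params.sd * z_d
    counts = np.maximum(np.rint(count_mean + count_sd * z_c), 0.0).astype(int)
    return distance, counts


def gen_boltzmann_window_samples(
    surface: Surface1D,
    window: BiasWindow,
    n: int,
    seed: int = 0,
    temperature: float = TEMPERATURE,
    grid_points: int = 8001,
) -> WindowTimeseries:
    """i.i.d. draws from exp(-(U + bias)/kT) by inverse-CDF on a dense grid.

    This is the exact-sampling oracle: it shares no code with the Metropolis
    sampler, so agreement of WHAM outputs between the two routes is an
    independent check of the chain.
    """
    kt = KB * temperature
    grid = np.linspace(DOMAIN[0], DOMAIN[1], grid_points)
    u = surface.energy(grid) + 0.5 * window.k * (grid - window.d_ref) ** 2
    u = u - u.min()
    pdf = np.exp(-u / kt)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    if cdf[-1] <= 0:
        raise FloatingPointError("biased density not integrable")
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    samples = np.interp(rng.random(n), cdf, grid)
    return WindowTimeseries(
        window=window, samples=samples, seed=seed, discarded=0, acceptance_rate=1.0
    )


# ---------------------------------------------------------------------------
# structure fixtures
# ---------------------------------------------------------------------------

#: Default region layout: 4 "helices" of 12 residues alternating with 4
#: "loops" of 4 residues — the smallest chain exercising region masks.
DEFAULT_REGIONS = [("helix", 12), ("loop", 4)] * 4


def _backbone_curve(n_res: int) -> np.ndarray:
    """Smooth synthetic Cα trace: a gentle helix-like spiral, 3.8 Å spacing."""
    t = np.arange(n_res) * 0.6
    return np.stack(
        [6.0 * np.cos(t), 6.0 * np.sin(t), 1.5 * np.arange(n_res)], axis=1
    )


def gen_structure_models(
    n_models: int,
    region_spec: list[tuple[str, int]] | None = None,
    jitter_spec: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[StructureModel], dict[str, np.ndarray]]:
    """Multi-model Cα-only structure with per-region Gaussian jitter.

    Model 0 is the unperturbed reference; models 1..n-1 add isotropic
    Gaussian noise with the per-region sigma from ``jitter_spec`` (Å).
    Returns the models and the boolean region masks.
    """
    region_spec = region_spec or DEFAULT_REGIONS
    jitter_spec = jitter_spec or {}
    labels: list[str] = []
    for name, count in region_spec:
        labels.extend([name] * count)
    n_res = len(labels)
    base = _backbone_curve(n_res)
    masks = {
        name: np.array([lab == name for lab in labels])
        for name in dict(region_spec)
    }
    sigma = np.array([jitter_spec.get(lab, 0.0) for lab in labels])[:, None]
    rng = np.random.default_rng(seed)
    resnames = ["ALA" if lab == "helix" else "GLY" for lab in labels]
    models = []
    for m in range(n_models):
        coords = base.copy()
        if m > 0:
            coords = coords + sigma * rng.standard_normal((n_res, 3))
        models.append(
            StructureModel(
                atom_names=["CA"] * n_res,
                residue_ids=np.arange(1, n_res + 1),
                residue_names=resnames,
                chain_ids=["A"] * n_res,
                coords=coords,
                model_index=m,
            )
        )
    return models, masks


def gen_structure_fixture(
    path,
    n_models: int,
    region_spec: list[tuple[str, int]] | None = None,
    jitter_spec: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Write the multi-model fixture as a standards-conforming PDB file."""
    from .io import write_structure  # local import to avoid a cycle

    models, masks = gen_structure_models(n_models, region_spec, jitter_spec, seed)
    write_structure(models, path)
    return masks
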