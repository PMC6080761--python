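"""Structural statistics on per-frame trajectory tables and structure models.

Covers the descriptive analyses of the molecular-dynamics part of the study:
hydrogen-bond occupancies, active-site water counts, distance/hydration
correlation with smoothing, distance histograms and percentile summaries,
Kabsch-superposed Cα RMSD by structural region, and simple interatomic
distance measurements on structure models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Partners whose occupancy falls below this percentage are suppressed in
#: occupancy reports ("only percentages >3% are shown").
OCCUPANCY_REPORT_FLOOR = 3.0


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition (MD-community convention).

    A frame counts as bonded when the donor–acceptor heavy-atom distance is
    at most ``distance_cutoff`` Å and the donor–hydrogen–acceptor angle is at
    least ``angle_cutoff`` degrees.
    """

    distance_cutoff: float = 3.5
    angle_cutoff: float = 140.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("hydrogen-bond cutoffs must be positive")

    def evaluate(self, distances: np.ndarray, angles: np.ndarray) -> np.ndarray:
        d = np.asarray(distances, dtype=float)
        a = np.asarray(angles, dtype=float)
        if d.shape != a.shape:
            raise ValueError("distance and angle series must have equal length")
        return (d <= self.distance_cutoff) & (a >= self.angle_cutoff)


@dataclass
class TrajectoryTable:
    """Per-frame observables: distances (Å), integer counts, boolean events."""

    frames: pd.DataFrame
    frame_spacing_ps: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.frames, pd.DataFrame):
            self.frames = pd.DataFrame(self.frames)
        for col in self.frames.columns:
            vals = self.frames[col]
            if pd.api.types.is_integer_dtype(vals) and (vals < 0).any():
                raise ValueError(f"count channel {col!r} has negative values")

    def __len__(self) -> int:
        return len(self.frames)

    def analysis_span(self, fraction: float = 0.5) -> pd.DataFrame:
        """Final ``fraction`` of frames (default: last half, the study's
        'last 50 ns' convention)."""
        start = int(np.ceil(len(self.frames) * (1.0 - fraction)))
        return self.frames.iloc[start:]


def hbond_occupancy(
    events=None,
    distances=None,
    angles=None,
    criteria: HBondCriteria | None = None,
) -> int:
    """Occupancy of one hydrogen bond as an integer percentage of frames.

    Pass either a boolean ``events`` series, or geometry series
    (``distances``, ``angles``) plus :class:`HBondCriteria`.
    """
    if events is None:
        if distances is None or angles is None:
            raise ValueError("supply events, or distances + angles with criteria")
        events = (criteria or HBondCriteria()).evaluate(distances, angles)
    events = np.asarray(events, dtype=bool)
    if events.size == 0:
        raise ValueError("empty event series")
    return int(round(100.0 * events.mean()))


def occupancy_report(event_channels: dict[str, np.ndarray]) -> dict[str, int]:
    """Per-partner occupancies with sub-3% partners suppressed."""
    out = {}
    for name, events in event_channels.items():
        pct = hbond_occupancy(events)
        if pct > OCCUPANCY_REPORT_FLOOR:
            out[name] = pct
    return out


def water_count_series(
    table: TrajectoryTable, channel: str, span_fraction: float = 0.5
) -> tuple[float, float]:
    """Mean and sample SD of a count channel over the analysis span."""
    frames = table.analysis_span(span_fraction)
    if channel not in frames.columns:
        raise KeyError(f"channel {channel!r} not in trajectory table")
    vals = frames[channel].to_numpy(dtype=float)
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def pearson(x, y) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a channel has zero variance")
    return float(stats.pearsonr(x, y).statistic)


def smooth(series, window_frames: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the edges.

    Output has the same length as the input.  ``window_frames`` must be odd
    (a centred window) and no longer than the series.
    """
    x = np.asarray(series, dtype=float)
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValueError("window must be a positive odd number of frames")
    if window_frames > len(x):
        raise ValueError("window longer than series")
    half = window_frames // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    idx = np.arange(n)
    h = np.minimum(np.minimum(idx, n - 1 - idx), half)
    lo = idx - h
    hi = idx + h + 1
    return (csum[hi] - csum[lo]) / (hi - lo)


def distance_histogram(
    series, bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Density-normalized distance histogram plus detected modes.

    Returns ``(density, edges, modes)`` where modes are bin-centre positions
    of local maxima of the lightly smoothed density (primary mode first).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(density) >= 3:
        win = min(5, len(density) if len(density) % 2 else len(density) - 1)
        sm = smooth(density, win)
    else:
        sm = density
    modes = []
    for i in range(len(sm)):
        left = sm[i - 1] if i > 0 else -np.inf
        right = sm[i + 1] if i < len(sm) - 1 else -np.inf
        if sm[i] > left and sm[i] >= right:
            modes.append((sm[i], centers[i]))
    modes.sort(reverse=True)
    return density, edges, [m for _, m in modes]


def percentiles(series) -> dict[int, float]:
    """5/25/50/75/95th percentiles with linear interpolation (type-7)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    qs = (5, 25, 50, 75, 95)
    vals = np.percentile(x, qs, method="linear")
    return {q: float(v) for q, v in zip(qs, vals)}


# ---------------------------------------------------------------------------
# structure-model operations
# ---------------------------------------------------------------------------


@dataclass
class StructureModel:
    """One model of a (possibly multi-model) structure: labelled point cloud."""

    atom_names: list[str]
    residue_ids: np.ndarray
    residue_names: list[str]
    chain_ids: list[str]
    coords: np.ndarray  # (n_atoms, 3), Å
    model_index: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in structure model")

    def atom_key(self, i: int) -> str:
        return f"{self.chain_ids[i]}/{self.residue_names[i]}{self.residue_ids[i]}/{self.atom_names[i]}"

    def find_atom(self, chain: str, resid: int, atom_name: str) -> int:
        for i in range(len(self.atom_names)):
            if (
                self.chain_ids[i] == chain
                and int(self.residue_ids[i]) == resid
                and self.atom_names[i] == atom_name
            ):
                return i
        candidates = sorted(
            {
                self.atom_key(i)
                for i in range(len(self.atom_names))
                if int(self.residue_ids[i]) == resid and self.chain_ids[i] == chain
            }
        )
        raise KeyError(
            f"atom {chain}/{resid}/{atom_name} not found; "
            f"nearby atoms: {', '.join(candidates[:8]) or 'none in that residue'}"
        )


class DegenerateSuperpositionError(ValueError):
    """Selection too small or collinear for a unique superposition."""


def kabsch_rmsd(
    coords_ref: np.ndarray,
    coords_mov: np.ndarray,
    selection_mask: np.ndarray | None = None,
    return_transform: bool = False,
):
    """RMSD after least-squares optimal rigid superposition (Kabsch).

    The optimal rotation is obtained from the SVD of the covariance matrix
    with the determinant correction that enforces a proper rotation.
    """
    a = np.asarray(coords_ref, dtype=float)
    b = np.asarray(coords_mov, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    if selection_mask is not None:
        mask = np.asarray(selection_mask, dtype=bool)
        a, b = a[mask], b[mask]
    if len(a) < 3:
        raise DegenerateSuperpositionError("need at least 3 atoms to superpose")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    cov = bc.T @ ac
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise DegenerateSuperpositionError("collinear selection: rotation not unique")
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt
    b_fit = bc @ rot
    rmsd = float(np.sqrt(np.mean(np.sum((b_fit - ac) ** 2, axis=1))))
    if return_transform:
        return rmsd, rot, a.mean(axis=0), b.mean(axis=0)
    return rmsd


def rmsd_profile(
    models: list[StructureModel],
    reference: StructureModel,
    region_masks: dict[str, np.ndarray],
    superpose_mask: np.ndarray | None = None,
    span_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-model, per-region RMSD after one global superposition per model.

    Each model is superposed on ``reference`` using ``superpose_mask``
    (default: all atoms — for Cα-only fixtures this is the full-protein Cα
    set), then the RMSD is evaluated over each region mask without
    re-fitting.  Returns a frame with one row per model plus ``mean``/``sd``
    summary rows over the final ``span_fraction`` of models.
    """
    ref = reference.coords
    n = len(ref)
    if superpose_mask is None:
        superpose_mask = np.ones(n, dtype=bool)
    rows = []
    for m in models:
        if m.coords.shape != ref.shape:
            raise ValueError(
                f"model {m.model_index}: atom count {len(m.coords)} != reference {n}"
            )
        _, rot, ref_cent, mov_cent = kabsch_rmsd(
            ref, m.coords, superpose_mask, return_transform=True
        )
        fitted = (m.coords - mov_cent) @ rot + ref_cent
        dev2 = np.sum((fitted - ref) ** 2, axis=1)
        row = {"model": m.model_index}
        row["all"] = float(np.sqrt(dev2[superpose_mask].mean()))
        for name, mask in region_masks.items():
            mask = np.asarray(mask, dtype=bool)
            row[name] = float(np.sqrt(dev2[mask].mean()))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("model")
    start = int(np.ceil(len(df) * (1.0 - span_fraction)))
    tail = df.iloc[start:]
    df.attrs["mean"] = tail.mean().to_dict()
    df.attrs["sd"] = tail.std(ddof=1).to_dict() if len(tail) > 1 else {
        c: 0.0 for c in df.columns
    }
    return df


def measure_distance(
    model: StructureModel, atom_a: tuple[str, int, str], atom_b: tuple[str, int, str]
) -> float:
    """Euclidean distance (Å) between two atoms given as (chain, resid, name)."""
    i = model.find_atom(*atom_a)
    j = model.find_atom(*atom_b)
    return float(np.linalg.norm(model.coords[i] - model.coords[j]))
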