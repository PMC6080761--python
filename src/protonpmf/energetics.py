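"""Reaction energies and barrier heights from a PMF.

A proton-transfer PMF is decomposed into the reactant state R (proton on the
Schiff base, global minimum of the D < 0 region), the product state P
(proton on the acceptor, D > 0) and the intermediate/barrier state I (the
maximum between them).  Direct-transfer PMFs often lack a clear product
valley, so P is located in three tiers: the deepest D > 0 local minimum
("clear"), a curvature-change shoulder with small slope ("shoulder"), or the
right-hand endpoint ("endpoint").  Extremum energies are refined by a
three-point parabola through the neighbouring grid values to remove binning
quantization.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pmf import PMFProfile

#: |dF/dD| below which a curvature sign change counts as a product shoulder
#: (kcal/mol/Å).
SHOULDER_SLOPE_MAX = 0.5

TABLE_COLUMNS = [
    "Path",
    "Proton Transfer",
    "Final Acceptor",
    "Monomer",
    "E162 Protonated",
    "Reaction Energy",
    "Barrier Height",
]


class NoBarrierWarning(UserWarning):
    """Emitted when the PMF has no interior maximum (barrier height 0)."""


@dataclass(frozen=True)
class StateAssignment:
    """Grid indices of the reactant / intermediate / product states."""

    reactant: int
    intermediate: int | None
    product: int
    product_valley: str  # "clear" | "shoulder" | "endpoint"
    method: str = "min-max-min"


@dataclass(frozen=True)
class PathwayEnergetics:
    """Energetics of one proton-transfer pathway, kcal/mol and Å."""

    reactant_d: float
    barrier_d: float | None
    product_d: float
    reaction_energy: float
    barrier_height: float
    product_valley: str


def _finite_block(pmf: PMFProfile) -> tuple[np.ndarray, np.ndarray]:
    """Largest contiguous run of defined PMF values containing its minimum."""
    ok = pmf.defined
    if not ok.any():
        raise ValueError("PMF has no defined values")
    idx = np.flatnonzero(ok)
    # split into contiguous runs, keep the longest
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    run = max(runs, key=len)
    return pmf.grid[run], pmf.free_energy[run]


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points (i-1, i, i+1); falls back to (x_i, y_i)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    if a == 0.0:
        return float(x[i]), float(y[i])
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    xv = -b / (2.0 * a)
    if not x0 <= xv <= x2:
        return float(x[i]), float(y[i])
    c = y1 - a * x1 * x1 - b * x1
    return float(xv), float(a * xv * xv + b * xv + c)


def _local_minima(y: np.ndarray) -> list[int]:
    out = []
    for i in range(1, len(y) - 1):
        if y[i] <= y[i - 1] and y[i] < y[i + 1]:
            out.append(i)
    return out


def locate_states(pmf: PMFProfile) -> StateAssignment:
    """Assign R, I and P on the PMF grid.

    R is the minimum over D < 0.  P is the deepest local minimum over D > 0
    when one exists; otherwise a shoulder (second-difference sign change with
    |slope| < 0.5 kcal/mol/Å); otherwise the endpoint.  I is the maximum
    between R and P.  A PMF with no interior maximum yields barrier index
    None and a :class:`NoBarrierWarning`.
    """
    x, y = _finite_block(pmf)
    if len(x) < 3:
        raise ValueError("PMF defined on fewer than 3 grid points")
    neg = x < 0
    if not neg.any():
        raise ValueError("PMF has no defined reactant (D < 0) region")
    i_r = int(np.argmin(np.where(neg, y, np.inf)))

    pos = np.flatnonzero(x > x[i_r])
    if pos.size < 2:
        raise ValueError("no product-side grid beyond the reactant minimum")

    # tier 1: clear valley — deepest local minimum with D > 0
    minima = [i for i in _local_minima(y) if x[i] > 0]
    if minima:
        i_p = min(minima, key=lambda i: y[i])
        valley = "clear"
    else:
        i_p = _find_shoulder(x, y, i_r)
        if i_p is not None:
            valley = "shoulder"
        else:
            i_p = len(x) - 1
            valley = "endpoint"

    between = np.arange(i_r + 1, i_p)
    if between.size == 0 or np.max(y[between]) <= max(y[i_r], y[i_p]):
        warnings.warn(
            "PMF has no interior maximum between reactant and product; "
            "barrier height set to 0",
            NoBarrierWarning,
            stacklevel=2,
        )
        i_i = None
    else:
        i_i = int(between[np.argmax(y[between])])

    # map back to full-grid indices
    offset = int(np.flatnonzero(pmf.grid == x[0])[0])
    return StateAssignment(
        reactant=i_r + offset,
        intermediate=None if i_i is None else i_i + offset,
        product=i_p + offset,
        product_valley=valley,
    )


def _find_shoulder(x: np.ndarray, y: np.ndarray, i_r: int) -> int | None:
    """Second-difference sign change at small |slope| on the product side."""
    d1 = np.gradient(y, x)
    d2 = np.gradient(d1, x)
    sign_change = np.flatnonzero(np.sign(d2[:-1]) * np.sign(d2[1:]) < 0)
    candidates = [
        i
        for i in sign_change
        if x[i] > 0 and i > i_r + 1 and abs(d1[i]) < SHOULDER_SLOPE_MAX
    ]
    if candidates:
        return int(min(candidates, key=lambda i: abs(d1[i])))
    return None


def pathway_energetics(pmf: PMFProfile) -> PathwayEnergetics:
    """Reaction energy and barrier height with parabolic sub-bin refinement."""
    assign = locate_states(pmf)
    x, y = pmf.grid, pmf.free_energy
    xr, fr = _parabolic_refine(x, y, assign.reactant)
    if assign.product_valley == "clear":
        xp, fp = _parabolic_refine(x, y, assign.product)
    else:
        xp, fp = float(x[assign.product]), float(y[assign.product])
    if assign.intermediate is None:
        xb, fb = None, fr
    else:
        xb, fb = _parabolic_refine(x, y, assign.intermediate)
    return PathwayEnergetics(
        reactant_d=xr,
        barrier_d=xb,
        product_d=xp,
        reaction_energy=fp - fr,
        barrier_height=max(fb - fr, 0.0),
        product_valley=assign.product_valley,
    )


def energetics_table(
    paths: list[tuple[object, PathwayEnergetics, dict]]
) -> pd.DataFrame:
    """Report table with one row per pathway.

    Each entry is ``(path_id, energetics, metadata)`` where metadata may
    carry 'proton_transfer' ("direct"/"via water"), 'final_acceptor',
    'monomer' and 'e162_protonated'.  Energies are reported to 0.1 kcal/mol.
    Rows are ordered by path id; duplicate ids are rejected.
    """
    ids = [p[0] for p in paths]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate path ids in energetics table")
    rows = []
    for path_id, en, meta in sorted(paths, key=lambda p: str(p[0])):
        rows.append(
            {
                "Path": path_id,
                "Proton Transfer": meta.get("proton_transfer", ""),
                "Final Acceptor": meta.get("final_acceptor", ""),
                "Monomer": meta.get("monomer", ""),
                "E162 Protonated": meta.get("e162_protonated", ""),
                "Reaction Energy": round(en.reaction_energy, 1),
                "Barrier Height": round(en.barrier_height, 1),
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_energetics_table(df: pd.DataFrame, path, header_comment: str = "") -> None:
    """Tab-separated table with '#'-prefixed header comments."""
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_energetics_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
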