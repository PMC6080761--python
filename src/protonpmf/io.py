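"""File formats and run configuration.

Window time-series files follow the de-facto standard umbrella-sampling
layout used by command-line WHAM tools: one two-column whitespace-delimited
file per window (time index, D in Å) plus a metadata file listing
``path  D_ref  k`` one window per line, with ``#`` comments.  Structures are
plain PDB, parsed with Biopython.  Run configuration is strict-schema YAML.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.PDB import PDBParser

from .constants import DEFAULT_FORCE_CONSTANT
from .sampling import BiasWindow, WindowTimeseries
from .trajectory import StructureModel


class WindowFileError(ValueError):
    """Malformed window time-series or metadata file."""


METADATA_NAME = "windows.meta"


def write_window_files(series: list[WindowTimeseries], directory) -> Path:
    """One series file per window plus a metadata file; returns its path.

    Samples are written to 6 decimals, so a round-trip is value-exact at
    that precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_lines = ["# path  D_ref(A)  k(kcal/mol/A^2)"]
    seen_refs = set()
    for ts in series:
        if ts.window.d_ref in seen_refs:
            raise WindowFileError(f"duplicate window D_ref {ts.window.d_ref}")
        seen_refs.add(ts.window.d_ref)
        fname = f"window_{ts.window.d_ref:+.2f}.dat"
        with open(directory / fname, "w") as fh:
            fh.write(f"# seed={ts.seed} discarded={ts.discarded}\n")
            for i, d in enumerate(ts.samples):
                fh.write(f"{i} {d:.6f}\n")
        meta_lines.append(f"{fname} {ts.window.d_ref:.6f} {ts.window.k:.6f}")
    meta_path = directory / METADATA_NAME
    meta_path.write_text("\n".join(meta_lines) + "\n")
    return meta_path


def read_window_files(metadata_path) -> list[WindowTimeseries]:
    """Read a metadata file and its window series back into memory."""
    metadata_path = Path(metadata_path)
    base = metadata_path.parent
    series: list[WindowTimeseries] = []
    seen_refs = set()
    for lineno, raw in enumerate(metadata_path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise WindowFileError(
                f"{metadata_path}:{lineno}: expected 'path D_ref k', got {raw!r}"
            )
        try:
            d_ref, k = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise WindowFileError(f"{metadata_path}:{lineno}: {exc}") from exc
        if d_ref in seen_refs:
            raise WindowFileError(f"{metadata_path}:{lineno}: duplicate D_ref {d_ref}")
        seen_refs.add(d_ref)
        samples = _read_series_file(base / parts[0])
        window = BiasWindow(
            d_ref=d_ref, k=k, prod_sweeps=len(samples), label=len(series)
        )
        series.append(WindowTimeseries(window=window, samples=samples, seed=0))
    if not series:
        raise WindowFileError(f"{metadata_path}: no windows listed")
    return series


def _read_series_file(path: Path) -> np.ndarray:
    values = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise WindowFileError(
                f"{path}:{lineno}: expected two columns, got {raw!r}"
            )
        try:
            values.append(float(parts[1]))
        except ValueError as exc:
            raise WindowFileError(f"{path}:{lineno}: {exc}") from exc
    if not values:
        raise WindowFileError(f"{path}: no samples")
    return np.array(values)


# ---------------------------------------------------------------------------
# PMF tables
# ---------------------------------------------------------------------------


def write_pmf_table(profile, path, header_comment: str = "") -> None:
    """Tab-separated PMF table (D, F) with '#'-prefixed header comments.

    Values are written with 17 significant digits, so a round-trip through
    :func:`read_pmf_table` is bit-exact; undefined bins are written as nan.
    """
    with open(path, "w") as fh:
        for line in header_comment.splitlines():
            fh.write(f"# {line}\n")
        fh.write(f"# temperature={profile.temperature:.17g} source={profile.source}\n")
        fh.write("# D(A)\tF(kcal/mol)\n")
        for d, f in zip(profile.grid, profile.free_energy):
            fh.write(f"{d:.17g}\t{f:.17g}\n")


def read_pmf_table(path):
    """Read a PMF table written by :func:`write_pmf_table`."""
    from .pmf import PMFProfile  # local import to avoid a cycle

    temperature = None
    grid, free_energy = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if raw.startswith("#"):
            for token in raw[1:].split():
                if token.startswith("temperature="):
                    temperature = float(token.split("=", 1)[1])
            continue
        if not raw.strip():
            continue
        parts = raw.split()
        if len(parts) != 2:
            raise WindowFileError(f"{path}:{lineno}: expected two columns, got {raw!r}")
        try:
            grid.append(float(parts[0]))
            free_energy.append(float(parts[1]))
        except ValueError as exc:
            raise WindowFileError(f"{path}:{lineno}: {exc}") from exc
    if not grid:
        raise WindowFileError(f"{path}: no PMF rows")
    if temperature is None:
        from .constants import TEMPERATURE

        temperature = TEMPERATURE
    return PMFProfile(
        grid=np.array(grid),
        free_energy=np.array(free_energy),
        temperature=temperature,
        source="file",
    )


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def read_structure(path) -> list[StructureModel]:
    """Parse a PDB file into one :class:`StructureModel` per MODEL record."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models: list[StructureModel] = []
    for m_idx, model in enumerate(structure):
        names, resids, resnames, chains, coords = [], [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    names.append(atom.get_name())
                    het, resseq, icode = residue.get_id()
                    resids.append(resseq)
                    resnames.append(residue.get_resname())
                    chains.append(chain.get_id())
                    coords.append(atom.get_coord())
        if not names:
            continue
        models.append(
            StructureModel(
                atom_names=names,
                residue_ids=np.array(resids),
                residue_names=resnames,
                chain_ids=chains,
                coords=np.array(coords, dtype=float),
                model_index=m_idx,
            )
        )
    if not models:
        raise WindowFileError(f"{path}: no ATOM records")
    return models


def write_structure(models: list[StructureModel], path) -> None:
    """Write models as a multi-model PDB (fixed-width ATOM records)."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(f"MODEL     {m.model_index + 1:4d}\n")
            for i in range(len(m.atom_names)):
                x, y, z = m.coords[i]
                name = m.atom_names[i]
                pad = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {i + 1:5d} {pad}{'':1s}{m.residue_names[i]:>3s} "
                    f"{m.chain_ids[i]:1s}{int(m.residue_ids[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{(name[0] if name else 'C'):>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full simulate→WHAM→energetics run."""

    # surface
    kind: str = "direct"                   # direct | water_mediated
    reaction_energy: float = 17.6
    barrier_height: float = 18.7
    reactant_position: float = -1.2
    product_position: float = 1.2
    # protocol
    acceptor_kind: str = "amino_acid"      # amino_acid | water
    force_constant: float = DEFAULT_FORCE_CONSTANT
    window_equil_sweeps: int = 25_000
    prod_sweeps: int = 25_000
    proposal_sigma: float = 0.05
    # wham
    bin_width: float = 0.05
    tolerance: float = 1e-7
    max_iterations: int = 100_000
    # analysis
    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 140.0
    analysis_span_fraction: float = 0.5
    smoothing_window: int = 101
    # seeds
    seed: int = 0
    # reporting
    path_id: int | str = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "water_mediated"):
            raise ValueError(f"surface.kind must be direct|water_mediated, got {self.kind!r}")
        if self.acceptor_kind not in ("amino_acid", "water"):
            raise ValueError(f"protocol.acceptor_kind invalid: {self.acceptor_kind!r}")
        if not 0 < self.bin_width <= 0.5:
            raise ValueError("wham.bin_width must lie in (0, 0.5] Å")
        if self.tolerance <= 0:
            raise ValueError("wham.tolerance must be positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("analysis.smoothing_window must be odd and positive")
        if not 0 < self.analysis_span_fraction <= 1:
            raise ValueError("analysis.analysis_span_fraction must lie in (0, 1]")


_SECTION_KEYS = {
    "surface": {
        "kind",
        "reaction_energy",
        "barrier_height",
        "reactant_position",
        "product_position",
    },
    "protocol": {
        "acceptor_kind",
        "force_constant",
        "window_equil_sweeps",
        "prod_sweeps",
        "proposal_sigma",
    },
    "wham": {"bin_width", "tolerance", "max_iterations"},
    "analysis": {
        "hbond_distance_cutoff",
        "hbond_angle_cutoff",
        "analysis_span_fraction",
        "smoothing_window",
    },
    "report": {"path_id", "metadata"},
}


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping of sections")
    kwargs = {}
    for section, payload in raw.items():
        if section == "seed":
            kwargs["seed"] = int(payload)
            continue
        if section not in _SECTION_KEYS:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(payload, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        unknown = set(payload) - _SECTION_KEYS[section]
        if unknown:
            raise ValueError(f"unknown keys in section {section!r}: {sorted(unknown)}")
        kwargs.update(payload)
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of a configuration, for table header provenance."""
    blob = yaml.safe_dump(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def default_config_path() -> Path:
    return Path(__file__).parent / "data" / "default_config.yaml"
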