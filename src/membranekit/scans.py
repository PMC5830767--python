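"""Data model and I/O for instrument scans and membrane configuration frames.

Triple-axis scans are stored as plain-text TSV with ``#``-prefixed metadata
lines; membrane frames are read from GRO/PDB coordinate files through
MDAnalysis. All quantities follow the package units (Å, Å⁻¹, meV, K, counts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K

__all__ = [
    "Scan",
    "ReflectivityScan",
    "MembraneFrame",
    "read_scan",
    "write_scan",
    "read_reflectivity",
    "write_reflectivity",
    "read_frames",
    "write_frames",
]

KNOWN_RESIDUES = frozenset({"DMPC", "CHOL", "ASA", "SOL"})


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class Scan:
    """One triple-axis scan: constant-q energy scan or constant-E q scan.

    Parameters
    ----------
    kind : {"constant_q", "constant_E"}
    fixed_value : float
        q_parallel in Å⁻¹ for constant_q scans, energy transfer in meV for
        constant_E scans.
    axis : array
        Strictly increasing scan axis (meV for constant_q, Å⁻¹ for constant_E).
    counts, errors : array
        Detector counts (≥ 0) and their uncertainties (> 0).
    temperature : float
        Sample temperature in K (enters detailed balance).
    sigma_el : float
        Gaussian width of the elastic line in meV, supplied by the instrument
        configuration (resolution-ellipsoid computation is out of scope).
    meta : dict
        Free-form metadata; generators attach ground truth here.
    """

    kind: str
    fixed_value: float
    axis: np.ndarray
    counts: np.ndarray
    errors: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K
    sigma_el: float = 0.3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("constant_q", "constant_E"):
            raise ValueError(f"unknown scan kind {self.kind!r}")
        self.axis = _as_float_array(self.axis, "axis")
        self.counts = _as_float_array(self.counts, "counts")
        self.errors = _as_float_array(self.errors, "errors")
        n = len(self.axis)
        if not (len(self.counts) == len(self.errors) == n):
            raise ValueError("axis, counts and errors must have equal length")
        if n < 8:
            raise ValueError(f"scan needs at least 8 points, got {n}")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("scan axis must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.errors <= 0):
            raise ValueError("errors must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.sigma_el <= 0:
            raise ValueError("sigma_el must be positive")

    def __len__(self) -> int:
        return len(self.axis)


@dataclass
class ReflectivityScan:
    """Out-of-plane (q_z) reflectivity scan showing the lamellar Bragg series."""

    q_z: np.ndarray
    counts: np.ndarray
    errors: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q_z = _as_float_array(self.q_z, "q_z")
        self.counts = _as_float_array(self.counts, "counts")
        self.errors = _as_float_array(self.errors, "errors")
        if not (len(self.q_z) == len(self.counts) == len(self.errors)):
            raise ValueError("q_z, counts and errors must have equal length")
        if np.any(self.q_z <= 0):
            raise ValueError("q_z must be positive")
        if np.any(np.diff(self.q_z) <= 0):
            raise ValueError("q_z must be strictly increasing")

    def __len__(self) -> int:
        return len(self.q_z)


@dataclass
class MembraneFrame:
    """One membrane configuration: coordinates, labels, orthorhombic box.

    z is the bilayer normal. Lateral (x, y) coordinates are wrapped into the
    primary box on construction; z is left as stored so the two leaflets and
    the water slabs keep their sign.
    """

    positions: np.ndarray          # (n_atoms, 3), Å
    elements: np.ndarray           # str per atom
    names: np.ndarray              # atom names
    resnames: np.ndarray           # DMPC | CHOL | ASA | SOL
    resids: np.ndarray             # int per atom
    box: np.ndarray                # (Lx, Ly, Lz), Å
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        for attr in ("elements", "names", "resnames"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        self.resids = np.asarray(self.resids, dtype=int)
        n = len(self.positions)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        for attr in ("elements", "names", "resnames", "resids"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"{attr} length does not match positions")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        unknown = set(np.unique(self.resnames)) - KNOWN_RESIDUES
        if unknown:
            warnings.warn(
                f"unknown residue names retained: {sorted(unknown)}",
                stacklevel=2,
            )
        # wrap lateral coordinates into [0, L)
        self.positions[:, 0] %= self.box[0]
        self.positions[:, 1] %= self.box[1]
        finite = np.isfinite(self.positions)
        if not finite.all():
            raise ValueError("non-finite coordinates")
        if n and np.all(np.abs(self.positions) < 10.0):
            warnings.warn(
                "all coordinates are below 10 Å; input may be in nm "
                "instead of Å", stacklevel=2,
            )

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def residue_census(self) -> dict[str, int]:
        """Number of residues per residue name."""
        census: dict[str, int] = {}
        for resname, resid in {(rn, ri) for rn, ri in
                               zip(self.resnames, self.resids)}:
            census[resname] = census.get(resname, 0) + 1
        return census

    def select(self, resname: str | None = None,
               name_prefix: str | None = None,
               names: Sequence[str] | None = None,
               elements: Sequence[str] | None = None) -> np.ndarray:
        """Indices of atoms matching all given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if resname is not None:
            mask &= self.resnames == resname
        if name_prefix is not None:
            mask &= np.array([str(nm).startswith(name_prefix)
                              for nm in self.names])
        if names is not None:
            allowed = set(names)
            mask &= np.array([str(nm) in allowed for nm in self.names])
        if elements is not None:
            allowed = set(elements)
            mask &= np.array([str(el) in allowed for el in self.elements])
        return np.nonzero(mask)[0]

    def bilayer_center(self) -> float:
        """z of the lipid (DMPC + CHOL) centre of geometry."""
        lipid = np.isin(self.resnames, ("DMPC", "CHOL"))
        if not lipid.any():
            lipid = slice(None)
        return float(np.mean(self.positions[lipid, 2]))


# ---------------------------------------------------------------------------
# scan TSV dialect
# ---------------------------------------------------------------------------

_META_KEYS = ("kind", "fixed_value", "temperature", "sigma_el")


def write_scan(scan: Scan, path) -> None:
    """Write a scan in the package TSV dialect (round-trips bit-for-bit)."""
    lines = [f"# kind: {scan.kind}",
             f"# fixed_value: {float(scan.fixed_value)!r}",
             f"# temperature: {float(scan.temperature)!r}",
             f"# sigma_el: {float(scan.sigma_el)!r}"]
    for a, c, e in zip(scan.axis, scan.counts, scan.errors):
        lines.append(f"{float(a)!r}\t{float(c)!r}\t{float(e)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_table(path) -> tuple[dict, np.ndarray]:
    meta: dict = {}
    rows: list[list[float]] = []
    ncols = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: {line!r}"
                ) from exc
            if len(row) < 2:
                raise ValueError(
                    f"{path}: line {lineno} has fewer than 2 columns")
            if ncols is None:
                ncols = len(row)
            elif len(row) != ncols:
                raise ValueError(
                    f"{path}: inconsistent column count at line {lineno}")
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return meta, np.asarray(rows, dtype=float)


def _errors_from_columns(table: np.ndarray) -> np.ndarray:
    if table.shape[1] >= 3:
        return table[:, 2].copy()
    # Poisson floor: a zero count would give zero weight otherwise
    return np.maximum(1.0, np.sqrt(table[:, 1]))


def read_scan(path, kind: str | None = None, sigma_el: float | None = None,
              temperature: float | None = None) -> Scan:
    """Read a TSV scan file.

    Columns are (axis, counts[, error]); header metadata lines start with
    ``#``. Explicit arguments override file metadata. Missing errors default
    to max(1, sqrt(counts)). The axis is sorted ascending with counts and
    errors permuted accordingly.
    """
    meta, table = _parse_table(path)
    kind = kind or meta.get("kind")
    if kind is None:
        raise ValueError(f"{path}: scan kind not given and not in metadata")
    sigma_el = sigma_el if sigma_el is not None else float(
        meta.get("sigma_el", 0.3))
    temperature = temperature if temperature is not None else float(
        meta.get("temperature", DEFAULT_TEMPERATURE_K))
    fixed_value = float(meta.get("fixed_value", math.nan))
    errors = _errors_from_columns(table)
    order = np.argsort(table[:, 0], kind="stable")
    return Scan(kind=kind, fixed_value=fixed_value, axis=table[order, 0],
                counts=table[order, 1], errors=errors[order],
                temperature=temperature, sigma_el=sigma_el,
                meta={k: v for k, v in meta.items() if k not in _META_KEYS})


def write_reflectivity(scan: ReflectivityScan, path) -> None:
    lines = ["# kind: reflectivity"]
    for a, c, e in zip(scan.q_z, scan.counts, scan.errors):
        lines.append(f"{float(a)!r}\t{float(c)!r}\t{float(e)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_reflectivity(path) -> ReflectivityScan:
    """Read an out-of-plane (q_z, counts[, error]) TSV scan."""
    meta, table = _parse_table(path)
    errors = _errors_from_columns(table)
    order = np.argsort(table[:, 0], kind="stable")
    return ReflectivityScan(q_z=table[order, 0], counts=table[order, 1],
                            errors=errors[order], meta=meta)


# ---------------------------------------------------------------------------
# membrane frames via MDAnalysis
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    for ch in str(name):
        if ch.isalpha():
            return ch.upper()
    return "X"


def _frame_from_universe(universe, meta: dict) -> MembraneFrame:
    atoms = universe.atoms
    if universe.dimensions is None or np.any(universe.dimensions[:3] <= 0):
        raise ValueError("coordinate file has no box record")
    try:
        elements = np.asarray(atoms.elements, dtype=object)
    except Exception:
        elements = np.asarray([_element_from_name(n) for n in atoms.names],
                              dtype=object)
    return MembraneFrame(
        positions=atoms.positions.astype(float),
        elements=elements,
        names=np.asarray(atoms.names, dtype=object),
        resnames=np.asarray(atoms.resnames, dtype=object),
        resids=np.asarray(atoms.resids, dtype=int),
        box=universe.dimensions[:3].astype(float),
        meta=dict(meta),
    )


def read_frames(paths: Iterable | str | Path) -> list[MembraneFrame]:
    """Read membrane frames from GRO/PDB coordinate files.

    Each file contributes one frame per model/trajectory frame. Coordinates
    are returned in Å (MDAnalysis convention).
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[MembraneFrame] = []
    for path in paths:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # MDAnalysis guessing chatter
            universe = mda.Universe(str(path))
        for i, _ts in enumerate(universe.trajectory):
            frames.append(_frame_from_universe(
                universe, meta={"source": str(path), "model": i}))
    return frames


def write_frames(frames: Sequence[MembraneFrame], directory,
                 prefix: str = "frame") -> list[Path]:
    """Write frames as GRO files (one file per frame); returns the paths."""
    import MDAnalysis as mda

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        resid_order = frame.resids
        # MDAnalysis wants residue-contiguous atoms; generators emit them so.
        uniq, res_index = np.unique(resid_order, return_inverse=True)
        universe = mda.Universe.empty(
            n_atoms=frame.n_atoms, n_residues=len(uniq),
            atom_resindex=res_index, trajectory=True)
        universe.add_TopologyAttr("names", [str(n) for n in frame.names])
        resname_per_res = [""] * len(uniq)
        for ri, rn in zip(res_index, frame.resnames):
            resname_per_res[ri] = str(rn)
        universe.add_TopologyAttr("resnames", resname_per_res)
        universe.add_TopologyAttr("resids", uniq)
        universe.atoms.positions = frame.positions
        universe.dimensions = [*frame.box, 90.0, 90.0, 90.0]
        path = directory / f"{prefix}_{i:04d}.gro"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe.atoms.write(str(path))
        paths.append(path)
    return paths
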