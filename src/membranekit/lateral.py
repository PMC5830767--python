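"""Lateral-organization analyses of membrane configuration frames.

Implements the per-leaflet lateral radial distribution function, the
grid-tessellation (GridMAT-style) area per lipid, distance-resolved area
and gauche-defect profiles around aspirin, electron / neutron
scattering-length density profiles along the bilayer normal, and
close-contact (hydrogen-bond proxy) statistics. All operations are
deterministic given the frames — no randomness enters the analysis paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import COHERENT_SCATTERING_LENGTH_FM, ELECTRONS
from .scans import MembraneFrame

__all__ = [
    "RDFResult",
    "AreaMap",
    "RadialProfile",
    "DensityProfile",
    "ContactStats",
    "lateral_rdf",
    "grid_area_map",
    "distance_resolved_area",
    "gauche_fraction",
    "chain_dihedrals",
    "distance_resolved_gauche",
    "density_profile",
    "contact_fraction",
    "reference_points",
]

log = logging.getLogger(__name__)

#: Reference atoms anchoring each species in the membrane plane: the DMPC
#: phosphorus, the cholesterol hydroxyl oxygen, and (handled separately)
#: the aspirin lateral centre of mass.
REFERENCE_ATOM_PREFIX = {"DMPC": "P", "CHOL": "O"}


# ---------------------------------------------------------------------------
# reference points and leaflets
# ---------------------------------------------------------------------------

@dataclass
class ReferencePoint:
    resid: int
    species: str
    xy: np.ndarray
    z: float
    leaflet: str                     # upper | lower


def _lateral_com(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Lateral centre of mass with minimum-image unwrapping around atom 0."""
    ref = positions[0, :2]
    d = positions[:, :2] - ref
    d -= box[:2] * np.round(d / box[:2])
    return (ref + d.mean(axis=0)) % box[:2]


def reference_points(frame: MembraneFrame,
                     species=("DMPC", "CHOL", "ASA")) -> list[ReferencePoint]:
    """One lateral anchor per residue, with per-frame leaflet assignment."""
    center = frame.bilayer_center()
    refs: list[ReferencePoint] = []
    for resid in np.unique(frame.resids):
        sel = frame.resids == resid
        resname = str(frame.resnames[sel][0])
        if resname not in species or resname == "SOL":
            continue
        pos = frame.positions[sel]
        if resname == "ASA":
            xy = _lateral_com(pos, frame.box)
            z = float(np.mean(pos[:, 2]))
        else:
            prefix = REFERENCE_ATOM_PREFIX.get(resname)
            names = frame.names[sel]
            hits = [i for i, nm in enumerate(names)
                    if str(nm).startswith(prefix)]
            if not hits:
                raise ValueError(f"residue {resid} ({resname}) lacks a "
                                 f"reference atom with prefix {prefix!r}")
            xy = pos[hits[0], :2]
            z = float(pos[hits[0], 2])
        refs.append(ReferencePoint(
            resid=int(resid), species=resname, xy=np.asarray(xy, dtype=float),
            z=z, leaflet="upper" if z >= center else "lower"))
    return refs


def _leaflet_of_atoms(frame: MembraneFrame, idx: np.ndarray) -> np.ndarray:
    center = frame.bilayer_center()
    return np.where(frame.positions[idx, 2] >= center, "upper", "lower")


# ---------------------------------------------------------------------------
# radial distribution functions
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray                   # bin centres, Å
    g: np.ndarray
    dimensionality: str             # lateral_2d | full_3d
    selections: tuple
    frames_averaged: int
    bin_width: float

    def first_peak(self, r_min: float = 1.0) -> float:
        """r of the first local maximum of g beyond ``r_min``."""
        mask = self.r >= r_min
        g, r = self.g[mask], self.r[mask]
        for i in range(1, len(g) - 1):
            if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 1.0:
                return float(r[i])
        return float(r[np.argmax(g)])


def lateral_rdf(frames, sel_a: dict, sel_b: dict, r_max: float,
                bin_width: float = 0.2, mode: str = "lateral_2d",
                same_leaflet: bool = True) -> RDFResult:
    """Radial distribution function between two atom selections.

    In ``lateral_2d`` mode distances are in-plane (x, y) with the minimum
    image convention and, by default, pairs are restricted to the same
    leaflet; normalisation is by the ideal two-dimensional density so that
    g → 1 for a homogeneous system. ``full_3d`` uses spherical-shell
    normalisation. Averaged over all frames.
    """
    if isinstance(frames, MembraneFrame):
        frames = [frames]
    if mode not in ("lateral_2d", "full_3d"):
        raise ValueError(f"unknown mode {mode!r}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    ideal = np.zeros(len(edges) - 1)
    for frame in frames:
        box = frame.box
        limit = min(box[0], box[1]) / 2.0 if mode == "lateral_2d" \
            else min(box) / 2.0
        if r_max > limit:
            raise ValueError(f"r_max {r_max} exceeds half the smallest box "
                             f"dimension ({limit:.2f} Å)")
        idx_a = frame.select(**sel_a)
        idx_b = frame.select(**sel_b)
        if len(idx_a) == 0 or len(idx_b) == 0:
            raise ValueError("empty selection")
        identical = len(idx_a) == len(idx_b) and np.array_equal(idx_a, idx_b)
        if mode == "lateral_2d" and same_leaflet:
            leaf_a = _leaflet_of_atoms(frame, idx_a)
            leaf_b = _leaflet_of_atoms(frame, idx_b)
            leaflets = ("upper", "lower")
        else:
            leaf_a = leaf_b = None
            leaflets = (None,)
        for leaflet in leaflets:
            ia = idx_a if leaflet is None else idx_a[leaf_a == leaflet]
            ib = idx_b if leaflet is None else idx_b[leaf_b == leaflet]
            if len(ia) == 0 or len(ib) == 0:
                continue
            if mode == "lateral_2d":
                pa = frame.positions[ia, :2] % box[:2]
                pb = frame.positions[ib, :2] % box[:2]
                boxsize = box[:2]
                area_or_vol = box[0] * box[1]
                shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
            else:
                pa = frame.positions[ia] % box
                pb = frame.positions[ib] % box
                boxsize = box
                area_or_vol = box[0] * box[1] * box[2]
                shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
            tree_a = cKDTree(pa, boxsize=boxsize)
            tree_b = cKDTree(pb, boxsize=boxsize)
            cum = tree_a.count_neighbors(tree_b, edges)
            binned = np.diff(cum).astype(float)
            if identical:
                binned[0] -= len(ia)     # remove self pairs at r = 0
            counts += binned
            ideal += len(ia) * len(ib) / area_or_vol * shell
    g = np.divide(counts, ideal, out=np.zeros_like(counts), where=ideal > 0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r=centers, g=g, dimensionality=mode,
                     selections=(tuple(sorted(sel_a.items())),
                                 tuple(sorted(sel_b.items()))),
                     frames_averaged=len(frames), bin_width=bin_width)


# ---------------------------------------------------------------------------
# grid-based area per lipid
# ---------------------------------------------------------------------------

@dataclass
class AreaMap:
    """Grid-tessellation areas for one leaflet.

    Every grid cell is claimed by the nearest reference point (periodic
    minimum image) in the leaflet, so the claimed areas tile the leaflet
    exactly: Σ areas = Lx·Ly.
    """

    areas: dict[int, float]         # resid -> Å²
    species: dict[int, str]
    leaflet: str
    cell_area: float
    box_area: float

    def areas_for(self, species: str = "DMPC") -> dict[int, float]:
        return {rid: a for rid, a in self.areas.items()
                if self.species[rid] == species}

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()))


def grid_area_map(frame: MembraneFrame, cell_size: float = 0.5,
                  policy: str = "chol_as_lipid") -> dict[str, AreaMap]:
    """Grid (GridMAT-style) area per lipid, per leaflet.

    ``policy`` is ``"chol_as_lipid"`` (cholesterol anchors compete for
    cells alongside DMPC) or ``"exclude_chol"`` (cholesterol anchors do
    not claim cells, so its area is absorbed into the surrounding DMPC —
    "DMPC-only" areas). Aspirin never claims cells: it resides in the
    headgroup plane between lipids, and the membrane plane is tiled by
    the lipids proper.
    """
    if cell_size > 0.5:
        raise ValueError("cell_size must be <= 0.5 Å")
    refs = [r for r in reference_points(frame) if r.species != "ASA"]
    if policy == "exclude_chol":
        refs = [r for r in refs if r.species != "CHOL"]
    elif policy != "chol_as_lipid":
        raise ValueError(f"unknown policy {policy!r}")
    box = frame.box
    nx = max(int(round(box[0] / cell_size)), 1)
    ny = max(int(round(box[1] / cell_size)), 1)
    cx = (np.arange(nx) + 0.5) * box[0] / nx
    cy = (np.arange(ny) + 0.5) * box[1] / ny
    cell_area = (box[0] / nx) * (box[1] / ny)
    out: dict[str, AreaMap] = {}
    for leaflet in ("upper", "lower"):
        members = [r for r in refs if r.leaflet == leaflet]
        if not members:
            continue
        rx = np.array([r.xy[0] for r in members])
        ry = np.array([r.xy[1] for r in members])
        dx = cx[:, None] - rx[None, :]
        dx -= box[0] * np.round(dx / box[0])
        dy = cy[:, None] - ry[None, :]
        dy -= box[1] * np.round(dy / box[1])
        d2 = dx[:, None, :] ** 2 + dy[None, :, :] ** 2   # (nx, ny, nrefs)
        owner = np.argmin(d2, axis=2)
        counts = np.bincount(owner.ravel(), minlength=len(members))
        out[leaflet] = AreaMap(
            areas={m.resid: float(c * cell_area)
                   for m, c in zip(members, counts)},
            species={m.resid: m.species for m in members},
            leaflet=leaflet, cell_area=cell_area,
            box_area=float(box[0] * box[1]))
    if not out:
        raise ValueError("no reference points in either leaflet")
    return out


# ---------------------------------------------------------------------------
# distance-resolved profiles around aspirin
# ---------------------------------------------------------------------------

@dataclass
class RadialProfile:
    """A statistic binned by lateral distance to the nearest aspirin."""

    bin_edges: np.ndarray           # half-open [a, b)
    values: np.ndarray              # mean statistic per bin (NaN if empty)
    counts: np.ndarray
    statistic: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])


def _min_image_lateral_distance(xy: np.ndarray, targets: np.ndarray,
                                box: np.ndarray) -> float:
    d = targets - xy
    d -= box[:2] * np.round(d / box[:2])
    return float(np.min(np.hypot(d[:, 0], d[:, 1])))


def _nearest_asa_distance(ref: ReferencePoint, asa_refs, box) -> float | None:
    targets = np.array([a.xy for a in asa_refs if a.leaflet == ref.leaflet])
    if len(targets) == 0:
        return None
    return _min_image_lateral_distance(ref.xy, targets, box)


def distance_resolved_area(frames, bin_edges=None, cell_size: float = 0.5,
                           policy: str = "chol_as_lipid") -> RadialProfile:
    """Mean DMPC area versus lateral distance to the nearest aspirin.

    Per frame, every DMPC's grid area is accumulated into the half-open
    distance bin of its same-leaflet distance to the nearest aspirin
    anchor; bins are averaged over frames.
    """
    if isinstance(frames, MembraneFrame):
        frames = [frames]
    edges = np.asarray(bin_edges if bin_edges is not None
                       else np.arange(0.0, 22.0, 2.0), dtype=float)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for frame in frames:
        refs = reference_points(frame)
        asa = [r for r in refs if r.species == "ASA"]
        if not asa:
            raise ValueError("frames contain no ASA")
        maps = grid_area_map(frame, cell_size=cell_size, policy=policy)
        for leaflet, amap in maps.items():
            for ref in refs:
                if ref.species != "DMPC" or ref.leaflet != leaflet:
                    continue
                dist = _nearest_asa_distance(ref, asa, frame.box)
                if dist is None:
                    continue
                i = np.searchsorted(edges, dist, side="right") - 1
                if 0 <= i < len(sums):
                    sums[i] += amap.areas[ref.resid]
                    counts[i] += 1
    values = np.divide(sums, counts, out=np.full_like(sums, np.nan),
                       where=counts > 0)
    return RadialProfile(bin_edges=edges, values=values, counts=counts,
                         statistic="area_per_dmpc")


# ---------------------------------------------------------------------------
# gauche defects
# ---------------------------------------------------------------------------

def gauche_fraction(angles, convention: str = "iupac") -> float:
    """Fraction of dihedrals in a gauche state.

    Angles are in degrees on (−180, 180]. In the IUPAC convention trans is
    ±180° and a dihedral is gauche when |φ| < 120°; Ryckaert–Bellemans
    input (trans at 0°) is shifted by 180° first so the classification is
    convention-independent.
    """
    phi = np.asarray(angles, dtype=float)
    if phi.size == 0:
        raise ValueError("empty dihedral set")
    if np.any(phi <= -180.0) or np.any(phi > 180.0):
        raise ValueError("angles must lie in (-180, 180] degrees")
    if convention == "rb":
        phi = ((phi + 180.0) + 180.0) % 360.0 - 180.0
    elif convention != "iupac":
        raise ValueError(f"unknown convention {convention!r}")
    return float(np.mean(np.abs(phi) < 120.0))


def chain_dihedrals(positions: np.ndarray,
                    box: np.ndarray | None = None) -> np.ndarray:
    """Dihedral angles (degrees, IUPAC, trans = ±180°) along a bead chain.

    Consecutive bonds are unwrapped by minimum image first so chains that
    cross the periodic boundary give correct torsions.
    """
    pos = np.asarray(positions, dtype=float).copy()
    if len(pos) < 4:
        return np.empty(0)
    if box is not None:
        for i in range(1, len(pos)):
            step = pos[i] - pos[i - 1]
            step -= box * np.round(step / box)
            pos[i] = pos[i - 1] + step
    b1 = pos[1:-2] - pos[0:-3]
    b2 = pos[2:-1] - pos[1:-2]
    b3 = pos[3:] - pos[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.degrees(np.arctan2(y, x))


def _tail_indices(frame: MembraneFrame, resid: int,
                  prefix: str) -> np.ndarray:
    sel = np.nonzero(frame.resids == resid)[0]
    tail = []
    for i in sel:
        name = str(frame.names[i])
        if name.startswith(prefix) and name[len(prefix):].isdigit():
            tail.append((int(name[len(prefix):]), i))
    tail.sort()
    return np.array([i for _, i in tail], dtype=int)


def _dmpc_gauche(frame: MembraneFrame, resid: int,
                 tail_prefixes=("C1", "C2")) -> float | None:
    fracs = []
    for prefix in tail_prefixes:
        idx = _tail_indices(frame, resid, prefix)
        if len(idx) < 4:
            raise ValueError(
                f"residue {resid}: tail {prefix!r} has {len(idx)} chain "
                "atoms; cannot resolve chain naming")
        angles = chain_dihedrals(frame.positions[idx], box=frame.box)
        fracs.append(gauche_fraction(angles))
    return float(np.mean(fracs)) if fracs else None


def distance_resolved_gauche(frames, bin_edges=None, stride: int = 50,
                             tail_prefixes=("C1", "C2")) -> RadialProfile:
    """Gauche fraction of DMPC tails versus distance to the nearest aspirin.

    Shell membership of each lipid is recomputed every ``stride`` frames
    (matching the index-file regeneration cadence of the original
    protocol) and cached between updates; SN1/SN2 tails are averaged.
    """
    if isinstance(frames, MembraneFrame):
        frames = [frames]
    edges = np.asarray(bin_edges if bin_edges is not None
                       else np.arange(0.0, 22.0, 2.0), dtype=float)
    if stride >= len(frames):
        log.info("stride %d >= frame count %d: membership evaluated once",
                 stride, len(frames))
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    membership: dict[int, int] = {}
    for fi, frame in enumerate(frames):
        if fi % max(stride, 1) == 0 or not membership:
            refs = reference_points(frame)
            asa = [r for r in refs if r.species == "ASA"]
            if not asa:
                raise ValueError("frames contain no ASA")
            membership = {}
            for ref in refs:
                if ref.species != "DMPC":
                    continue
                dist = _nearest_asa_distance(ref, asa, frame.box)
                if dist is None:
                    continue
                i = np.searchsorted(edges, dist, side="right") - 1
                if 0 <= i < len(sums):
                    membership[ref.resid] = i
        for resid, i in membership.items():
            frac = _dmpc_gauche(frame, resid, tail_prefixes)
            if frac is not None:
                sums[i] += frac
                counts[i] += 1
    values = np.divide(sums, counts, out=np.full_like(sums, np.nan),
                       where=counts > 0)
    return RadialProfile(bin_edges=edges, values=values, counts=counts,
                         statistic="gauche_fraction")


# ---------------------------------------------------------------------------
# density profiles along the normal
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    z: np.ndarray                   # bin centres, bilayer-centred, Å
    densities: dict[str, np.ndarray]
    weighting: str                  # electron | neutron_sl
    bin_width: float
    box_area: float
    frames_averaged: int

    def integral(self, group: str) -> float:
        """∫ρ dz × lateral box area (total electrons or scattering length)."""
        return float(np.sum(self.densities[group]) * self.bin_width
                     * self.box_area)


def density_profile(frames, groups: dict[str, dict],
                    weighting: str = "electron",
                    deuteration: dict | None = None,
                    bin_width: float = 1.0,
                    symmetrize: bool = False) -> DensityProfile:
    """Per-group density along the bilayer normal.

    Histograms atom z positions (bilayer-centred: the lipid centre maps to
    z = 0), weighted by electrons per element or by coherent neutron
    scattering length (fm), with hydrogens in the ``deuteration`` selection
    treated as ²H. Averaged over frames.
    """
    if isinstance(frames, MembraneFrame):
        frames = [frames]
    if weighting not in ("electron", "neutron_sl"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if bin_width > 1.0:
        raise ValueError("bin_width must be <= 1 Å")
    table = ELECTRONS if weighting == "electron" \
        else COHERENT_SCATTERING_LENGTH_FM
    per_group_z: dict[str, list] = {g: [] for g in groups}
    per_group_w: dict[str, list] = {g: [] for g in groups}
    box_area = None
    zmin, zmax = np.inf, -np.inf
    for frame in frames:
        center = frame.bilayer_center()
        box_area = float(frame.box[0] * frame.box[1])
        deut = set(frame.select(**deuteration)) if deuteration else set()
        for gname, sel in groups.items():
            idx = frame.select(**sel)
            z = frame.positions[idx, 2] - center
            w = np.empty(len(idx))
            for j, i in enumerate(idx):
                el = str(frame.elements[i]).upper()
                if weighting == "neutron_sl" and el == "H" and i in deut:
                    el = "D"
                if el not in table:
                    raise ValueError(f"unknown element {el!r}")
                w[j] = table[el]
            per_group_z[gname].append(z)
            per_group_w[gname].append(w)
            if len(z):
                zmin, zmax = min(zmin, z.min()), max(zmax, z.max())
    lo = np.floor(zmin / bin_width) * bin_width
    hi = np.ceil(zmax / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    densities = {}
    for gname in groups:
        z = np.concatenate(per_group_z[gname])
        w = np.concatenate(per_group_w[gname])
        hist, _ = np.histogram(z, bins=edges, weights=w)
        rho = hist / (box_area * bin_width * len(frames))
        if symmetrize:
            rho = 0.5 * (rho + rho[::-1])
        densities[gname] = rho
    return DensityProfile(z=0.5 * (edges[1:] + edges[:-1]),
                          densities=densities, weighting=weighting,
                          bin_width=bin_width, box_area=box_area,
                          frames_averaged=len(frames))


# ---------------------------------------------------------------------------
# close contacts (hydrogen-bond distance proxy)
# ---------------------------------------------------------------------------

@dataclass
class ContactStats:
    """Per-molecule-pair close-contact statistics over a trajectory."""

    pair_fractions: dict[tuple[int, int], float]
    per_frame_counts: np.ndarray
    cutoff: float
    n_frames: int

    @property
    def any_contact_fraction(self) -> float:
        return float(np.mean(self.per_frame_counts > 0))

    def fraction(self, resid_a: int, resid_b: int) -> float:
        return self.pair_fractions.get((resid_a, resid_b), 0.0)


def contact_fraction(frames, sel_a: dict, sel_b: dict,
                     cutoff: float = 3.5) -> ContactStats:
    """Heavy-atom close contacts between two molecular groups.

    A molecule pair is "in contact" in a frame when any heavy-atom pair is
    within ``cutoff`` (3D minimum image); the per-pair time fraction over
    the trajectory is the hydrogen-bond distance proxy.
    """
    if isinstance(frames, MembraneFrame):
        frames = [frames]
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pair_hits: dict[tuple[int, int], int] = {}
    per_frame = np.zeros(len(frames), dtype=int)
    for fi, frame in enumerate(frames):
        heavy = ~np.isin([str(e).upper() for e in frame.elements],
                         ("H", "D"))
        idx_a = np.array([i for i in frame.select(**sel_a) if heavy[i]])
        idx_b = np.array([i for i in frame.select(**sel_b) if heavy[i]])
        if len(idx_a) == 0 or len(idx_b) == 0:
            raise ValueError("empty heavy-atom selection")
        box = frame.box
        pa = frame.positions[idx_a] % box
        pb = frame.positions[idx_b] % box
        tree_a = cKDTree(pa, boxsize=box)
        tree_b = cKDTree(pb, boxsize=box)
        hits = tree_a.query_ball_tree(tree_b, cutoff)
        frame_pairs = set()
        for ia, neighbours in enumerate(hits):
            ra = int(frame.resids[idx_a[ia]])
            for ib in neighbours:
                rb = int(frame.resids[idx_b[ib]])
                if ra != rb:
                    frame_pairs.add((ra, rb))
        for pair in frame_pairs:
            pair_hits[pair] = pair_hits.get(pair, 0) + 1
        per_frame[fi] = len(frame_pairs)
    fractions = {pair: n / len(frames) for pair, n in sorted(pair_hits.items())}
    return ContactStats(pair_fractions=fractions, per_frame_counts=per_frame,
                        cutoff=cutoff, n_frames=len(frames))
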