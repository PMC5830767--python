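"""Synthetic-data generators with machine-readable ground truth.

Every generator draws noise from an integer-seeded stream and attaches its
ground truth to the output's ``meta`` dictionary, so analysis tests read
truth from the attachment rather than re-deriving it. The generators
emulate: triple-axis scans from a three-branch phonon dispersion with
Lorentzian damping, detailed balance and Poisson counting noise; lamellar
Bragg series forward-modelled from an analytic scattering-length-density
profile; and coarse membrane frames with hexagonal tail packing, an
oblique aspirin superlattice, cholesterol rings around aspirin, local
area dilation and tunable gauche statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_TEMPERATURE_K
from .scans import MembraneFrame, ReflectivityScan, Scan
from .spectral import PhononMode, SpectralParams, evaluate_spectrum

__all__ = [
    "BranchSpec",
    "DispersionSpec",
    "MembraneSpec",
    "simulate_constant_q_scan",
    "simulate_constant_e_scan",
    "simulate_reflectivity",
    "default_sld_profile",
    "build_membrane_frames",
]


# ---------------------------------------------------------------------------
# dispersion specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchSpec:
    """Quadratic-minimum parameters of one dispersion branch."""

    alpha: float                    # meV·Å², curvature
    q0: float                       # Å⁻¹, position of the minimum
    omega0: float                   # meV, depth of the minimum
    width: float = 0.2              # meV, Lorentzian HWHM of the mode
    amplitude: float = 100.0        # Stokes peak counts scale

    def __post_init__(self):
        if self.alpha <= 0 or self.omega0 <= 0:
            raise ValueError("alpha and omega0 must be positive")

    def energy_at(self, q: float) -> float:
        return self.alpha * (q - self.q0) ** 2 + self.omega0


@dataclass(frozen=True)
class DispersionSpec:
    """Three-branch (gel / fluid / lo) dispersion specification."""

    branches: dict[str, BranchSpec]

    def __iter__(self):
        return iter(sorted(self.branches.items(),
                           key=lambda kv: kv[1].omega0))

    @staticmethod
    def well_separated() -> "DispersionSpec":
        """Default generator conditions: three well-separated minima at
        0.6 / 1.1 / 1.8 meV (q0 = 1.4 Å⁻¹)."""
        return DispersionSpec(branches={
            "lo": BranchSpec(alpha=4.8, q0=1.4, omega0=0.6, width=0.15,
                             amplitude=240.0),
            "fluid": BranchSpec(alpha=14.9, q0=1.4, omega0=1.1, width=0.25,
                                amplitude=200.0),
            "gel": BranchSpec(alpha=41.0, q0=1.4, omega0=1.8, width=0.30,
                              amplitude=160.0),
        })

    @staticmethod
    def chol() -> "DispersionSpec":
        """Cholesterol-sample branch parameters (30 mol% cholesterol)."""
        return DispersionSpec(branches={
            "gel": BranchSpec(alpha=41.0, q0=1.4, omega0=0.72, width=0.35,
                              amplitude=160.0),
            "fluid": BranchSpec(alpha=14.9, q0=1.4, omega0=1.09, width=0.30,
                                amplitude=200.0),
            "lo": BranchSpec(alpha=4.8, q0=1.4, omega0=0.51, width=0.14,
                             amplitude=240.0),
        })

    @staticmethod
    def asa() -> "DispersionSpec":
        """Aspirin-sample branch parameters (29% cholesterol + 10% aspirin)."""
        return DispersionSpec(branches={
            "gel": BranchSpec(alpha=1.5, q0=1.4, omega0=0.65, width=0.35,
                              amplitude=160.0),
            "fluid": BranchSpec(alpha=11.0, q0=1.4, omega0=1.12, width=0.30,
                                amplitude=200.0),
            "lo": BranchSpec(alpha=3.7, q0=1.4, omega0=0.66, width=0.31,
                             amplitude=240.0),
        })


DEFAULT_BACKGROUNDS = {"a_el": 8000.0, "a_inc": 500.0, "sigma_inc": 0.5,
                       "slope": -4.0, "intercept": 80.0}


def simulate_constant_q_scan(spec: DispersionSpec, q: float = 1.4,
                             omega=None, counts_scale: float = 1.0,
                             backgrounds: dict | None = None,
                             temperature: float = DEFAULT_TEMPERATURE_K,
                             sigma_el: float = 0.3,
                             seed: int = 0) -> Scan:
    """Generate a Poisson-noised constant-q energy scan.

    Each branch contributes a phonon doublet at its dispersion energy at
    ``q`` (anti-Stokes amplitude from detailed balance). The true spectral
    parameters are attached under ``meta['truth']``.
    """
    if counts_scale <= 0:
        raise ValueError("counts_scale must be positive")
    omega = np.asarray(omega, dtype=float) if omega is not None \
        else np.linspace(-2.0, 4.0, 108)
    if omega[0] >= 0 or omega[-1] <= 0:
        raise ValueError("omega grid must span both Stokes and anti-Stokes "
                         "sides")
    bg = dict(DEFAULT_BACKGROUNDS, **(backgrounds or {}))
    modes = tuple(
        PhononMode(mu=branch.energy_at(q), sigma=branch.width,
                   amp_plus=branch.amplitude * counts_scale)
        for _, branch in spec if branch.amplitude > 0)
    truth = SpectralParams(
        a_el=bg["a_el"] * counts_scale, a_inc=bg["a_inc"] * counts_scale,
        sigma_inc=bg["sigma_inc"], slope=bg["slope"] * counts_scale,
        intercept=bg["intercept"] * counts_scale, modes=modes,
        temperature=temperature, sigma_el=sigma_el)
    expected = np.maximum(evaluate_spectrum(truth, omega), 0.05)
    rng = np.random.default_rng([seed, 1])
    counts = rng.poisson(expected).astype(float)
    return Scan(kind="constant_q", fixed_value=q, axis=omega, counts=counts,
                errors=np.maximum(1.0, np.sqrt(counts)),
                temperature=temperature, sigma_el=sigma_el,
                meta={"truth": truth, "seed": seed})


def simulate_constant_e_scan(spec: DispersionSpec, energy: float,
                             q_grid=None, counts_scale: float = 1.0,
                             backgrounds: dict | None = None,
                             seed: int = 0) -> Scan:
    """Generate a constant-energy q-scan.

    Phonon peaks sit at the q roots of each branch's quadratic dispersion
    (two per branch when the energy is above the minimum, one merged peak
    at tangency); amplitudes are scaled by the inverse local slope of the
    dispersion (density-of-states flavour), bounded above. Exponential
    background plus a broad Lorentzian near 2.5 Å⁻¹, Poisson noise.
    """
    if counts_scale <= 0:
        raise ValueError("counts_scale must be positive")
    q = np.asarray(q_grid, dtype=float) if q_grid is not None \
        else np.linspace(0.7, 3.0, 116)
    bg = dict({"b0": 600.0, "b1": 1.2, "bg_amp": 60.0, "bg_center": 2.5,
               "bg_width": 0.4}, **(backgrounds or {}))
    expected = bg["b0"] * counts_scale * np.exp(-bg["b1"] * q)
    expected = expected + bg["bg_amp"] * counts_scale / (
        1.0 + ((q - bg["bg_center"]) / bg["bg_width"]) ** 2)
    roots: list[dict] = []
    for name, branch in spec:
        if branch.amplitude <= 0 or energy < branch.omega0:
            continue
        dq = math.sqrt((energy - branch.omega0) / branch.alpha)
        slope = 2.0 * branch.alpha * dq      # |dω/dq| at the crossing
        amp = branch.amplitude * counts_scale * min(
            1.0, 1.0 / max(slope, 0.25))
        width_q = float(np.clip(branch.width / max(slope, 1.0), 0.02, 0.25))
        for root in ({branch.q0} if dq == 0
                     else {branch.q0 - dq, branch.q0 + dq}):
            roots.append({"branch": name, "q": root, "width": width_q,
                          "amplitude": amp})
            expected = expected + amp / (1.0 + ((q - root) / width_q) ** 2)
    rng = np.random.default_rng([seed, 2])
    counts = rng.poisson(np.maximum(expected, 0.05)).astype(float)
    return Scan(kind="constant_E", fixed_value=energy, axis=q, counts=counts,
                errors=np.maximum(1.0, np.sqrt(counts)),
                meta={"truth": {"roots": roots, "background": bg},
                      "no_crossing": len(roots) == 0, "seed": seed})


# ---------------------------------------------------------------------------
# lamellar reflectivity
# ---------------------------------------------------------------------------

def _gaussian_morphology(d_z: float, d_hh: float):
    """Chain-deuterated bilayer morphology from wrapped Gaussians: tail
    maxima near |z| ≈ 10 Å, headgroup minima at |z| = d_hh/2, and a
    deuterated-water/tail maximum at the repeat edge."""
    def wrapped_gaussian(z, center, sigma):
        out = np.zeros_like(z)
        for k in (-1, 0, 1):
            out += np.exp(-((z - center + k * d_z) ** 2) / (2 * sigma**2))
        return out

    def rho(z):
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for sign in (-1.0, 1.0):
            out += 1.0 * wrapped_gaussian(z, sign * 10.0, 4.0)
            out += -1.4 * wrapped_gaussian(z, sign * d_hh / 2.0, 2.5)
        out += 0.9 * wrapped_gaussian(z, d_z / 2.0, 3.0)
        out += 0.9 * wrapped_gaussian(z, -d_z / 2.0, 3.0)
        return out

    return rho


def default_sld_profile(d_z: float = 61.1, d_hh: float = 46.0,
                        n_harmonics: int = 9, floor: float = 0.12):
    """Analytic relative SLD of a chain-deuterated bilayer (callable of z).

    The profile is the ``n_harmonics``-term cosine series of the Gaussian
    bilayer morphology with weak harmonics floored at ``floor`` times the
    strongest one, so every lamellar order carries measurable intensity —
    mirroring experiments where around nine orders are observed. Being
    band-limited, its form factors are exact and the forward/inverse
    round trip has an analytic truth.
    """
    base = _gaussian_morphology(d_z, d_hh)
    f_n = _form_factors(base, d_z, n_harmonics)
    f_floor = floor * np.max(np.abs(f_n))
    f_n = np.where(np.abs(f_n) < f_floor,
                   np.where(f_n >= 0, 1.0, -1.0) * f_floor, f_n)

    def rho(z):
        z = np.asarray(z, dtype=float)
        out = np.zeros_like(z)
        for n, f in enumerate(f_n, start=1):
            out += f * np.cos(2.0 * np.pi * n * z / d_z)
        return out

    return rho


def _form_factors(profile, d_z: float, n_orders: int) -> np.ndarray:
    z = np.linspace(-d_z / 2.0, d_z / 2.0, 4001)
    rho = profile(z)
    return np.array([np.trapezoid(rho * np.cos(2 * np.pi * n * z / d_z), z)
                     for n in range(1, n_orders + 1)])


def _band_limited_minima_separation(f_n: np.ndarray, d_z: float) -> float:
    """Separation of the interior minima of the Fourier partial sum."""
    z = np.linspace(-d_z / 2.0, d_z / 2.0, 6111)
    rho = np.zeros_like(z)
    for n, f in enumerate(f_n, start=1):
        rho += f * np.cos(2 * np.pi * n * z / d_z)
    interior = np.nonzero((rho[1:-1] < rho[:-2]) & (rho[1:-1] < rho[2:]))[0] + 1
    neg = [i for i in interior if z[i] < 0]
    pos = [i for i in interior if z[i] > 0]
    i_neg = min(neg, key=lambda i: rho[i])
    i_pos = min(pos, key=lambda i: rho[i])

    def refine(i):
        denom = rho[i - 1] - 2 * rho[i] + rho[i + 1]
        if denom == 0:
            return z[i]
        return z[i] + 0.5 * (rho[i - 1] - rho[i + 1]) / denom * (z[1] - z[0])

    return float(refine(i_pos) - refine(i_neg))


def simulate_reflectivity(profile=None, d_z: float = 61.1,
                          n_orders: int = 9, counts_scale: float = 2e4,
                          peak_sigma: float = 0.004,
                          background: float = 20.0,
                          q_step: float = 0.0008,
                          seed: int = 0) -> ReflectivityScan:
    """Forward-model a lamellar Bragg series from an analytic SLD profile.

    F_n = ∫ρ(z)cos(2πnz/d_z)dz, I_n = F_n²/q_n; peaks are rendered as
    Gaussians of width ``peak_sigma`` on a flat background with Poisson
    noise. Ground truth (form factors, phases, intensities, band-limited
    head-minimum separation) is attached to ``meta['truth']``.
    """
    if n_orders < 3:
        raise ValueError("need at least 3 orders")
    profile = profile or default_sld_profile(d_z=d_z)
    f_n = _form_factors(profile, d_z, n_orders)
    q_n = 2.0 * np.pi * np.arange(1, n_orders + 1) / d_z
    i_n = f_n**2 / q_n
    q = np.arange(0.6 * q_n[0], q_n[-1] + 8 * peak_sigma + 0.02, q_step)
    expected = np.full_like(q, background)
    amps = counts_scale * i_n / i_n.max()
    for qc, amp in zip(q_n, amps):
        expected = expected + amp * np.exp(-((q - qc) ** 2)
                                           / (2 * peak_sigma**2))
    rng = np.random.default_rng([seed, 3])
    counts = rng.poisson(expected).astype(float)
    truth = {"d_z": d_z, "form_factors": f_n, "phases": np.sign(f_n),
             "intensities": i_n, "positions": q_n,
             "d_hh_band": _band_limited_minima_separation(f_n, d_z),
             "peak_sigma": peak_sigma, "amps": amps}
    return ReflectivityScan(q_z=q, counts=counts,
                            errors=np.maximum(1.0, np.sqrt(counts)),
                            meta={"truth": truth, "seed": seed})


# ---------------------------------------------------------------------------
# membrane frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneSpec:
    """Conditions for the coarse membrane-frame generator.

    Defaults are the study conditions: 48.6 Å² target DMPC area, a
    21.2 × 18 Å (γ = 103°) aspirin superlattice, +5% local area dilation
    within 5 Å of aspirin, cholesterol rings at 11.5 and 19 Å, head–head
    spacing 46 Å.

    Geometry: acyl tails sit on a hexagonal lattice and each lipid owns two
    adjacent tail sites, so the lipid area is √3·s² for tail spacing s.
    The lattice spacing is derived from ``apl`` (s = √(apl/√3), 5.30 Å at
    48.6 Å²) unless ``tail_spacing`` is set explicitly, in which case it
    takes geometric precedence and the effective lipid area becomes
    √3·tail_spacing² (4.8 Å spacing → 39.9 Å²) — space filling forbids
    honouring both knobs at once.
    """

    n_lipids: int = 128             # lipid sites over both leaflets
    chol_fraction: float = 0.0
    asa_fraction: float = 0.0
    apl: float = 48.6               # target DMPC area, Å²
    tail_spacing: float | None = None   # Å, overrides apl when set
    superlattice: tuple = (21.2, 18.0, 103.0)   # a, b (Å), gamma (deg)
    chol_rings: tuple = (11.5, 19.0)            # Å, rings around aspirin
    dilation: float = 0.05          # fractional area increase near aspirin
    dilation_radius: float = 5.0    # Å
    gauche_near: float = 0.25       # gauche probability within gauche_radius
    gauche_far: float = 0.25
    gauche_radius: float = 6.0      # Å
    d_hh: float = 46.0              # Å, head plane separation
    box_z: float = 72.0             # Å
    n_tail_beads: int = 10
    waters_per_lipid: int = 3
    jitter: float = 0.25            # Å, per-frame lateral jitter

    def __post_init__(self):
        if not (0 <= self.chol_fraction <= 1 and 0 <= self.asa_fraction <= 1
                and self.chol_fraction + self.asa_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1] and sum to <= 1")
        if self.apl <= 0 or self.d_hh <= 0:
            raise ValueError("areas and spacings must be positive")
        if self.tail_spacing is not None and self.tail_spacing <= 0:
            raise ValueError("tail_spacing must be positive")
        if self.box_z < self.d_hh + 10.0:
            raise ValueError("box_z too small for the bilayer plus water")

    @property
    def lattice_spacing(self) -> float:
        """Hexagonal tail-lattice spacing s (Å)."""
        if self.tail_spacing is not None:
            return self.tail_spacing
        return math.sqrt(self.apl / math.sqrt(3.0))

    @property
    def effective_apl(self) -> float:
        """Lipid area actually realised by the tail lattice (√3·s²)."""
        return math.sqrt(3.0) * self.lattice_spacing**2


BOND_LENGTH = 1.54
BOND_ANGLE_DEG = 111.0


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """Internal-to-Cartesian placement of the next chain bead."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(angle),
                   bond * math.sin(angle) * math.cos(dihedral),
                   bond * math.sin(angle) * math.sin(dihedral)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_tail(origin: np.ndarray, down: float, n_beads: int,
                dihedrals_deg: np.ndarray) -> np.ndarray:
    """Bead chain grown from ``origin`` toward the bilayer centre.

    The all-trans zigzag lies in the yz-plane, so a straight tail keeps
    its lattice x position exactly (hexagonal tail packing survives).
    """
    t = math.radians((180.0 - BOND_ANGLE_DEG) / 2.0)
    u1 = np.array([0.0, math.sin(t), -down * math.cos(t)])
    u2 = np.array([0.0, -math.sin(t), -down * math.cos(t)])
    pos = [origin, origin + BOND_LENGTH * u1]
    pos.append(pos[1] + BOND_LENGTH * u2)
    for phi in dihedrals_deg:
        pos.append(_place_atom(pos[-3], pos[-2], pos[-1], BOND_LENGTH,
                               BOND_ANGLE_DEG, phi))
    return np.asarray(pos[:n_beads])


def _lipid_lattice(n_sites: int, s: float):
    """Lipid head positions on a dimer tiling of the hexagonal tail lattice.

    Tails sit on a hexagonal lattice of spacing ``s`` (row height √3/2·s,
    alternate rows offset by s/2); each lipid owns two x-adjacent tail
    sites, so heads sit at pair midpoints and the per-lipid area is √3·s².
    Returns (head xy array, Lx, Ly); the pair count per row and the row
    count are chosen to keep the box close to square (row count even for
    periodic continuation).
    """
    best = None
    for npair in range(1, n_sites + 1):
        if n_sites % npair:
            continue
        ny = n_sites // npair
        if ny % 2:
            continue
        lx, ly = npair * 2 * s, ny * s * math.sqrt(3.0) / 2.0
        badness = abs(math.log(lx / ly))
        if best is None or badness < best[0]:
            best = (badness, npair, ny)
    if best is None:
        raise ValueError(f"cannot tile {n_sites} lipids with an even row "
                         "count")
    _, npair, ny = best
    row_h = s * math.sqrt(3.0) / 2.0
    pts = np.array([[(2 * i + 0.5) * s + 0.5 * (j % 2) * s,
                     (j + 0.5) * row_h]
                    for j in range(ny) for i in range(npair)])
    return pts, npair * 2 * s, ny * row_h


def _superlattice_points(a_len, b_len, gamma_deg, lx, ly):
    av = np.array([a_len, 0.0])
    bv = np.array([b_len * math.cos(math.radians(gamma_deg)),
                   b_len * math.sin(math.radians(gamma_deg))])
    pts = []
    n_max = int(max(lx, ly) / min(a_len, abs(bv[1]))) + 3
    for i in range(-n_max, n_max + 1):
        for j in range(-n_max, n_max + 1):
            p = (i * av + j * bv) % np.array([lx, ly])
            pts.append(p)
    pts = np.asarray(pts)
    # dedupe wrapped duplicates
    keep: list[np.ndarray] = []
    for p in pts:
        if all(np.linalg.norm(((p - k + [lx / 2, ly / 2]) %
                               [lx, ly]) - [lx / 2, ly / 2]) > 1.0
               for k in keep):
            keep.append(p)
    return np.asarray(keep)


def _dilate(xy: np.ndarray, centers: np.ndarray, delta: float, radius: float,
            spacing: float, lx: float, ly: float) -> np.ndarray:
    """Radial displacement field giving ≈ +delta areal strain near a centre.

    The linear zone u = (δ/2)·r extends past the first neighbour shell
    (radius + half a lattice spacing), so lipids inside ``radius`` see
    their whole neighbourhood expand; the field then decays to zero over a
    wide annulus so the compensating compression is spread thinly across
    the rest of the leaflet (as a barostatted membrane would).
    """
    r1 = radius + 0.5 * spacing
    r2 = min(4.0 * radius + spacing, 0.45 * min(lx, ly))
    out = xy.copy()
    for c in centers:
        d = out - c
        d[:, 0] -= lx * np.round(d[:, 0] / lx)
        d[:, 1] -= ly * np.round(d[:, 1] / ly)
        r = np.hypot(d[:, 0], d[:, 1])
        u = np.zeros_like(r)
        inner = (r > 1e-9) & (r < r1)
        taper = (r >= r1) & (r < r2)
        u[inner] = (delta / 2.0) * r[inner]
        u[taper] = (delta / 2.0) * r1 * (r2 - r[taper]) / (r2 - r1)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r > 1e-9, u / r, 0.0)
        out += d * scale[:, None]
    out[:, 0] %= lx
    out[:, 1] %= ly
    return out


def build_membrane_frames(spec: MembraneSpec, n_frames: int = 1,
                          seed: int = 0) -> list[MembraneFrame]:
    """Build coarse membrane frames with known lateral organisation.

    Per leaflet: DMPC heads on a jittered hexagonal lattice at the target
    area; aspirin centres on the oblique superlattice in the headgroup
    plane; cholesterol preferentially on rings around aspirin; the lattice
    locally dilated near aspirin; tails grown bead-by-bead with per-
    dihedral gauche draws. Ground truth (site species/positions, aspirin
    centres, per-lipid gauche states and distances) is attached to
    ``meta['truth']`` of every frame.
    """
    n_sites = spec.n_lipids // 2
    s = spec.lattice_spacing
    base_xy, lx, ly = _lipid_lattice(n_sites, s)
    if n_sites * spec.effective_apl > lx * ly * 1.0001:
        raise ValueError("target area times site count exceeds the box")
    n_asa = int(round(spec.asa_fraction * n_sites))
    n_chol = int(round(spec.chol_fraction * n_sites))
    rng_layout = np.random.default_rng([seed, 10])
    frames: list[MembraneFrame] = []

    # --- per-leaflet static layout (shared by all frames) -----------------
    layout = {}
    for leaflet, down in (("upper", 1.0), ("lower", -1.0)):
        sites = base_xy.copy()
        asa_centers = np.empty((0, 2))
        if n_asa > 0:
            lattice_pts = _superlattice_points(*spec.superlattice, lx, ly)
            pick = rng_layout.choice(len(lattice_pts),
                                     size=min(n_asa, len(lattice_pts)),
                                     replace=False)
            asa_centers = lattice_pts[pick]
        species = np.array(["DMPC"] * len(sites), dtype=object)
        chol_xy = []
        if n_chol > 0:
            if len(asa_centers) and spec.chol_rings:
                candidates = []
                for c in asa_centers:
                    for radius in spec.chol_rings:
                        for angle in rng_layout.uniform(0, 2 * np.pi, 6):
                            cand = (c + radius * np.array([np.cos(angle),
                                                           np.sin(angle)])) \
                                % [lx, ly]
                            # cholesterol occupies lattice positions not
                            # taken by aspirin: keep ring points clear of
                            # every aspirin centre
                            d = asa_centers - cand
                            d[:, 0] -= lx * np.round(d[:, 0] / lx)
                            d[:, 1] -= ly * np.round(d[:, 1] / ly)
                            if np.min(np.hypot(d[:, 0], d[:, 1])) < 5.0:
                                continue
                            candidates.append(cand)
                pick = rng_layout.choice(len(candidates), size=n_chol,
                                         replace=False)
                # cholesterol sits at the exact ring position (sharp
                # ring signature in the cholesterol–aspirin RDF); the
                # nearest DMPC site is vacated in exchange
                for i in pick:
                    pos = np.asarray(candidates[i])
                    chol_xy.append(pos)
                    d = sites - pos
                    d[:, 0] -= lx * np.round(d[:, 0] / lx)
                    d[:, 1] -= ly * np.round(d[:, 1] / ly)
                    for v in np.argsort(np.hypot(d[:, 0], d[:, 1])):
                        if species[v] == "DMPC":
                            species[v] = "REMOVED"
                            break
            else:
                pick = rng_layout.choice(len(sites), size=n_chol,
                                         replace=False)
                species[pick] = "CHOL"
                chol_xy = [sites[i].copy() for i in pick]
        # dilation around aspirin
        if len(asa_centers) and spec.dilation > 0:
            sites = _dilate(sites, asa_centers, spec.dilation,
                            spec.dilation_radius, s, lx, ly)
        layout[leaflet] = {"sites": sites, "species": species,
                           "asa": asa_centers, "chol": chol_xy,
                           "down": down}

    n_dihedrals = max(spec.n_tail_beads - 3, 0)
    for fi in range(n_frames):
        rng = np.random.default_rng([seed, 20, fi])
        positions, elements, names, resnames, resids = [], [], [], [], []
        truth_gauche: dict[int, dict] = {}
        truth_sites: dict[int, dict] = {}
        resid = 0

        def add_atom(pos, element, name, resname, rid):
            positions.append(pos)
            elements.append(element)
            names.append(name)
            resnames.append(resname)
            resids.append(rid)

        for leaflet, lay in layout.items():
            down = lay["down"]
            z_head = down * spec.d_hh / 2.0
            asa_centers = lay["asa"]
            for si, xy0 in enumerate(lay["sites"]):
                if lay["species"][si] != "DMPC":
                    continue
                resid += 1
                xy = xy0 + rng.normal(0.0, spec.jitter, 2)
                if len(asa_centers):
                    d = asa_centers - xy0
                    d[:, 0] -= lx * np.round(d[:, 0] / lx)
                    d[:, 1] -= ly * np.round(d[:, 1] / ly)
                    dist_asa = float(np.min(np.hypot(d[:, 0], d[:, 1])))
                else:
                    dist_asa = np.inf
                p_g = spec.gauche_near if dist_asa < spec.gauche_radius \
                    else spec.gauche_far
                add_atom(np.array([xy[0], xy[1], z_head]), "P", "P", "DMPC",
                         resid)
                add_atom(np.array([xy[0], xy[1] + 0.8,
                                   z_head + down * 1.2]), "N", "N", "DMPC",
                         resid)
                states_all = []
                for ti, prefix in enumerate(("C1", "C2")):
                    dx = (-1 if ti == 0 else 1) * s / 2.0
                    origin = np.array([xy[0] + dx, xy[1],
                                       z_head - down * 1.8])
                    gauche = rng.random(n_dihedrals) < p_g
                    signs = rng.choice([-1.0, 1.0], n_dihedrals)
                    phi = np.where(gauche, signs * 60.0, 180.0)
                    phi = phi + rng.normal(0.0, 8.0, n_dihedrals)
                    phi = (phi + 180.0) % 360.0 - 180.0
                    chain = _build_tail(origin, down, spec.n_tail_beads, phi)
                    for bi, pos in enumerate(chain, start=1):
                        add_atom(pos, "C", f"{prefix}{bi}", "DMPC", resid)
                    states_all.append(gauche)
                truth_gauche[resid] = {
                    "p": p_g,
                    "states": np.concatenate(states_all),
                    "fraction": float(np.mean(np.concatenate(states_all))),
                    "dist_asa": dist_asa,
                }
                truth_sites[resid] = {"species": "DMPC", "xy": xy0,
                                      "leaflet": leaflet}
            for pos in lay["chol"]:
                resid += 1
                xy = np.asarray(pos) + rng.normal(0.0, spec.jitter, 2)
                z0 = down * spec.d_hh / 2.0
                add_atom(np.array([xy[0], xy[1], z0]), "O", "O1", "CHOL",
                         resid)
                for bi in range(1, 5):
                    add_atom(np.array([xy[0], xy[1], z0 - down * 2.2 * bi]),
                             "C", f"C{bi}", "CHOL", resid)
                truth_sites[resid] = {"species": "CHOL", "xy": np.asarray(pos),
                                      "leaflet": leaflet}
            for c in asa_centers:
                resid += 1
                xy = np.asarray(c) + rng.normal(0.0, spec.jitter / 2.0, 2)
                z0 = down * spec.d_hh / 2.0
                offsets = np.array([[0.0, 0.0], [1.3, 0.0], [-1.3, 0.0],
                                    [0.0, 1.3], [0.0, -1.3]])
                for (ox, oy), (el, nm) in zip(
                        offsets, (("C", "C1"), ("C", "C2"), ("C", "C3"),
                                  ("O", "O1"), ("O", "O2"))):
                    add_atom(np.array([xy[0] + ox, xy[1] + oy, z0]), el, nm,
                             "ASA", resid)
                truth_sites[resid] = {"species": "ASA", "xy": np.asarray(c),
                                      "leaflet": leaflet}
        # waters in the two slabs outside the headgroup planes
        n_w = spec.waters_per_lipid * spec.n_lipids
        z_lo, z_hi = spec.d_hh / 2.0 + 4.0, spec.box_z / 2.0 - 2.0
        for _ in range(n_w):
            resid += 1
            side = 1.0 if rng.random() < 0.5 else -1.0
            base = np.array([rng.uniform(0, lx), rng.uniform(0, ly),
                             side * rng.uniform(z_lo, z_hi)])
            add_atom(base, "O", "OW", "SOL", resid)
            add_atom(base + [0.76, 0.59, 0.0], "H", "HW1", "SOL", resid)
            add_atom(base + [-0.76, 0.59, 0.0], "H", "HW2", "SOL", resid)
        truth = {"sites": truth_sites, "gauche": truth_gauche,
                 "asa_upper": layout["upper"]["asa"],
                 "asa_lower": layout["lower"]["asa"],
                 "lattice_constant": s,
                 "apl_effective": spec.effective_apl,
                 "spec": spec, "frame": fi}
        frames.append(MembraneFrame(
            positions=np.asarray(positions), elements=elements, names=names,
            resnames=resnames, resids=resids,
            box=np.array([lx, ly, spec.box_z]), meta={"truth": truth}))
    return frames
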