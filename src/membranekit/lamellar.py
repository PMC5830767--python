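"""Elastic-scattering analysis of oriented multibilayer stacks.

Out-of-plane reflectivity shows a lamellar Bragg series at q_n = 2πn/d_z.
Integrated peak intensities, combined with a ±1 phase array ν_n, give the
relative scattering-length density profile in the standard
oriented-multilayer form

    ρ(z) = Σ_n √(I_n q_n) · ν_n · cos(2πnz/d_z),

where √q_n is the Lorentz correction converting integrated intensity to
form-factor amplitude. For chain-deuterated bilayers the profile's interior
minima sit in the headgroups; their separation is the head–head spacing
d_HH. The in-plane chain-correlation peak at q_T gives the area per acyl
chain under hexagonal packing, A_T = 8π²/(√3 q_T²).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import curve_fit

from .scans import ReflectivityScan, Scan

__all__ = [
    "BraggPeakSet",
    "SLDProfile",
    "InPlanePeak",
    "find_bragg_peaks",
    "lamellar_spacing",
    "reconstruct_sld",
    "head_head_spacing",
    "area_per_tail",
    "fit_inplane_peak",
]

log = logging.getLogger(__name__)

#: Contaminant windows in in-plane scans (silicon/aluminium higher orders), Å⁻¹.
DEFAULT_EXCLUDE_WINDOWS = ((1.225, 1.275), (1.675, 1.725), (1.925, 1.975))


@dataclass
class BraggPeakSet:
    """Detected lamellar Bragg peaks with integrated intensities."""

    orders: np.ndarray              # harmonic index n
    positions: np.ndarray           # q_n, Å⁻¹
    intensities: np.ndarray         # integrated, counts·Å⁻¹
    position_errors: np.ndarray
    d_z: float                      # Å

    def __post_init__(self):
        self.orders = np.asarray(self.orders, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.position_errors = np.asarray(self.position_errors, dtype=float)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("peak positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("integrated intensities must be non-negative")
        if self.d_z <= 0:
            raise ValueError("d_z must be positive")

    def __len__(self):
        return len(self.orders)


@dataclass
class SLDProfile:
    """Relative scattering-length density on a uniform z grid."""

    z: np.ndarray                   # Å, spanning [−d_z/2, d_z/2]
    rho: np.ndarray
    phases: np.ndarray              # ν_n, ±1 per order used
    d_z: float
    d_hh: float | None = None      # filled by head_head_spacing

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        steps = np.diff(self.z)
        if not np.allclose(steps, steps[0]):
            raise ValueError("z grid must be uniform")


@dataclass
class InPlanePeak:
    """Chain-correlation peak and the hexagonal-packing area per tail."""

    q_t: float
    q_t_err: float
    a_t: float
    fit: dict = field(default_factory=dict)


def _gaussian_linear(q, amp, center, width, slope, offset):
    return amp * np.exp(-((q - center) ** 2) / (2 * width**2)) \
        + slope * q + offset


def find_bragg_peaks(scan: ReflectivityScan, max_orders: int = 9,
                     prominence: float | None = None,
                     equidistance_tol: float = 0.02) -> BraggPeakSet:
    """Detect and integrate the lamellar Bragg series.

    Each detected maximum is fit with a Gaussian plus local linear
    background over a ±3·width window; the integrated intensity is the
    Gaussian area above background. Harmonic orders are assigned by rounding
    q/Δq̂ with Δq̂ the median successive spacing, so a missing order does not
    shift the labels; d_z = 2π / slope of the through-origin regression of
    q_n on n.
    """
    counts = scan.counts
    if prominence is None:
        prominence = 8.0 * float(np.median(scan.errors))
    dq = float(np.mean(np.diff(scan.q_z)))
    min_distance = max(int(0.01 / dq), 1)
    idx, props = signal.find_peaks(counts, prominence=prominence,
                                   distance=min_distance)
    if len(idx) > max_orders:
        keep = np.sort(np.argsort(props["prominences"])[::-1][:max_orders])
        idx = idx[keep]
    if len(idx) < 3:
        raise ValueError(f"found only {len(idx)} resolvable Bragg peaks; "
                         "need at least 3")
    widths_pts = signal.peak_widths(counts, idx, rel_height=0.5)[0]
    positions, intensities, pos_errors = [], [], []
    for i, wpts in zip(idx, widths_pts):
        sigma_guess = max(wpts, 2.0) * dq / 2.3548
        lo = scan.q_z[i] - 3.0 * 2.3548 * sigma_guess
        hi = scan.q_z[i] + 3.0 * 2.3548 * sigma_guess
        window = (scan.q_z >= lo) & (scan.q_z <= hi)
        q_w, c_w, e_w = scan.q_z[window], counts[window], scan.errors[window]
        if len(q_w) < 6:
            log.info("peak at %.4f Å⁻¹ has too narrow a window; skipped",
                     scan.q_z[i])
            continue
        p0 = [max(counts[i] - np.median(c_w), 1.0), scan.q_z[i],
              sigma_guess, 0.0, float(np.median(c_w))]
        try:
            popt, pcov = curve_fit(_gaussian_linear, q_w, c_w, p0=p0,
                                   sigma=e_w, absolute_sigma=True,
                                   maxfev=10000)
        except RuntimeError:
            log.info("Gaussian fit failed at %.4f Å⁻¹; skipped", scan.q_z[i])
            continue
        amp, center, width = popt[0], popt[1], abs(popt[2])
        positions.append(center)
        intensities.append(amp * width * np.sqrt(2.0 * np.pi))
        pos_errors.append(float(np.sqrt(max(pcov[1, 1], 0.0))))
    if len(positions) < 3:
        raise ValueError("fewer than 3 Bragg peaks survived fitting")
    order = np.argsort(positions)
    positions = np.asarray(positions)[order]
    intensities = np.asarray(intensities)[order]
    pos_errors = np.asarray(pos_errors)[order]
    spacing = float(np.median(np.diff(positions))) if len(positions) > 1 \
        else positions[0]
    orders = np.maximum(np.round(positions / spacing).astype(int), 1)
    # duplicate order labels would mean the spacing estimate failed
    if len(np.unique(orders)) != len(orders):
        raise ValueError("could not assign unique harmonic orders")
    slope = float(np.sum(orders * positions) / np.sum(orders**2))
    deviation = np.abs(positions - orders * slope)
    if np.any(deviation > equidistance_tol * slope):
        warnings.warn("Bragg peaks deviate from equidistance by more than "
                      f"{equidistance_tol:.0%} of Δq_z", stacklevel=2)
    return BraggPeakSet(orders=orders, positions=positions,
                        intensities=intensities, position_errors=pos_errors,
                        d_z=2.0 * np.pi / slope)


def lamellar_spacing(peaks: BraggPeakSet) -> float:
    """Lamellar repeat d_z = 2π/Δq_z from the fitted common spacing."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks for a spacing")
    slope = float(np.sum(peaks.orders * peaks.positions)
                  / np.sum(peaks.orders**2))
    return 2.0 * np.pi / slope


def reconstruct_sld(peaks: BraggPeakSet, phases,
                    z_step: float = 0.1) -> SLDProfile:
    """Fourier-reconstruct the relative SLD profile from Bragg intensities.

    ρ(z) = Σ_n √(I_n q_n) ν_n cos(2πnz/d_z) on a uniform grid over one
    repeat [−d_z/2, d_z/2]; the scale is relative (phases and magnitudes
    only, no absolute normalisation).
    """
    phases = np.asarray(phases, dtype=float)
    if np.any(np.abs(phases) != 1):
        raise ValueError("phases must be ±1")
    if int(peaks.orders.max()) > len(phases):
        raise ValueError(f"orders up to {int(peaks.orders.max())} but only "
                         f"{len(phases)} phases")
    d_z = peaks.d_z
    n_pts = int(np.ceil(d_z / min(z_step, 0.25))) + 1
    z = np.linspace(-d_z / 2.0, d_z / 2.0, n_pts)
    rho = np.zeros_like(z)
    used_phases = []
    for n, q_n, i_n in zip(peaks.orders, peaks.positions, peaks.intensities):
        nu = phases[n - 1]
        used_phases.append(nu)
        rho += np.sqrt(max(i_n, 0.0) * q_n) * nu * np.cos(
            2.0 * np.pi * n * z / d_z)
    return SLDProfile(z=z, rho=rho, phases=np.asarray(used_phases), d_z=d_z)


def _parabolic_refine(z: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through points i−1, i, i+1."""
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(z[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(z[i] + delta * (z[i + 1] - z[i]))


def head_head_spacing(profile: SLDProfile,
                      asymmetry_tol: float = 1.0) -> float:
    """Head–head spacing from the interior headgroup minima of the profile.

    The two interior local minima flanking the bilayer centre (one on each
    side) are refined by parabolic interpolation over three grid points;
    d_HH is their separation. Minima at the repeat-unit edges do not count.
    """
    rho, z = profile.rho, profile.z
    interior = np.nonzero((rho[1:-1] < rho[:-2]) & (rho[1:-1] < rho[2:]))[0] + 1
    neg = [i for i in interior if z[i] < 0]
    pos = [i for i in interior if z[i] > 0]
    if not neg or not pos:
        raise ValueError("no interior minima on both sides of the centre")
    i_neg = min(neg, key=lambda i: rho[i])
    i_pos = min(pos, key=lambda i: rho[i])
    z_neg = _parabolic_refine(z, rho, i_neg)
    z_pos = _parabolic_refine(z, rho, i_pos)
    if abs(z_pos + z_neg) > asymmetry_tol:
        warnings.warn(f"headgroup minima asymmetric about 0 by "
                      f"{abs(z_pos + z_neg):.2f} Å", stacklevel=2)
    d_hh = z_pos - z_neg
    profile.d_hh = d_hh
    return d_hh


def area_per_tail(q_t: float) -> float:
    """Area per acyl chain from hexagonal packing: A_T = 8π²/(√3 q_T²)."""
    if q_t <= 0:
        raise ValueError("q_T must be positive")
    return 8.0 * np.pi**2 / (np.sqrt(3.0) * q_t**2)


def _lorentzian_linear(q, amp, center, width, slope, offset):
    return amp / (1.0 + ((q - center) / width) ** 2) + slope * q + offset


def fit_inplane_peak(scan: Scan, window=(1.2, 1.6),
                     exclude_windows=DEFAULT_EXCLUDE_WINDOWS) -> InPlanePeak:
    """Extract q_T from an in-plane scan by Lorentzian fit.

    Fits a Lorentzian plus linear background over ``window`` after masking
    the substrate contaminant windows; returns the peak position, its
    standard error, and the hexagonal-packing area per tail.
    """
    mask = (scan.axis >= window[0]) & (scan.axis <= window[1])
    for lo, hi in exclude_windows:
        mask &= ~((scan.axis >= lo) & (scan.axis <= hi))
    q, c, e = scan.axis[mask], scan.counts[mask], scan.errors[mask]
    if len(q) < 8:
        raise ValueError("too few points in the fit window")
    i_max = int(np.argmax(c))
    p0 = [max(c[i_max] - np.median(c), 1.0), q[i_max], 0.05, 0.0,
          float(np.median(c))]
    popt, pcov = curve_fit(_lorentzian_linear, q, c, p0=p0, sigma=e,
                           absolute_sigma=True, maxfev=10000)
    q_t = float(popt[1])
    q_t_err = float(np.sqrt(max(pcov[1, 1], 0.0)))
    return InPlanePeak(q_t=q_t, q_t_err=q_t_err, a_t=area_per_tail(q_t),
                       fit={"amp": popt[0], "width": abs(popt[2]),
                            "slope": popt[3], "offset": popt[4]})
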