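"""Phonon dispersion assembly, branch assignment, and minimum fitting.

Dispersion points (q∥, ℏω) collected from constant-q and constant-E fits
are assigned to gel / fluid / liquid-ordered branches by nearest anchor
curve, and each branch's minimum is fitted with the empirical quadratic

    ℏω(q∥) = α (q∥ − q∥₀)² + ℏω₀,

where ℏω₀ (depth of the minimum) tracks lipid order and α (curvature)
is an empirical softness metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .spectral import ConstantEFitResult, SpectralFitResult

__all__ = [
    "DispersionPoint",
    "BranchFitResult",
    "DispersionBranchModel",
    "DEFAULT_ANCHORS",
    "collect_points",
    "assign_branches",
    "fit_branch_minimum",
    "compare_branch_parameters",
    "compare_samples",
    "width_at_minimum",
]

log = logging.getLogger(__name__)

BRANCHES = ("gel", "fluid", "lo")

#: Default anchor curves (q∥ in Å⁻¹, ℏω in meV) following the observed
#: morphology of the three branches in cholesterol-rich DMPC: a steep gel
#: branch, a broad fluid minimum near 1.1 meV, and the lowest-lying
#: liquid-ordered minimum at 0.5–0.7 meV. Anchors are configuration, not
#: algorithm: assignment in the source experiments was by visual
#: correspondence.
DEFAULT_ANCHORS: dict[str, list[tuple[float, float]]] = {
    "gel": [(1.0, 5.0), (1.2, 2.5), (1.4, 0.75), (1.6, 2.5), (1.8, 5.0)],
    "fluid": [(1.0, 1.9), (1.2, 1.3), (1.4, 1.1), (1.6, 1.3), (1.8, 1.9)],
    "lo": [(1.0, 1.2), (1.2, 0.75), (1.4, 0.55), (1.6, 0.75), (1.8, 1.2)],
}


@dataclass
class DispersionPoint:
    """One phonon observation in the (q∥, ℏω) plane."""

    q_par: float
    energy: float
    energy_err: float
    width: float | None = None          # HWHM in meV, constant-q points only
    width_err: float | None = None
    source: str = "constant_q"          # constant_q | constant_E
    branch: str = "unassigned"

    def __post_init__(self):
        if self.q_par <= 0:
            raise ValueError("q_par must be positive")
        if self.energy <= 0:
            raise ValueError("energy must be positive")
        if self.energy_err <= 0:
            raise ValueError("energy_err must be positive")


def collect_points(fit_results) -> list[DispersionPoint]:
    """Assemble dispersion points from converged spectral fits.

    Constant-q fits contribute (fixed q, fitted μ); constant-E fits
    contribute (fitted q centre, fixed E). Non-converged fits and
    non-detected modes are skipped with a log entry.
    """
    points: list[DispersionPoint] = []
    for res in fit_results:
        if not res.converged:
            log.info("skipping non-converged fit (%s)", res.message)
            continue
        if isinstance(res, SpectralFitResult):
            q = res.scan.fixed_value
            for i in res.detected_modes():
                mode = res.params.modes[i]
                err = res.mode_stderr(i, "mu")
                if not np.isfinite(err) or err <= 0:
                    log.info("mode %d has no position error; skipped", i)
                    continue
                points.append(DispersionPoint(
                    q_par=q, energy=mode.mu, energy_err=err,
                    width=mode.sigma,
                    width_err=res.mode_stderr(i, "sigma"),
                    source="constant_q"))
        elif isinstance(res, ConstantEFitResult):
            energy = res.scan.fixed_value
            # a constant-E scan carries no energy uncertainty of its own;
            # use half the energy step of the instrument setup if supplied
            e_err = float(res.scan.meta.get("energy_err", 0.1))
            for i in res.detected_peaks():
                points.append(DispersionPoint(
                    q_par=float(res.centers[i]), energy=energy,
                    energy_err=e_err, source="constant_E"))
        else:
            raise TypeError(f"unsupported fit result {type(res)!r}")
    return points


def _polyline_distance(q: float, w: float, anchors,
                       q_scale: float, e_scale: float) -> float:
    """Min scaled distance from a point to the piecewise-linear anchor curve."""
    pts = np.asarray(anchors, dtype=float)
    px = np.array([q / q_scale, w / e_scale])
    xy = np.column_stack([pts[:, 0] / q_scale, pts[:, 1] / e_scale])
    if len(xy) == 1:
        return float(np.hypot(*(px - xy[0])))
    best = np.inf
    for a, b in zip(xy[:-1], xy[1:]):
        ab = b - a
        t = np.clip(np.dot(px - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        best = min(best, float(np.linalg.norm(px - (a + t * ab))))
    return best


def _anchor_energy_at(q: float, anchors) -> float:
    pts = np.asarray(sorted(anchors), dtype=float)
    return float(np.interp(q, pts[:, 0], pts[:, 1]))


def assign_branches(points, anchors=None, q_scale: float = 1.0,
                    e_scale: float = 1.0,
                    cutoff: float | None = None) -> list[DispersionPoint]:
    """Label each point with the nearest anchor curve's branch (in place).

    Distance is measured in unit-free (q/q_scale, ω/e_scale) coordinates;
    ties go to the branch with the lower anchor energy at the point's q.
    Points farther than ``cutoff`` from every curve stay unassigned.
    Deterministic: no randomness is involved.
    """
    anchors = anchors or DEFAULT_ANCHORS
    if any(len(v) < 1 for v in anchors.values()):
        raise ValueError("every branch needs at least one anchor")
    for pt in points:
        dists = {br: _polyline_distance(pt.q_par, pt.energy, anc,
                                        q_scale, e_scale)
                 for br, anc in anchors.items()}
        dmin = min(dists.values())
        if cutoff is not None and dmin > cutoff:
            pt.branch = "unassigned"
            continue
        candidates = [br for br, d in dists.items() if d <= dmin + 1e-12]
        if len(candidates) > 1:
            candidates.sort(
                key=lambda br: _anchor_energy_at(pt.q_par, anchors[br]))
        pt.branch = candidates[0]
    return points


# ---------------------------------------------------------------------------
# quadratic minimum fit
# ---------------------------------------------------------------------------

@dataclass
class BranchFitResult:
    """Quadratic fit ℏω = α(q−q₀)² + ℏω₀ around a branch minimum."""

    alpha: float
    q0: float
    omega0: float
    bse: dict[str, float]
    cov: np.ndarray
    fit_range: tuple[float, float]
    branch: str = "unassigned"
    n_points: int = 0
    chi2: float = np.nan

    @property
    def params(self) -> dict[str, float]:
        return {"alpha": self.alpha, "q0": self.q0, "omega0": self.omega0}

    @property
    def opens_upward(self) -> bool:
        return self.alpha > 0

    def summary(self) -> str:
        return (
            f"Branch '{self.branch}' quadratic minimum fit "
            f"({self.n_points} points in "
            f"[{self.fit_range[0]}, {self.fit_range[1]}] Å⁻¹)\n"
            f"  alpha  = {self.alpha:.4g} ± {self.bse['alpha']:.2g} meV·Å²\n"
            f"  q0     = {self.q0:.4g} ± {self.bse['q0']:.2g} Å⁻¹\n"
            f"  omega0 = {self.omega0:.4g} ± {self.bse['omega0']:.2g} meV"
        )


def _quadratic(q, alpha, q0, omega0):
    return alpha * (q - q0) ** 2 + omega0


class DispersionBranchModel:
    """Weighted quadratic model for one branch's dispersion minimum."""

    def __init__(self, points, fit_range: tuple[float, float] = (1.0, 2.0),
                 branch: str | None = None):
        pts = [p for p in points
               if (branch is None or p.branch == branch)
               and fit_range[0] <= p.q_par <= fit_range[1]]
        if len(pts) < 4:
            raise ValueError(
                f"need at least 4 points in range {fit_range}, got {len(pts)}")
        self.points = pts
        self.fit_range = tuple(fit_range)
        self.branch = branch or (pts[0].branch if pts else "unassigned")

    def fit(self) -> BranchFitResult:
        q = np.array([p.q_par for p in self.points])
        w = np.array([p.energy for p in self.points])
        err = np.array([p.energy_err for p in self.points])
        i0 = int(np.argmin(w))
        p0 = [max((w.max() - w.min()) / max((q - q[i0]).max() ** 2, 1e-3), 1.0),
              q[i0], w[i0]]
        popt, pcov = curve_fit(_quadratic, q, w, p0=p0, sigma=err,
                               absolute_sigma=True, maxfev=20000)
        bse = {name: float(np.sqrt(pcov[i, i]))
               for i, name in enumerate(("alpha", "q0", "omega0"))}
        resid = (_quadratic(q, *popt) - w) / err
        res = BranchFitResult(
            alpha=float(popt[0]), q0=float(popt[1]), omega0=float(popt[2]),
            bse=bse, cov=pcov, fit_range=self.fit_range, branch=self.branch,
            n_points=len(q), chi2=float(np.sum(resid**2)))
        if res.alpha <= 0:
            log.warning("branch %s: fitted dispersion does not open upward "
                        "(alpha = %.3g)", self.branch, res.alpha)
        return res


def fit_branch_minimum(points, fit_range=(1.0, 2.0),
                       branch: str | None = None) -> BranchFitResult:
    """Fit the quadratic dispersion minimum to one branch's points."""
    return DispersionBranchModel(points, fit_range=fit_range,
                                 branch=branch).fit()


# ---------------------------------------------------------------------------
# sample comparison
# ---------------------------------------------------------------------------

@dataclass
class ParameterComparison:
    name: str
    value_a: float
    value_b: float
    se_a: float
    se_b: float
    z: float
    significant: bool


@dataclass
class ComparisonReport:
    branch: str
    comparisons: list[ParameterComparison] = field(default_factory=list)
    z_threshold: float = 1.96

    def significant_parameters(self) -> list[str]:
        return [c.name for c in self.comparisons if c.significant]

    def summary(self) -> str:
        lines = [f"Branch '{self.branch}' comparison "
                 f"(|z| > {self.z_threshold} flags significance)"]
        for c in self.comparisons:
            mark = "  *" if c.significant else ""
            lines.append(
                f"  {c.name}: {c.value_a:.3g} ± {c.se_a:.2g} vs "
                f"{c.value_b:.3g} ± {c.se_b:.2g}  z = {c.z:.2f}{mark}")
        return "\n".join(lines)


def _z_statistic(a, se_a, b, se_b) -> float:
    return abs(a - b) / float(np.hypot(se_a, se_b))


def compare_branch_parameters(fit_a, fit_b,
                              z_threshold: float = 1.96) -> ComparisonReport:
    """Two-sample z comparison of branch-fit parameters.

    ``fit_a``/``fit_b`` are BranchFitResults or plain mappings
    name -> (value, stderr). Parameters without a finite standard error are
    skipped with a warning entry in the log (large printed uncertainties are
    carried through untouched).
    """

    def _items(fit):
        if isinstance(fit, BranchFitResult):
            return {k: (v, fit.bse[k]) for k, v in fit.params.items()}
        return dict(fit)

    items_a, items_b = _items(fit_a), _items(fit_b)
    branch = getattr(fit_a, "branch", "unassigned")
    report = ComparisonReport(branch=branch, z_threshold=z_threshold)
    for name in items_a:
        if name not in items_b:
            continue
        (va, sa), (vb, sb) = items_a[name], items_b[name]
        if not (np.isfinite(sa) and np.isfinite(sb) and sa > 0 and sb > 0):
            log.warning("parameter %s skipped: missing standard error", name)
            continue
        z = _z_statistic(va, sa, vb, sb)
        report.comparisons.append(ParameterComparison(
            name=name, value_a=va, value_b=vb, se_a=sa, se_b=sb, z=z,
            significant=z > z_threshold))
    return report


def compare_samples(fits_a: dict, fits_b: dict,
                    z_threshold: float = 1.96) -> dict[str, ComparisonReport]:
    """Compare two samples' branch fits, branch by branch."""
    return {br: compare_branch_parameters(fits_a[br], fits_b[br],
                                          z_threshold=z_threshold)
            for br in fits_a if br in fits_b}


def width_at_minimum(points, branch_fit: BranchFitResult):
    """Phonon width at the q closest to the branch minimum.

    Widths from constant-q scans taken at the dispersion minimum are closest
    to the true damping (elsewhere the sloped dispersion inside the
    resolution ellipsoid broadens the line); this picks the constant-q point
    nearest q₀.
    """
    candidates = [p for p in points
                  if p.branch == branch_fit.branch
                  and p.source == "constant_q" and p.width is not None]
    if not candidates:
        raise ValueError(f"no constant-q widths for branch "
                         f"{branch_fit.branch!r}")
    best = min(candidates, key=lambda p: abs(p.q_par - branch_fit.q0))
    return best.width, best.width_err
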