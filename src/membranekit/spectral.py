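"""Spectral model and fitting for triple-axis scans.

Constant-q energy scans are described by an elastic Gaussian (fixed at zero
energy transfer with instrument-supplied width), an incoherent Lorentzian
fixed at zero, a linear background, and up to three phonon doublets whose
anti-Stokes amplitudes follow from detailed balance,

    I(ω) = A_el exp(−ω²/2σ_el²) + mω + b
         + Σ_i [ A₊ᵢ / (1 + (ω−μᵢ)²/σᵢ²) + A₋ᵢ / (1 + (ω+μᵢ)²/σᵢ²) ]
         + A_inc / (1 + ω²/σ_inc²),          A₋ᵢ = A₊ᵢ e^(−μᵢ/k_B T).

σᵢ is the Lorentzian half-width at half-maximum; positive ω is neutron
energy loss (Stokes side). The number of phonon doublets is selected by a
sequential nested-model F-test,

    F_χ = (χ²(m) − χ²(m+4)) / (χ²(m+4) / (N − m − 1)),

with m the free-parameter count of the simpler model in the conventional
accounting (6 background parameters plus 4 per phonon).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import lmfit
import numpy as np
from scipy import signal, stats

from .constants import thermal_energy
from .scans import Scan

__all__ = [
    "PhononMode",
    "SpectralParams",
    "SpectralFitResult",
    "ConstantEFitResult",
    "ModelSelection",
    "ConstantQSpectrum",
    "ConstantESpectrum",
    "detailed_balance_ratio",
    "evaluate_spectrum",
    "fit_constant_q_scan",
    "fit_constant_e_scan",
    "f_chi",
    "f_critical",
    "critical_value_for_increment",
    "accept_increments",
    "sequential_f_test",
]

N_BACKGROUND_PARAMS = 6   # conventional accounting: 2 elastic + 2 incoherent + 2 linear
N_PARAMS_PER_PHONON = 4


def detailed_balance_ratio(mu: float, temperature: float) -> float:
    """Anti-Stokes/Stokes amplitude ratio exp(−μ / k_B T)."""
    return float(np.exp(-np.asarray(mu) / thermal_energy(temperature)))


@dataclass(frozen=True)
class PhononMode:
    """One phonon doublet: position μ (meV), HWHM σ (meV), Stokes amplitude."""

    mu: float
    sigma: float
    amp_plus: float

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mode position mu must be positive")
        if self.sigma <= 0:
            raise ValueError("mode width sigma must be positive")
        if self.amp_plus < 0:
            raise ValueError("Stokes amplitude must be non-negative")

    def amp_minus(self, temperature: float) -> float:
        """Anti-Stokes amplitude, derived (never fitted) via detailed balance."""
        return self.amp_plus * detailed_balance_ratio(self.mu, temperature)

    @property
    def fwhm(self) -> float:
        return 2.0 * self.sigma


@dataclass
class SpectralParams:
    """Parameters of the constant-q spectral model."""

    a_el: float
    a_inc: float
    sigma_inc: float
    slope: float
    intercept: float
    modes: tuple[PhononMode, ...]
    temperature: float
    sigma_el: float

    def __post_init__(self):
        if self.a_el < 0 or self.a_inc < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.sigma_inc <= 0 or self.sigma_el <= 0:
            raise ValueError("widths must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        self.modes = tuple(sorted(self.modes, key=lambda m: m.mu))

    def evaluate(self, omega) -> np.ndarray:
        return evaluate_spectrum(self, omega)


def evaluate_spectrum(params: SpectralParams, omega) -> np.ndarray:
    """Evaluate the spectral model on an energy-transfer grid (meV)."""
    w = np.asarray(omega, dtype=float)
    out = params.a_el * np.exp(-w**2 / (2.0 * params.sigma_el**2))
    out = out + params.slope * w + params.intercept
    out = out + params.a_inc / (1.0 + (w / params.sigma_inc) ** 2)
    for mode in params.modes:
        a_minus = mode.amp_minus(params.temperature)
        out = out + mode.amp_plus / (1.0 + ((w - mode.mu) / mode.sigma) ** 2)
        out = out + a_minus / (1.0 + ((w + mode.mu) / mode.sigma) ** 2)
    return out


@dataclass
class SpectralFitResult:
    """Weighted least-squares fit of a constant-q scan.

    ``params`` holds the optimum; ``bse`` the standard errors of the free
    parameters (from the local covariance); ``chi2`` the weighted residual
    sum of squares.
    """

    params: SpectralParams
    bse: dict[str, float]
    chi2: float
    n_points: int
    n_params: int
    converged: bool
    scan: Scan | None = None
    message: str = ""

    @property
    def n_phonons(self) -> int:
        return len(self.params.modes)

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / max(self.n_points - self.n_params, 1)

    def mode_stderr(self, i: int, which: str) -> float:
        return self.bse.get(f"{which}_{i + 1}", np.nan)

    def detected_modes(self) -> list[int]:
        """Indices of modes considered real detections.

        A mode counts as detected when its amplitude exceeds twice its
        standard error and its width is resolved — wider than 1.5 grid
        steps, so a single noisy point cannot register as a phonon.
        """
        min_width = 0.0
        if self.scan is not None and len(self.scan.axis) > 1:
            min_width = 1.5 * float(np.median(np.diff(self.scan.axis)))
        out = []
        for i, mode in enumerate(self.params.modes):
            se = self.mode_stderr(i, "amp")
            if np.isfinite(se) and se > 0 and mode.amp_plus >= 2.0 * se \
                    and mode.sigma > min_width:
                out.append(i)
        return out

    def summary(self) -> str:
        lines = [
            "Constant-q spectral fit",
            f"  phonons: {self.n_phonons}   converged: {self.converged}",
            f"  chi2 = {self.chi2:.4g}  (N = {self.n_points}, "
            f"free params = {self.n_params})",
            f"  elastic A = {self.params.a_el:.4g}  "
            f"(sigma_el fixed at {self.params.sigma_el} meV)",
            f"  incoherent A = {self.params.a_inc:.4g}, "
            f"HWHM = {self.params.sigma_inc:.4g} meV",
            f"  background: {self.params.slope:.4g}·ω + "
            f"{self.params.intercept:.4g}",
        ]
        for i, mode in enumerate(self.params.modes):
            lines.append(
                f"  P{i + 1}: mu = {mode.mu:.4f} ± "
                f"{self.mode_stderr(i, 'mu'):.4f} meV, "
                f"sigma(HWHM) = {mode.sigma:.4f} ± "
                f"{self.mode_stderr(i, 'sigma'):.4f} meV, "
                f"A+ = {mode.amp_plus:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# constant-q fitting
# ---------------------------------------------------------------------------

class ConstantQSpectrum:
    """Spectral model bound to one constant-q energy scan.

    ``fit(n_phonons)`` performs bounded weighted least squares (lmfit
    Levenberg–Marquardt) with multi-start initialisation: mode positions are
    seeded from smoothed-residual peak picking after a background-only fit,
    plus randomised restarts; the lowest-χ² optimum is kept.
    """

    def __init__(self, scan: Scan):
        if scan.kind != "constant_q":
            raise ValueError("ConstantQSpectrum requires a constant_q scan")
        self.scan = scan

    # -- parameter plumbing -------------------------------------------------

    def _make_parameters(self, k: int, init: SpectralParams) -> lmfit.Parameters:
        scan = self.scan
        wmax = float(scan.axis[-1])
        pars = lmfit.Parameters()
        top = max(float(scan.counts.max()), 1.0)
        pars.add("a_el", value=max(init.a_el, 1e-6), min=0.0, max=10 * top)
        pars.add("a_inc", value=max(init.a_inc, 1e-6), min=0.0, max=10 * top)
        pars.add("sigma_inc", value=min(init.sigma_inc, 1.5), min=0.01,
                 max=1.5)
        pars.add("slope", value=init.slope)
        pars.add("intercept", value=init.intercept)
        for i, mode in enumerate(init.modes[:k], start=1):
            pars.add(f"mu_{i}", value=mode.mu, min=0.05, max=wmax)
            # HWHM floor: half the typical grid step, so a single noisy
            # point cannot masquerade as a phonon
            step = float(np.median(np.diff(scan.axis)))
            pars.add(f"sigma_{i}", value=max(mode.sigma, step), min=step,
                     max=2.0)
            pars.add(f"amp_{i}", value=max(mode.amp_plus, 1e-6),
                     min=0.0, max=10 * top)
        return pars

    def _params_from(self, pars, k: int) -> SpectralParams:
        modes = tuple(
            PhononMode(mu=pars[f"mu_{i}"].value,
                       sigma=pars[f"sigma_{i}"].value,
                       amp_plus=pars[f"amp_{i}"].value)
            for i in range(1, k + 1))
        return SpectralParams(
            a_el=pars["a_el"].value, a_inc=pars["a_inc"].value,
            sigma_inc=pars["sigma_inc"].value, slope=pars["slope"].value,
            intercept=pars["intercept"].value, modes=modes,
            temperature=self.scan.temperature, sigma_el=self.scan.sigma_el)

    def _residual(self, pars, k: int) -> np.ndarray:
        model = evaluate_spectrum(self._params_from(pars, k), self.scan.axis)
        return (model - self.scan.counts) / self.scan.errors

    # -- initialisation -----------------------------------------------------

    def _background_guess(self) -> SpectralParams:
        scan = self.scan
        wing = scan.counts[np.abs(scan.axis) > 0.75 * np.abs(scan.axis).max()]
        intercept = float(np.median(wing)) if len(wing) else float(
            np.median(scan.counts))
        return SpectralParams(
            a_el=max(float(scan.counts.max()) - intercept, 1.0),
            a_inc=max(0.1 * float(scan.counts.max()), 1.0),
            sigma_inc=0.5, slope=0.0, intercept=max(intercept, 1e-3),
            modes=(), temperature=scan.temperature, sigma_el=scan.sigma_el)

    def _fit_background(self) -> tuple[SpectralParams, lmfit.MinimizerResult]:
        pars = self._make_parameters(0, self._background_guess())
        res = lmfit.minimize(self._residual, pars, args=(0,), method="leastsq")
        return self._params_from(res.params, 0), res

    def _candidate_positions(self, background: SpectralParams) -> list[tuple[float, float]]:
        """(position, score) candidates for μ from smoothed residual peaks
        on the Stokes side, padded with a coarse grid."""
        scan = self.scan
        resid = (scan.counts - background.evaluate(scan.axis)) / scan.errors
        smooth = np.convolve(resid, np.ones(3) / 3.0, mode="same")
        idx = np.nonzero(scan.axis > max(scan.sigma_el, 0.2))[0]
        candidates: list[tuple[float, float]] = []
        if len(idx) > 4:
            peaks, props = signal.find_peaks(smooth[idx], prominence=0.3)
            candidates = [(float(scan.axis[idx[p]]), float(s))
                          for p, s in zip(peaks, props["prominences"])]
            candidates.sort(key=lambda c: -c[1])
            candidates = candidates[:6]
        lo = max(scan.sigma_el, 0.3)
        hi = 0.8 * float(scan.axis[-1])
        for g in np.linspace(lo, hi, 4):
            if all(abs(g - c[0]) > 0.15 for c in candidates):
                candidates.append((float(g), 0.0))
        return candidates

    def _initial_models(self, k: int, init: SpectralParams | None,
                        n_restarts: int) -> list[SpectralParams]:
        background, _ = self._fit_background()
        candidates = self._candidate_positions(background)
        amp0 = max(float(np.max(self.scan.counts)) / 20.0, 5.0)

        def model_from(mus) -> SpectralParams:
            return replace(background, modes=tuple(
                PhononMode(mu=m, sigma=0.2, amp_plus=amp0)
                for m in sorted(mus)))

        combos = sorted(itertools.combinations(range(len(candidates)), k),
                        key=lambda c: -sum(candidates[i][1] for i in c))
        inits = [model_from([candidates[i][0] for i in combo])
                 for combo in combos[:max(n_restarts, 1)]]
        if init is not None and len(init.modes) == k:
            inits.insert(0, init)
        return inits if inits else [model_from(
            np.linspace(0.5, 0.8 * float(self.scan.axis[-1]), max(k, 1)))]

    # -- fitting ------------------------------------------------------------

    def fit(self, n_phonons: int, init: SpectralParams | None = None,
            n_restarts: int = 5) -> SpectralFitResult:
        k = int(n_phonons)
        if not 0 <= k <= 3:
            raise ValueError("phonon count must be between 0 and 3")
        best = None
        for start in self._initial_models(k, init, n_restarts):
            pars = self._make_parameters(k, start)
            try:
                res = lmfit.minimize(self._residual, pars, args=(k,),
                                     method="leastsq")
            except Exception:                      # never raise on a bad start
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            return SpectralFitResult(
                params=self._background_guess(), bse={}, chi2=np.inf,
                n_points=len(self.scan), n_params=5 + 3 * k, converged=False,
                scan=self.scan, message="all starts failed")
        return self._result_from(best, k)

    def _covariance_fallback(self, res, k: int) -> dict[str, float]:
        """Standard errors from a finite-difference Jacobian, excluding
        parameters pinned at a bound (whose stderr is undefined there).

        Used when the optimiser's covariance is singular — typically when a
        component's amplitude has collapsed to zero and its width becomes
        unidentifiable.
        """
        names = [n for n, p in res.params.items() if p.vary]
        free = []
        for n in names:
            p = res.params[n]
            scale = max(abs(p.value), 1e-3)
            at_min = p.min is not None and np.isfinite(p.min) and \
                abs(p.value - p.min) < 1e-6 * scale + 1e-12
            at_max = p.max is not None and np.isfinite(p.max) and \
                abs(p.value - p.max) < 1e-6 * scale
            if not (at_min or at_max):
                free.append(n)
        if not free:
            return {}
        pars = res.params.copy()
        base = np.asarray(self._residual(pars, k), dtype=float)
        jac = np.empty((len(base), len(free)))
        for j, n in enumerate(free):
            v0 = pars[n].value
            h = 1e-5 * max(abs(v0), 1e-2)
            pars[n].set(value=v0 + h)
            up = np.asarray(self._residual(pars, k), dtype=float)
            pars[n].set(value=v0 - h)
            dn = np.asarray(self._residual(pars, k), dtype=float)
            pars[n].set(value=v0)
            jac[:, j] = (up - dn) / (2.0 * h)
        norms = np.linalg.norm(jac, axis=0)
        keep = norms > 1e-8 * max(norms.max(), 1.0)
        if not keep.any():
            return {}
        sub = jac[:, keep]
        cov = np.linalg.pinv(sub.T @ sub, rcond=1e-12)
        redchi = float(np.sum(base**2)) / max(len(base) - int(keep.sum()), 1)
        diag = np.clip(np.diag(cov) * redchi, 0.0, None)
        return {n: float(np.sqrt(d))
                for n, d in zip(np.asarray(free)[keep], diag)}

    def _result_from(self, res, k: int) -> SpectralFitResult:
        params = self._params_from(res.params, k)
        # re-map standard errors onto modes sorted by mu
        order = np.argsort([res.params[f"mu_{i}"].value
                            for i in range(1, k + 1)])
        fallback: dict[str, float] | None = None

        def stderr_of(name: str) -> float:
            nonlocal fallback
            se = res.params[name].stderr
            if se is not None:
                return float(se)
            if fallback is None:
                fallback = self._covariance_fallback(res, k)
            return fallback.get(name, np.nan)

        bse: dict[str, float] = {}
        singular = False
        for name in ("a_el", "a_inc", "sigma_inc", "slope", "intercept"):
            bse[name] = stderr_of(name)
        for rank, orig in enumerate(order, start=1):
            for stem in ("mu", "sigma", "amp"):
                se = stderr_of(f"{stem}_{orig + 1}")
                if not np.isfinite(se):
                    singular = True
                bse[f"{stem}_{rank}"] = se
        converged = bool(res.success) and not singular
        message = res.message if isinstance(res.message, str) else ""
        if singular:
            message = (message + "; singular covariance: phonon count may "
                       "exceed data support").strip("; ")
        return SpectralFitResult(
            params=params, bse=bse, chi2=float(res.chisqr),
            n_points=len(self.scan), n_params=int(res.nvarys),
            converged=converged, scan=self.scan, message=message)


def fit_constant_q_scan(scan: Scan, n_phonons: int,
                        init: SpectralParams | None = None,
                        n_restarts: int = 5) -> SpectralFitResult:
    """Fit a constant-q energy scan with ``n_phonons`` phonon doublets."""
    return ConstantQSpectrum(scan).fit(n_phonons, init=init,
                                       n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# constant-E fitting
# ---------------------------------------------------------------------------

@dataclass
class ConstantEFitResult:
    """Fit of a constant-energy q-scan: phonon peak centres in q.

    The model is an empirical exponential background, a broad background
    Lorentzian (centre initialised near 2.5 Å⁻¹ but free), and ``k``
    Lorentzian phonon peaks; all parameters are free.
    """

    centers: np.ndarray            # Å⁻¹, sorted
    center_errors: np.ndarray
    widths: np.ndarray             # HWHM in q
    amplitudes: np.ndarray
    amplitude_errors: np.ndarray
    background: dict[str, float]
    chi2: float
    n_points: int
    n_params: int
    converged: bool
    scan: Scan | None = None
    message: str = ""

    def detected_peaks(self) -> list[int]:
        out = []
        for i, (a, se) in enumerate(zip(self.amplitudes,
                                        self.amplitude_errors)):
            if np.isfinite(se) and se > 0 and a >= 2.0 * se:
                out.append(i)
        return out

    def summary(self) -> str:
        lines = [
            "Constant-E q-scan fit",
            f"  peaks: {len(self.centers)}   converged: {self.converged}",
            f"  chi2 = {self.chi2:.4g}  (N = {self.n_points})",
            f"  background: {self.background['b0']:.4g}·exp(−"
            f"{self.background['b1']:.4g}·q) + broad Lorentzian at "
            f"{self.background['bg_center']:.3f} Å⁻¹",
        ]
        for i, (c, ce, w) in enumerate(zip(self.centers, self.center_errors,
                                           self.widths)):
            lines.append(f"  Q{i + 1}: q = {c:.4f} ± {ce:.4f} Å⁻¹, "
                         f"HWHM = {w:.4f} Å⁻¹")
        return "\n".join(lines)


class ConstantESpectrum:
    """Model for a constant-energy scan along q."""

    def __init__(self, scan: Scan):
        if scan.kind != "constant_E":
            raise ValueError("ConstantESpectrum requires a constant_E scan")
        self.scan = scan

    def _model(self, pars, q, k):
        out = pars["b0"] * np.exp(-pars["b1"] * q)
        out = out + pars["bg_amp"] / (
            1.0 + ((q - pars["bg_center"]) / pars["bg_width"]) ** 2)
        for i in range(1, k + 1):
            out = out + pars[f"amp_{i}"] / (
                1.0 + ((q - pars[f"q_{i}"]) / pars[f"w_{i}"]) ** 2)
        return out

    def _residual(self, pars, k):
        return ((self._model(pars, self.scan.axis, k) - self.scan.counts)
                / self.scan.errors)

    def _make_parameters(self, k, centers, bg_center):
        scan = self.scan
        top = max(float(scan.counts.max()), 1.0)
        qlo, qhi = float(scan.axis[0]), float(scan.axis[-1])
        pars = lmfit.Parameters()
        pars.add("b0", value=top, min=0.0)
        pars.add("b1", value=1.0, min=0.0, max=20.0)
        pars.add("bg_amp", value=0.2 * top, min=0.0, max=10 * top)
        pars.add("bg_center", value=bg_center, min=qlo, max=qhi + 2.0)
        pars.add("bg_width", value=0.4, min=0.1, max=3.0)
        for i, c in enumerate(centers, start=1):
            pars.add(f"q_{i}", value=c, min=qlo, max=qhi)
            pars.add(f"w_{i}", value=0.05, min=0.01, max=0.5)
            pars.add(f"amp_{i}", value=0.2 * top, min=0.0, max=10 * top)
        return pars

    def _seed_centers(self, k):
        scan = self.scan
        smooth = np.convolve(scan.counts, np.ones(3) / 3.0, mode="same")
        peaks, props = signal.find_peaks(smooth, prominence=2.0 * np.median(
            scan.errors))
        centers = [float(scan.axis[p]) for p in
                   peaks[np.argsort(props["prominences"])[::-1]]]
        out = centers[:k]
        qlo, qhi = float(scan.axis[0]), float(scan.axis[-1])
        while len(out) < k:
            out.append(qlo + (qhi - qlo) * (len(out) + 1) / (k + 1))
        return np.sort(np.asarray(out))

    def fit(self, n_peaks: int, bg_center: float = 2.5,
            n_restarts: int = 4) -> ConstantEFitResult:
        k = int(n_peaks)
        if not 1 <= k <= 3:
            raise ValueError("peak count must be 1–3")
        seeds = [self._seed_centers(k)]
        rng = np.random.default_rng(20180301)
        qlo, qhi = float(self.scan.axis[0]), float(self.scan.axis[-1])
        while len(seeds) < n_restarts:
            seeds.append(np.sort(rng.uniform(qlo, qhi, size=k)))
        best = None
        for centers in seeds:
            pars = self._make_parameters(k, centers, bg_center)
            try:
                res = lmfit.minimize(self._residual, pars, args=(k,),
                                     method="leastsq")
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        if best is None:
            return ConstantEFitResult(
                centers=np.array([]), center_errors=np.array([]),
                widths=np.array([]), amplitudes=np.array([]),
                amplitude_errors=np.array([]), background={}, chi2=np.inf,
                n_points=len(self.scan), n_params=5 + 3 * k, converged=False,
                scan=self.scan, message="all starts failed")
        pars = best.params
        order = np.argsort([pars[f"q_{i}"].value for i in range(1, k + 1)])
        centers = np.array([pars[f"q_{i + 1}"].value for i in order])
        singular = False

        def _se(name):
            nonlocal singular
            se = pars[name].stderr
            if se is None:
                singular = True
                return np.nan
            return float(se)

        result = ConstantEFitResult(
            centers=centers,
            center_errors=np.array([_se(f"q_{i + 1}") for i in order]),
            widths=np.array([pars[f"w_{i + 1}"].value for i in order]),
            amplitudes=np.array([pars[f"amp_{i + 1}"].value for i in order]),
            amplitude_errors=np.array([_se(f"amp_{i + 1}") for i in order]),
            background={key: float(pars[key].value) for key in
                        ("b0", "b1", "bg_amp", "bg_center", "bg_width")},
            chi2=float(best.chisqr), n_points=len(self.scan),
            n_params=int(best.nvarys),
            converged=bool(best.success) and not singular, scan=self.scan,
            message="singular covariance" if singular else "")
        return result


def fit_constant_e_scan(scan: Scan, n_peaks: int,
                        bg_center: float = 2.5) -> ConstantEFitResult:
    """Fit a constant-energy q-scan with ``n_peaks`` phonon peaks."""
    return ConstantESpectrum(scan).fit(n_peaks, bg_center=bg_center)


# ---------------------------------------------------------------------------
# F-test model selection
# ---------------------------------------------------------------------------

def f_chi(chi2_m: float, chi2_m4: float, n_points: int, m: int) -> float:
    """Nested-model F statistic for four added parameters.

    (χ²(m) − χ²(m+4)) / (χ²(m+4) / (N − m − 1)), with ``m`` the simpler
    model's free-parameter count.
    """
    if chi2_m4 < 0 or chi2_m < chi2_m4:
        raise ValueError("need chi2_m >= chi2_m4 >= 0 (nested models)")
    if n_points <= m + 5:
        raise ValueError("too few points for the added parameters")
    if chi2_m4 == 0:
        raise ZeroDivisionError("richer model has zero chi2; F undefined")
    return (chi2_m - chi2_m4) / (chi2_m4 / (n_points - m - 1))


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-tail critical value of the F distribution."""
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.isf(alpha, df1, df2))


def critical_value_for_increment(n_points: int, m_simpler: int, alpha: float,
                                 df_policy="standard") -> float:
    """Critical F value for adding one phonon (four parameters).

    The F_χ statistic is the χ² drop divided by the richer model's reduced
    χ² — it is *not* divided by the number of added parameters. The
    conventional additional-term F-test therefore compares F_χ/df1 against
    the F(df1, df2) quantile; equivalently, the critical value on the
    F_χ scale is df1 times the quantile, which is what this returns.

    ``df_policy`` is 'standard' (df1 = 4 added parameters, df2 = N − m − 5,
    the richer model's residual dof), 'paper' (df1 = 1, df2 = N − m − 1,
    matching the printed statistic's denominator), or an explicit
    (df1, df2) pair.
    """
    if df_policy == "standard":
        df1, df2 = 4, n_points - m_simpler - 5
    elif df_policy == "paper":
        df1, df2 = 1, n_points - m_simpler - 1
    else:
        df1, df2 = df_policy
    return df1 * f_critical(alpha, df1, df2)


def accept_increments(f_values, critical_values) -> int:
    """Phonon count chosen by sequential acceptance.

    ``f_values[i]`` tests phonon i+2 against i+1; acceptance stops at the
    first increment whose F does not exceed its critical value.
    """
    k = 1
    for f_val, crit in zip(f_values, critical_values):
        if f_val > crit:
            k += 1
        else:
            break
    return k


@dataclass
class ModelSelection:
    """Sequential F-test over 1..k_max phonons for one scan."""

    fits: list[SpectralFitResult]
    f_chi_values: list[float]
    f_critical_values: list[float]
    chosen_k: int
    alpha: float
    df_policy: object = "standard"
    complete: bool = True
    message: str = ""

    @property
    def chosen_fit(self) -> SpectralFitResult:
        return self.fits[self.chosen_k - 1]

    def summary(self) -> str:
        lines = [f"Sequential F-test (alpha = {self.alpha}, "
                 f"df policy = {self.df_policy})"]
        for i, (f_val, crit) in enumerate(zip(self.f_chi_values,
                                              self.f_critical_values)):
            verdict = "accept" if f_val > crit else "reject"
            lines.append(f"  adding phonon {i + 2}: F_chi = {f_val:.2f}  "
                         f"critical = {crit:.2f}  -> {verdict}")
        lines.append(f"  chosen phonon count: {self.chosen_k}")
        return "\n".join(lines)


def sequential_f_test(scan: Scan, k_max: int = 3, alpha: float = 0.025,
                      df_policy="standard",
                      n_restarts: int = 5) -> ModelSelection:
    """Fit 1..k_max phonons successively and select the count by F-test.

    Each richer fit is warm-started from the simpler optimum (guaranteeing
    the nested-model χ² decrease) in addition to the usual multi-start.
    """
    model = ConstantQSpectrum(scan)
    fits: list[SpectralFitResult] = []
    f_values: list[float] = []
    criticals: list[float] = []
    complete = True
    message = ""
    for k in range(1, k_max + 1):
        init = None
        if fits and fits[-1].converged:
            prev = fits[-1].params
            extra = PhononMode(
                mu=min(max(prev.modes[-1].mu * 1.5, 0.3),
                       0.9 * float(scan.axis[-1])),
                sigma=0.2, amp_plus=1e-3)
            init = replace(prev, modes=prev.modes + (extra,))
        fit = model.fit(k, init=init, n_restarts=n_restarts)
        if not fit.converged and not np.isfinite(fit.chi2):
            complete = False
            message = f"fit with {k} phonons failed; selection stopped"
            break
        fits.append(fit)
        if k > 1:
            if fits[-1].chi2 > fits[-2].chi2 + 1e-9 * max(fits[-2].chi2, 1.0):
                # nested models must not increase chi2; fall back to the
                # warm start which reproduces the simpler model exactly
                warnings.warn("richer model increased chi2; keeping simpler "
                              "optimum for the increment", stacklevel=2)
                fits[-1] = replace(fits[-1], chi2=fits[-2].chi2)
            m_simpler = N_BACKGROUND_PARAMS + N_PARAMS_PER_PHONON * (k - 1)
            f_values.append(f_chi(fits[-2].chi2, fits[-1].chi2, len(scan),
                                  m_simpler))
            criticals.append(critical_value_for_increment(
                len(scan), m_simpler, alpha, df_policy))
    chosen = accept_increments(f_values, criticals) if fits else 0
    chosen = min(chosen, len(fits))
    return ModelSelection(fits=fits, f_chi_values=f_values,
                          f_critical_values=criticals, chosen_k=chosen,
                          alpha=alpha, df_policy=df_policy,
                          complete=complete, message=message)
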