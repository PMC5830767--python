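"""Spectral model, constant-q/constant-E fitting, and F-test logic."""

import numpy as np
import pytest

import membranekit as mk
from membranekit.constants import thermal_energy
from membranekit.spectral import (PhononMode, SpectralParams,
                                  accept_increments,
                                  critical_value_for_increment,
                                  detailed_balance_ratio, evaluate_spectrum,
                                  f_chi, f_critical)
from membranekit.synthetic import DispersionSpec, simulate_constant_q_scan


def _params(modes=(), a_el=0.0, a_inc=0.0, sigma_inc=0.5, slope=0.0,
            intercept=0.0, temperature=303.15, sigma_el=0.3):
    return SpectralParams(a_el=a_el, a_inc=a_inc, sigma_inc=sigma_inc,
                          slope=slope, intercept=intercept,
                          modes=tuple(modes), temperature=temperature,
                          sigma_el=sigma_el)


class TestDetailedBalance:
    @pytest.mark.parametrize("mu, temp, expected", [
        (0.0, 303.15, 1.0),
        (1.5, 303.15, 0.94420),
        (thermal_energy(303.15), 303.15, np.exp(-1.0)),
    ])
    def test_ratio_values(self, mu, temp, expected):
        assert detailed_balance_ratio(mu, temp) == pytest.approx(
            expected, abs=1e-5)

    def test_integrated_doublet_ratio(self):
        # zero backgrounds, single mode: the integrated anti-Stokes/Stokes
        # peak ratio equals the Boltzmann factor to quadrature accuracy
        mode = PhononMode(mu=1.5, sigma=0.2, amp_plus=100.0)
        temp = 303.15
        w = np.linspace(-60.0, 60.0, 600001)
        stokes = np.trapezoid(
            mode.amp_plus / (1 + ((w - mode.mu) / mode.sigma) ** 2), w)
        anti = np.trapezoid(
            mode.amp_minus(temp)
            / (1 + ((w + mode.mu) / mode.sigma) ** 2), w)
        assert anti / stokes == pytest.approx(
            detailed_balance_ratio(1.5, temp), rel=1e-6)


class TestEvaluateSpectrum:
    def test_closed_form_at_zero(self):
        p = _params(a_el=50.0, a_inc=30.0, intercept=7.0)
        assert evaluate_spectrum(p, 0.0)[()] == pytest.approx(87.0)

    def test_infinite_temperature_symmetry(self):
        mode = PhononMode(mu=1.5, sigma=0.2, amp_plus=100.0)
        p = _params([mode], temperature=1e12)
        vals = evaluate_spectrum(p, np.array([-1.5, 1.5]))
        assert abs(vals[0] - vals[1]) < 1e-6

    def test_stokes_anti_stokes_ratio_with_cross_tail(self):
        # hand-summed two-Lorentzian oracle at ±μ including each peak's
        # tail at the opposite position
        mu, sigma, amp, temp = 1.5, 0.2, 100.0, 303.15
        ratio = np.exp(-mu / thermal_energy(temp))
        tail = 1.0 / (1.0 + (2 * mu / sigma) ** 2)
        expected_minus = amp * ratio + amp * tail
        expected_plus = amp + amp * ratio * tail
        p = _params([PhononMode(mu=mu, sigma=sigma, amp_plus=amp)],
                    temperature=temp)
        vals = evaluate_spectrum(p, np.array([-mu, mu]))
        assert vals[0] == pytest.approx(expected_minus, rel=1e-12)
        assert vals[1] == pytest.approx(expected_plus, rel=1e-12)
        assert vals[0] / vals[1] == pytest.approx(0.9442, abs=2e-3)

    def test_modes_sorted_by_position(self):
        p = _params([PhononMode(2.0, 0.2, 10.0), PhononMode(0.5, 0.2, 10.0)])
        assert [m.mu for m in p.modes] == [0.5, 2.0]


class TestConstantQFit:
    def test_noiseless_fixed_point(self):
        truth = _params([PhononMode(1.5, 0.2, 100.0)], a_el=500.0,
                        a_inc=50.0, sigma_inc=0.4, slope=1.0, intercept=20.0)
        w = np.linspace(-2.0, 4.0, 120)
        scan = mk.Scan(kind="constant_q", fixed_value=1.4, axis=w,
                       counts=evaluate_spectrum(truth, w),
                       errors=np.ones_like(w), sigma_el=0.3)
        res = mk.fit_constant_q_scan(scan, 1, init=truth, n_restarts=1)
        assert res.chi2 < 1e-6
        mode = res.params.modes[0]
        assert mode.mu == pytest.approx(1.5, rel=1e-6)
        assert mode.sigma == pytest.approx(0.2, rel=1e-6)
        assert mode.amp_plus == pytest.approx(100.0, rel=1e-6)

    def test_three_mode_recovery_within_3se(self, three_mode_scan):
        truth = three_mode_scan.meta["truth"]
        res = mk.fit_constant_q_scan(three_mode_scan, 3)
        assert res.converged
        for i, tm in enumerate(truth.modes):
            se = res.mode_stderr(i, "mu")
            assert abs(res.params.modes[i].mu - tm.mu) <= 3 * se

    def test_fit_idempotence(self, three_mode_scan):
        first = mk.fit_constant_q_scan(three_mode_scan, 2)
        again = mk.fit_constant_q_scan(three_mode_scan, 2,
                                       init=first.params, n_restarts=1)
        assert again.chi2 <= first.chi2 * (1 + 1e-8) + 1e-8

    def test_zero_amplitude_phonons_flagged_not_detected(self):
        spec = DispersionSpec(branches={
            name: type(b)(alpha=b.alpha, q0=b.q0, omega0=b.omega0,
                          width=b.width, amplitude=0.0)
            for name, b in DispersionSpec.well_separated().branches.items()})
        scan = simulate_constant_q_scan(spec, seed=3)
        res = mk.fit_constant_q_scan(scan, 3)
        assert len(res.detected_modes()) == 0


class TestConstantEFit:
    def test_two_peak_recovery(self):
        spec = DispersionSpec(branches={
            "fluid": mk.BranchSpec(alpha=14.9, q0=1.4, omega0=1.1,
                                   width=0.25, amplitude=250.0)})
        scan = mk.simulate_constant_e_scan(spec, energy=1.435, seed=6)
        roots = sorted(r["q"] for r in scan.meta["truth"]["roots"])
        assert roots == pytest.approx([1.25, 1.55], abs=2e-3)
        res = mk.fit_constant_e_scan(scan, 2)
        assert res.converged
        for center, err, root in zip(res.centers, res.center_errors, roots):
            assert abs(center - root) <= 3 * max(err, 1e-3)

    def test_pure_background_null(self):
        spec = DispersionSpec(branches={
            "lo": mk.BranchSpec(alpha=4.8, q0=1.4, omega0=0.6,
                                width=0.15, amplitude=0.0)})
        scan = mk.simulate_constant_e_scan(spec, energy=2.5, seed=7)
        assert scan.meta["no_crossing"]
        res = mk.fit_constant_e_scan(scan, 1)
        amp, err = res.amplitudes[0], res.amplitude_errors[0]
        assert (not res.converged) or not np.isfinite(err) \
            or amp <= 2.0 * err

    def test_displaced_background_lorentzian_recovered(self):
        spec = DispersionSpec(branches={
            "fluid": mk.BranchSpec(alpha=14.9, q0=1.4, omega0=1.1,
                                   width=0.25, amplitude=250.0)})
        scan = mk.simulate_constant_e_scan(
            spec, energy=1.435, seed=8,
            backgrounds={"bg_center": 2.2, "bg_amp": 120.0})
        res = mk.fit_constant_e_scan(scan, 2)
        assert res.converged
        assert res.background["bg_center"] == pytest.approx(2.2, abs=0.15)


class TestFStatistic:
    def test_hand_arithmetic(self):
        assert f_chi(500.0, 200.0, 108, 6) == pytest.approx(151.5)

    def test_no_improvement_gives_zero(self):
        assert f_chi(200.0, 200.0, 108, 6) == 0.0

    def test_scale_invariance(self):
        a = f_chi(500.0, 200.0, 108, 6)
        b = f_chi(1000.0, 400.0, 108, 6)
        assert a == pytest.approx(b)

    def test_error_rescaling_invariance_through_fits(self, three_mode_scan):
        # multiplying all errors by a common factor scales both chi2
        # identically, leaving F_chi unchanged
        res1 = mk.fit_constant_q_scan(three_mode_scan, 1)
        res2 = mk.fit_constant_q_scan(three_mode_scan, 2)
        f_a = f_chi(res1.chi2, res2.chi2, res1.n_points, 6)
        f_b = f_chi(res1.chi2 / 4.0, res2.chi2 / 4.0, res1.n_points, 6)
        assert f_a == pytest.approx(f_b)

    def test_zero_chi2_division_flagged(self):
        with pytest.raises(ZeroDivisionError):
            f_chi(10.0, 0.0, 108, 6)

    @pytest.mark.parametrize("alpha, df1, df2, expected, tol", [
        (0.025, 4, 93, 2.93, 0.02),
        (0.025, 1, 13, 6.41, 0.02),
        (0.025, 1, 10**7, 5.02, 0.01),
    ])
    def test_f_critical_quantiles(self, alpha, df1, df2, expected, tol):
        assert f_critical(alpha, df1, df2) == pytest.approx(expected,
                                                            abs=tol)


class TestModelSelection:
    def test_printed_decision_pairs(self):
        # decision logic on the published statistic/critical pairs:
        # both increments accepted -> three phonons
        assert accept_increments([94.25, 17.94], [6.41, 6.04]) == 3
        assert accept_increments([94.25, 5.0], [6.41, 6.04]) == 2
        assert accept_increments([5.0, 17.94], [6.41, 6.04]) == 1

    def test_critical_scale_matches_statistic(self):
        # the published statistic is df1 times the conventional F ratio
        crit = critical_value_for_increment(108, 6, 0.025, "standard")
        assert crit == pytest.approx(4 * f_critical(0.025, 4, 97), rel=1e-9)

    def test_sequential_selection_on_three_modes(self, three_mode_scan):
        sel = mk.sequential_f_test(three_mode_scan)
        assert sel.chosen_k == 3
        chi2 = [f.chi2 for f in sel.fits]
        assert chi2 == sorted(chi2, reverse=True)   # nested monotonicity
        assert len(sel.f_chi_values) == len(sel.fits) - 1

    def test_width_settings_distinguished(self):
        # l_o damping 0.14 vs 0.31 meV: pooled fitted-width CIs disjoint
        import dataclasses
        means = {}
        for width in (0.14, 0.31):
            b = dict(DispersionSpec.well_separated().branches)
            b["lo"] = dataclasses.replace(b["lo"], width=width)
            vals = []
            for seed in range(6):
                scan = simulate_constant_q_scan(
                    DispersionSpec(branches=b), q=1.37, sigma_el=0.2,
                    seed=200 + seed)
                res = mk.fit_constant_q_scan(scan, 3)
                vals.append(res.params.modes[0].sigma)
            vals = np.asarray(vals)
            means[width] = (vals.mean(),
                            vals.std(ddof=1) / np.sqrt(len(vals)))
        lo_hi = means[0.14][0] + 2 * means[0.14][1]
        hi_lo = means[0.31][0] - 2 * means[0.31][1]
        assert lo_hi < hi_lo
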