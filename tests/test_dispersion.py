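"""Dispersion assembly, branch assignment, quadratic fits, comparisons."""

import numpy as np
import pytest

import membranekit as mk
from membranekit.dispersion import (DEFAULT_ANCHORS, DispersionPoint,
                                    assign_branches, collect_points,
                                    compare_branch_parameters,
                                    fit_branch_minimum, width_at_minimum)
from membranekit.synthetic import DispersionSpec

#: Published quadratic-fit parameters (value, stderr) for the cholesterol
#: and aspirin samples: alpha in meV·Å², omega0 in meV, per branch.
TABLE_CHOL = {
    "gel": {"alpha": (41.0, 95.0), "omega0": (0.72, 0.70)},
    "fluid": {"alpha": (14.9, 3.0), "omega0": (1.09, 0.28)},
    "lo": {"alpha": (4.8, 0.3), "omega0": (0.51, 0.02)},
}
TABLE_ASA = {
    "gel": {"alpha": (1.5, 28.0), "omega0": (0.65, 1.49)},
    "fluid": {"alpha": (11.0, 4.0), "omega0": (1.12, 0.51)},
    "lo": {"alpha": (3.7, 0.9), "omega0": (0.66, 0.07)},
}


def _quad_points(alpha, q0, omega0, qs, err=0.05, rng=None, branch="lo"):
    pts = []
    for q in qs:
        energy = alpha * (q - q0) ** 2 + omega0
        if rng is not None:
            energy = energy + rng.normal(0.0, err)
        pts.append(DispersionPoint(q_par=float(q), energy=float(energy),
                                   energy_err=err, branch=branch))
    return pts


class TestCollectPoints:
    def test_constant_q_contributes_detected_modes(self, three_mode_scan):
        res = mk.fit_constant_q_scan(three_mode_scan, 3)
        pts = collect_points([res])
        assert len(pts) == len(res.detected_modes())
        assert all(p.q_par == three_mode_scan.fixed_value for p in pts)
        assert all(p.source == "constant_q" for p in pts)

    def test_constant_e_contributes_fixed_energy(self):
        spec = DispersionSpec(branches={
            "fluid": mk.BranchSpec(alpha=14.9, q0=1.4, omega0=1.1,
                                   width=0.25, amplitude=250.0)})
        scan = mk.simulate_constant_e_scan(spec, energy=1.435, seed=6)
        res = mk.fit_constant_e_scan(scan, 2)
        pts = collect_points([res])
        assert len(pts) == len(res.detected_peaks())
        assert all(p.energy == 1.435 for p in pts)

    def test_non_converged_fits_skipped(self, three_mode_scan):
        res = mk.fit_constant_q_scan(three_mode_scan, 2)
        import dataclasses
        broken = dataclasses.replace(res, converged=False)
        assert collect_points([broken]) == []

    def test_mixed_set_point_count(self, three_mode_scan):
        res = mk.fit_constant_q_scan(three_mode_scan, 3)
        pts = collect_points([res, res])
        assert len(pts) == 2 * len(res.detected_modes())


class TestAssignBranches:
    def test_nearest_anchor(self):
        anchors = {"lo": [(1.4, 0.6)], "fluid": [(1.4, 1.1)]}
        (pt,) = assign_branches(
            [DispersionPoint(1.4, 0.55, 0.05)], anchors)
        assert pt.branch == "lo"

    def test_tie_goes_to_lower_energy_branch(self):
        anchors = {"gel": [(1.4, 0.5)], "fluid": [(1.4, 1.5)]}
        (pt,) = assign_branches([DispersionPoint(1.4, 1.0, 0.05)], anchors)
        assert pt.branch == "gel"

    def test_cutoff_leaves_unassigned(self):
        (pt,) = assign_branches([DispersionPoint(3.0, 5.0, 0.1)],
                                DEFAULT_ANCHORS, cutoff=0.5)
        assert pt.branch == "unassigned"

    def test_deterministic(self):
        pts1 = [DispersionPoint(1.2, 0.8, 0.05)]
        pts2 = [DispersionPoint(1.2, 0.8, 0.05)]
        assign_branches(pts1)
        assign_branches(pts2)
        assert pts1[0].branch == pts2[0].branch

    def test_synthetic_cloud_labels_match_truth(self):
        rng = np.random.default_rng(11)
        spec = DispersionSpec.chol()
        pts, truth = [], []
        for name, branch in spec.branches.items():
            for q in np.linspace(1.05, 1.95, 10):
                e = branch.energy_at(q) + rng.normal(0, 0.05)
                if e <= 0 or e > 6:
                    continue
                pts.append(DispersionPoint(q, e, 0.05))
                truth.append(name)
        anchors = {name: [(q, b.energy_at(q))
                          for q in np.linspace(1.0, 2.0, 9)]
                   for name, b in spec.branches.items()}
        assign_branches(pts, anchors)
        agree = np.mean([p.branch == t for p, t in zip(pts, truth)])
        assert agree >= 0.95


class TestBranchFit:
    @pytest.mark.parametrize("alpha, omega0", [(4.8, 0.51), (3.7, 0.66)])
    def test_noiseless_exact_recovery(self, alpha, omega0):
        pts = _quad_points(alpha, 1.4, omega0, np.linspace(1.0, 2.0, 12))
        fit = fit_branch_minimum(pts)
        assert fit.alpha == pytest.approx(alpha, abs=1e-9)
        assert fit.q0 == pytest.approx(1.4, abs=1e-9)
        assert fit.omega0 == pytest.approx(omega0, abs=1e-9)

    def test_too_few_points_rejected(self):
        pts = _quad_points(4.8, 1.4, 0.51, [1.1, 1.4, 1.7])
        with pytest.raises(ValueError, match="4 points"):
            fit_branch_minimum(pts)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(3)
        pts = _quad_points(4.8, 1.4, 0.51, np.linspace(1.0, 2.0, 12),
                           rng=rng)
        fit = fit_branch_minimum(pts)
        delta = 0.15
        shifted = [DispersionPoint(p.q_par + delta, p.energy, p.energy_err,
                                   branch=p.branch) for p in pts]
        fit2 = fit_branch_minimum(shifted,
                                  fit_range=(1.0 + delta, 2.0 + delta))
        assert fit2.q0 == pytest.approx(fit.q0 + delta, abs=1e-8)
        assert fit2.alpha == pytest.approx(fit.alpha, rel=1e-8)
        assert fit2.omega0 == pytest.approx(fit.omega0, rel=1e-8)

    def test_noisy_recovery_within_2se(self):
        hits = 0
        n = 40
        for seed in range(n):
            rng = np.random.default_rng(1000 + seed)
            pts = _quad_points(4.8, 1.4, 0.51, np.linspace(1.0, 2.0, 12),
                               err=0.05, rng=rng)
            fit = fit_branch_minimum(pts)
            ok = (abs(fit.alpha - 4.8) <= 2 * fit.bse["alpha"]
                  and abs(fit.omega0 - 0.51) <= 2 * fit.bse["omega0"])
            hits += ok
        assert hits / n >= 0.80


class TestComparison:
    def test_lo_omega0_significant(self):
        rep = compare_branch_parameters(TABLE_CHOL["lo"], TABLE_ASA["lo"])
        z = {c.name: c.z for c in rep.comparisons}
        assert z["omega0"] == pytest.approx(2.06, abs=0.01)
        assert z["alpha"] == pytest.approx(1.16, abs=0.01)
        assert rep.significant_parameters() == ["omega0"]

    def test_identical_fits_not_significant(self):
        rep = compare_branch_parameters(TABLE_CHOL["lo"], TABLE_CHOL["lo"])
        assert all(c.z == 0 for c in rep.comparisons)
        assert rep.significant_parameters() == []

    def test_large_gel_uncertainties_carried_through(self):
        rep = compare_branch_parameters(TABLE_CHOL["gel"], TABLE_ASA["gel"])
        z = {c.name: c.z for c in rep.comparisons}
        assert z["alpha"] < 1.96 and z["omega0"] < 1.96

    def test_missing_stderr_skipped(self):
        rep = compare_branch_parameters(
            {"alpha": (4.8, np.nan), "omega0": (0.51, 0.02)},
            {"alpha": (3.7, 0.9), "omega0": (0.66, 0.07)})
        assert [c.name for c in rep.comparisons] == ["omega0"]


class TestWidthAtMinimum:
    def test_picks_point_nearest_q0(self):
        pts = [DispersionPoint(1.2, 0.8, 0.05, width=0.3, width_err=0.05,
                               branch="lo"),
               DispersionPoint(1.42, 0.52, 0.05, width=0.14, width_err=0.03,
                               branch="lo")]
        fit = fit_branch_minimum(
            _quad_points(4.8, 1.4, 0.51, np.linspace(1.0, 2.0, 8)))
        fit.branch = "lo"
        width, err = width_at_minimum(pts, fit)
        assert width == 0.14
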