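"""Lateral RDFs, grid area maps, gauche statistics, densities, contacts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import membranekit as mk
from membranekit.constants import COHERENT_SCATTERING_LENGTH_FM
from membranekit.lateral import (chain_dihedrals, contact_fraction,
                                 density_profile, distance_resolved_area,
                                 gauche_fraction, grid_area_map, lateral_rdf)
from membranekit.scans import MembraneFrame


def _frame(positions, names, resnames, resids, box, elements=None):
    positions = np.asarray(positions, dtype=float)
    return MembraneFrame(
        positions=positions,
        elements=(elements if elements is not None
                  else [n[0] for n in names]),
        names=names, resnames=resnames, resids=resids,
        box=np.asarray(box, dtype=float))


def _square_lattice_frame(n_side=10, spacing=7.0, z=(15.0, -15.0)):
    """n_side² lipids per leaflet on a square lattice: P atom only."""
    pos, names, resnames, resids = [], [], [], []
    rid = 0
    for zval in z:
        for i in range(n_side):
            for j in range(n_side):
                rid += 1
                pos.append([(i + 0.5) * spacing, (j + 0.5) * spacing, zval])
                names.append("P")
                resnames.append("DMPC")
                resids.append(rid)
    box = [n_side * spacing, n_side * spacing, 60.0]
    return _frame(pos, names, resnames, resids, box, elements=["P"] * rid)


class TestGaucheFraction:
    def test_all_trans_is_zero(self):
        assert gauche_fraction([180.0, 180.0, -180.0 + 1e-9]) == 0.0

    def test_mixed_counting(self):
        assert gauche_fraction([60.0, -60.0, 180.0, 180.0]) == 0.5

    def test_bernoulli_sampling(self):
        rng = np.random.default_rng(12)
        n = 10**4
        gauche = rng.random(n) < 0.3
        angles = np.where(gauche, rng.choice([-60.0, 60.0], n), 180.0)
        assert gauche_fraction(angles) == pytest.approx(0.30, abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gauche_fraction([])

    def test_rb_convention_shift(self):
        # Ryckaert-Bellemans trans is 0 deg
        assert gauche_fraction([0.0, 0.0, 120.1], convention="rb") == \
            pytest.approx(1 / 3)

    @given(st.lists(st.floats(min_value=-179.9, max_value=180.0),
                    min_size=1, max_size=50))
    @settings(max_examples=30, deadline=None)
    def test_sign_flip_invariance(self, angles):
        arr = np.asarray(angles)
        flipped = np.where(arr == 180.0, arr, -arr)
        assert gauche_fraction(arr) == gauche_fraction(flipped)


class TestChainDihedrals:
    def test_constructed_butane_geometry(self):
        # four points with a known 60-degree torsion
        from membranekit.synthetic import _place_atom
        a = np.array([0.0, 0.0, 0.0])
        b = np.array([1.54, 0.0, 0.0])
        c = b + np.array([0.5, 1.45, 0.0])
        for phi in (180.0, 60.0, -60.0):
            d = _place_atom(a, b, c, 1.54, 111.0, phi)
            (angle,) = chain_dihedrals(np.array([a, b, c, d]))
            assert abs(abs(angle) - abs(phi)) < 1e-6

    def test_periodic_unwrap(self):
        # chain crossing the x boundary still yields a trans dihedral
        box = np.array([20.0, 20.0, 20.0])
        chain = np.array([[19.0, 0.0, 0.0], [0.5, 1.0, 0.0],
                          [2.0, 0.0, 0.0], [3.5, 1.0, 0.0]])
        (angle,) = chain_dihedrals(chain, box=box)
        assert abs(angle) == pytest.approx(180.0, abs=1e-6)


class TestLateralRDF:
    def test_uniform_points_normalise_to_one(self):
        rng = np.random.default_rng(8)
        n = 4000
        box = [100.0, 100.0, 40.0]
        pos = np.column_stack([rng.uniform(0, 100, n),
                               rng.uniform(0, 100, n),
                               np.full(n, 10.0)])
        frame = _frame(pos, ["C1"] * n, ["DMPC"] * n, np.arange(1, n + 1),
                       box, elements=["C"] * n)
        sel = {"resname": "DMPC"}
        rdf = lateral_rdf(frame, sel, sel, r_max=30.0, bin_width=0.5)
        window = (rdf.r >= 10) & (rdf.r <= 25)
        assert np.mean(np.abs(rdf.g[window] - 1.0)) < 0.05

    def test_r_max_guard(self, plain_membrane_frame):
        sel = {"resname": "DMPC"}
        with pytest.raises(ValueError, match="half the smallest"):
            lateral_rdf(plain_membrane_frame, sel, sel, r_max=1000.0)

    def test_hexagonal_tail_lattice_peak(self):
        from membranekit.synthetic import MembraneSpec, build_membrane_frames
        spec = MembraneSpec(tail_spacing=4.8, gauche_near=0.0,
                            gauche_far=0.0, jitter=0.1)
        frame = build_membrane_frames(spec, 1, seed=3)[0]
        sel = {"resname": "DMPC", "names": ("C15", "C25")}
        rdf = lateral_rdf(frame, sel, sel, r_max=18.0, bin_width=0.25)
        assert abs(rdf.first_peak(r_min=2.0) - 4.8) <= 0.125


class TestGridAreaMap:
    def test_square_lattice_uniform_areas(self):
        frame = _square_lattice_frame()
        maps = grid_area_map(frame, cell_size=0.5)
        for amap in maps.values():
            areas = np.array(list(amap.areas.values()))
            assert np.allclose(areas, 49.0)

    def test_displacement_conserves_and_shifts_area(self):
        frame = _square_lattice_frame()
        # move one upper-leaflet lipid towards its +x neighbour
        idx = 5
        frame.positions[idx, 0] += 2.0
        maps = grid_area_map(frame, cell_size=0.5)
        amap = maps["upper"]
        areas = amap.areas
        moved = idx + 1                         # resids start at 1
        assert areas[moved] < 49.0
        assert sum(areas.values()) == pytest.approx(amap.box_area)

    def test_conservation_on_generated_frames(self, asa_membrane_frames):
        maps = grid_area_map(asa_membrane_frames[0])
        for amap in maps.values():
            assert sum(amap.areas.values()) == pytest.approx(
                amap.box_area, rel=1e-9)

    def test_target_area_recovered(self, plain_membrane_frame):
        maps = grid_area_map(plain_membrane_frame)
        areas = [a for m in maps.values()
                 for a in m.areas_for("DMPC").values()]
        assert np.mean(areas) == pytest.approx(48.6, abs=1.0)


class TestDistanceResolvedArea:
    def test_half_open_bin_edges(self):
        # one DMPC at exactly 5.0 Å from the aspirin centre with edges
        # [0, 5, 10) must land in the second bin
        pos = [[30.0, 30.0, 15.0],
               [35.0, 30.0, 15.0], [36.3, 30.0, 15.0], [33.7, 30.0, 15.0],
               [35.0, 31.3, 15.0], [35.0, 28.7, 15.0],
               [30.0, 30.0, -15.0]]
        names = ["P", "C1", "C2", "C3", "O1", "O2", "P"]
        resnames = ["DMPC", "ASA", "ASA", "ASA", "ASA", "ASA", "DMPC"]
        resids = [1, 2, 2, 2, 2, 2, 3]
        elements = ["P", "C", "C", "C", "O", "O", "P"]
        frame = _frame(pos, names, resnames, resids, [60.0, 60.0, 60.0],
                       elements=elements)
        prof = distance_resolved_area(frame, bin_edges=[0.0, 5.0, 10.0])
        assert prof.counts[0] == 0
        assert prof.counts[1] == 1

    def test_dilated_frames_recover_five_percent(self):
        from membranekit.synthetic import MembraneSpec, build_membrane_frames
        base = dict(n_lipids=512, asa_fraction=0.03)
        frames = build_membrane_frames(MembraneSpec(**base, dilation=0.05),
                                       2, seed=5)
        prof = distance_resolved_area(frames)
        near = np.nansum(prof.values[:3] * prof.counts[:3]) \
            / prof.counts[:3].sum()
        far = np.nansum(prof.values[6:] * prof.counts[6:]) \
            / prof.counts[6:].sum()
        assert near / far == pytest.approx(1.05, abs=0.02)
        assert near > 50.0                      # absolute level, Å²
        null = distance_resolved_area(build_membrane_frames(
            MembraneSpec(**base, dilation=0.0), 2, seed=5))
        null_near = np.nansum(null.values[:3] * null.counts[:3]) \
            / null.counts[:3].sum()
        null_far = np.nansum(null.values[6:] * null.counts[6:]) \
            / null.counts[6:].sum()
        assert null_near / null_far == pytest.approx(1.0, abs=0.01)

    def test_no_asa_rejected(self, plain_membrane_frame):
        with pytest.raises(ValueError, match="ASA"):
            distance_resolved_area(plain_membrane_frame)


class TestDistanceResolvedGauche:
    def test_two_plateau_recovery_and_null(self):
        from membranekit.synthetic import MembraneSpec, build_membrane_frames
        spec = MembraneSpec(n_lipids=512, asa_fraction=0.05,
                            gauche_near=0.35, gauche_far=0.25)
        frames = build_membrane_frames(spec, 3, seed=9)
        prof = mk.distance_resolved_gauche(frames, stride=50)
        near = np.nansum(prof.values[:3] * prof.counts[:3]) \
            / prof.counts[:3].sum()
        far = np.nansum(prof.values[5:] * prof.counts[5:]) \
            / prof.counts[5:].sum()
        assert near == pytest.approx(0.35, abs=0.02)
        assert far == pytest.approx(0.25, abs=0.02)
        flat = MembraneSpec(n_lipids=512, asa_fraction=0.05,
                            gauche_near=0.25, gauche_far=0.25)
        prof0 = mk.distance_resolved_gauche(
            build_membrane_frames(flat, 3, seed=9), stride=50)
        # flat within sampling noise: each lipid contributes the mean of
        # 14 Bernoulli(0.25) dihedrals, so a bin of n lipids has standard
        # error sqrt(p(1-p)/14/n)
        for value, count in zip(prof0.values, prof0.counts):
            if count < 10:
                continue
            se = np.sqrt(0.25 * 0.75 / 14.0 / count)
            assert abs(value - 0.25) < 4.0 * se

    def test_membership_matches_generator_truth(self, asa_membrane_frames):
        frame = asa_membrane_frames[0]
        truth = frame.meta["truth"]["gauche"]
        from membranekit.lateral import _dmpc_gauche
        for resid, entry in list(truth.items())[:10]:
            assert _dmpc_gauche(frame, resid) == pytest.approx(
                entry["fraction"], abs=1e-9)


class TestDensityProfile:
    def test_water_electron_conservation(self, asa_membrane_frames):
        prof = density_profile(asa_membrane_frames,
                               {"SOL": {"resname": "SOL"}})
        n_sol = asa_membrane_frames[0].residue_census()["SOL"]
        assert prof.integral("SOL") == pytest.approx(10.0 * n_sol,
                                                     rel=1e-3)

    def test_asa_peaks_in_headgroup_region(self, asa_membrane_frames):
        prof = density_profile(asa_membrane_frames,
                               {"ASA": {"resname": "ASA"}})
        dens = prof.densities["ASA"]
        top = prof.z[np.argsort(dens)[::-1][:2]]
        d_hh = asa_membrane_frames[0].meta["truth"]["spec"].d_hh
        assert sorted(np.round(np.abs(top), 0)) == pytest.approx(
            [d_hh / 2, d_hh / 2], abs=1.5)

    def test_deuteration_flips_contrast_sign(self):
        n = 50
        pos = np.column_stack([np.linspace(1, 39, n), np.full(n, 20.0),
                               np.linspace(-5, 5, n)])
        frame = _frame(pos, ["H1"] * n, ["SOL"] * n, np.arange(1, n + 1),
                       [40.0, 40.0, 40.0], elements=["H"] * n)
        sel = {"resname": "SOL"}
        plain = density_profile(frame, {"g": sel}, weighting="neutron_sl")
        deut = density_profile(frame, {"g": sel}, weighting="neutron_sl",
                               deuteration=sel)
        ratio = COHERENT_SCATTERING_LENGTH_FM["D"] \
            / COHERENT_SCATTERING_LENGTH_FM["H"]
        mask = plain.densities["g"] != 0
        assert np.all(plain.densities["g"][mask] < 0)
        assert np.all(deut.densities["g"][mask] > 0)
        assert np.allclose(deut.densities["g"][mask]
                           / plain.densities["g"][mask], ratio)

    def test_unknown_element_rejected(self):
        frame = _frame([[1.0, 1.0, 0.0]], ["Qq"], ["SOL"], [1],
                       [10.0, 10.0, 10.0], elements=["Q"])
        with pytest.raises(ValueError, match="element"):
            density_profile(frame, {"g": {"resname": "SOL"}})


class TestContacts:
    def _pair_frames(self, separations):
        frames = []
        for d in separations:
            pos = [[10.0, 10.0, 10.0], [10.0 + d, 10.0, 10.0]]
            frames.append(_frame(pos, ["O1", "O1"], ["CHOL", "ASA"], [1, 2],
                                 [40.0, 40.0, 40.0], elements=["O", "O"]))
        return frames

    def test_permanent_contact(self):
        stats = contact_fraction(self._pair_frames([3.0] * 5),
                                 {"resname": "CHOL"}, {"resname": "ASA"})
        assert stats.fraction(1, 2) == 1.0

    def test_never_in_contact(self):
        stats = contact_fraction(self._pair_frames([8.0] * 5),
                                 {"resname": "CHOL"}, {"resname": "ASA"})
        assert stats.fraction(1, 2) == 0.0
        assert stats.any_contact_fraction == 0.0

    def test_transient_contact_fraction(self):
        seps = [3.0, 8.0, 8.0, 3.0, 8.0, 8.0, 3.0, 8.0, 8.0, 8.0]
        stats = contact_fraction(self._pair_frames(seps),
                                 {"resname": "CHOL"}, {"resname": "ASA"})
        assert stats.fraction(1, 2) == pytest.approx(0.30)

    def test_hydrogens_excluded(self):
        pos = [[10.0, 10.0, 10.0], [12.0, 10.0, 10.0], [13.0, 10.0, 10.0]]
        frame = _frame(pos, ["O1", "HW1", "O1"], ["CHOL", "ASA", "ASA"],
                       [1, 2, 2], [40.0, 40.0, 40.0],
                       elements=["O", "H", "O"])
        stats = contact_fraction(frame, {"resname": "CHOL"},
                                 {"resname": "ASA"}, cutoff=2.5)
        assert stats.fraction(1, 2) == 0.0      # only H within cutoff
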