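"""Perturbation ensembles, superposition, water matching, filtering, ADPs."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from jointxn.analysis_tools import (PerturbationSpec, adp_histogram,
                                    all_atom_rmsd, chi_angle_deltas,
                                    compare_models, filter_reliable,
                                    match_waters, perturb_model,
                                    real_space_cc, superpose_mainchain)
from jointxn.fixtures import CrystalScenario, make_toy_structure, make_xn_pair
from jointxn.model_core import Atom, Model, UnitCell
from jointxn.scattering import calc_map, calc_structure_factors, unique_reflections
from tests_helpers import (exhaustive_match_count as _exhaustive_match_count,
                           quaternion_grid_rmsd as _quaternion_grid_rmsd,
                           water_model as _water_model)


class TestPerturbation:
    def test_achieved_rmsd_within_band(self, peptide5):
        ens = perturb_model(peptide5, PerturbationSpec(0.5, replicates=5, seed=7))
        for m in ens:
            r = all_atom_rmsd(m, peptide5)
            assert 0.45 <= r <= 0.55

    def test_small_target_limit(self, peptide5):
        ens = perturb_model(peptide5, PerturbationSpec(1e-3, replicates=1, seed=7,
                                                       regularize=False))
        assert all_atom_rmsd(ens[0], peptide5) < 2e-3

    def test_deterministic(self, peptide5):
        a = perturb_model(peptide5, PerturbationSpec(0.4, replicates=2, seed=9))
        b = perturb_model(peptide5, PerturbationSpec(0.4, replicates=2, seed=9))
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.positions(), mb.positions())

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PerturbationSpec(-0.5)


class TestSuperposition:
    def test_self_is_identity(self, peptide5):
        sup = superpose_mainchain(peptide5, peptide5)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3))

    def test_recovers_rigid_motion(self, peptide5):
        moved = peptide5.copy()
        R = Rotation.from_euler("xyz", [25, -40, 110], degrees=True).as_matrix()
        moved.set_positions(peptide5.positions() @ R.T + [3.0, -1.0, 2.0])
        sup = superpose_mainchain(moved, peptide5)
        assert sup.rmsd < 1e-9

    def test_matches_quaternion_grid_oracle(self, rng):
        P = rng.normal(size=(4, 3)) * 3.0
        Q = rng.normal(size=(4, 3)) * 3.0
        cell = UnitCell(20, 20, 20)

        def as_model(X):
            names = ["N", "CA", "C", "O"]
            return Model(atoms=[Atom(i + 1, names[i], names[i][0], False, "A", 1,
                                     "GLY", X[i], 10.0, 1.0) for i in range(4)],
                         cell=cell)

        sup = superpose_mainchain(as_model(P), as_model(Q))
        oracle = _quaternion_grid_rmsd(P, Q)
        assert sup.rmsd == pytest.approx(oracle, abs=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_motion_invariance(self, peptide5, rng):
        other = peptide5.copy()
        other.set_positions(peptide5.positions() + rng.normal(0, 0.3, (len(peptide5), 3)))
        r1 = superpose_mainchain(other, peptide5).rmsd
        R = Rotation.from_euler("zyx", [13, 77, -50], degrees=True).as_matrix()
        moved = other.copy()
        moved.set_positions(other.positions() @ R.T + [5.0, 6.0, 7.0])
        r2 = superpose_mainchain(moved, peptide5).rmsd
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_too_few_atoms(self, peptide5):
        lone = Model(atoms=[a for a in peptide5.atoms if a.name == "CA"][:1],
                     cell=peptide5.cell)
        with pytest.raises(ValueError):
            superpose_mainchain(lone, lone)


class TestWaterMatching:
    def test_identical_models_no_lone(self, peptide5):
        rep = match_waters(peptide5, peptide5)
        assert rep.pct_lone_a == 0.0 and rep.pct_lone_b == 0.0

    def test_cutoff_decides_049_vs_051(self):
        a = _water_model([[10, 10, 10], [10, 10, 11.0]])
        b = _water_model([[10, 10, 10.49]])
        rep = match_waters(a, b, cutoff=0.5)
        assert rep.n_matched == 1
        assert rep.matched[0][0] == 0            # the 0.49 A pair wins
        assert len(rep.lone_a) == 1 and len(rep.lone_b) == 0

    def test_matched_count_equals_exhaustive_assignment(self, rng):
        pa = 15 + rng.normal(0, 1.2, (10, 3))
        pb = 15 + rng.normal(0, 1.2, (12, 3))
        rep = match_waters(_water_model(pa), _water_model(pb), cutoff=0.5)
        assert rep.n_matched == _exhaustive_match_count(pa, pb, 0.5)

    def test_symmetric_in_arguments(self, rng):
        pa = 15 + rng.normal(0, 1.0, (8, 3))
        pb = 15 + rng.normal(0, 1.0, (9, 3))
        ab = match_waters(_water_model(pa), _water_model(pb))
        ba = match_waters(_water_model(pb), _water_model(pa))
        assert ab.n_matched == ba.n_matched
        assert len(ab.lone_a) == len(ba.lone_b)

    def test_periodic_image_matched(self):
        cell = UnitCell(20, 20, 20)
        a = _water_model([[0.1, 10, 10]], cell)
        b = _water_model([[19.9, 10, 10]], cell)
        rep = match_waters(a, b, cutoff=0.5)
        assert rep.n_matched == 1


@pytest.fixture(scope="module")
def maps():
    model = make_toy_structure(3, seed=5, n_waters=2)
    hkl = unique_reflections(model.cell, model.symops, 2.0)
    F = calc_structure_factors(model, hkl, "xray")
    full = calc_map(hkl, F, model.cell)
    null = calc_map(hkl, F - F, model.cell, d_min=2.0)
    return model, hkl, full, null


class TestMapFiltering:
    def test_nothing_excluded_for_self_map(self, maps):
        model, hkl, full, null = maps
        rep = filter_reliable(model, full, null, hkl, "xray")
        assert rep.excluded == []
        assert len(rep.kept) == len(model.residues())

    def test_omitted_residue_excluded_by_cc(self, maps):
        model, hkl, _full, null = maps
        omit = model.copy()
        omit.atoms = [a for a in omit.atoms if not (a.resnum == 2 and not a.is_water)]
        F = calc_structure_factors(omit, hkl, "xray")
        omit_map = calc_map(hkl, F, model.cell)
        rep = filter_reliable(model, omit_map, null, hkl, "xray")
        excluded_keys = {k[1] for k, _why in rep.excluded if k[3] != "HOH"}
        assert 2 in excluded_keys

    def test_altloc_water_excluded(self, maps):
        model, hkl, full, null = maps
        flagged = model.copy()
        flagged.atoms[flagged.waters()[0]].altloc = "A"
        rep = filter_reliable(flagged, full, null, hkl, "xray")
        assert any("alternate" in why for _k, why in rep.excluded)

    def test_cc_self_high_and_control_low(self, maps):
        model, hkl, full, _null = maps
        res = model.residues()
        first = next(iter(res.values()))
        assert real_space_cc(model, first, full, hkl, "xray") > 0.99

    def test_cc_invariant_to_scale_and_offset(self, maps):
        from jointxn.scattering import MapGrid
        model, hkl, full, _null = maps
        res = next(iter(model.residues().values()))
        cc1 = real_space_cc(model, res, full, hkl, "xray")
        scaled = MapGrid(3.0 * full.values + 7.0, model.cell)
        cc2 = real_space_cc(model, res, scaled, hkl, "xray")
        assert cc1 == pytest.approx(cc2, abs=1e-12)


class TestAdpHistogram:
    def test_uniform_b(self, peptide5):
        m = peptide5.copy()
        for a in m.atoms:
            a.b_iso = 20.0
        h = adp_histogram(m, bin_width=5.0)
        assert (h.counts > 0).sum() == 1
        assert h.stats["protein"]["mean"] == 20.0

    def test_counts_conserve_non_h_atoms(self, peptide5):
        h = adp_histogram(peptide5)
        assert h.total == sum(1 for a in peptide5.atoms if not a.is_hydrogen)

    def test_shifted_b_shifts_mode(self, peptide5):
        m = peptide5.copy()
        for a in m.atoms:
            a.b_iso += 20.0
        h0 = adp_histogram(peptide5, bin_width=5.0)
        h1 = adp_histogram(m, bin_width=5.0)
        assert np.argmax(h1.counts) > np.argmax(h0.counts)


class TestComparison:
    def test_pair_report_consistent_with_construction(self):
        sc = CrystalScenario(n_residues=6, n_waters=8,
                             divergent_water_fraction=0.5, adp_offset=4.0, seed=3)
        xm, nm = make_xn_pair(sc)
        rep = compare_models(xm, nm)
        truth = nm.info["water_truth"]
        assert rep.waters.n_matched >= truth["common"]
        assert len(rep.waters.lone_a) <= truth["displaced"] + truth["deleted_from_neutron"]
        mean_diff = rep.adp_a.stats["protein"]["mean"] - rep.adp_b.stats["protein"]["mean"]
        assert mean_diff == pytest.approx(4.0, abs=1e-9)
        assert rep.mainchain_rmsd < 1e-9

    def test_chi_deltas_flag_rotated_side_chain(self):
        m = make_toy_structure(3, seed=1, n_waters=0)
        rotated = m.copy()
        from jointxn.chem import nerf_place, dihedral
        quad = [rotated.find_atom("A", 1, nm) for nm in ("N", "CA", "CB", "OG")]
        chi = dihedral(*[rotated.atoms[i].pos for i in quad])
        rotated.atoms[quad[3]].pos = nerf_place(
            rotated.atoms[quad[0]].pos, rotated.atoms[quad[1]].pos,
            rotated.atoms[quad[2]].pos, 1.417, 110.8, chi + 60.0)
        _deltas, changed = chi_angle_deltas(m, rotated)
        assert ("A", 1) in changed
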