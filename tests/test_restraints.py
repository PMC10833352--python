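"""Geometry restraints, the top-out residual and hydrogen machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointxn import chem
from jointxn.fixtures import make_toy_structure
from jointxn.restraints import (build_reference_restraints, build_restraints,
                                classify_hydrogens, geometry_residual,
                                place_riding_hydrogens, set_h_torsion,
                                topout_residual)


class TestTopOut:
    def test_zero_at_zero(self):
        v, d = topout_residual(0.0, 2.5, 15.0)
        assert v == 0.0 and d == 0.0

    def test_asymptote(self):
        v, _ = topout_residual(150.0, 2.5, 15.0)
        assert v == pytest.approx((15.0 / 2.5) ** 2, abs=1e-4)

    def test_harmonic_near_zero(self):
        delta = 1.5  # 0.1 * L
        v, _ = topout_residual(delta, 2.5, 15.0)
        assert v == pytest.approx((delta / 2.5) ** 2, rel=0.01)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(delta=st.floats(-720, 720), sigma=st.floats(0.5, 10),
           limit=st.floats(1, 90))
    def test_bounded_even_monotone(self, delta, sigma, limit):
        """0 <= rho <= L^2/sigma^2 everywhere; even; monotone in |wrapped delta|."""
        v, _ = topout_residual(delta, sigma, limit)
        v_neg, _ = topout_residual(-delta, sigma, limit)
        assert 0.0 <= v <= (limit / sigma) ** 2 + 1e-12
        assert v == pytest.approx(v_neg, rel=1e-12, abs=1e-12)
        w = abs(chem.wrap_angle(delta))
        if w > 1.0:
            v_smaller, _ = topout_residual(w - 1.0, sigma, limit)
            assert v_smaller <= v + 1e-12

    def test_derivative_matches_finite_difference(self):
        for delta in (-40.0, -3.0, 0.7, 12.0, 90.0):
            v, d = topout_residual(delta, 2.5, 15.0)
            vp, _ = topout_residual(delta + 1e-6, 2.5, 15.0)
            vm, _ = topout_residual(delta - 1e-6, 2.5, 15.0)
            assert d == pytest.approx((vp - vm) / 2e-6, rel=1e-5, abs=1e-8)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            topout_residual(1.0, -1.0, 15.0)


class TestGeometryResidual:
    def test_zero_at_ideal_geometry(self, peptide5):
        rs = build_restraints(peptide5)
        v, g = geometry_residual(peptide5, rs)
        assert v < 1e-6
        assert np.abs(g).max() < 1e-2

    def test_one_sigma_stretch_contributes_one(self):
        m = make_toy_structure(1, seed=0, n_waters=0)
        rs = build_restraints(m)
        rs.angles = []
        rs.bonds = rs.bonds[:1]
        b = rs.bonds[0]
        u = m.atoms[b.i].pos - m.atoms[b.j].pos
        m.atoms[b.i].pos = m.atoms[b.j].pos + u / np.linalg.norm(u) * (
            b.ideal + b.sigma)
        v, _ = geometry_residual(m, rs)
        assert v == pytest.approx(1.0, rel=1e-9)

    def test_gradients_match_finite_differences(self, rng):
        m = make_toy_structure(3, seed=2, n_waters=0)
        rs = build_restraints(m)
        rs.reference_torsions = build_reference_restraints(m, m)
        for a in m.atoms:
            a.pos = a.pos + rng.normal(0, 0.05, 3)
        _v, g = geometry_residual(m, rs)
        for j in rng.choice(len(m.atoms), 10, replace=False):
            for ax in range(3):
                m.atoms[j].pos[ax] += 1e-6
                vp, _ = geometry_residual(m, rs)
                m.atoms[j].pos[ax] -= 2e-6
                vm, _ = geometry_residual(m, rs)
                m.atoms[j].pos[ax] += 1e-6
                fd = (vp - vm) / 2e-6
                if abs(fd) > 1e-5:
                    assert g[j, ax] == pytest.approx(fd, rel=1e-4)

    def test_dangling_reference_errors(self, peptide5):
        rs = build_restraints(peptide5)
        rs.bonds[0].i = 10 ** 6
        with pytest.raises(IndexError):
            geometry_residual(peptide5, rs)


class TestReferenceRestraints:
    def test_identity_reference_gives_zero_residual(self, peptide5):
        refs = build_reference_restraints(peptide5, peptide5)
        from jointxn.restraints import RestraintSet
        rs = RestraintSet(reference_torsions=refs)
        v, _ = geometry_residual(peptide5, rs)
        assert v == pytest.approx(0.0, abs=1e-18)

    def test_rotated_chi_produces_delta(self):
        work = make_toy_structure(3, seed=1, n_waters=0)
        ref = work.copy()
        # rotate Ser chi1 in the reference by 30 degrees: move OG (and its H)
        ser_og = ref.find_atom("A", 1, "OG")
        quad = [ref.find_atom("A", 1, nm) for nm in ("N", "CA", "CB", "OG")]
        chi = chem.dihedral(*[ref.atoms[i].pos for i in quad])
        from jointxn.chem import nerf_place
        ref.atoms[ser_og].pos = nerf_place(
            ref.atoms[quad[0]].pos, ref.atoms[quad[1]].pos, ref.atoms[quad[2]].pos,
            1.417, 110.8, chi + 30.0)
        restr = build_reference_restraints(work, ref)
        deltas = []
        for r in restr:
            phi = chem.dihedral(*[work.atoms[i].pos for i in (r.i, r.j, r.k, r.l)])
            deltas.append(abs(chem.wrap_angle(phi - r.target)))
        big = [d for d in deltas if d > 1.0]
        assert len(big) == 1
        assert big[0] == pytest.approx(30.0, abs=1e-6)

    def test_torsion_inventory_matches_hand_enumeration(self):
        """3 residues SER-ALA-TYR: phi for 2,3; psi for 1,2; chi1 for SER,
        chi1+chi2 for TYR."""
        m = make_toy_structure(3, seed=1, n_waters=0)
        restr = build_reference_restraints(m, m)
        # phi: residues 2,3 (needs previous C); psi: residues 1,2 (needs next N)
        expected = 2 + 2 + 1 + 2
        assert len(restr) == expected

    def test_working_model_never_altered(self, peptide5):
        before = peptide5.positions().copy()
        build_reference_restraints(peptide5, peptide5)
        assert np.array_equal(peptide5.positions(), before)

    def test_no_matchable_torsions_errors(self, peptide5):
        other = peptide5.copy()
        for a in other.atoms:
            a.chain = "Z"
        with pytest.raises(ValueError, match="matchable"):
            build_reference_restraints(peptide5, other)


class TestHydrogenClassification:
    def test_hydroxyls_rotatable_amide_riding(self, peptide5):
        labels = classify_hydrogens(peptide5.copy())
        by_name = {}
        for m_idx, lab in labels.items():
            a = peptide5.atoms[m_idx]
            by_name[(a.resname, a.name)] = lab
        assert by_name[("SER", "HG")] == "rotatable"
        assert by_name[("TYR", "HH")] == "rotatable"
        assert by_name[("SER", "H")] == "riding"
        assert by_name[("TYR", "HD1")] == "riding"

    def test_census_matches_hand_count(self):
        m = make_toy_structure(2, seed=0, n_waters=0)  # SER, ALA
        labels = classify_hydrogens(m)
        counts = {"riding": 0, "rotatable": 0}
        for lab in labels.values():
            counts[lab] += 1
        # SER: H, HA, HB2, HB3 riding; HG rotatable
        # ALA: H, HA riding; HB1-3 rotatable (methyl)
        assert counts == {"riding": 6, "rotatable": 4}


class TestRidingPlacement:
    def test_idempotent(self, peptide5):
        m = peptide5.copy()
        place_riding_hydrogens(m)
        p1 = m.positions().copy()
        place_riding_hydrogens(m)
        assert np.abs(m.positions() - p1).max() < 1e-9

    def test_bond_lengths_and_convention_ratio(self):
        m = make_toy_structure(3, seed=4, n_waters=0)
        place_riding_hydrogens(m, convention="nuclear")
        ha = m.find_atom("A", 2, "HA")
        ca = m.find_atom("A", 2, "CA")
        nuclear = np.linalg.norm(m.atoms[ha].pos - m.atoms[ca].pos)
        assert nuclear == pytest.approx(chem.NUCLEAR_XH["C"], abs=1e-6)
        place_riding_hydrogens(m, convention="electron-cloud")
        cloud = np.linalg.norm(m.atoms[ha].pos - m.atoms[ca].pos)
        assert 0.80 <= cloud / nuclear <= 0.90

    def test_methyl_angles_tetrahedral(self):
        m = make_toy_structure(2, seed=0, n_waters=0)  # has ALA methyl
        cb = m.find_atom("A", 2, "CB")
        hs = [m.find_atom("A", 2, f"HB{i}") for i in (1, 2, 3)]
        for i in range(3):
            for j in range(i + 1, 3):
                ang = chem.bond_angle(m.atoms[hs[i]].pos, m.atoms[cb].pos,
                                      m.atoms[hs[j]].pos)
                assert ang == pytest.approx(109.5, abs=0.5)

    def test_xh_residual_zero_after_placement(self):
        m = make_toy_structure(3, seed=4, n_waters=0)
        rng = np.random.default_rng(0)
        for a in m.atoms:
            if a.is_hydrogen:
                a.pos = a.pos + rng.normal(0, 0.2, 3)
        place_riding_hydrogens(m)
        rs = build_restraints(m)
        classify_hydrogens(m)
        riding = {i for i, a in enumerate(m.atoms)
                  if a.is_hydrogen and a.h_class == "riding"}
        xh = [b for b in rs.bonds
              if (b.i in riding) != (b.j in riding)
              and "H" in (m.atoms[b.i].element, m.atoms[b.j].element)]
        from jointxn.restraints import RestraintSet
        v, _ = geometry_residual(m, RestraintSet(bonds=xh))
        assert v < 1e-10

    def test_rotatable_untouched(self):
        m = make_toy_structure(1, seed=0, n_waters=0)  # SER
        hg = m.find_atom("A", 1, "HG")
        moved = m.atoms[hg].pos + np.array([0.3, 0.1, -0.2])
        m.atoms[hg].pos = moved.copy()
        place_riding_hydrogens(m)
        assert np.array_equal(m.atoms[hg].pos, moved)


def test_dictionary_text_file_round_trip(tmp_path):
    """The restraint dictionary survives the text-file round trip, including
    the two X--H length conventions."""
    from jointxn.chem import default_dictionary, read_dictionary, write_dictionary
    dic = default_dictionary()
    path = tmp_path / "restraints.tsv"
    write_dictionary(dic, str(path))
    back = read_dictionary(str(path))
    assert back.bonds.keys() == dic.bonds.keys()
    assert back.angles.keys() == dic.angles.keys()
    for k, v in dic.bonds.items():
        assert back.bonds[k] == pytest.approx(v, abs=1e-6)
    key = ("SER", "HG", "OG")
    assert back.bond_ideal(key, True, "electron-cloud") == pytest.approx(
        dic.bond_ideal(key, True, "electron-cloud"), abs=1e-5)


def test_set_h_torsion_round_trip():
    from jointxn.restraints import measure_h_torsion
    m = make_toy_structure(1, seed=0, n_waters=0)
    hg = m.find_atom("A", 1, "HG")
    set_h_torsion(m, hg, 73.0)
    _axis, phi = measure_h_torsion(m, hg)
    assert phi == pytest.approx(73.0, abs=1e-6)
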