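"""Scattering tables, structure factors, maps and completeness."""

import cmath
import math

import numpy as np
import pytest

from jointxn.fixtures import make_toy_structure, simulate_data
from jointxn.model_core import Atom, Model, SymOp, UnitCell, symops_from_spacegroup
from jointxn.scattering import (FORM_FACTORS, SCATTERING_LENGTHS, calc_map,
                                calc_structure_factors, completeness,
                                d_spacing, d_spacings, neutron_length,
                                read_reflections, unique_reflections,
                                write_reflections, xray_f0, xray_form_factor)


class TestTables:
    def test_f0_is_electron_count(self):
        assert xray_f0("S") == pytest.approx(16.0, abs=0.05)
        assert xray_f0("C") == pytest.approx(6.0, abs=0.05)
        assert xray_f0("O") == pytest.approx(8.0, abs=0.05)

    def test_form_factor_monotone_nonincreasing(self):
        s = np.linspace(0, 1, 200)
        for el in FORM_FACTORS:
            f = xray_form_factor(el, s * s)
            assert np.all(np.diff(f) <= 1e-12), el

    def test_scattering_length_signs(self):
        assert SCATTERING_LENGTHS["H"] < 0
        assert SCATTERING_LENGTHS["D"] > 0
        assert neutron_length("S") == pytest.approx(2.8, abs=0.05)

    def test_unknown_element_errors(self):
        with pytest.raises(KeyError, match="Xx"):
            xray_form_factor("Xx", 0.1)
        with pytest.raises(KeyError):
            neutron_length("Xx")


class TestDSpacing:
    def test_cubic_axis(self):
        cell = UnitCell(10, 10, 10)
        assert d_spacing((1, 0, 0), cell) == pytest.approx(10.0)
        assert d_spacing((0, 0, 2), cell) == pytest.approx(5.0)

    def test_triclinic_against_metric_tensor(self):
        cell = UnitCell(7.0, 9.0, 11.0, 75.0, 85.0, 95.0)
        # independent oracle: reciprocal metric tensor from the direct one
        ar, br, cr = 7.0, 9.0, 11.0
        al, be, ga = map(math.radians, (75.0, 85.0, 95.0))
        G = np.array([
            [ar * ar, ar * br * math.cos(ga), ar * cr * math.cos(be)],
            [ar * br * math.cos(ga), br * br, br * cr * math.cos(al)],
            [ar * cr * math.cos(be), br * cr * math.cos(al), cr * cr]])
        Gstar = np.linalg.inv(G)
        h = np.array([1, 2, 3])
        expected = 1.0 / math.sqrt(h @ Gstar @ h)
        assert d_spacing(h, cell) == pytest.approx(expected, rel=1e-10)

    def test_zero_index_errors(self):
        with pytest.raises(ValueError):
            d_spacing((0, 0, 0), UnitCell(10, 10, 10))


from tests_helpers import naive_structure_factor as _naive_structure_factor


class TestStructureFactors:
    def test_point_scatterer_at_origin(self):
        cell = UnitCell(10, 10, 10)
        m = Model(atoms=[Atom(1, "C", "C", False, "A", 1, "UNK",
                              np.zeros(3), 0.0, 1.0)], cell=cell)
        hkl = np.array([[1, 0, 0], [2, 3, 1], [0, 0, 4]])
        F = calc_structure_factors(m, hkl, "neutron")
        assert np.allclose(F, SCATTERING_LENGTHS["C"])

    def test_centrosymmetric_phases(self):
        cell = UnitCell(10, 10, 10)
        p = np.array([1.3, 2.1, 0.7])
        atoms = [Atom(1, "C", "C", False, "A", 1, "UNK", p, 5.0, 1.0),
                 Atom(2, "C", "C", False, "A", 1, "UNK", -p, 5.0, 1.0)]
        m = Model(atoms=atoms, cell=cell)
        F = calc_structure_factors(m, unique_reflections(cell, m.symops, 3.0), "xray")
        assert np.abs(F.imag).max() < 1e-9 * np.abs(F).max()

    @pytest.mark.parametrize("radiation", ["xray", "neutron"])
    def test_against_naive_oracle(self, exchanged5, radiation):
        hkl = unique_reflections(exchanged5.cell, exchanged5.symops, 4.0)[:25]
        F = calc_structure_factors(exchanged5, hkl, radiation)
        for i, h in enumerate(hkl):
            ref = _naive_structure_factor(exchanged5, h, radiation)
            assert abs(F[i] - ref) <= 1e-8 * abs(ref)

    def test_exchange_site_linearity(self):
        cell = UnitCell(10, 10, 10)
        p = np.array([2.0, 3.0, 4.0])
        atoms = [
            Atom(1, "H", "H", False, "A", 1, "UNK", p, 0.0, 0.5, exch_id=0),
            Atom(2, "D", "H", True, "A", 1, "UNK", p, 0.0, 0.5, exch_id=0),
        ]
        m = Model(atoms=atoms, cell=cell)
        F = calc_structure_factors(m, np.array([[1, 1, 0]]), "neutron")
        b = 0.5 * (SCATTERING_LENGTHS["H"] + SCATTERING_LENGTHS["D"])
        assert abs(F[0]) == pytest.approx(abs(b), rel=1e-12)

    def test_linearity_over_submodels(self, peptide5):
        hkl = unique_reflections(peptide5.cell, peptide5.symops, 3.5)[:40]
        half = len(peptide5.atoms) // 2
        a = Model(atoms=peptide5.atoms[:half], cell=peptide5.cell)
        b = Model(atoms=peptide5.atoms[half:], cell=peptide5.cell)
        Fa = calc_structure_factors(a, hkl, "xray")
        Fb = calc_structure_factors(b, hkl, "xray")
        F = calc_structure_factors(peptide5, hkl, "xray")
        assert np.abs(F - (Fa + Fb)).max() <= 1e-10 * np.abs(F).max()

    def test_symmetry_summed_equals_p1_expanded(self):
        from dataclasses import replace
        cell = UnitCell(12, 14, 16, 90, 95, 90)
        ops = symops_from_spacegroup("P 1 21 1")
        atoms = [Atom(1, "C", "C", False, "A", 1, "UNK",
                      np.array([2.0, 3.0, 4.0]), 10.0, 1.0),
                 Atom(2, "O", "O", False, "A", 1, "UNK",
                      np.array([5.0, 2.5, 3.0]), 12.0, 1.0)]
        m_sym = Model(atoms=atoms, cell=cell, symops=ops, spacegroup="P 1 21 1")
        expanded = []
        for k, op in enumerate(ops):
            for a in atoms:
                f2 = op.rot @ cell.fractionalize(a.pos) + op.trans
                expanded.append(replace(a, serial=10 * k + a.serial,
                                        pos=cell.orthogonalize(f2)))
        m_p1 = Model(atoms=expanded, cell=cell)
        hkl = unique_reflections(cell, ops, 2.0)
        F1 = calc_structure_factors(m_sym, hkl, "xray")
        F2 = calc_structure_factors(m_p1, hkl, "xray")
        assert np.abs(F1 - F2).max() <= 1e-8 * np.abs(F1).max()

    def test_neutron_flat_xray_decays(self, peptide5):
        """For B=0 models, neutron |F| statistics hold with resolution while
        X-ray |F| decay with the form factor."""
        m = peptide5.copy()
        for a in m.atoms:
            a.b_iso = 0.0
        hkl = unique_reflections(m.cell, m.symops, 1.5)
        d = d_spacings(hkl, m.cell)
        inner, outer = d > 4.0, d < 1.8
        fx = np.abs(calc_structure_factors(m, hkl, "xray"))
        assert fx[outer].mean() < fx[inner].mean()

    def test_unknown_element_in_model(self):
        cell = UnitCell(10, 10, 10)
        m = Model(atoms=[Atom(1, "FE", "Fe", False, "A", 1, "UNK",
                              np.zeros(3), 0.0, 1.0)], cell=cell)
        with pytest.raises(KeyError, match="Fe"):
            calc_structure_factors(m, np.array([[1, 0, 0]]), "xray")


class TestMaps:
    def test_peak_at_atom(self):
        cell = UnitCell(10, 10, 10)
        pos = np.array([3.0, 6.0, 2.0])
        m = Model(atoms=[Atom(1, "C", "C", False, "A", 1, "UNK", pos, 5.0, 1.0)],
                  cell=cell)
        hkl = unique_reflections(cell, m.symops, 1.5)
        F = calc_structure_factors(m, hkl, "xray")
        grid = calc_map(hkl, F, cell)
        peak = np.unravel_index(np.argmax(grid.values), grid.shape)
        peak_cart = grid.grid_to_cart(np.array(peak))
        assert np.linalg.norm(peak_cart - pos) < 10.0 / min(grid.shape) * 1.8

    def test_null_difference_map(self, peptide5):
        hkl = unique_reflections(peptide5.cell, peptide5.symops, 2.5)
        F = calc_structure_factors(peptide5, hkl, "xray")
        grid = calc_map(hkl, F - F, peptide5.cell, d_min=2.5)
        assert np.abs(grid.values).max() < 1e-9

    def test_parseval(self, peptide5):
        hkl = unique_reflections(peptide5.cell, peptide5.symops, 2.5)
        F = calc_structure_factors(peptide5, hkl, "xray")
        grid = calc_map(hkl, F, peptide5.cell)
        V = peptide5.cell.volume
        n = np.prod(grid.shape)
        lhs = 2 * np.sum(np.abs(F) ** 2)          # Friedel mates included
        rhs = np.sum(grid.values ** 2) * (V / n) * V
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_grid_too_coarse_errors(self, peptide5):
        hkl = unique_reflections(peptide5.cell, peptide5.symops, 2.5)
        F = calc_structure_factors(peptide5, hkl, "xray")
        with pytest.raises(ValueError, match="coarse"):
            calc_map(hkl, F, peptide5.cell, shape=(8, 8, 8))


class TestCompleteness:
    def test_full_sphere(self, peptide5):
        refl = simulate_data(peptide5, "xray", 3.0, completeness=1.0, seed=1)
        assert completeness(refl, peptide5.symops, 3.0) == 1.0

    def test_half_deleted(self, peptide5, rng):
        refl = simulate_data(peptide5, "xray", 3.0, completeness=1.0, seed=1)
        n = len(refl)
        keep = np.zeros(n, dtype=bool)
        keep[rng.choice(n, n // 2, replace=False)] = True
        sub = refl.subset(keep)
        assert completeness(sub, peptide5.symops, 3.0) == pytest.approx(
            0.5, abs=1.0 / n + 1e-9)

    def test_denominator_against_brute_force(self):
        """P1 cubic a=10, d_min=5: enumerate |h|,|k|,|l| <= 2 and filter."""
        cell = UnitCell(10, 10, 10)
        count = 0
        seen = set()
        for h in range(-2, 3):
            for k in range(-2, 3):
                for l in range(-2, 3):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    if 1.0 / math.sqrt((h / 10) ** 2 + (k / 10) ** 2 + (l / 10) ** 2) >= 5.0:
                        key = max((h, k, l), (-h, -k, -l))
                        seen.add(key)
        possible = unique_reflections(cell, [SymOp.identity()], 5.0)
        assert len(possible) == len(seen)


class TestReflectionIO:
    @pytest.mark.parametrize("suffix", [".cif", ".tsv"])
    def test_round_trip(self, tmp_path, peptide5, suffix):
        refl = simulate_data(peptide5, "xray", 3.0, noise=0.05, seed=2)
        path = tmp_path / ("data" + suffix)
        write_reflections(refl, str(path))
        back = read_reflections(str(path), cell=peptide5.cell,
                                radiation="xray" if suffix == ".tsv" else None)
        assert len(back) == len(refl)
        assert np.array_equal(back.hkl, refl.hkl)
        assert np.allclose(back.f_obs, refl.f_obs, rtol=1e-5)
        assert np.array_equal(back.free, refl.free)
        assert back.radiation == "xray"

    def test_duplicate_indices_rejected(self, peptide5):
        from jointxn.scattering import ReflectionSet
        with pytest.raises(ValueError, match="duplicate"):
            ReflectionSet(np.array([[1, 0, 0], [1, 0, 0]]),
                          np.ones(2), np.ones(2), peptide5.cell)
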