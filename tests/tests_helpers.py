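"""Shared independent oracles for the test suite.

These deliberately avoid the library's own vectorized/algebraic code paths:
plain-Python direct summation for structure factors, quaternion grid search
plus simplex polish for superposition, and bitmask recursion for maximum
water assignment.
"""

import cmath
import math
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.spatial.transform import Rotation

from jointxn.model_core import Atom, Model, UnitCell
from jointxn.scattering import SCATTERING_LENGTHS, d_spacings, xray_form_factor


def naive_structure_factor(model, h, radiation):
    """Per-reflection direct-summation oracle (plain Python loop)."""
    d = d_spacings(np.array([h], dtype=float), model.cell)[0]
    s2 = 1.0 / (4 * d * d)
    total = 0j
    for op in model.symops:
        for a in model.atoms:
            if radiation == "neutron":
                f = SCATTERING_LENGTHS["D" if a.is_deuterium else a.element]
            else:
                f = xray_form_factor(a.element, s2)
            x = op.rot @ (model.cell.frac @ a.pos) + op.trans
            total += a.occ * f * math.exp(-a.b_iso * s2) * cmath.exp(
                2j * math.pi * np.dot(h, x))
    return total


def quaternion_grid_rmsd(P, Q, n_grid=600, seed=0):
    """Superposition oracle: coarse quaternion grid plus Nelder-Mead polish;
    never touches the SVD algebra it checks."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(q):
        q = q / np.linalg.norm(q)
        R = Rotation.from_quat(q).as_matrix()
        return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = None
    for q in rng.normal(size=(n_grid, 4)):
        c = cost(q)
        if best is None or c < best[0]:
            best = (c, q)
    res = scipy_minimize(cost, best[1], method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-14,
                                  "maxiter": 5000})
    return res.fun


def exhaustive_match_count(A, B, cutoff):
    """Maximum one-to-one matching under the cutoff, by exhaustive bitmask
    recursion over the B side."""
    ok = [[np.linalg.norm(np.asarray(a) - np.asarray(b)) <= cutoff for b in B]
          for a in A]

    @lru_cache(maxsize=None)
    def best(i, used_mask):
        if i == len(A):
            return 0
        out = best(i + 1, used_mask)
        for j in range(len(B)):
            if ok[i][j] and not used_mask & (1 << j):
                out = max(out, 1 + best(i + 1, used_mask | (1 << j)))
        return out

    return best(0, 0)


def water_model(positions, cell=None):
    cell = cell or UnitCell(30, 30, 30)
    atoms = [Atom(i + 1, "O", "O", False, "W", i + 1, "HOH",
                  np.asarray(p, dtype=float), 20.0, 1.0)
             for i, p in enumerate(positions)]
    return Model(atoms=atoms, cell=cell)
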