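"""Scattering tables, structure factors, map synthesis and completeness.

X-ray atomic form factors use the standard four-Gaussian parameterization
f(s) = sum_i a_i exp(-b_i s^2) + c with s = sin(theta)/lambda, so f(0) is
the electron count.  Neutron coherent scattering lengths are per
element/isotope and resolution-independent; hydrogen's is negative while
deuterium's is positive, which is what makes H/D substitution visible to
neutrons.

Structure factors are computed by direct summation over explicit symmetry
operators:

    F(h) = sum_ops sum_j occ_j f_j(s) exp(-B_j s^2) exp(2 pi i h.(R x_j + t))

Exchange sites need no special casing: the H and D records carry
complementary occupancies, so for neutrons the site contributes
occ_H*b_H + occ_D*b_D at one position, and for X-rays both records use the
hydrogen form factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .model_core import Model, SymOp, UnitCell

# Four-Gaussian X-ray form-factor coefficients (a1..a4, b1..b4, c),
# electrons; f(0) = sum(a) + c equals the electron count.
FORM_FACTORS: dict[str, tuple] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
}

# Coherent neutron scattering lengths in fm; key "D" is deuterium.
SCATTERING_LENGTHS: dict[str, float] = {
    "H": -3.7390,
    "D": 6.671,
    "C": 6.6460,
    "N": 9.36,
    "O": 5.803,
    "S": 2.847,
}


def xray_f0(element: str) -> float:
    a, _b, c = FORM_FACTORS[element]
    return sum(a) + c


def xray_form_factor(element: str, stol2) -> np.ndarray:
    """f(s) for (sin theta / lambda)^2 values ``stol2``."""
    if element not in FORM_FACTORS:
        raise KeyError(f"no X-ray form factor for element {element!r}")
    a, b, c = FORM_FACTORS[element]
    stol2 = np.asarray(stol2, dtype=float)
    f = np.full_like(stol2, float(c))
    for ai, bi in zip(a, b):
        f = f + ai * np.exp(-bi * stol2)
    return f


def neutron_length(element: str, is_deuterium: bool = False) -> float:
    key = "D" if is_deuterium else element
    if key not in SCATTERING_LENGTHS:
        raise KeyError(f"no neutron scattering length for element {key!r}")
    return SCATTERING_LENGTHS[key]


# ---------------------------------------------------------------------------
# Reflections
# ---------------------------------------------------------------------------

@dataclass
class ReflectionSet:
    hkl: np.ndarray                    # (M, 3) int
    f_obs: np.ndarray                  # (M,) amplitudes, arbitrary scale
    sigma: np.ndarray                  # (M,)
    cell: UnitCell
    free: np.ndarray | None = None     # (M,) bool, True = free
    radiation: str = "unknown"         # xray | neutron | unknown
    d: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        seen = {tuple(h) for h in self.hkl}
        if len(seen) != len(self.hkl):
            raise ValueError("duplicate Miller indices in reflection set")
        if self.d is None:
            self.d = d_spacings(self.hkl, self.cell)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d_min(self) -> float:
        return float(self.d.min())

    def subset(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(self.hkl[mask], self.f_obs[mask], self.sigma[mask],
                             self.cell,
                             None if self.free is None else self.free[mask],
                             self.radiation, self.d[mask])


def d_spacing(hkl, cell: UnitCell) -> float:
    """d-spacing of one reflection, via the reciprocal metric tensor."""
    h = np.asarray(hkl, dtype=float)
    if not h.any():
        raise ValueError("d-spacing undefined for (0,0,0)")
    return float(d_spacings(h.reshape(1, 3), cell)[0])


def d_spacings(hkl: np.ndarray, cell: UnitCell) -> np.ndarray:
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    # reciprocal basis = rows of frac matrix; |h . A*|= 1/d
    rec = hkl @ cell.frac
    inv_d = np.linalg.norm(rec, axis=1)
    if np.any(inv_d == 0):
        raise ValueError("d-spacing undefined for (0,0,0)")
    return 1.0 / inv_d


def unique_reflections(cell: UnitCell, symops: list[SymOp], d_min: float) -> np.ndarray:
    """All symmetry- and Friedel-unique Miller indices with d >= d_min,
    by brute-force enumeration and orbit canonicalization."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = [int(np.ceil(np.linalg.norm(cell.orth[:, i]) / d_min)) + 1 for i in range(3)]
    grid = np.mgrid[-hmax[0]:hmax[0] + 1, -hmax[1]:hmax[1] + 1, -hmax[2]:hmax[2] + 1]
    hkl = grid.reshape(3, -1).T
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = d_spacings(hkl, cell)
    hkl = hkl[d >= d_min - 1e-9]
    reps = {_orbit_rep(h, symops) for h in hkl}
    return np.array(sorted(reps), dtype=int)


def _orbit_rep(h, symops: list[SymOp]) -> tuple:
    cands = []
    for op in symops:
        hr = np.rint(np.asarray(h, dtype=float) @ op.rot).astype(int)
        cands.append(tuple(hr))
        cands.append(tuple(-hr))
    return max(cands)


def completeness(refl: ReflectionSet, symops: list[SymOp], d_min: float) -> float:
    """Observed unique reflections over theoretically possible ones to d_min."""
    possible = unique_reflections(refl.cell, symops, d_min)
    observed = {_orbit_rep(h, symops) for h, d in zip(refl.hkl, refl.d)
                if d >= d_min - 1e-9}
    observed &= {tuple(h) for h in possible}
    return len(observed) / len(possible)


# ---------------------------------------------------------------------------
# Structure factors
# ---------------------------------------------------------------------------

def _atom_scattering(model: Model, stol2: np.ndarray, radiation: str) -> np.ndarray:
    """Per-(reflection, atom) scattering factor, without occupancy or DW."""
    n = len(model.atoms)
    out = np.empty((len(stol2), n))
    if radiation == "neutron":
        for j, a in enumerate(model.atoms):
            out[:, j] = neutron_length(a.element, a.is_deuterium)
    elif radiation == "xray":
        cache: dict[str, np.ndarray] = {}
        for j, a in enumerate(model.atoms):
            el = a.element  # H and D scatter identically for X-rays
            if el not in cache:
                cache[el] = xray_form_factor(el, stol2)
            out[:, j] = cache[el]
    else:
        raise ValueError(f"unknown radiation {radiation!r}")
    return out


@dataclass
class SFParts:
    """Structure factors with per-atom pieces for analytic gradients.

    ``unit[m, j]`` is atom j's complex contribution to reflection m at unit
    occupancy; ``contrib = occ * unit`` and ``F = contrib.sum(axis=1)``.
    The B derivative of contrib is ``-stol2[:, None] * contrib``; Cartesian
    gradients are obtained by :meth:`xyz_gradient` without ever building the
    (reflection, atom, 3) tensor.
    """
    F: np.ndarray
    unit: np.ndarray
    occ: np.ndarray
    stol2: np.ndarray
    op_terms: list          # per symop: (M, N) unit-occupancy complex terms
    op_phase_grads: list    # per symop: (M, 3) d(phase)/d(Cartesian)

    @property
    def contrib(self) -> np.ndarray:
        return self.unit * self.occ[None, :]

    def xyz_gradient(self, w: np.ndarray) -> np.ndarray:
        """Per-atom (N, 3) gradient of sum_m Re(w_m * F_m) over coordinates."""
        out = np.zeros((self.unit.shape[1], 3))
        for term, g in zip(self.op_terms, self.op_phase_grads):
            wt = 1j * (w[:, None] * term * self.occ[None, :])
            out += np.real(wt.T @ g)
        return out

    def dxyz_single(self, m: int, j: int) -> np.ndarray:
        """d(contrib[m, j]) / d(Cartesian coords of atom j)."""
        out = np.zeros(3, dtype=complex)
        for term, g in zip(self.op_terms, self.op_phase_grads):
            out += 1j * term[m, j] * self.occ[j] * g[m]
        return out


def structure_factor_parts(model: Model, hkl: np.ndarray, radiation: str,
                           want_xyz_grad: bool = False):
    """Direct-summation structure factors; returns ``(F, SFParts, parts)``.

    The third element duplicates ``parts`` for backward-compatible unpacking.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    d = d_spacings(hkl, model.cell)
    stol2 = 1.0 / (4.0 * d * d)
    f = _atom_scattering(model, stol2, radiation)
    occ = model.occupancies()
    b = model.b_factors()
    dw = np.exp(-np.outer(stol2, b))
    amp_unit = f * dw                             # without occupancy

    xyz = model.positions()
    frac = model.cell.fractionalize(xyz)          # (N, 3)
    fmat = model.cell.frac                        # frac = fmat @ cart

    unit = np.zeros((len(hkl), len(model.atoms)), dtype=complex)
    op_terms = []
    op_grads = []
    twopi = 2.0 * np.pi
    for op in model.symops:
        hr = hkl @ op.rot                         # (M, 3) fractional-basis
        phase = twopi * (hr @ frac.T + (hkl @ op.trans)[:, None])
        term = amp_unit * np.exp(1j * phase)
        unit = unit + term
        op_terms.append(term)
        op_grads.append(twopi * (hr @ fmat))      # (M, 3) d(phase)/d(cart)
    F = (unit * occ[None, :]).sum(axis=1)
    parts = SFParts(F, unit, occ, stol2, op_terms, op_grads)
    return F, parts, parts


def calc_structure_factors(model: Model, hkl: np.ndarray, radiation: str) -> np.ndarray:
    """Complex structure factors F(h) for the given Miller indices."""
    F, _, _ = structure_factor_parts(model, hkl, radiation)
    return F


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

class MapGrid:
    """Real-space density sampled on a unit-cell grid."""

    def __init__(self, values: np.ndarray, cell: UnitCell):
        self.values = np.asarray(values, dtype=float)
        self.cell = cell

    @property
    def shape(self):
        return self.values.shape

    @property
    def rmsd(self) -> float:
        return float(np.sqrt(np.mean((self.values - self.values.mean()) ** 2)))

    def normalized(self) -> np.ndarray:
        """Map values on the r.m.s.d. (sigma) scale (zeros for a flat map)."""
        r = self.rmsd
        if r == 0:
            return np.zeros_like(self.values)
        return (self.values - self.values.mean()) / r

    def value_at(self, xyz: np.ndarray, normalized: bool = True) -> float:
        """Trilinear interpolation at a Cartesian position (cell-periodic)."""
        vals = self.normalized() if normalized else self.values
        f = self.cell.fractionalize(np.asarray(xyz, dtype=float)) % 1.0
        n = np.array(self.shape)
        g = f * n
        i0 = np.floor(g).astype(int)
        t = g - i0
        out = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((t[0] if dx else 1 - t[0])
                         * (t[1] if dy else 1 - t[1])
                         * (t[2] if dz else 1 - t[2]))
                    idx = (i0 + (dx, dy, dz)) % n
                    out += w * vals[idx[0], idx[1], idx[2]]
        return float(out)

    def grid_to_cart(self, ijk: np.ndarray) -> np.ndarray:
        f = np.asarray(ijk, dtype=float) / np.array(self.shape)
        return self.cell.orthogonalize(f)

    def write_ccp4(self, path) -> None:
        grid = gemmi.FloatGrid(*self.shape)
        grid.set_unit_cell(self.cell.to_gemmi())
        arr = np.array(grid, copy=False)
        arr[...] = self.values.astype(np.float32)
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))


def map_grid_shape(cell: UnitCell, d_min: float, factor: float = 3.0) -> tuple[int, int, int]:
    spacing = d_min / factor
    return tuple(int(np.ceil(np.linalg.norm(cell.orth[:, i]) / spacing)) for i in range(3))


def calc_map(hkl: np.ndarray, coeffs: np.ndarray, cell: UnitCell,
             shape: tuple[int, int, int] | None = None,
             d_min: float | None = None) -> MapGrid:
    """Fourier synthesis: rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x).

    ``hkl`` is a Friedel-unique half set; mates are filled by conjugation.
    The grid must sample at least d_min/3 per axis.
    """
    hkl = np.asarray(hkl, dtype=int)
    coeffs = np.asarray(coeffs, dtype=complex)
    if d_min is None:
        d_min = float(d_spacings(hkl, cell).min())
    if shape is None:
        shape = map_grid_shape(cell, d_min)
    for i in range(3):
        axis_len = np.linalg.norm(cell.orth[:, i])
        if axis_len / shape[i] > d_min / 3.0 + 1e-9:
            raise ValueError("map grid too coarse for d_min/3 sampling")
    grid = np.zeros(shape, dtype=complex)
    n = np.array(shape)
    idx_p = np.mod(hkl, n)
    idx_m = np.mod(-hkl, n)
    for (ip, im, F) in zip(idx_p, idx_m, coeffs):
        grid[tuple(ip)] += F
        if tuple(im) != tuple(ip):
            grid[tuple(im)] += np.conj(F)
    # ifftn uses exp(+2 pi i k.x)/N; conjugating input gives the crystallographic
    # exp(-2 pi i h.x) convention
    rho = np.fft.ifftn(np.conj(grid)).real * (np.prod(shape) / cell.volume)
    return MapGrid(rho, cell)


# ---------------------------------------------------------------------------
# Reflection file I/O (mmCIF _refln loop; TSV dialect)
# ---------------------------------------------------------------------------

def write_reflections(refl: ReflectionSet, path) -> None:
    path = str(path)
    if path.endswith((".tsv", ".txt")):
        df = pd.DataFrame({
            "index_h": refl.hkl[:, 0], "index_k": refl.hkl[:, 1],
            "index_l": refl.hkl[:, 2],
            "F_meas_au": refl.f_obs, "F_meas_sigma_au": refl.sigma,
            "status": _status_column(refl),
        })
        df.to_csv(path, sep="\t", index=False)
        return
    doc = gemmi.cif.Document()
    block = doc.add_new_block("reflections")
    block.set_pair("_cell.length_a", f"{refl.cell.a:.6f}")
    block.set_pair("_cell.length_b", f"{refl.cell.b:.6f}")
    block.set_pair("_cell.length_c", f"{refl.cell.c:.6f}")
    block.set_pair("_cell.angle_alpha", f"{refl.cell.alpha:.6f}")
    block.set_pair("_cell.angle_beta", f"{refl.cell.beta:.6f}")
    block.set_pair("_cell.angle_gamma", f"{refl.cell.gamma:.6f}")
    block.set_pair("_diffrn_radiation.type", refl.radiation)
    loop = block.init_loop("_refln.", ["index_h", "index_k", "index_l",
                                       "F_meas_au", "F_meas_sigma_au", "status"])
    status = _status_column(refl)
    for (h, k, l), F, s, st in zip(refl.hkl, refl.f_obs, refl.sigma, status):
        loop.add_row([str(h), str(k), str(l), f"{F:.6f}", f"{s:.6f}", st])
    doc.write_file(path)


def _status_column(refl: ReflectionSet) -> list[str]:
    if refl.free is None:
        return ["x"] * len(refl)
    return ["f" if fl else "o" for fl in refl.free]


def read_reflections(path, cell: UnitCell | None = None,
                     radiation: str | None = None) -> ReflectionSet:
    path = str(path)
    if path.endswith((".tsv", ".txt")):
        if cell is None:
            raise ValueError("TSV reflection files carry no cell; pass one")
        df = pd.read_csv(path, sep="\t")
        hkl = df[["index_h", "index_k", "index_l"]].to_numpy(dtype=int)
        status = df["status"].astype(str).to_numpy()
        free = None if (status == "x").all() else (status == "f")
        return ReflectionSet(hkl, df["F_meas_au"].to_numpy(),
                             df["F_meas_sigma_au"].to_numpy(), cell, free,
                             radiation or "unknown")
    doc = gemmi.cif.read(path)
    block = doc.sole_block()
    if cell is None:
        cell = UnitCell(*[float(block.find_value(f"_cell.{k}"))
                          for k in ("length_a", "length_b", "length_c",
                                    "angle_alpha", "angle_beta", "angle_gamma")])
    if radiation is None:
        rad = block.find_value("_diffrn_radiation.type")
        radiation = rad if rad in ("xray", "neutron") else "unknown"
    table = block.find("_refln.", ["index_h", "index_k", "index_l",
                                   "F_meas_au", "F_meas_sigma_au", "status"])
    rows = [[row[i] for i in range(6)] for row in table]
    if not rows:
        raise ValueError(f"no _refln loop found in {path}")
    hkl = np.array([[int(r[0]), int(r[1]), int(r[2])] for r in rows])
    f_obs = np.array([float(r[3]) for r in rows])
    sigma = np.array([float(r[4]) for r in rows])
    status = [r[5] for r in rows]
    free = None if all(s == "x" for s in status) else np.array([s == "f" for s in status])
    return ReflectionSet(hkl, f_obs, sigma, cell, free, radiation)
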