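"""Atomic-model data types, PDB/mmCIF I/O and H/D exchange-site handling.

A :class:`Model` is a flat list of :class:`Atom` records plus the unit cell,
explicit symmetry operators and an X--H bond-length convention tag
(``nuclear`` for neutron models, ``electron-cloud`` for X-ray models).
Labile hydrogens (bonded to N, O or S) can be expanded into H/D *exchange
sites*: two co-located records with complementary occupancies
(occ_H + occ_D = 1) sharing one coordinate and one B factor.

File I/O is delegated to gemmi; deuterium survives the round trip through
the element field of the atom records.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import chem

WATER_NAMES = {"HOH", "DOD", "WAT"}


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit-cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("unit-cell angles must lie in (0, 180)")
        g = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        if g.volume <= 0:
            raise ValueError("degenerate unit cell")
        self._gemmi = g
        # 3x3 orthogonalization / fractionalization matrices
        self.orth = np.array(g.orth.mat.tolist())
        self.frac = np.array(g.frac.mat.tolist())

    @property
    def volume(self) -> float:
        return self._gemmi.volume

    def to_gemmi(self) -> gemmi.UnitCell:
        return self._gemmi

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.frac.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self.orth.T

    def __deepcopy__(self, memo):
        return UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass
class SymOp:
    rot: np.ndarray        # 3x3, fractional basis
    trans: np.ndarray      # 3-vector of fractions

    def __post_init__(self):
        self.rot = np.asarray(self.rot, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if abs(abs(np.linalg.det(self.rot)) - 1.0) > 1e-9:
            raise ValueError("symmetry rotation must have |det| = 1")

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(np.eye(3), np.zeros(3))


def symops_from_spacegroup(name: str) -> list[SymOp]:
    sg = gemmi.SpaceGroup(name)
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append(SymOp(rot, tran))
    return ops


@dataclass
class Atom:
    serial: int
    name: str
    element: str               # chemical element; H for both H and D
    is_deuterium: bool
    chain: str
    resnum: int
    resname: str
    pos: np.ndarray            # Cartesian Angstrom
    b_iso: float
    occ: float
    altloc: str = ""
    icode: str = ""
    exch_id: int | None = None
    h_class: str | None = None  # riding | rotatable (hydrogens only)

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy {self.occ} outside [0, 1]")
        if self.b_iso < 0:
            raise ValueError("negative B factor")
        if self.is_deuterium and self.element != "H":
            raise ValueError("isotope tag only valid for hydrogen")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_NAMES


@dataclass
class ExchangeSite:
    """One labile hydrogen position modelled as superposed H and D."""
    exch_id: int
    i_h: int
    i_d: int

    def occ_d(self, model: "Model") -> float:
        return model.atoms[self.i_d].occ


@dataclass
class Model:
    atoms: list[Atom]
    cell: UnitCell
    symops: list[SymOp] = field(default_factory=lambda: [SymOp.identity()])
    convention: str = "nuclear"
    spacegroup: str = "P 1"

    # -- basic accessors ---------------------------------------------------

    def copy(self) -> "Model":
        return _copy.deepcopy(self)

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    def set_positions(self, xyz: np.ndarray) -> None:
        for a, p in zip(self.atoms, xyz):
            a.pos = np.array(p, dtype=float)

    def b_factors(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms])

    def occupancies(self) -> np.ndarray:
        return np.array([a.occ for a in self.atoms])

    def residues(self) -> dict[tuple, list[int]]:
        """Atom indices grouped by (chain, resnum, icode, resname)."""
        out: dict[tuple, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain, a.resnum, a.icode, a.resname), []).append(i)
        return out

    def find_atom(self, chain: str, resnum: int, name: str,
                  deuterium: bool | None = None) -> int | None:
        for i, a in enumerate(self.atoms):
            if (a.chain == chain and a.resnum == resnum and a.name == name
                    and (deuterium is None or a.is_deuterium == deuterium)):
                return i
        return None

    def exchange_sites(self) -> list[ExchangeSite]:
        by_id: dict[int, dict[bool, int]] = {}
        for i, a in enumerate(self.atoms):
            if a.exch_id is not None:
                by_id.setdefault(a.exch_id, {})[a.is_deuterium] = i
        sites = []
        for eid in sorted(by_id):
            pair = by_id[eid]
            if set(pair) != {False, True}:
                raise ValueError(f"exchange group {eid} lacks an H/D partner")
            sites.append(ExchangeSite(eid, pair[False], pair[True]))
        return sites

    def waters(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_water]

    def protein_atoms(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_water]

    # -- connectivity ------------------------------------------------------

    def connectivity(self) -> list[tuple[int, int]]:
        """Bond list: template bonds where the residue type is known, plus
        the peptide link, with a distance fallback (< 1.2 x covalent-radius
        sum) for anything else."""
        bonds: list[tuple[int, int]] = []
        residues = self.residues()
        index = {}
        for key, idxs in residues.items():
            for i in idxs:
                a = self.atoms[i]
                index[(a.chain, a.resnum, a.icode, a.name, a.is_deuterium)] = i

        def lookup(chain, resnum, icode, name):
            i = index.get((chain, resnum, icode, name, False))
            if i is None:
                i = index.get((chain, resnum, icode, name, True))
            return i

        covered = set()
        for (chain, resnum, icode, resname), idxs in residues.items():
            if resname in chem.SIDECHAIN_RECIPES:
                for na, nb in chem.residue_bonds(resname):
                    ia = lookup(chain, resnum, icode, na)
                    ib = lookup(chain, resnum, icode, nb)
                    if ia is not None and ib is not None:
                        bonds.append((ia, ib))
                        covered.update((ia, ib))
                # exchange partners share the parent bond
                for i in idxs:
                    a = self.atoms[i]
                    if a.exch_id is not None and a.is_deuterium:
                        ip = lookup(chain, resnum, icode,
                                    self._recipe_parent(resname, a.name))
                        if ip is not None:
                            bonds.append((ip, i))
                            covered.add(i)
                # peptide link to the next residue
                inext = lookup(chain, resnum + 1, icode, "N")
                ic = lookup(chain, resnum, icode, "C")
                if ic is not None and inext is not None:
                    bonds.append((ic, inext))

        # distance fallback for uncovered non-water atoms (e.g. ad hoc toys)
        rest = [i for i, a in enumerate(self.atoms)
                if i not in covered and not a.is_water
                and a.resname not in chem.SIDECHAIN_RECIPES]
        for ii, i in enumerate(rest):
            for j in rest[ii + 1:]:
                ai, aj = self.atoms[i], self.atoms[j]
                rmax = 1.2 * (chem.COVALENT_RADIUS.get(ai.element, 0.8)
                              + chem.COVALENT_RADIUS.get(aj.element, 0.8))
                if np.linalg.norm(ai.pos - aj.pos) < rmax:
                    bonds.append((i, j))
        return bonds

    @staticmethod
    def _recipe_parent(resname: str, h_name: str) -> str:
        names = {rec[0]: rec[2] for rec in chem.SIDECHAIN_RECIPES[resname]}
        if h_name in names:
            return names[h_name]
        # deuterium records of exchange sites are named D* after their H twin
        if h_name.startswith("D") and "H" + h_name[1:] in names:
            return names["H" + h_name[1:]]
        return h_name

    def hydrogen_parent(self, i: int, bonds: list[tuple[int, int]] | None = None) -> int | None:
        """Index of the covalent heavy-atom neighbour of hydrogen ``i``."""
        a = self.atoms[i]
        if not a.is_hydrogen:
            raise ValueError("not a hydrogen")
        if a.resname in chem.SIDECHAIN_RECIPES:
            pname = self._recipe_parent(a.resname, a.name)
            j = self.find_atom(a.chain, a.resnum, pname, deuterium=False)
            if j is not None and not self.atoms[j].is_hydrogen:
                return j
        best, best_d = None, 1.5
        for j, b in enumerate(self.atoms):
            if j == i or b.is_hydrogen:
                continue
            d = float(np.linalg.norm(a.pos - b.pos))
            if d < best_d:
                best, best_d = j, d
        return best


# ---------------------------------------------------------------------------
# gemmi conversion and file I/O
# ---------------------------------------------------------------------------

def _to_gemmi(model: Model) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = model.cell.to_gemmi()
    st.spacegroup_hm = model.spacegroup
    gm = gemmi.Model("1")
    # group atoms into residues, preserving order
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in model.atoms:
        key = (a.chain, a.resnum, a.icode, a.resname)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    occ_d = [s.occ_d(model) for s in model.exchange_sites()]
    water_name = "HOH"
    if model.convention != "electron-cloud" and occ_d and float(np.mean(occ_d)) > 0.5:
        water_name = "DOD"
    chains: dict[str, gemmi.Chain] = {}
    for key in order:
        chain_name, resnum, icode, resname = key
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
        res = gemmi.Residue()
        res.name = water_name if resname in WATER_NAMES else resname
        res.seqid = gemmi.SeqId(resnum, icode if icode else " ")
        for a in groups[key]:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element("D" if a.is_deuterium else a.element)
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occ
            ga.b_iso = a.b_iso
            ga.serial = a.serial
            if a.altloc:
                ga.altloc = a.altloc
            res.add_atom(ga)
        chains[chain_name].add_residue(res)
    for ch in chains.values():
        gm.add_chain(ch)
    st.add_model(gm)
    return st


def _from_gemmi(st: gemmi.Structure, convention: str | None) -> Model:
    if st.cell.volume <= 0 or (st.cell.a == 1 and st.cell.b == 1 and st.cell.c == 1):
        raise ValueError("model file carries no unit cell; refusing to invent one")
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                    st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg_name = st.spacegroup_hm or "P 1"
    symops = symops_from_spacegroup(sg_name)
    atoms: list[Atom] = []
    serial = 0
    for ch in st[0]:
        for res in ch:
            for ga in res:
                serial += 1
                el = ga.element.name
                is_d = el == "D"
                atoms.append(Atom(
                    serial=ga.serial or serial,
                    name=ga.name,
                    element="H" if is_d else el,
                    is_deuterium=is_d,
                    chain=ch.name,
                    resnum=res.seqid.num,
                    resname=res.name,
                    pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    b_iso=ga.b_iso,
                    occ=ga.occ,
                    altloc=ga.altloc if ga.altloc else "",
                    icode=(res.seqid.icode or "").strip(),
                ))
    if convention is None:
        convention = "nuclear" if any(a.is_deuterium for a in atoms) else "electron-cloud"
    model = Model(atoms=atoms, cell=cell, symops=symops,
                  convention=convention, spacegroup=sg_name)
    _detect_exchange_sites(model)
    return model


def _detect_exchange_sites(model: Model, tol: float = 1e-3) -> None:
    """Pair co-located H/D records within a residue into exchange sites."""
    next_id = 0
    residues = model.residues()
    for idxs in residues.values():
        hs = [i for i in idxs if model.atoms[i].is_hydrogen and not model.atoms[i].is_deuterium]
        ds = [i for i in idxs if model.atoms[i].is_deuterium]
        used = set()
        for ih in hs:
            for idd in ds:
                if idd in used:
                    continue
                if np.linalg.norm(model.atoms[ih].pos - model.atoms[idd].pos) < tol:
                    model.atoms[ih].exch_id = next_id
                    model.atoms[idd].exch_id = next_id
                    next_id += 1
                    used.add(idd)
                    break


def read_model(path, format: str | None = None, convention: str | None = None) -> Model:
    """Read a PDB or mmCIF model file into a :class:`Model`.

    ``format`` is inferred from the extension when omitted.
    """
    path = str(path)
    fmt = format or ("mmcif" if path.endswith((".cif", ".mmcif")) else "pdb")
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown model format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()
    return _from_gemmi(st, convention)


def write_model(model: Model, path, format: str | None = None) -> None:
    path = str(path)
    fmt = format or ("mmcif" if path.endswith((".cif", ".mmcif")) else "pdb")
    for a in model.atoms:
        if not 0.0 <= a.occ <= 1.0:
            raise ValueError(f"atom {a.serial} occupancy {a.occ} outside [0, 1]")
    st = _to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(path)
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# Exchange-site construction and D -> H conversion
# ---------------------------------------------------------------------------

def _is_labile(model: Model, i: int) -> bool | None:
    """True if hydrogen ``i`` is bonded to N/O/S; None if no neighbour found."""
    j = model.hydrogen_parent(i)
    if j is None:
        return None
    return model.atoms[j].element in ("N", "O", "S")


def build_exchange_sites(model: Model, mode: str = "all-labile",
                         initial_occ_d: float = 0.5) -> Model:
    """Expand labile hydrogens into H/D exchange sites.

    ``all-labile``: every H bonded to N/O/S becomes an exchange site with
    occ_D = ``initial_occ_d``.  ``perdeuterate``: C-bound H become pure D
    and labile sites become exchange sites.  ``none``: identity.
    Hydrogens with no covalent neighbour within 1.5 A are flagged in the
    returned model's ``orphan_hydrogens`` attribute and left unmodified.
    """
    if mode not in ("all-labile", "none", "perdeuterate"):
        raise ValueError(f"unknown exchange mode {mode!r}")
    out = model.copy()
    out.orphan_hydrogens = []  # type: ignore[attr-defined]
    if mode == "none":
        return out
    next_id = max([a.exch_id for a in out.atoms if a.exch_id is not None], default=-1) + 1
    new_atoms: list[Atom] = []
    max_serial = max((a.serial for a in out.atoms), default=0)
    for i, a in enumerate(out.atoms):
        new_atoms.append(a)
        if not a.is_hydrogen or a.is_deuterium or a.exch_id is not None:
            continue
        labile = _is_labile(out, i)
        if labile is None:
            out.orphan_hydrogens.append(i)  # type: ignore[attr-defined]
            continue
        if labile:
            max_serial += 1
            a.exch_id = next_id
            a.occ = 1.0 - initial_occ_d
            d_name = "D" + a.name[1:] if a.name.startswith("H") else "D" + a.name
            d = replace(a, serial=max_serial, is_deuterium=True, name=d_name,
                        occ=initial_occ_d, pos=a.pos.copy())
            new_atoms.append(d)
            next_id += 1
        elif mode == "perdeuterate":
            a.is_deuterium = True
    out.atoms = new_atoms
    return out


def convert_for_xray(model: Model) -> Model:
    """Derive the X-ray variant of a neutron model.

    All D become H, exchange sites collapse to a single full-occupancy H,
    water hydrogens are removed entirely, and the convention tag switches to
    electron-cloud so that X--H restraint targets take the shorter values.
    Heavy-atom coordinates are untouched; the operation is idempotent.
    """
    out = model.copy()
    kept: list[Atom] = []
    for a in out.atoms:
        if a.is_water and a.is_hydrogen:
            continue
        if a.exch_id is not None:
            if a.is_deuterium:
                continue
            a.occ = 1.0
            a.exch_id = None
        a.is_deuterium = False
        kept.append(a)
    out.atoms = kept
    out.convention = "electron-cloud"
    return out
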