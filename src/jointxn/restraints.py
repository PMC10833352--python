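"""Geometry restraints, top-out reference-model torsion restraints and
riding-hydrogen machinery.

The geometry residual is

    T_geom = sum_bonds ((d - d0)/sigma)^2 + sum_angles ((th - th0)/sigma)^2
             + sum_ref_torsions rho(delta)

where the reference-torsion residual uses the *top-out* form

    rho(delta) = (L^2/sigma^2) (1 - exp(-delta^2 / L^2)),

harmonic (delta/sigma)^2 near zero and asymptotically flat at L^2/sigma^2,
so a torsion far from its reference target feels almost no pull — the
restraint encourages agreement without forcing it.  Reference restraints
are built over heavy atoms only and never alter the reference model.

Hydrogens are classified *riding* (position fully determined by the parent
geometry: backbone amide H, CH/CH2 groups, aromatic H) or *rotatable*
(a residual degree of freedom: hydroxyls, thiols, terminal methyls, water).
Riding hydrogens are rebuilt deterministically from their internal-coordinate
recipes at the convention's ideal X--H length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import chem
from .chem import (RestraintDictionary, default_dictionary, dihedral,
                   nerf_place, wrap_angle)
from .model_core import Model


@dataclass
class BondRestraint:
    i: int
    j: int
    ideal: float
    sigma: float


@dataclass
class AngleRestraint:
    i: int
    j: int              # central atom
    k: int
    ideal: float
    sigma: float


@dataclass
class ReferenceTorsionRestraint:
    i: int
    j: int
    k: int
    l: int
    target: float       # degrees, from the reference model
    sigma: float        # degrees
    limit: float        # top-out asymptote parameter L, degrees
    label: str = ""


@dataclass
class RestraintSet:
    bonds: list[BondRestraint] = field(default_factory=list)
    angles: list[AngleRestraint] = field(default_factory=list)
    reference_torsions: list[ReferenceTorsionRestraint] = field(default_factory=list)

    def __len__(self):
        return len(self.bonds) + len(self.angles) + len(self.reference_torsions)


# ---------------------------------------------------------------------------
# Top-out residual
# ---------------------------------------------------------------------------

def topout_residual(delta: float, sigma: float, limit: float) -> tuple[float, float]:
    """Value and d/d(delta) of the top-out residual at a wrapped angular
    deviation ``delta`` (degrees)."""
    if sigma <= 0 or limit <= 0:
        raise ValueError("sigma and limit must be positive")
    d = wrap_angle(delta)
    e = math.exp(-(d * d) / (limit * limit))
    value = (limit * limit) / (sigma * sigma) * (1.0 - e)
    deriv = 2.0 * d / (sigma * sigma) * e
    return value, deriv


# ---------------------------------------------------------------------------
# Geometry residual with analytic gradients
# ---------------------------------------------------------------------------

def _angle_and_grad(pa, pb, pc):
    """Angle a-b-c in degrees and its Cartesian gradients."""
    u = pa - pb
    v = pc - pb
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    uh = u / nu
    vh = v / nv
    c = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    s = math.sqrt(max(1.0 - c * c, 1e-12))
    theta = math.degrees(math.acos(c))
    deg = 180.0 / math.pi
    ga = deg * (c * uh - vh) / (nu * s)
    gc = deg * (c * vh - uh) / (nv * s)
    gb = -(ga + gc)
    return theta, ga, gb, gc


def _dihedral_and_grad(p0, p1, p2, p3):
    """Dihedral p0-p1-p2-p3 in degrees and its Cartesian gradients."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    sq1 = float(np.dot(n1, n1))
    sq2 = float(np.dot(n2, n2))
    if sq1 < 1e-12 or sq2 < 1e-12:
        raise ValueError("degenerate dihedral")
    phi = chem.dihedral(p0, p1, p2, p3)
    deg = 180.0 / math.pi
    g0 = deg * nb2 / sq1 * n1
    g3 = -deg * nb2 / sq2 * n2
    c1 = float(np.dot(b1, b2)) / (nb2 * nb2)
    c2 = float(np.dot(b3, b2)) / (nb2 * nb2)
    g1 = (-1.0 - c1) * g0 + c2 * g3
    g2 = c1 * g0 + (-1.0 - c2) * g3
    return phi, g0, g1, g2, g3


def geometry_residual(model: Model, restraints: RestraintSet) -> tuple[float, np.ndarray]:
    """Harmonic bond/angle terms plus top-out reference torsions."""
    xyz = model.positions()
    n = len(model.atoms)
    for r in restraints.bonds + restraints.angles + restraints.reference_torsions:
        for idx in (r.i, r.j, getattr(r, "k", 0), getattr(r, "l", 0)):
            if idx >= n:
                raise IndexError(f"restraint references missing atom {idx}")
    value = 0.0
    grad = np.zeros((n, 3))
    for r in restraints.bonds:
        u = xyz[r.i] - xyz[r.j]
        d = float(np.linalg.norm(u))
        resid = (d - r.ideal) / r.sigma
        value += resid * resid
        g = (2.0 * resid / r.sigma) * (u / d)
        grad[r.i] += g
        grad[r.j] -= g
    for r in restraints.angles:
        theta, ga, gb, gc = _angle_and_grad(xyz[r.i], xyz[r.j], xyz[r.k])
        resid = (theta - r.ideal) / r.sigma
        value += resid * resid
        f = 2.0 * resid / r.sigma
        grad[r.i] += f * ga
        grad[r.j] += f * gb
        grad[r.k] += f * gc
    for r in restraints.reference_torsions:
        phi, g0, g1, g2, g3 = _dihedral_and_grad(xyz[r.i], xyz[r.j], xyz[r.k], xyz[r.l])
        delta = wrap_angle(phi - r.target)
        v, dv = topout_residual(delta, r.sigma, r.limit)
        value += v
        for idx, g in ((r.i, g0), (r.j, g1), (r.k, g2), (r.l, g3)):
            grad[idx] += dv * g
    return value, grad


# ---------------------------------------------------------------------------
# Restraint enumeration from connectivity + dictionary
# ---------------------------------------------------------------------------

def build_restraints(model: Model,
                     dictionary: RestraintDictionary | None = None) -> RestraintSet:
    """Bond and angle restraints for a model of known residue types.

    Deuterium records of exchange sites are excluded (their coordinates are
    slaved to the H partner); X--H ideals follow the model's convention tag.
    """
    dic = dictionary or default_dictionary()
    rs = RestraintSet()
    atoms = model.atoms
    slaved = {i for s in model.exchange_sites() for i in (s.i_d,)}
    bonds = [(i, j) for i, j in model.connectivity()
             if i not in slaved and j not in slaved]

    def bond_key(i, j):
        ai, aj = atoms[i], atoms[j]
        if (ai.chain, ai.resnum, ai.icode) == (aj.chain, aj.resnum, aj.icode):
            a, b = sorted((ai.name, aj.name))
            return (ai.resname, a, b)
        return ("link", "C", "N")

    for i, j in bonds:
        key = bond_key(i, j)
        if key not in dic.bonds:
            continue
        is_xh = "H" in (atoms[i].element, atoms[j].element)
        ideal = dic.bond_ideal(key, is_xh, model.convention)
        rs.bonds.append(BondRestraint(i, j, ideal, dic.bond_sigma))

    adj: dict[int, list[int]] = {}
    for i, j in bonds:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    for center, nbrs in adj.items():
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, k = nbrs[x], nbrs[y]
                ai, ac, ak = atoms[i], atoms[center], atoms[k]
                same = (ai.chain, ai.resnum, ai.icode) == (ak.chain, ak.resnum, ak.icode) \
                    == (ac.chain, ac.resnum, ac.icode)
                if same:
                    a, b = sorted((ai.name, ak.name))
                    key = (ai.resname, a, ac.name, b)
                else:
                    cand = [("link", ai.name, ac.name, ak.name),
                            ("link", ak.name, ac.name, ai.name)]
                    key = next((c for c in cand if c in dic.angles), None)
                if key is None or key not in dic.angles:
                    continue
                rs.angles.append(AngleRestraint(i, center, k,
                                                dic.angle_ideal(key), dic.angle_sigma))
    return rs


# ---------------------------------------------------------------------------
# Reference-model torsion restraints
# ---------------------------------------------------------------------------

def enumerate_heavy_torsions(model: Model) -> list[tuple[str, tuple[int, int, int, int]]]:
    """All defined heavy-atom torsions (phi, psi, chi_n) as labelled
    atom-index quadruples."""
    torsions = []
    residues = sorted({(a.chain, a.resnum) for a in model.atoms
                       if not a.is_water and a.resname in chem.SIDECHAIN_RECIPES})

    def find(chain, resnum, name):
        return model.find_atom(chain, resnum, name, deuterium=False)

    for chain, resnum in residues:
        resname = next(a.resname for a in model.atoms
                       if a.chain == chain and a.resnum == resnum)
        quads = {
            "phi": [(chain, resnum - 1, "C"), (chain, resnum, "N"),
                    (chain, resnum, "CA"), (chain, resnum, "C")],
            "psi": [(chain, resnum, "N"), (chain, resnum, "CA"),
                    (chain, resnum, "C"), (chain, resnum + 1, "N")],
        }
        for ci, names in enumerate(chem.CHI_TORSIONS.get(resname, []), start=1):
            quads[f"chi{ci}"] = [(chain, resnum, nm) for nm in names]
        for label, spec in quads.items():
            idxs = [find(*s) for s in spec]
            if all(i is not None for i in idxs):
                torsions.append((f"{chain}{resnum}.{label}", tuple(idxs)))
    return torsions


def build_reference_restraints(working: Model, reference: Model,
                               sigma: float = 2.5, limit: float = 15.0,
                               log: list | None = None) -> list[ReferenceTorsionRestraint]:
    """One top-out torsion restraint per heavy-atom torsion of the working
    model whose residue (chain id, number, type) exists in the reference;
    the target is the equivalent torsion measured in the reference model.
    The working model is never altered (no rotamer correction)."""
    ref_index = {(a.chain, a.resnum, a.name): i for i, a in enumerate(reference.atoms)
                 if not a.is_hydrogen and not a.is_deuterium}
    ref_types = {(a.chain, a.resnum): a.resname for a in reference.atoms if not a.is_water}
    out = []
    for label, idxs in enumerate_heavy_torsions(working):
        atoms = [working.atoms[i] for i in idxs]
        if any(a.is_hydrogen for a in atoms):
            continue
        if any(ref_types.get((a.chain, a.resnum)) != a.resname for a in atoms):
            if log is not None:
                log.append(f"skipped {label}: unmatched residue in reference")
            continue
        ref_idx = [ref_index.get((a.chain, a.resnum, a.name)) for a in atoms]
        if any(i is None for i in ref_idx):
            if log is not None:
                log.append(f"skipped {label}: missing reference atoms")
            continue
        target = dihedral(*[reference.atoms[i].pos for i in ref_idx])
        out.append(ReferenceTorsionRestraint(*idxs, target=target, sigma=sigma,
                                             limit=limit, label=label))
    if not out:
        raise ValueError("no matchable torsions between working and reference models")
    return out


def write_reference_restraints(restraints: list[ReferenceTorsionRestraint],
                               model: Model, path) -> None:
    with open(path, "w") as fh:
        fh.write("# label\tatoms\ttarget_deg\tsigma_deg\tlimit_deg\n")
        for r in restraints:
            names = "-".join(model.atoms[i].name for i in (r.i, r.j, r.k, r.l))
            fh.write(f"{r.label}\t{names}\t{r.target:.3f}\t{r.sigma:.3f}\t{r.limit:.3f}\n")


# ---------------------------------------------------------------------------
# Hydrogen classification and riding placement
# ---------------------------------------------------------------------------

def classify_hydrogens(model: Model) -> dict[int, str]:
    """Label every hydrogen riding or rotatable; sets ``Atom.h_class``."""
    labels: dict[int, str] = {}
    for i, a in enumerate(model.atoms):
        if not a.is_hydrogen:
            continue
        if a.is_water:
            labels[i] = "rotatable"
        elif a.resname in chem.ROTATABLE_H:
            labels[i] = "rotatable" if a.name in chem.ROTATABLE_H[a.resname] else "riding"
        else:
            j = model.hydrogen_parent(i)
            if j is None:
                raise ValueError(f"hydrogen {a.serial} ({a.name}) has no bonded parent")
            labels[i] = "rotatable" if model.atoms[j].element in ("O", "S") else "riding"
        a.h_class = labels[i]
    return labels


def _h_recipe(resname: str, name: str):
    for rec in chem.SIDECHAIN_RECIPES[resname]:
        if rec[0] == name:
            return rec
    return None


def place_riding_hydrogens(model: Model, convention: str | None = None) -> Model:
    """Rebuild riding hydrogens deterministically from parent geometry at the
    convention's ideal X--H length (in place; returns the model).

    Rotatable hydrogens are untouched.  Deuterium exchange partners are
    re-co-located with their H records afterwards.  Idempotent.
    """
    convention = convention or model.convention
    classify_hydrogens(model)
    index = {(a.chain, a.resnum, a.name, a.is_deuterium): i
             for i, a in enumerate(model.atoms)}

    def pos_of(chain, resnum, name):
        i = index.get((chain, resnum, name, False))
        if i is None:
            i = index.get((chain, resnum, name, True))
        return None if i is None else model.atoms[i].pos

    for i, a in enumerate(model.atoms):
        if not a.is_hydrogen or a.h_class != "riding" or a.is_water:
            continue
        if a.is_deuterium and a.exch_id is not None:
            continue  # synced below
        if a.resname not in chem.SIDECHAIN_RECIPES:
            continue
        rec = _h_recipe(a.resname, a.name)
        if rec is None:
            continue
        _nm, _el, parent, aref, tref, _l, ang, tor = rec
        length = chem.xh_length(chem.residue_elements(a.resname)[parent], convention)
        p_parent = pos_of(a.chain, a.resnum, parent)
        p_aref = pos_of(a.chain, a.resnum, aref)
        if a.name == "H":
            # amide H: in the peptide plane, anti to the previous carbonyl C
            p_prev_c = pos_of(a.chain, a.resnum - 1, "C")
            p_tref = p_prev_c if p_prev_c is not None else pos_of(a.chain, a.resnum, tref)
            ang, tor = 118.2, 180.0
        else:
            p_tref = pos_of(a.chain, a.resnum, tref)
        if p_parent is None or p_aref is None or p_tref is None:
            a.h_class = "riding-orphan"
            continue
        a.pos = nerf_place(p_tref, p_aref, p_parent, length, ang, tor)
    sync_exchange_positions(model)
    return model


def sync_exchange_positions(model: Model) -> None:
    """Re-co-locate D exchange records with their H partners (position + B)."""
    for s in model.exchange_sites():
        model.atoms[s.i_d].pos = model.atoms[s.i_h].pos.copy()
        model.atoms[s.i_d].b_iso = model.atoms[s.i_h].b_iso


def measure_h_torsion(model: Model, i: int) -> tuple[tuple, float] | None:
    """Current recipe torsion (tref, aref, parent, H) of a hydrogen, with the
    atom-name tuple identifying the axis.  None if the recipe is unknown."""
    a = model.atoms[i]
    if a.resname not in chem.SIDECHAIN_RECIPES:
        return None
    rec = _h_recipe(a.resname, a.name)
    if rec is None:
        return None
    _nm, _el, parent, aref, tref, _l, _ang, _tor = rec

    def find(name):
        j = model.find_atom(a.chain, a.resnum, name, deuterium=False)
        if j is None:
            j = model.find_atom(a.chain, a.resnum, name, deuterium=True)
        return j

    idxs = [find(tref), find(aref), find(parent)]
    if any(j is None for j in idxs):
        return None
    phi = dihedral(model.atoms[idxs[0]].pos, model.atoms[idxs[1]].pos,
                   model.atoms[idxs[2]].pos, a.pos)
    return (tref, aref, parent), phi


def set_h_torsion(model: Model, i: int, torsion: float,
                  convention: str | None = None) -> bool:
    """Rebuild hydrogen ``i`` at the recipe geometry with the given torsion."""
    a = model.atoms[i]
    convention = convention or model.convention
    rec = _h_recipe(a.resname, a.name) if a.resname in chem.SIDECHAIN_RECIPES else None
    if rec is None:
        return False
    _nm, _el, parent, aref, tref, _l, ang, _tor = rec

    def find(name):
        j = model.find_atom(a.chain, a.resnum, name, deuterium=False)
        if j is None:
            j = model.find_atom(a.chain, a.resnum, name, deuterium=True)
        return j

    idxs = [find(tref), find(aref), find(parent)]
    if any(j is None for j in idxs):
        return False
    length = chem.xh_length(chem.residue_elements(a.resname)[parent], convention)
    a.pos = nerf_place(model.atoms[idxs[0]].pos, model.atoms[idxs[1]].pos,
                       model.atoms[idxs[2]].pos, length, ang, torsion)
    if a.exch_id is not None:
        sync_exchange_positions(model)
    return True
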