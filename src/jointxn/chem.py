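"""Residue topology, internal-coordinate templates and the restraint dictionary.

The toolkit carries its own small amino-acid alphabet (GLY, ALA, SER, MET,
TYR) defined by internal-coordinate build recipes.  Each atom is placed from
three previously placed atoms by the standard bond-length / bond-angle /
torsion construction (NeRF).  The same recipes drive riding-hydrogen
placement, torsion enumeration for reference-model restraints, and the
self-consistent restraint dictionary (ideal bond lengths and angles are
measured once from the nuclear-convention templates).

X--H bond lengths come in two conventions: *nuclear* (internuclear
distances, appropriate for neutron scattering) and *electron-cloud*
(centroid of the bonding electron density, appropriate for X-rays).  The
electron-cloud values are 15% shorter by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# internuclear X--H ideal lengths in Angstrom, by parent element
NUCLEAR_XH = {"C": 1.09, "N": 1.01, "O": 0.97, "S": 1.34}
# electron-cloud lengths are shorter; 0.85 is the midpoint of the
# observed 10-20% contraction
ELECTRON_CLOUD_FACTOR = 0.85

COVALENT_RADIUS = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}

BOND_SIGMA = 0.02      # Angstrom
ANGLE_SIGMA = 2.0      # degrees


def nerf_place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from positions A, B, C so that |C-D| = length,
    angle(B,C,D) = angle and dihedral(A,B,C,D) = torsion."""
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in internal-coordinate placement")
    n /= nn
    m = np.cross(n, bc)
    # sign chosen so that dihedral(a, b, c, d) measures back exactly tau
    d_local = np.array([
        -length * math.cos(theta),
        length * math.sin(theta) * math.cos(tau),
        -length * math.sin(theta) * math.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = p0 - p1
    v = p2 - p1
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def wrap_angle(delta: float) -> float:
    """Wrap an angular difference to (-180, 180]."""
    d = (delta + 180.0) % 360.0 - 180.0
    if d == -180.0:
        d = 180.0
    return d


# ---------------------------------------------------------------------------
# Side-chain recipes.
#
# Each entry: (name, element, parent, angle_ref, torsion_ref, length, angle,
# torsion).  "XH" as length means look up NUCLEAR_XH[parent element].
# Backbone atoms N, CA, C, O are placed by the chain builder; side-chain and
# hydrogen recipes reference them by name.  Hydrogens are listed after heavy
# atoms so every reference is already placed.
# ---------------------------------------------------------------------------

_CB = ("CB", "C", "CA", "N", "C", 1.530, 110.5, 122.5)
_HA = ("HA", "H", "CA", "N", "C", "XH", 108.9, -119.5)
_H = ("H", "H", "N", "CA", "C", "XH", 118.2, 180.0)

SIDECHAIN_RECIPES: dict[str, list[tuple]] = {
    "GLY": [
        _H,
        ("HA2", "H", "CA", "N", "C", "XH", 108.9, -119.5),
        ("HA3", "H", "CA", "N", "C", "XH", 108.9, 122.5),
    ],
    "ALA": [
        _CB, _H, _HA,
        ("HB1", "H", "CB", "CA", "N", "XH", 109.5, 60.0),
        ("HB2", "H", "CB", "CA", "N", "XH", 109.5, 180.0),
        ("HB3", "H", "CB", "CA", "N", "XH", 109.5, -60.0),
    ],
    "SER": [
        _CB,
        ("OG", "O", "CB", "CA", "N", 1.417, 110.8, 180.0),
        _H, _HA,
        ("HB2", "H", "CB", "CA", "OG", "XH", 109.3, 119.0),
        ("HB3", "H", "CB", "CA", "OG", "XH", 109.3, -119.0),
        ("HG", "H", "OG", "CB", "CA", "XH", 109.5, 180.0),
    ],
    "MET": [
        _CB,
        ("CG", "C", "CB", "CA", "N", 1.520, 114.1, -65.0),
        ("SD", "S", "CG", "CB", "CA", 1.803, 112.7, 180.0),
        ("CE", "C", "SD", "CG", "CB", 1.791, 100.9, 180.0),
        _H, _HA,
        ("HB2", "H", "CB", "CA", "CG", "XH", 109.3, 119.0),
        ("HB3", "H", "CB", "CA", "CG", "XH", 109.3, -119.0),
        ("HG2", "H", "CG", "CB", "SD", "XH", 109.3, 119.0),
        ("HG3", "H", "CG", "CB", "SD", "XH", 109.3, -119.0),
        ("HE1", "H", "CE", "SD", "CG", "XH", 109.5, 60.0),
        ("HE2", "H", "CE", "SD", "CG", "XH", 109.5, 180.0),
        ("HE3", "H", "CE", "SD", "CG", "XH", 109.5, -60.0),
    ],
    "TYR": [
        _CB,
        ("CG", "C", "CB", "CA", "N", 1.512, 113.8, 180.0),
        ("CD1", "C", "CG", "CB", "CA", 1.389, 120.8, 90.0),
        ("CD2", "C", "CG", "CB", "CA", 1.389, 120.8, -90.0),
        ("CE1", "C", "CD1", "CG", "CB", 1.382, 121.2, 180.0),
        ("CE2", "C", "CD2", "CG", "CB", 1.382, 121.2, 180.0),
        ("CZ", "C", "CE1", "CD1", "CG", 1.378, 119.6, 0.0),
        ("OH", "O", "CZ", "CE1", "CD1", 1.376, 119.9, 180.0),
        _H, _HA,
        ("HB2", "H", "CB", "CA", "CG", "XH", 109.3, 119.0),
        ("HB3", "H", "CB", "CA", "CG", "XH", 109.3, -119.0),
        ("HD1", "H", "CD1", "CG", "CB", "XH", 119.6, 0.0),
        ("HD2", "H", "CD2", "CG", "CB", "XH", 119.6, 0.0),
        ("HE1", "H", "CE1", "CD1", "CG", "XH", 119.6, 180.0),
        ("HE2", "H", "CE2", "CD2", "CG", "XH", 119.6, 180.0),
        ("HH", "H", "OH", "CZ", "CE1", "XH", 109.5, 0.0),
    ],
}

# Bonds not implied by the parent relation (ring closures).
EXTRA_BONDS = {"TYR": [("CZ", "CE2")]}

# Hydrogens whose position retains a degree of freedom given the parent
# geometry (hydroxyls, thiols, freely rotating terminal methyls, water).
ROTATABLE_H = {
    "GLY": set(),
    "ALA": {"HB1", "HB2", "HB3"},
    "SER": {"HG"},
    "MET": {"HE1", "HE2", "HE3"},
    "TYR": {"HH"},
}

# Heavy-atom side-chain torsions (chi angles) per residue type.
CHI_TORSIONS = {
    "GLY": [],
    "ALA": [],
    "SER": [("N", "CA", "CB", "OG")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
}

RESIDUE_TYPES = tuple(SIDECHAIN_RECIPES)


def xh_length(parent_element: str, convention: str) -> float:
    """Ideal X--H bond length for the given convention."""
    base = NUCLEAR_XH[parent_element]
    if convention == "electron-cloud":
        return base * ELECTRON_CLOUD_FACTOR
    return base


def recipe_length(recipe: tuple, elements: dict[str, str], convention: str) -> float:
    length = recipe[5]
    if length == "XH":
        return xh_length(elements[recipe[2]], convention)
    return float(length)


def residue_bonds(resname: str) -> list[tuple[str, str]]:
    """Intra-residue bond list (pairs of atom names) from the recipes."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    for rec in SIDECHAIN_RECIPES[resname]:
        bonds.append((rec[2], rec[0]))
    bonds.extend(EXTRA_BONDS.get(resname, []))
    return bonds


def residue_elements(resname: str) -> dict[str, str]:
    els = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    for rec in SIDECHAIN_RECIPES[resname]:
        els[rec[0]] = rec[1]
    return els


# ---------------------------------------------------------------------------
# Restraint dictionary
# ---------------------------------------------------------------------------

@dataclass
class RestraintDictionary:
    """Ideal geometry values measured from the internal-coordinate templates.

    Bond keys are ``(resname, name_a, name_b)`` with names sorted; the
    special resname ``"link"`` covers the peptide bond and its flanking
    angles.  X--H ideals are stored under the nuclear convention; use
    :meth:`bond_ideal` with a convention to obtain either value.
    """

    bonds: dict[tuple, float]
    angles: dict[tuple, float]
    bond_sigma: float = BOND_SIGMA
    angle_sigma: float = ANGLE_SIGMA
    xh_factor: float = ELECTRON_CLOUD_FACTOR

    def bond_ideal(self, key: tuple, is_xh: bool, convention: str) -> float:
        ideal = self.bonds[key]
        if is_xh and convention == "electron-cloud":
            ideal *= self.xh_factor
        return ideal

    def angle_ideal(self, key: tuple) -> float:
        return self.angles[key]


def _build_template_chain(sequence, phi=-57.0, psi=-47.0):
    """Build an ideal-geometry peptide in internal coordinates.

    Returns a list of per-residue dicts mapping atom name -> position, under
    the nuclear X--H convention.
    """
    residues = []
    prev = None
    for i, resname in enumerate(sequence):
        pos: dict[str, np.ndarray] = {}
        if prev is None:
            pos["N"] = np.array([0.0, 0.0, 0.0])
            pos["CA"] = np.array([1.458, 0.0, 0.0])
            # place C using the N-CA-C angle in the xy plane
            th = math.radians(111.2)
            pos["C"] = pos["CA"] + 1.525 * np.array([math.cos(math.pi - th),
                                                     math.sin(math.pi - th), 0.0])
        else:
            pos["N"] = nerf_place(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
            pos["CA"] = nerf_place(prev["CA"], prev["C"], pos["N"], 1.458, 121.7, 180.0)
            pos["C"] = nerf_place(prev["C"], pos["N"], pos["CA"], 1.525, 111.2, phi)
        pos["O"] = nerf_place(pos["N"], pos["CA"], pos["C"], 1.231, 120.8,
                              wrap_angle(psi + 180.0))
        els = residue_elements(resname)
        for rec in SIDECHAIN_RECIPES[resname]:
            name, _el, parent, aref, tref, _l, ang, tor = rec
            if name == "H" and prev is not None:
                # amide H lies in the peptide plane, anti to the carbonyl C
                pos[name] = nerf_place(prev["C"], pos["CA"], pos["N"],
                                       xh_length("N", "nuclear"), 118.2, 180.0)
                continue
            length = recipe_length(rec, els, "nuclear")
            pos[name] = nerf_place(pos[tref], pos[aref], pos[parent], length, ang, tor)
        residues.append(pos)
        prev = pos
    return residues


def _measure_dictionary() -> RestraintDictionary:
    seq = list(RESIDUE_TYPES) + ["ALA"]  # trailing ALA exposes link geometry for all
    chain = _build_template_chain(seq)
    bonds: dict[tuple, float] = {}
    angles: dict[tuple, float] = {}

    def bkey(resname, a, b):
        a, b = sorted((a, b))
        return (resname, a, b)

    for resname, pos in zip(seq, chain):
        adj: dict[str, list[str]] = {}
        for a, b in residue_bonds(resname):
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
            k = bkey(resname, a, b)
            bonds.setdefault(k, float(np.linalg.norm(pos[a] - pos[b])))
        for center, nbrs in adj.items():
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    a, b = sorted((nbrs[i], nbrs[j]))
                    k = (resname, a, center, b)
                    angles.setdefault(k, bond_angle(pos[a], pos[center], pos[b]))

    # peptide link: C(i)-N(i+1) bond and flanking angles
    p0, p1 = chain[0], chain[1]
    bonds[("link", "C", "N")] = float(np.linalg.norm(p0["C"] - p1["N"]))
    angles[("link", "CA", "C", "N")] = bond_angle(p0["CA"], p0["C"], p1["N"])
    angles[("link", "O", "C", "N")] = bond_angle(p0["O"], p0["C"], p1["N"])
    angles[("link", "C", "N", "CA")] = bond_angle(p0["C"], p1["N"], p1["CA"])
    angles[("link", "C", "N", "H")] = bond_angle(p0["C"], p1["N"], p1["H"])
    return RestraintDictionary(bonds=bonds, angles=angles)


_DICTIONARY: RestraintDictionary | None = None


def default_dictionary() -> RestraintDictionary:
    global _DICTIONARY
    if _DICTIONARY is None:
        _DICTIONARY = _measure_dictionary()
    return _DICTIONARY


def write_dictionary(dic: RestraintDictionary, path) -> None:
    """Write a restraint dictionary as a tab-separated text file.

    X--H bond ideals are stored under both length conventions (nuclear and
    electron-cloud columns); non-H bonds repeat the same value."""
    with open(path, "w") as fh:
        fh.write("# kind\tresidue\tatoms\tideal_nuclear\tideal_electron_cloud\tsigma\n")
        for (res, a, b), ideal in sorted(dic.bonds.items()):
            is_xh = a.startswith(("H", "D")) or b.startswith(("H", "D"))
            cloud = ideal * dic.xh_factor if is_xh else ideal
            fh.write(f"bond\t{res}\t{a}-{b}\t{ideal:.6f}\t{cloud:.6f}\t{dic.bond_sigma}\n")
        for key, ideal in sorted(dic.angles.items()):
            res, names = key[0], "-".join(key[1:])
            fh.write(f"angle\t{res}\t{names}\t{ideal:.6f}\t{ideal:.6f}\t{dic.angle_sigma}\n")


def read_dictionary(path) -> RestraintDictionary:
    """Read a restraint dictionary written by :func:`write_dictionary`."""
    bonds: dict[tuple, float] = {}
    angles: dict[tuple, float] = {}
    bond_sigma, angle_sigma, factor = BOND_SIGMA, ANGLE_SIGMA, ELECTRON_CLOUD_FACTOR
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            kind, res, names, nuclear, cloud, sigma = line.rstrip("\n").split("\t")
            key = (res, *names.split("-"))
            if kind == "bond":
                bonds[key] = float(nuclear)
                bond_sigma = float(sigma)
                if float(cloud) != float(nuclear):
                    factor = float(cloud) / float(nuclear)
            elif kind == "angle":
                angles[key] = float(nuclear)
                angle_sigma = float(sigma)
            else:
                raise ValueError(f"unknown restraint kind {kind!r}")
    if not bonds:
        raise ValueError(f"no restraints found in {path}")
    return RestraintDictionary(bonds=bonds, angles=angles, bond_sigma=bond_sigma,
                               angle_sigma=angle_sigma, xh_factor=factor)
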