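"""Validation machinery: perturbation ensembles, main-chain superposition,
water-site matching, map-based reliability filtering and ADP histograms.

Perturbation follows a kick-and-regularize scheme: seeded Gaussian
displacement of all non-riding atoms, optional geometry-regularization
descent, then isotropic rescaling of the displacement field so the achieved
all-atom r.m.s.d. lands on the requested level (the protocol's documented
levels are 0.5 and 0.9 A, 20 replicates each).

Water matching is one-to-one and greedy in distance order under a 0.5 A
cutoff; waters without a counterpart are *lone* waters.  Symmetry images
within one cell shell are considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .model_core import Model
from .restraints import (build_restraints, classify_hydrogens, geometry_residual,
                         place_riding_hydrogens, sync_exchange_positions)
from .scattering import MapGrid, calc_map, calc_structure_factors


# ---------------------------------------------------------------------------
# Perturbation ensembles
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSpec:
    target_rmsd: float            # Angstrom
    replicates: int = 20
    seed: int = 0
    regularize: bool = True

    def __post_init__(self):
        if self.target_rmsd <= 0:
            raise ValueError("target r.m.s.d. must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def all_atom_rmsd(a: Model, b: Model) -> float:
    pa, pb = a.positions(), b.positions()
    if pa.shape != pb.shape:
        raise ValueError("models differ in atom count")
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def perturb_model(model: Model, spec: PerturbationSpec) -> list[Model]:
    """Seeded perturbation ensemble at a controlled all-atom r.m.s.d.

    Each replicate: Gaussian kick of non-riding atoms, optional short
    geometry regularization, then iterative isotropic rescaling of the
    displacement field (riding H rebuilt each pass) until the achieved
    all-atom r.m.s.d. is within 1% of the target.
    """
    from .refine import minimize  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    base = model.copy()
    classify_hydrogens(base)
    slaved = {s.i_d for s in base.exchange_sites()}
    kicked = [i for i, a in enumerate(base.atoms)
              if i not in slaved and not (a.is_hydrogen and a.h_class == "riding")]
    restraints = build_restraints(base) if spec.regularize else None
    orig = base.positions()
    out = []
    for _rep in range(spec.replicates):
        m = base.copy()
        xyz = m.positions()
        xyz[kicked] += rng.normal(0.0, spec.target_rmsd / np.sqrt(3.0),
                                  (len(kicked), 3))
        m.set_positions(xyz)
        sync_exchange_positions(m)
        if spec.regularize:
            def geom(mm):
                return geometry_residual(mm, restraints)
            m, _tr = minimize(m, geom, kicked, max_iter=15)
        for _pass in range(6):
            place_riding_hydrogens(m)
            sync_exchange_positions(m)
            achieved = all_atom_rmsd(m, base)
            if abs(achieved - spec.target_rmsd) <= 0.01 * spec.target_rmsd:
                break
            scale = spec.target_rmsd / achieved
            xyz = m.positions()
            xyz[kicked] = orig[kicked] + scale * (xyz[kicked] - orig[kicked])
            m.set_positions(xyz)
            sync_exchange_positions(m)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

MAINCHAIN = ("N", "CA", "C", "O")


@dataclass
class Superposition:
    rotation: np.ndarray           # 3x3 proper rotation (det = +1)
    translation: np.ndarray        # applied after rotation
    rmsd: float                    # post-fit main-chain r.m.s.d.
    n_atoms: int

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.atleast_2d(xyz) @ self.rotation.T + self.translation

    def transform_model(self, model: Model) -> Model:
        out = model.copy()
        out.set_positions(self.apply(out.positions()))
        return out


def _matched_mainchain(mobile: Model, fixed: Model):
    fix_index = {(a.chain, a.resnum, a.name): i for i, a in enumerate(fixed.atoms)
                 if not a.is_water and a.name in MAINCHAIN and not a.is_hydrogen}
    pairs = []
    for i, a in enumerate(mobile.atoms):
        if a.is_water or a.is_hydrogen or a.name not in MAINCHAIN:
            continue
        j = fix_index.get((a.chain, a.resnum, a.name))
        if j is not None:
            pairs.append((i, j))
    return pairs


def superpose_mainchain(mobile: Model, fixed: Model) -> Superposition:
    """Least-squares rigid-body superposition (Kabsch, proper rotation) on
    matched main-chain N/CA/C/O atoms."""
    pairs = _matched_mainchain(mobile, fixed)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 matched main-chain atoms")
    P = np.array([mobile.atoms[i].pos for i, _ in pairs])
    Q = np.array([fixed.atoms[j].pos for _, j in pairs])
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = (P @ R.T) + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return Superposition(R, t, rmsd, len(pairs))


# ---------------------------------------------------------------------------
# Water matching
# ---------------------------------------------------------------------------

@dataclass
class WaterMatchReport:
    matched: list[tuple[int, int, float]]     # (idx in A, idx in B, distance)
    lone_a: list[int]
    lone_b: list[int]
    cutoff: float

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def pct_lone_a(self) -> float:
        tot = len(self.lone_a) + self.n_matched
        return 100.0 * len(self.lone_a) / tot if tot else 0.0

    @property
    def pct_lone_b(self) -> float:
        tot = len(self.lone_b) + self.n_matched
        return 100.0 * len(self.lone_b) / tot if tot else 0.0


def _water_oxygens(model: Model) -> list[int]:
    return [i for i in model.waters() if model.atoms[i].element == "O"]


def _sym_min_dist(cell, symops, pa: np.ndarray, pb: np.ndarray) -> float:
    """Distance from pa to the nearest image of pb (ops x one cell shell)."""
    fb = cell.fractionalize(pb)
    fa = cell.fractionalize(pa)
    best = np.inf
    for op in symops:
        fb2 = op.rot @ fb + op.trans
        d = fa - fb2
        d -= np.round(d)
        best = min(best, float(np.linalg.norm(cell.orthogonalize(d))))
    return best


def match_waters(a: Model, b: Model, cutoff: float = 0.5,
                 use_symmetry: bool = True) -> WaterMatchReport:
    """Greedy one-to-one matching of water oxygens by ascending distance.

    Both models must already be in the same frame (superpose first when
    comparing refined structures)."""
    ia = _water_oxygens(a)
    ib = _water_oxygens(b)
    cand = []
    for i in ia:
        for j in ib:
            if use_symmetry:
                d = _sym_min_dist(a.cell, b.symops, a.atoms[i].pos, b.atoms[j].pos)
            else:
                d = float(np.linalg.norm(a.atoms[i].pos - b.atoms[j].pos))
            if d <= cutoff:
                cand.append((d, a.atoms[i].serial, b.atoms[j].serial, i, j))
    cand.sort()
    used_a, used_b = set(), set()
    matched = []
    for d, _sa, _sb, i, j in cand:
        if i in used_a or j in used_b:
            continue
        matched.append((i, j, d))
        used_a.add(i)
        used_b.add(j)
    lone_a = [i for i in ia if i not in used_a]
    lone_b = [j for j in ib if j not in used_b]
    return WaterMatchReport(matched, lone_a, lone_b, cutoff)


# ---------------------------------------------------------------------------
# Map-based reliability filtering
# ---------------------------------------------------------------------------

def model_density_map(model: Model, hkl: np.ndarray, radiation: str,
                      shape) -> MapGrid:
    """Model-computed density on the given grid shape."""
    f = calc_structure_factors(model, hkl, radiation)
    return calc_map(hkl, f, model.cell, shape=shape)


def real_space_cc(model: Model, atom_indices: list[int], grid: MapGrid,
                  hkl: np.ndarray, radiation: str,
                  mask_radius: float = 1.5,
                  model_map: MapGrid | None = None) -> float:
    """Pearson correlation between the map and the full-model density over
    grid points within the mask radius of the selected atoms."""
    if not atom_indices:
        raise ValueError("empty atom selection")
    if model_map is None:
        model_map = model_density_map(model, hkl, radiation, grid.shape)
    mask = _mask_points(model.cell, grid.shape,
                        np.array([model.atoms[i].pos for i in atom_indices]),
                        mask_radius)
    if not mask.any():
        raise ValueError("empty map mask")
    x = grid.values[mask]
    y = model_map.values[mask]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _mask_points(cell, shape, centers: np.ndarray, radius: float) -> np.ndarray:
    n = np.array(shape)
    mask = np.zeros(shape, dtype=bool)
    # conservative per-axis half-widths in grid units
    spacing = np.array([np.linalg.norm(cell.orth[:, i]) for i in range(3)]) / n
    half = np.ceil(radius / spacing).astype(int) + 1
    for c in centers:
        fc = cell.fractionalize(c) % 1.0
        g0 = np.round(fc * n).astype(int)
        rng = [np.arange(g0[i] - half[i], g0[i] + half[i] + 1) for i in range(3)]
        gi, gj, gk = np.meshgrid(*rng, indexing="ij")
        fr = np.stack([gi / n[0], gj / n[1], gk / n[2]], axis=-1)
        d = fr - cell.fractionalize(c)
        d -= np.round(d)
        cart = d @ cell.orth.T
        ok = np.linalg.norm(cart, axis=-1) <= radius
        mask[gi[ok] % n[0], gj[ok] % n[1], gk[ok] % n[2]] = True
    return mask


@dataclass
class ReliabilityReport:
    kept: list[tuple]
    excluded: list[tuple[tuple, str]]


def filter_reliable(model: Model, map_2fofc: MapGrid, map_diff: MapGrid,
                    hkl: np.ndarray, radiation: str,
                    cc_residue: float = 0.9, cc_water: float = 0.7,
                    neg_peak: float = -3.0, weak_density: float = 1.7) -> ReliabilityReport:
    """Partition residues/waters into reliable and excluded.

    Excluded: residues with map-model CC < 0.9; waters with CC < 0.7 or
    modelled as alternates; any entity with a difference-map value below
    -3 r.m.s.d. at an atom while its average model-map density over atomic
    centres is below 1.7 r.m.s.d."""
    kept, excluded = [], []
    mm = model_density_map(model, hkl, radiation, map_2fofc.shape)
    for key, idxs in model.residues().items():
        is_water = key[3] in ("HOH", "DOD", "WAT")
        if is_water and any(model.atoms[i].altloc for i in idxs):
            excluded.append((key, "water modelled as alternate conformation"))
            continue
        cc = real_space_cc(model, idxs, map_2fofc, hkl, radiation, model_map=mm)
        thresh = cc_water if is_water else cc_residue
        if cc < thresh:
            excluded.append((key, f"map-model CC {cc:.3f} < {thresh}"))
            continue
        diffs = [map_diff.value_at(model.atoms[i].pos) for i in idxs]
        dens = [map_2fofc.value_at(model.atoms[i].pos) for i in idxs]
        if min(diffs) < neg_peak and float(np.mean(dens)) < weak_density:
            excluded.append((key, "negative difference peak with weak density"))
            continue
        kept.append(key)
    return ReliabilityReport(kept, excluded)


# ---------------------------------------------------------------------------
# ADP histograms and model comparison
# ---------------------------------------------------------------------------

@dataclass
class AdpHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    stats: dict        # per partition: min/max/mean

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def adp_histogram(model: Model, bin_width: float = 5.0) -> AdpHistogram:
    """Histogram of isotropic ADPs over non-H atoms, with per-partition
    (protein / water) min, max and mean."""
    b_all = np.array([a.b_iso for a in model.atoms if not a.is_hydrogen])
    b_prot = np.array([a.b_iso for a in model.atoms
                       if not a.is_hydrogen and not a.is_water])
    b_wat = np.array([a.b_iso for a in model.atoms
                      if not a.is_hydrogen and a.is_water])
    top = (np.floor(b_all.max() / bin_width) + 1) * bin_width if len(b_all) else bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(b_all, bins=edges)
    stats = {}
    for name, arr in (("protein", b_prot), ("water", b_wat)):
        if len(arr):
            stats[name] = {"min": float(arr.min()), "max": float(arr.max()),
                           "mean": float(arr.mean())}
    return AdpHistogram(edges, counts, stats)


def chi_angle_deltas(a: Model, b: Model, changed_threshold: float = 30.0):
    """Per-residue chi-angle absolute deviations between matched residues;
    deltas above the threshold are flagged as rotamer-changed proxies."""
    deltas = {}
    b_index = {(at.chain, at.resnum, at.name): i for i, at in enumerate(b.atoms)
               if not at.is_hydrogen}
    for chain, resnum in sorted({(at.chain, at.resnum) for at in a.atoms
                                 if not at.is_water and at.resname in chem.CHI_TORSIONS}):
        resname = next(at.resname for at in a.atoms
                       if at.chain == chain and at.resnum == resnum)
        row = []
        for names in chem.CHI_TORSIONS.get(resname, []):
            ia = [a.find_atom(chain, resnum, nm) for nm in names]
            ib = [b_index.get((chain, resnum, nm)) for nm in names]
            if any(x is None for x in ia + ib):
                continue
            chi_a = chem.dihedral(*[a.atoms[i].pos for i in ia])
            chi_b = chem.dihedral(*[b.atoms[i].pos for i in ib])
            row.append(abs(chem.wrap_angle(chi_a - chi_b)))
        if row:
            deltas[(chain, resnum)] = row
    changed = [k for k, v in deltas.items() if max(v) > changed_threshold]
    return deltas, changed


@dataclass
class ComparisonReport:
    mainchain_rmsd: float
    n_superposed: int
    waters: WaterMatchReport
    chi_deltas: dict
    rotamer_changed: list
    adp_a: AdpHistogram
    adp_b: AdpHistogram
    excluded: list = field(default_factory=list)


def compare_models(a: Model, b: Model, cutoff: float = 0.5) -> ComparisonReport:
    """Superpose b onto a by main-chain atoms, then compare waters, chi
    angles and ADP distributions."""
    sup = superpose_mainchain(b, a)
    b_fit = sup.transform_model(b)
    waters = match_waters(a, b_fit, cutoff=cutoff)
    deltas, changed = chi_angle_deltas(a, b_fit)
    return ComparisonReport(sup.rmsd, sup.n_atoms, waters, deltas, changed,
                            adp_histogram(a), adp_histogram(b))
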