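"""Synthetic crystal scenarios: toy structures, X-ray/neutron model pairs
and simulated reflection data.

Every generator is seeded and bit-reproducible, and emits its own ground
truth (composition bookkeeping, true coordinates, water correspondence) so
oracle tests never need external data.  The default scenario family mirrors
the situation that motivates two-model joint refinement: X-ray and neutron
data arising from *different* crystals of the same protein, sharing the
fold but differing in water structure and overall ADP level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import chem
from .model_core import Atom, Model, SymOp, UnitCell, build_exchange_sites, convert_for_xray
from .restraints import classify_hydrogens, sync_exchange_positions
from .scattering import ReflectionSet, calc_structure_factors, unique_reflections
from .targets import assign_free_flags

_SEQ_CYCLE = ("SER", "ALA", "TYR", "GLY", "MET")


@dataclass
class CrystalScenario:
    n_residues: int = 10
    n_waters: int = 10
    divergent_water_fraction: float = 0.0
    adp_offset: float = 0.0            # added to the X-ray model's B factors
    hd_scheme: str = "exchanged"       # hydrogenated | exchanged | perdeuterated
    xray_altloc: bool = False
    d_min_xray: float = 1.5
    d_min_neutron: float = 2.5
    completeness_xray: float = 1.0
    completeness_neutron: float = 0.75
    noise_xray: float = 0.0
    noise_neutron: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.completeness_xray <= 1 or not 0 < self.completeness_neutron <= 1:
            raise ValueError("completeness must lie in (0, 1]")
        if min(self.noise_xray, self.noise_neutron) < 0:
            raise ValueError("noise must be non-negative")


def make_toy_structure(n_residues: int, seed: int = 0, n_waters: int | None = None,
                       b_base: float = 15.0, padding: float = 4.0) -> Model:
    """Mixed-sequence ideal-geometry helix with explicit H, packed in a P1
    cell with >= ``padding`` A of margin, plus waters near polar atoms.

    The returned model carries a ``info`` dict with the generator's own
    composition bookkeeping (expected atom counts per class).
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    seq = [_SEQ_CYCLE[i % len(_SEQ_CYCLE)] for i in range(n_residues)]
    chain = chem._build_template_chain(seq)

    atoms: list[Atom] = []
    serial = 0
    for resnum, (resname, pos) in enumerate(zip(seq, chain), start=1):
        for name, p in pos.items():
            serial += 1
            el = chem.residue_elements(resname).get(name, name[0])
            b = float(np.clip(rng.normal(b_base, 2.0), 5.0, 40.0))
            atoms.append(Atom(serial=serial, name=name, element=el,
                              is_deuterium=False, chain="A", resnum=resnum,
                              resname=resname, pos=p.copy(), b_iso=b, occ=1.0))

    xyz = np.array([a.pos for a in atoms])
    lo = xyz.min(axis=0)
    shift = padding - lo
    for a in atoms:
        a.pos = a.pos + shift
    xyz = xyz + shift
    extent = xyz.max(axis=0) + padding
    cell = UnitCell(float(extent[0]), float(extent[1]), float(extent[2]))

    model = Model(atoms=atoms, cell=cell, symops=[SymOp.identity()],
                  convention="nuclear", spacegroup="P 1")
    # hydrogens inherit the parent ADP (the standard riding-ADP convention)
    for i, a in enumerate(model.atoms):
        if a.is_hydrogen:
            j = model.hydrogen_parent(i)
            if j is not None:
                a.b_iso = model.atoms[j].b_iso

    # waters near polar protein atoms, pointing away from the centroid
    if n_waters is None:
        n_waters = max(2, n_residues)
    centroid = xyz.mean(axis=0)
    polar = [a for a in atoms if a.element in ("O", "N")]
    placed = 0
    attempts = 0
    wser = serial
    while placed < n_waters and attempts < 50 * n_waters:
        attempts += 1
        anchor = polar[rng.integers(len(polar))]
        direction = anchor.pos - centroid + rng.normal(0, 0.8, 3)
        nd = np.linalg.norm(direction)
        if nd < 1e-6:
            continue
        p = anchor.pos + direction / nd * 2.8
        if np.any(p < 1.2) or np.any(p > extent - 1.2):
            continue
        all_pos = np.array([a.pos for a in model.atoms])
        if np.min(np.linalg.norm(all_pos - p, axis=1)) < 2.4:
            continue
        wser += 1
        placed += 1
        model.atoms.append(Atom(serial=wser, name="O", element="O",
                                is_deuterium=False, chain="W",
                                resnum=placed, resname="HOH", pos=p,
                                b_iso=b_base + 5.0, occ=1.0))
    classify_hydrogens(model)
    per_res = {r: 4 + len(chem.SIDECHAIN_RECIPES[r]) for r in set(seq)}
    model.info = {  # type: ignore[attr-defined]
        "sequence": seq,
        "protein_atoms": sum(per_res[r] for r in seq),
        "waters": placed,
        "atom_count": sum(per_res[r] for r in seq) + placed,
        "seed": seed,
    }
    return model


def make_xn_pair(scenario: CrystalScenario) -> tuple[Model, Model]:
    """X-ray / neutron model pair sharing a fold but differing by X--H
    convention, a fraction of divergent waters and a uniform ADP offset.

    Ground truth for the water correspondence is attached as
    ``neutron_model.info["water_truth"]``.
    """
    rng = np.random.default_rng(scenario.seed)
    base = make_toy_structure(scenario.n_residues, seed=scenario.seed,
                              n_waters=scenario.n_waters)
    if scenario.hd_scheme == "exchanged":
        neutron = build_exchange_sites(base, "all-labile")
    elif scenario.hd_scheme == "perdeuterated":
        neutron = build_exchange_sites(base, "perdeuterate")
    elif scenario.hd_scheme == "hydrogenated":
        neutron = base.copy()
    else:
        raise ValueError(f"unknown H/D scheme {scenario.hd_scheme!r}")
    neutron.convention = "nuclear"
    neutron.info = dict(base.info)  # type: ignore[attr-defined]

    xray = convert_for_xray(neutron)
    xray.info = dict(base.info)  # type: ignore[attr-defined]
    for a in xray.atoms:
        a.b_iso = min(a.b_iso + scenario.adp_offset, 999.0)

    # diverge a fraction of the waters: half displaced (> 0.5 A) in the
    # X-ray model, half deleted from the neutron model (X-ray models
    # typically carry more waters)
    waters = [i for i in xray.waters()]
    n_div = int(round(scenario.divergent_water_fraction * len(waters)))
    div = list(rng.choice(waters, size=n_div, replace=False)) if n_div else []
    displaced, deleted = div[: (n_div + 1) // 2], div[(n_div + 1) // 2:]
    for i in displaced:
        step = rng.normal(0, 1.0, 3)
        step = step / np.linalg.norm(step) * rng.uniform(0.8, 1.5)
        xray.atoms[i].pos = xray.atoms[i].pos + step
    del_keys = {(xray.atoms[i].chain, xray.atoms[i].resnum) for i in deleted}
    neutron.atoms = [a for a in neutron.atoms
                     if not (a.is_water and (a.chain, a.resnum) in del_keys)]

    neutron.info["water_truth"] = {  # type: ignore[attr-defined]
        "common": len(waters) - n_div,
        "displaced": len(displaced),
        "deleted_from_neutron": len(deleted),
    }
    if scenario.xray_altloc:
        _add_altloc(xray, rng)
    return xray, neutron


def _add_altloc(model: Model, rng) -> None:
    """Give one Ser OG an alternative conformation in the X-ray model."""
    for i, a in enumerate(model.atoms):
        if a.resname == "SER" and a.name == "OG":
            a.altloc = "A"
            a.occ = 0.6
            b = replace(a, serial=max(x.serial for x in model.atoms) + 1,
                        altloc="B", occ=0.4,
                        pos=a.pos + rng.normal(0, 0.4, 3))
            model.atoms.insert(i + 1, b)
            return


def simulate_data(model: Model, radiation: str, d_min: float,
                  completeness: float = 1.0, noise: float = 0.0,
                  seed: int = 0, free_fraction: float = 0.05) -> ReflectionSet:
    """F_obs = |F_calc| (1 + eps), eps ~ N(0, noise), randomly thinned to the
    completeness target, with seeded free flags."""
    if not 0 < completeness <= 1:
        raise ValueError("completeness must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    hkl = unique_reflections(model.cell, model.symops, d_min)
    f_true = np.abs(calc_structure_factors(model, hkl, radiation))
    eps = rng.normal(0.0, noise, len(hkl)) if noise > 0 else np.zeros(len(hkl))
    f_obs = np.maximum(f_true * (1.0 + eps), 1e-6)
    sigma = np.maximum(noise, 1e-3) * f_obs
    if completeness < 1.0:
        keep = rng.random(len(hkl)) < completeness
        if keep.sum() < 10:
            keep[:10] = True
        hkl, f_obs, sigma = hkl[keep], f_obs[keep], sigma[keep]
    refl = ReflectionSet(hkl, f_obs, sigma, model.cell, radiation=radiation)
    if free_fraction > 0:
        refl.free = assign_free_flags(refl, free_fraction, seed + 1).flags
    return refl
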