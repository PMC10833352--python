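"""The refinement engine: gradient-driven minimization of coordinates, B
factors and exchange occupancies, ordered-solvent update, macrocycle
orchestration and restraint-weight grid optimization.

The total target is ``T_data + w * T_geom`` where the data term is the
normalized amplitude least squares of :mod:`jointxn.targets` and ``w`` is
the geometry weight (auto-estimated by gradient-norm matching when not
given).  Minimization uses a quasi-Newton method with line search
(L-BFGS-B); accepted steps never increase the target.  B factors are
floored at 1 A^2 through bounds, and exchange-site deuterium occupancies
are refined through a logistic transform so occ_D stays in [0, 1] and
occ_H + occ_D = 1 holds exactly at all times.

Deuterium records of exchange sites are *slaved*: their position and B
follow the H partner, and gradients on the D record fold back onto it.
Riding hydrogens are frozen during coordinate minimization and re-placed
from parent geometry at macrocycle boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .model_core import Atom, Model
from .restraints import (RestraintSet, build_reference_restraints, build_restraints,
                         classify_hydrogens, geometry_residual,
                         place_riding_hydrogens, sync_exchange_positions)
from .scattering import ReflectionSet, calc_map, structure_factor_parts
from .targets import TargetResult, lsq_target_and_gradients, r_factor, r_factor_model

DataTerm = tuple[float, ReflectionSet, str]   # (weight, reflections, radiation)


@dataclass
class RefinementStrategy:
    refine_xyz: bool = True
    refine_b: bool = True
    refine_occ: bool = True
    solvent_update: bool = False
    h_mode: str = "riding"            # riding | individual | hybrid
    macrocycles: int = 3
    weight: float | None = None       # geometry weight; None = auto
    optimize_weights: bool = False
    max_iter: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.macrocycles < 1:
            raise ValueError("need at least one macrocycle")
        if self.h_mode not in ("riding", "individual", "hybrid"):
            raise ValueError(f"unknown H treatment {self.h_mode!r}")


@dataclass
class RefinementTrace:
    rows: list[dict] = field(default_factory=list)

    def append(self, **kw):
        self.rows.append(kw)

    def __len__(self):
        return len(self.rows)

    def last(self) -> dict:
        return self.rows[-1]


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------

def _slaved_deuterium(model: Model) -> set[int]:
    return {s.i_d for s in model.exchange_sites()}


def free_coordinate_indices(model: Model, h_mode: str) -> list[int]:
    """Atoms whose coordinates are refinable under the given H treatment."""
    classify_hydrogens(model)
    slaved = _slaved_deuterium(model)
    out = []
    for i, a in enumerate(model.atoms):
        if i in slaved:
            continue
        if a.is_hydrogen and h_mode in ("riding", "hybrid") and a.h_class == "riding":
            continue
        out.append(i)
    return out


def _fold_slaved(model: Model, g_xyz: np.ndarray, g_b: np.ndarray | None = None):
    for s in model.exchange_sites():
        g_xyz[s.i_h] += g_xyz[s.i_d]
        g_xyz[s.i_d] = 0.0
        if g_b is not None:
            g_b[s.i_h] += g_b[s.i_d]
            g_b[s.i_d] = 0.0


def _data_target(model: Model, data_terms: list[DataTerm]) -> TargetResult:
    n = len(model.atoms)
    total = TargetResult(0.0, np.zeros((n, 3)), np.zeros(n))
    for weight, refl, radiation in data_terms:
        if weight == 0:
            continue
        t = lsq_target_and_gradients(model, refl, radiation)
        total.value += weight * t.value
        total.g_xyz += weight * t.g_xyz
        total.g_b += weight * t.g_b
        for eid, g in t.g_occd.items():
            total.g_occd[eid] = total.g_occd.get(eid, 0.0) + weight * g
    return total


def auto_weight(model: Model, data_terms: list[DataTerm],
                restraints: RestraintSet) -> float:
    """Geometry weight from gradient-norm matching at the current model."""
    t = _data_target(model, data_terms)
    _gv, gg = geometry_residual(model, restraints)
    nd = float(np.linalg.norm(t.g_xyz))
    ng = float(np.linalg.norm(gg))
    if ng < 1e-12 or nd < 1e-12:
        return 1.0
    return nd / ng


# ---------------------------------------------------------------------------
# Minimizers
# ---------------------------------------------------------------------------

def minimize(model: Model, target_fn, free_idx: list[int],
             max_iter: int = 100) -> tuple[Model, list[float]]:
    """Generic coordinate minimizer.

    ``target_fn(model) -> (value, grad(N, 3))``; only the atoms in
    ``free_idx`` move (slaved deuterium follows its H partner).  Returns the
    updated model and the per-iteration target trace (non-increasing over
    accepted steps).
    """
    model = model.copy()
    idx = np.asarray(free_idx, dtype=int)
    if len(idx) == 0:
        return model, []
    x0 = model.positions()[idx].ravel()
    trace: list[float] = []
    last = {"v": None}

    def fun(x):
        xyz = model.positions()
        xyz[idx] = x.reshape(-1, 3)
        model.set_positions(xyz)
        sync_exchange_positions(model)
        v, g = target_fn(model)
        if not np.isfinite(v):
            raise FloatingPointError("non-finite refinement target")
        g = g.copy()
        _fold_slaved(model, g)
        last["v"] = v
        return v, g[idx].ravel()

    res = _scipy_minimize(fun, x0, jac=True, method="L-BFGS-B",
                          callback=lambda xk: trace.append(last["v"]),
                          options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10})
    fun(res.x)
    trace.append(last["v"])
    return model, trace


def minimize_coordinates(model: Model, data_terms: list[DataTerm],
                         restraints: RestraintSet, w_geom: float,
                         h_mode: str = "individual",
                         max_iter: int = 60) -> tuple[Model, list[float]]:
    def target(m):
        t = _data_target(m, data_terms)
        gv, gg = geometry_residual(m, restraints)
        return t.value + w_geom * gv, t.g_xyz + w_geom * gg

    return minimize(model, target, free_coordinate_indices(model, h_mode), max_iter)


def _riding_b_parents(model: Model, h_mode: str) -> dict[int, int]:
    """Riding hydrogens ride their parent's ADP too: map H index -> parent
    index for B slaving (riding/hybrid treatments only)."""
    if h_mode == "individual":
        return {}
    classify_hydrogens(model)
    out = {}
    for i, a in enumerate(model.atoms):
        if a.is_hydrogen and a.h_class == "riding" and not (
                a.is_deuterium and a.exch_id is not None):
            j = model.hydrogen_parent(i)
            if j is not None:
                out[i] = j
    return out


def minimize_b_factors(model: Model, data_terms: list[DataTerm],
                       max_iter: int = 40, b_min: float = 1.0,
                       h_mode: str = "individual") -> Model:
    model = model.copy()
    slaved = _slaved_deuterium(model)
    b_parents = _riding_b_parents(model, h_mode)
    idx = np.array([i for i in range(len(model.atoms))
                    if i not in slaved and i not in b_parents], dtype=int)
    b0 = model.b_factors()[idx]

    def sync_b():
        for h, p in b_parents.items():
            model.atoms[h].b_iso = model.atoms[p].b_iso
        sync_exchange_positions(model)

    def fun(b):
        for i, bi in zip(idx, b):
            model.atoms[i].b_iso = float(bi)
        sync_b()
        t = _data_target(model, data_terms)
        gfold = t.g_b.copy()
        for s in model.exchange_sites():
            gfold[s.i_h] += gfold[s.i_d]
            gfold[s.i_d] = 0.0
        for h, p in b_parents.items():
            gfold[p] += gfold[h]
            gfold[h] = 0.0
        return t.value, gfold[idx]

    res = _scipy_minimize(fun, np.maximum(b0, b_min), jac=True, method="L-BFGS-B",
                          bounds=[(b_min, None)] * len(idx),
                          options={"maxiter": max_iter, "ftol": 1e-12})
    fun(res.x)
    return model


def minimize_occupancies(model: Model, data_terms: list[DataTerm],
                         max_iter: int = 30) -> Model:
    """Refine exchange-site occ_D through a logistic transform; occ_H is
    always the exact complement."""
    model = model.copy()
    sites = model.exchange_sites()
    if not sites:
        return model
    occ0 = np.clip([s.occ_d(model) for s in sites], 1e-4, 1 - 1e-4)
    u0 = np.log(occ0 / (1 - occ0))

    def fun(u):
        occ = 1.0 / (1.0 + np.exp(-u))
        for s, q in zip(sites, occ):
            model.atoms[s.i_d].occ = float(q)
            model.atoms[s.i_h].occ = float(1.0 - q)
        t = _data_target(model, data_terms)
        g = np.array([t.g_occd.get(s.exch_id, 0.0) for s in sites])
        return t.value, g * occ * (1.0 - occ)

    res = _scipy_minimize(fun, u0, jac=True, method="L-BFGS-B",
                          options={"maxiter": max_iter, "ftol": 1e-14})
    fun(res.x)
    return model


# ---------------------------------------------------------------------------
# Ordered-solvent update
# ---------------------------------------------------------------------------

def _min_image_dists(cell, points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Minimum-image distances (len(points), len(targets)) under P1 translations."""
    fp = cell.fractionalize(points)
    ft = cell.fractionalize(targets)
    d = fp[:, None, :] - ft[None, :, :]
    d -= np.round(d)
    cart = d @ cell.orth.T
    return np.linalg.norm(cart, axis=2)


def update_solvent(model: Model, refl: ReflectionSet, radiation: str,
                   add_threshold: float = 3.0, keep_threshold: float = 1.0,
                   dist_min: float = 2.2, dist_max: float = 3.5,
                   b_offset: float = 5.0) -> Model:
    """Remove waters with weak model-phased 2Fo-Fc density and add waters at
    strong difference-map peaks near polar atoms.

    Added waters get B = (mean protein B) + ``b_offset``.
    """
    model = model.copy()
    F, _parts, _ = structure_factor_parts(model, refl.hkl, radiation)
    fc = np.abs(F)
    work = np.ones(len(refl), bool) if refl.free is None else ~refl.free
    rep = r_factor(refl.f_obs[work], fc[work])
    k = rep.scale
    phase = np.where(fc > 0, F / np.where(fc > 0, fc, 1.0), 1.0)
    m2 = (2.0 * refl.f_obs / k - fc) * phase
    diff = (refl.f_obs / k - fc) * phase
    map2 = calc_map(refl.hkl, m2, model.cell)
    mapd = calc_map(refl.hkl, diff, model.cell)

    # removal pass
    drop_keys = set()
    for i in model.waters():
        a = model.atoms[i]
        if a.name == "O" or a.element == "O":
            if map2.value_at(a.pos) < keep_threshold:
                drop_keys.add((a.chain, a.resnum))
    model.atoms = [a for a in model.atoms
                   if not (a.is_water and (a.chain, a.resnum) in drop_keys)]

    # addition pass: difference-map peaks
    grid = mapd.normalized()
    peak_mask = grid > add_threshold
    for ax in range(3):
        for shift in (1, -1):
            peak_mask &= grid >= np.roll(grid, shift, axis=ax)
    peaks = np.argwhere(peak_mask)
    if len(peaks) == 0:
        return model
    n = np.array(grid.shape)
    # parabolic sub-grid interpolation per axis
    frac_peaks = []
    heights = []
    for ijk in peaks:
        offs = np.zeros(3)
        for ax in range(3):
            im = tuple((ijk + np.eye(3, dtype=int)[ax] * s) % n for s in (-1, 1))
            fm, fp = grid[im[0][0], im[0][1], im[0][2]], grid[im[1][0], im[1][1], im[1][2]]
            f0 = grid[tuple(ijk)]
            denom = fm - 2 * f0 + fp
            if abs(denom) > 1e-9:
                offs[ax] = float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))
        frac_peaks.append((ijk + offs) / n)
        heights.append(grid[tuple(ijk)])
    cart = model.cell.orthogonalize(np.array(frac_peaks))
    order = np.argsort(heights)[::-1]

    all_pos = model.positions()
    polar = np.array([a.pos for a in model.atoms if a.element in ("N", "O", "S")])
    prot_b = [a.b_iso for a in model.atoms if not a.is_water and a.element != "H"]
    new_b = float(np.mean(prot_b)) + b_offset if prot_b else 20.0
    wnums = [a.resnum for a in model.atoms if a.is_water and a.chain == "W"]
    next_num = max(wnums, default=0) + 1
    max_serial = max((a.serial for a in model.atoms), default=0)
    added = []
    for oi in order:
        p = cart[oi]
        d_all = _min_image_dists(model.cell, p[None, :], all_pos)[0] if len(all_pos) else np.array([9.9])
        if d_all.min() < dist_min:
            continue
        if len(polar):
            d_pol = _min_image_dists(model.cell, p[None, :], polar)[0]
            if not np.any((d_pol >= dist_min) & (d_pol <= dist_max)):
                continue
        if added:
            d_new = _min_image_dists(model.cell, p[None, :], np.array(added))[0]
            if d_new.min() < dist_min:
                continue
        max_serial += 1
        model.atoms.append(Atom(serial=max_serial, name="O", element="O",
                                is_deuterium=False, chain="W", resnum=next_num,
                                resname="HOH", pos=p, b_iso=new_b, occ=1.0))
        added.append(p)
        next_num += 1
    return model


# ---------------------------------------------------------------------------
# Macrocycles
# ---------------------------------------------------------------------------

def refine_macrocycles(model: Model, refl: ReflectionSet | list[DataTerm],
                       strategy: RefinementStrategy, radiation: str = "neutron",
                       reference: Model | None = None, ref_sigma: float = 2.5,
                       ref_limit: float = 15.0,
                       restraints: RestraintSet | None = None) -> tuple[Model, RefinementTrace]:
    """Run macrocycles of (riding re-placement) -> coordinates -> B ->
    occupancies -> solvent update, recording R statistics per cycle.

    ``refl`` may be a single reflection set (with ``radiation``) or a list
    of weighted data terms for combined-target refinement.  ``reference``
    adds top-out reference-model torsion restraints rebuilt every cycle.
    ``restraints`` overrides the automatically built bond/angle set (it is
    then the caller's duty to keep indices valid; solvent update is
    disabled in that case).
    """
    data_terms: list[DataTerm] = (refl if isinstance(refl, list)
                                  else [(1.0, refl, radiation)])
    model = model.copy()
    classify_hydrogens(model)
    trace = RefinementTrace()
    if not (strategy.refine_xyz or strategy.refine_b or strategy.refine_occ
            or strategy.solvent_update):
        for _c in range(strategy.macrocycles):
            trace.append(**_report_row(model, data_terms, None, 0.0))
        return model, trace

    w = strategy.weight

    for cycle in range(strategy.macrocycles):
        rs = restraints if restraints is not None else build_restraints(model)
        if reference is not None:
            rs.reference_torsions = build_reference_restraints(
                model, reference, sigma=ref_sigma, limit=ref_limit)
        if w is None:
            w = auto_weight(model, data_terms, rs)
        if strategy.h_mode in ("riding", "hybrid"):
            place_riding_hydrogens(model)
        target_value = None
        if strategy.refine_xyz:
            model, tr = minimize_coordinates(model, data_terms, rs, w,
                                             h_mode=strategy.h_mode,
                                             max_iter=strategy.max_iter)
            if strategy.h_mode in ("riding", "hybrid"):
                place_riding_hydrogens(model)
            target_value = tr[-1] if tr else None
        if strategy.refine_b:
            model = minimize_b_factors(model, data_terms, max_iter=strategy.max_iter,
                                       h_mode=strategy.h_mode)
        if strategy.refine_occ and model.exchange_sites():
            model = minimize_occupancies(model, data_terms)
        if strategy.solvent_update and restraints is None:
            weight0, refl0, rad0 = data_terms[0]
            model = update_solvent(model, refl0, rad0)
        trace.append(**_report_row(model, data_terms, target_value, w))
    return model, trace


def _report_row(model: Model, data_terms: list[DataTerm],
                target_value, weight) -> dict:
    row: dict = {"weight": weight, "target": target_value,
                 "n_waters": len({(model.atoms[i].chain, model.atoms[i].resnum)
                                  for i in model.waters()})}
    for wgt, refl, radiation in data_terms:
        rep = r_factor_model(model, refl, radiation)
        row[f"r_work_{radiation}"] = rep.r_work
        row[f"r_free_{radiation}"] = rep.r_free
        row[f"r_gap_{radiation}"] = rep.r_gap
    first_rad = data_terms[0][2]
    row["r_work"] = row[f"r_work_{first_rad}"]
    row["r_free"] = row[f"r_free_{first_rad}"]
    row["r_gap"] = row[f"r_gap_{first_rad}"]
    return row


# ---------------------------------------------------------------------------
# Weight grid search
# ---------------------------------------------------------------------------

def default_weight_grid(model: Model, data_terms: list[DataTerm],
                        restraints: RestraintSet | None = None,
                        factors=(0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0)) -> list[float]:
    rs = restraints if restraints is not None else build_restraints(model)
    w0 = auto_weight(model, data_terms, rs)
    return [w0 * f for f in factors]


def optimize_weight(model: Model, refl: ReflectionSet | list[DataTerm],
                    strategy: RefinementStrategy, radiation: str = "neutron",
                    candidates: list[float] | None = None,
                    reference: Model | None = None,
                    restraints: RestraintSet | None = None) -> tuple[float, list[tuple[float, float]]]:
    """Grid search over geometry weights, each tried by a short refinement
    from the same starting model; returns the weight with the lowest R_free
    (ties broken toward the larger, more restrained, weight)."""
    data_terms: list[DataTerm] = (refl if isinstance(refl, list)
                                  else [(1.0, refl, radiation)])
    if candidates is None:
        candidates = default_weight_grid(model, data_terms, restraints)
    if len(candidates) < 1:
        raise ValueError("need at least one weight candidate")
    results = []
    for w in candidates:
        st = _dc_replace(strategy, weight=w, macrocycles=1,
                         optimize_weights=False, solvent_update=False)
        _m, tr = refine_macrocycles(model, data_terms, st, reference=reference,
                                    restraints=restraints)
        rfree = tr.last()["r_free"]
        score = rfree if rfree is not None else tr.last()["r_work"]
        results.append((w, score))
    best = min(results, key=lambda t: (round(t[1], 12), -t[0]))
    return best[0], results
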