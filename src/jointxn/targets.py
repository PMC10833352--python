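"""Crystallographic targets, R statistics, free flags and data disambiguation.

The data target is amplitude least squares on the working set,

    T = sum_w (|F_obs| - k |F_calc|)^2 / sum_w |F_obs|^2,

with a linear scale factor k = sum |F_obs||F_calc| / sum |F_calc|^2 derived
from the working reflections.  Because k is the least-squares minimizer of T
in k, gradients taken at fixed k are exact.  Analytic gradients are provided
with respect to Cartesian coordinates, isotropic B factors and exchange-site
deuterium occupancies.

The combined X-ray + neutron target is the flat weighted sum

    T = w_x T_xray + w_n T_neutron + w T_geom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import Model, convert_for_xray
from .scattering import ReflectionSet, structure_factor_parts


@dataclass
class RFactorReport:
    r_work: float
    r_free: float | None
    scale: float
    n_work: int
    n_free: int

    @property
    def r_gap(self) -> float | None:
        if self.r_free is None:
            return None
        return self.r_free - self.r_work


@dataclass
class FreeFlagSet:
    flags: np.ndarray          # True = free
    fraction: float
    seed: int


@dataclass
class JointTargetSpec:
    w_x: float = 1.0
    w_n: float = 1.0
    w: float = 1.0

    def __post_init__(self):
        if min(self.w_x, self.w_n, self.w) < 0:
            raise ValueError("weights must be non-negative")


def assign_free_flags(refl: ReflectionSet, fraction: float, seed: int) -> FreeFlagSet:
    """Seeded work/free assignment; free count is round(fraction * N)."""
    if len(refl) == 0:
        raise ValueError("empty reflection set")
    if not 0.0 <= fraction <= 0.5:
        raise ValueError("free fraction must lie in [0, 0.5]")
    n_free = int(round(fraction * len(refl)))
    rng = np.random.default_rng(seed)
    flags = np.zeros(len(refl), dtype=bool)
    flags[rng.choice(len(refl), size=n_free, replace=False)] = True
    return FreeFlagSet(flags, fraction, seed)


def scale_factor(f_obs: np.ndarray, f_calc: np.ndarray) -> float:
    denom = float(np.sum(f_calc * f_calc))
    if denom == 0:
        raise ValueError("zero calculated amplitudes")
    return float(np.sum(f_obs * f_calc)) / denom


def r_factor(f_obs: np.ndarray, f_calc: np.ndarray,
             free: np.ndarray | None = None) -> RFactorReport:
    """R = sum | |F_obs| - k |F_calc| | / sum |F_obs| with the work-set scale
    reused for the free set."""
    f_obs = np.abs(np.asarray(f_obs, dtype=float))
    f_calc = np.abs(np.asarray(f_calc, dtype=float))
    work = np.ones(len(f_obs), dtype=bool) if free is None else ~np.asarray(free)
    if work.sum() == 0:
        raise ValueError("empty work selection")
    if np.sum(f_obs[work]) == 0:
        raise ValueError("zero observed amplitudes")
    k = scale_factor(f_obs[work], f_calc[work])

    def _r(sel):
        return float(np.sum(np.abs(f_obs[sel] - k * f_calc[sel])) / np.sum(f_obs[sel]))

    r_work = _r(work)
    r_free = None
    n_free = 0
    if free is not None and np.asarray(free).sum() > 0:
        r_free = _r(np.asarray(free))
        n_free = int(np.asarray(free).sum())
    return RFactorReport(r_work, r_free, k, int(work.sum()), n_free)


def r_factor_model(model: Model, refl: ReflectionSet, radiation: str) -> RFactorReport:
    from .scattering import calc_structure_factors
    f_calc = np.abs(calc_structure_factors(model, refl.hkl, radiation))
    return r_factor(refl.f_obs, f_calc, refl.free)


@dataclass
class TargetResult:
    value: float
    g_xyz: np.ndarray                  # (N, 3) per-atom Cartesian gradient
    g_b: np.ndarray                    # (N,) B-factor gradient
    g_occd: dict[int, float] = field(default_factory=dict)  # exch_id -> dT/docc_D
    scale: float = 1.0


def lsq_target_and_gradients(model: Model, refl: ReflectionSet,
                             radiation: str) -> TargetResult:
    """Work-set least-squares target with analytic gradients.

    Gradients for a deuterium record of an exchange site are accumulated on
    the site's occ_D; its coordinates/B are slaved to the H partner by the
    refinement engine, so positional gradients are reported per record and
    combined there.
    """
    work = np.ones(len(refl), dtype=bool) if refl.free is None else ~refl.free
    sub = refl.subset(work)
    F, parts, _ = structure_factor_parts(model, sub.hkl, radiation)
    f_calc = np.abs(F)
    f_obs = sub.f_obs
    norm = float(np.sum(f_obs ** 2))
    if norm == 0:
        raise ValueError("zero observed amplitudes")
    k = scale_factor(f_obs, f_calc)
    resid = f_obs - k * f_calc
    value = float(np.sum(resid ** 2)) / norm

    # dT/d|F_h| ; the dk/dparam term vanishes because k minimizes T in k
    w = (-2.0 * k / norm) * resid                        # (M,)
    safe = np.where(f_calc > 0, f_calc, 1.0)
    unit = np.conj(F) / safe                             # d|F| = Re(unit dF)
    wu = w * unit                                        # (M,)

    stol2 = 1.0 / (4.0 * sub.d ** 2)
    g_xyz = parts.xyz_gradient(wu)
    g_b = np.real(wu @ (-stol2[:, None] * parts.contrib))
    g_occd: dict[int, float] = {}
    for site in model.exchange_sites():
        gu = np.real(wu @ (parts.unit[:, site.i_d] - parts.unit[:, site.i_h]))
        g_occd[site.exch_id] = float(gu)
    return TargetResult(value, g_xyz, g_b, g_occd, k)


def combined_target(spec: JointTargetSpec, model: Model,
                    xray_refl: ReflectionSet | None,
                    neutron_refl: ReflectionSet | None,
                    restraints=None) -> TargetResult:
    """Flat weighted sum w_x T_xray + w_n T_neutron + w T_geom."""
    if spec.w_x == spec.w_n == spec.w == 0:
        raise ValueError("all weights are zero")
    n = len(model.atoms)
    total = TargetResult(0.0, np.zeros((n, 3)), np.zeros(n))
    for weight, refl, radiation in ((spec.w_x, xray_refl, "xray"),
                                    (spec.w_n, neutron_refl, "neutron")):
        if weight == 0 or refl is None:
            continue
        t = lsq_target_and_gradients(model, refl, radiation)
        total.value += weight * t.value
        total.g_xyz += weight * t.g_xyz
        total.g_b += weight * t.g_b
        for eid, g in t.g_occd.items():
            total.g_occd[eid] = total.g_occd.get(eid, 0.0) + weight * g
    if spec.w > 0 and restraints is not None:
        from .restraints import geometry_residual
        gv, gg = geometry_residual(model, restraints)
        total.value += spec.w * gv
        total.g_xyz += spec.w * gg
    return total


# ---------------------------------------------------------------------------
# X-ray / neutron data-array disambiguation
# ---------------------------------------------------------------------------

@dataclass
class DisambiguationResult:
    labels: tuple[str, str]            # per input array: xray|neutron|ambiguous
    r_matrix: np.ndarray               # 2x2: rows = arrays, cols = (xray, neutron)
    margins: tuple[float, float]


def disambiguate_arrays(model: Model, array_a: ReflectionSet,
                        array_b: ReflectionSet,
                        margin_threshold: float = 0.02) -> DisambiguationResult:
    """Label two reflection arrays of unknown radiation type.

    Computes R for each (array, scattering-table) combination — the wrong
    table gives a substantially higher R — and labels each array with the
    radiation giving the lower value; arrays whose R difference is below the
    margin are labelled ambiguous.
    """
    from .scattering import calc_structure_factors
    xray_model = convert_for_xray(model)
    rmat = np.zeros((2, 2))
    for i, arr in enumerate((array_a, array_b)):
        fx = np.abs(calc_structure_factors(xray_model, arr.hkl, "xray"))
        fn = np.abs(calc_structure_factors(model, arr.hkl, "neutron"))
        rmat[i, 0] = r_factor(arr.f_obs, fx).r_work
        rmat[i, 1] = r_factor(arr.f_obs, fn).r_work
    margins = tuple(abs(rmat[i, 0] - rmat[i, 1]) for i in range(2))
    labels = []
    for i in range(2):
        if margins[i] < margin_threshold:
            labels.append("ambiguous")
        else:
            labels.append("xray" if rmat[i, 0] < rmat[i, 1] else "neutron")
    return DisambiguationResult(tuple(labels), rmat, margins)
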