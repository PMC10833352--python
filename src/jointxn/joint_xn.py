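"""Joint X-ray + neutron refinement: the legacy single-model protocol and
the two-model protocol with cross-model information flow.

Legacy joint refinement minimizes one combined target
w_x T_xray + w_n T_neutron + w T_geom for a single model — appropriate when
the X-ray and neutron crystals are truly identical, but a single model
cannot satisfy two data sets whose solvent or side-chain details differ.

The two-model protocol refines an X-ray model (electron-cloud X--H lengths)
against the X-ray data and a neutron model (nuclear lengths) against the
neutron data.  Each cycle the refined X-ray model — typically the more
accurate one — supplies top-out reference torsion restraints to the neutron
model, and the X-ray model retrieves the orientations of rotatable
hydrogens that are unambiguously resolved in the neutron map.  Waters
evolve independently in the two models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis_tools import ComparisonReport, compare_models
from .model_core import Model
from .refine import (RefinementStrategy, RefinementTrace, refine_macrocycles,
                     update_solvent)
from .restraints import (classify_hydrogens, measure_h_torsion, set_h_torsion)
from .scattering import MapGrid, ReflectionSet, calc_map, structure_factor_parts
from .targets import JointTargetSpec, r_factor


@dataclass
class JointXNJob:
    xray_model: Model
    xray_data: ReflectionSet
    neutron_model: Model
    neutron_data: ReflectionSet
    cycles: int = 3
    ref_sigma: float = 2.5            # degrees
    ref_limit: float = 15.0           # degrees
    transfer_threshold: float = 2.5   # neutron-map r.m.s.d. units
    use_reference: bool = True
    transfer_h: bool = True
    strategy_x: RefinementStrategy = field(default_factory=lambda: RefinementStrategy(
        h_mode="riding", macrocycles=1))
    strategy_n: RefinementStrategy = field(default_factory=lambda: RefinementStrategy(
        h_mode="riding", macrocycles=1))

    def __post_init__(self):
        if self.xray_model.convention != "electron-cloud":
            raise ValueError("X-ray model must carry the electron-cloud convention")
        if self.neutron_model.convention != "nuclear":
            raise ValueError("neutron model must carry the nuclear convention")


@dataclass
class JointXNResult:
    xray_model: Model
    neutron_model: Model
    trace_x: RefinementTrace
    trace_n: RefinementTrace
    comparison: ComparisonReport | None = None


def _matched_residues(a: Model, b: Model) -> int:
    keys_a = {(at.chain, at.resnum, at.resname) for at in a.atoms if not at.is_water}
    keys_b = {(at.chain, at.resnum, at.resname) for at in b.atoms if not at.is_water}
    return len(keys_a & keys_b)


def run_new_joint(job: JointXNJob, compare: bool = True) -> JointXNResult:
    """The two-model joint XN protocol.

    Per cycle: (1) refine the X-ray model against the X-ray data; (2) rebuild
    reference torsion restraints from it onto the neutron model; (3) refine
    the neutron model against the neutron data under those restraints;
    (4) transfer well-resolved rotatable-H orientations from the neutron
    model back to the X-ray model.
    """
    if _matched_residues(job.xray_model, job.neutron_model) == 0:
        raise ValueError("no matchable residues between the two models")
    xm = job.xray_model.copy()
    nm = job.neutron_model.copy()
    trace_x = RefinementTrace()
    trace_n = RefinementTrace()
    for _cycle in range(job.cycles):
        xm, tx = refine_macrocycles(xm, job.xray_data, job.strategy_x, "xray")
        trace_x.rows.extend(tx.rows)
        nm, tn = refine_macrocycles(
            nm, job.neutron_data, job.strategy_n, "neutron",
            reference=xm if job.use_reference else None,
            ref_sigma=job.ref_sigma, ref_limit=job.ref_limit)
        trace_n.rows.extend(tn.rows)
        if job.transfer_h:
            nmap = model_phased_map(nm, job.neutron_data, "neutron")
            xm = transfer_h_orientations(nm, nmap, xm, job.transfer_threshold)
    comparison = compare_models(xm, nm) if compare else None
    return JointXNResult(xm, nm, trace_x, trace_n, comparison)


def run_legacy_joint(model: Model, xray_refl: ReflectionSet,
                     neutron_refl: ReflectionSet, spec: JointTargetSpec,
                     strategy: RefinementStrategy) -> tuple[Model, RefinementTrace]:
    """Single-model joint refinement against the combined target
    w_x T_xray + w_n T_neutron + w T_geom."""
    if spec.w_x == spec.w_n == spec.w == 0:
        raise ValueError("all weights are zero")
    data_terms = []
    if spec.w_x > 0:
        data_terms.append((spec.w_x, xray_refl, "xray"))
    if spec.w_n > 0:
        data_terms.append((spec.w_n, neutron_refl, "neutron"))
    from dataclasses import replace
    # spec.w scales the geometry term: 0 disables it, otherwise it multiplies
    # the strategy's (possibly auto-estimated) geometry weight
    if spec.w == 0:
        st = replace(strategy, weight=0.0)
    elif strategy.weight is not None:
        st = replace(strategy, weight=spec.w * strategy.weight)
    else:
        st = strategy
    return refine_macrocycles(model, data_terms, st)


def model_phased_map(model: Model, refl: ReflectionSet, radiation: str,
                     kind: str = "2fofc") -> MapGrid:
    """Simplified model-phased map: (2|Fo|/k - |Fc|) exp(i phi_c) or
    (|Fo|/k - |Fc|) exp(i phi_c)."""
    F, _parts, _ = structure_factor_parts(model, refl.hkl, radiation)
    fc = np.abs(F)
    work = np.ones(len(refl), bool) if refl.free is None else ~refl.free
    k = r_factor(refl.f_obs[work], fc[work]).scale
    phase = np.where(fc > 0, F / np.where(fc > 0, fc, 1.0), 1.0)
    if kind == "2fofc":
        coeff = (2.0 * refl.f_obs / k - fc) * phase
    elif kind == "diff":
        coeff = (refl.f_obs / k - fc) * phase
    else:
        raise ValueError(f"unknown map kind {kind!r}")
    return calc_map(refl.hkl, coeff, model.cell)


def transfer_h_orientations(source: Model, source_map: MapGrid, dest: Model,
                            threshold: float = 2.5) -> Model:
    """Copy rotatable-H torsions from source to dest where the source map
    supports the source H position (value >= threshold in r.m.s.d. units).

    The hydrogen is rebuilt at dest's convention length; below-threshold
    sites are untouched.  Idempotent.
    """
    dest = dest.copy()
    classify_hydrogens(source)
    classify_hydrogens(dest)
    dest_index = {(a.chain, a.resnum, a.name): i for i, a in enumerate(dest.atoms)
                  if a.is_hydrogen and not (a.is_deuterium and a.exch_id is not None)}
    for i, a in enumerate(source.atoms):
        if not a.is_hydrogen or a.h_class != "rotatable" or a.is_water:
            continue
        if a.is_deuterium and a.exch_id is not None:
            continue  # H partner carries the site
        if np.isfinite(threshold) and source_map.value_at(a.pos) < threshold:
            continue
        if not np.isfinite(threshold):
            continue
        j = dest_index.get((a.chain, a.resnum, a.name))
        if j is None:
            continue
        meas = measure_h_torsion(source, i)
        if meas is None:
            continue
        _axis, torsion = meas
        set_h_torsion(dest, j, torsion)
    return dest
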