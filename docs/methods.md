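# Methods

`jointxn` implements a two-model joint X-ray/neutron (XN) refinement
protocol at desk scale, together with the machinery needed to exercise and
validate it on synthetic crystals: structure-factor calculation, amplitude
least-squares targets with analytic gradients, geometry and reference-model
restraints, a macrocycle refinement engine, perturbation ensembles and
model-comparison statistics. This note records the model, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## The scientific setting

Neutron diffraction sees nuclei, so hydrogen (b = −3.74 fm) and deuterium
(b = +6.67 fm) scatter as strongly as C/N/O, and protonation states become
observable — at the price of weaker data: neutron sets are almost always
lower-resolution and less complete than X-ray sets from the same system,
while the model must carry explicit H/D atoms, roughly doubling the atom
count. Two consequences drive the design:

1. **Overfitting.** Refining every H/D as an individual atom against weak
   neutron data buys a lower R_work at the cost of a wider R_free − R_work
   gap. The *riding* model (H positions rebuilt deterministically from
   parent geometry; only hydrogens with a genuine degree of freedom —
   hydroxyls, thiols, terminal methyls, water — refine) removes those
   parameters.
2. **Two crystals, two structures.** X-ray and neutron data usually come
   from different crystals. Their solvent structure and ADP levels differ,
   so a single model cannot satisfy both data sets. The legacy joint
   target `T = w_x·T_xray + w_n·T_neutron + w·T_geom` (implemented here as
   that flat weighted sum) shares one model; the two-model protocol instead
   refines an X-ray model against the X-ray data and a neutron model
   against the neutron data, coupling them through information flow rather
   than shared coordinates.

## The two-model protocol

Per cycle:

1. the X-ray model (electron-cloud X–H bond lengths) is refined against the
   X-ray data;
2. every heavy-atom torsion of the neutron model receives a reference
   restraint whose target is the equivalent torsion in the refined X-ray
   model;
3. the neutron model (nuclear X–H lengths) is refined against the neutron
   data under those restraints;
4. rotatable-hydrogen orientations that are well supported by the neutron
   map (default ≥ 2.5 r.m.s.d. at the H position) are copied back to the
   X-ray model, rebuilt at the electron-cloud bond length.

Waters evolve independently in the two models; nothing couples them. The
X-ray-first update order reflects the typical accuracy ordering of the two
data sets and is configurable. Reference restraints are rebuilt every
cycle so they track the X-ray model as it improves. Asn/Gln amide
orientation transfer from the neutron map is deliberately not implemented.

The reference-torsion residual is the **top-out** function

    rho(Δ) = (L²/σ²)·(1 − exp(−Δ²/L²)),   Δ wrapped to (−180°, 180°],

harmonic `(Δ/σ)²` near zero and flat at `L²/σ²` for large deviations, so a
genuinely different conformation is not forced onto the working model, and
no automated rotamer correction is ever applied. Defaults σ = 2.5°,
L = 15° are package choices (both configurable); the asymptotic scale was
picked so a restraint saturates at a 36-fold single-restraint penalty,
strong enough to guide a 0.5 Å-perturbed model yet weak next to the bonded
geometry terms.

## Targets and gradients

The data target is normalized amplitude least squares on the working set,
`T = Σ(|Fo| − k|Fc|)² / Σ|Fo|²` with the linear scale
`k = Σ|Fo||Fc|/Σ|Fc|²`. Because k is the minimizer of T in k, gradients
taken at fixed k are exact. This deliberately stands in for the
maximum-likelihood targets of production programs: all benchmarks run on
synthetic amplitudes generated without bulk solvent, anisotropy or model
incompleteness, which is precisely the regime where least squares is
appropriate. Difference maps are plain `(|Fo|/k − |Fc|)·exp(iφc)` and
`(2|Fo|/k − |Fc|)·exp(iφc)` syntheses; r.m.s.d.-unit thresholds apply to
these simplified maps.

Structure factors are computed by direct summation over explicit symmetry
operators with 4-Gaussian X-ray form factors (H, C, N, O, S) and coherent
neutron scattering lengths (b_H = −3.7390 fm, b_D = +6.671 fm,
b_S = +2.847 fm). An H/D exchange site is two co-located records with
complementary occupancies, so its neutron contribution
`occ_H·b_H + occ_D·b_D` falls out of the ordinary sum; for X-rays both
records use the hydrogen form factor. Analytic gradients with respect to
coordinates, B_iso and occ_D are contracted per symmetry operator without
materializing the (reflection × atom × 3) tensor.

## Refinement engine

Minimization is L-BFGS-B (bounded quasi-Newton with line search); accepted
steps never increase the target. Macrocycles run riding-H re-placement →
coordinate minimization → B minimization → exchange-occupancy minimization
→ optional ordered-solvent update.

* **Parameterization.** Exchange-site D records are slaved to the H
  partner (identical position and B; occ_H = 1 − occ_D exactly, enforced
  through a logistic transform of occ_D). Riding hydrogens are frozen
  during coordinate minimization and re-placed from parent geometry at
  macrocycle boundaries rather than chain-ruled onto parents; the analytic
  gradient contract therefore applies to individually parameterized atoms,
  and the lag introduced by frozen riding H vanishes over macrocycles.
  In riding mode, riding-H ADPs ride too (B_H = B_parent), which is the
  standard convention; rotatable H keep individual ADPs.
* **Bounds.** B_iso ≥ 1 Å² via box bounds; occ_D ∈ [0, 1] by construction.
* **Geometry weight.** `T = T_data + w·T_geom`, with w estimated by
  gradient-norm matching (‖g_data‖/‖g_geom‖) at the cycle start when not
  given. The optional grid search refines each of 7 candidates
  (0.03–30 × the estimate) for one short macrocycle from the same start
  and keeps the weight with the lowest R_free, ties broken toward the more
  restrained side.
* **Solvent update.** Waters whose 2Fo−Fc value at the O position is below
  1.0 r.m.s.d. are removed; difference-map peaks above 3.0 r.m.s.d.
  (parabolic sub-grid interpolation) that lie 2.2–3.5 Å from a polar atom
  and ≥ 2.2 Å from all atoms become new waters with
  B = mean protein B + 5 Å². The numeric thresholds are package choices.
* **Determinism.** All stochastic steps are seeded; identical seeds give
  bit-identical traces.

## Geometry, hydrogen conventions and the restraint dictionary

The toolkit carries a five-residue alphabet (GLY, ALA, SER, MET, TYR)
defined by internal-coordinate build recipes (NeRF construction). Ideal
bond lengths and angles are *measured once from the nuclear-convention
templates*, making fixtures and restraints self-consistent by
construction; bond σ = 0.02 Å, angle σ = 2.0°. Planarity, chirality and
non-bonded terms are not needed at the perturbation levels used and are
not implemented.

X–H bonds come in two conventions: nuclear (C–H 1.09, N–H 1.01, O–H 0.97,
S–H 1.34 Å) and electron-cloud at 0.85 × nuclear — the midpoint of the
observed 10–20% foreshortening of the bonding-electron centroid. The
model's convention tag decides which ideals riding placement and bond
restraints use; `convert_for_xray` switches a neutron model to the
electron-cloud convention, collapses exchange sites to single hydrogens
and strips water H/D entirely.

Labile-site rule: an H covalently bonded (within 1.2 × the covalent-radius
sum) to N, O or S exchanges; C-bound H do not. Exchange D records are
named D* after their H twin, as in deposited neutron structures.

## Synthetic crystals and what they do (not) show

`make_toy_structure` builds an ideal-geometry mixed-sequence helix
(Ser/Tyr for rotatable hydroxyls, Met for sulfur, explicit H) in a padded
P1 cell, with waters near polar atoms and B factors drawn around 15 Å²
(hydrogens inherit the parent ADP, the riding-ADP convention).
`make_xn_pair` derives an X-ray/neutron pair sharing the fold but
differing by X–H convention, a chosen fraction of divergent waters
(displaced > 0.5 Å or absent from the neutron model) and a uniform ADP
offset — the differences actually observed between separately refined
X-ray and neutron models. `simulate_data` produces
`F_obs = |F_calc|·(1 + ε)`, ε ~ N(0, noise), thinned to a completeness
target, with seeded free flags (10% free sets in the benchmarks — at the
~10³ reflections of these fixtures, 5% would leave fewer than the
conventional minimum of ~100 free reflections and make R_free too noisy
to read).

Benchmark conditions (fixed): riding-vs-individual uses 10-residue
exchanged fixtures, 2.5 Å neutron data at 60/75% completeness, 8% noise,
0.2 Å regularized starting perturbations, 3 macrocycles; the
new-joint-vs-neutron-only family uses pairs with 30% divergent waters and
a +3 Å² ADP offset, 1.8 Å/98% X-ray and 2.2 Å/75% neutron data, 0.5 Å
neutron starting perturbations, 3 coupling cycles. Problem sizes were
chosen so the full benchmark suite runs on a single CPU in minutes.

These fixtures lack bulk solvent, anisotropy, radiation damage, twinning,
alternate conformations (beyond an optional extra altloc), measurement
error structure beyond relative Gaussian noise, and real rotamer
distributions. Passing benchmarks therefore demonstrates that the
*mechanisms* behave as described — extra H parameters widen the R gap on
weak data; cross-model restraints reduce it — not that the magnitudes
match any particular real crystal.

## Perturbation ensembles

Ensembles are generated by a kick-and-regularize scheme: seeded Gaussian
displacement of all non-riding atoms, a short geometry-regularization
descent, then iterative isotropic rescaling of the displacement field
(riding H rebuilt each pass) until the all-atom r.m.s.d. is within 1% of
the requested level. The two documented protocol levels are 0.5 and
0.9 Å with 20 replicates each; `scripts/acceptance.py` regenerates both
calibrations from scratch. Molecular dynamics is not used; only the
r.m.s.d. contract is promised.

## Comparison machinery

Models are superposed on main-chain N/CA/C/O atoms (Kabsch, proper
rotation). Waters match one-to-one greedily in ascending distance under a
0.5 Å cutoff, considering symmetry images within one cell shell; unmatched
waters are *lone*, and lone percentages are reported against each model's
own water count. Greedy matching is checked against exhaustive assignment
on small configurations in the tests. Map-based reliability filtering
excludes residues with real-space CC < 0.9, waters with CC < 0.7 or an
altloc, and entities showing a difference-map value < −3 r.m.s.d. at an
atom with mean model-map density < 1.7 r.m.s.d. Rotamer changes are
proxied by chi-angle deltas > 30° rather than a rotamer library. ADP
histograms are over non-H atoms with protein/water partitions.

## Known limitations

* Least-squares target only; no ML, no bulk solvent, no anisotropic ADPs,
  no twinning, no anomalous scattering.
* Five residue types; no ligands or nucleic acids; symmetry limited to
  explicitly enumerated operators (fixtures are P1/P2₁).
* Only exchange-site occupancies refine; altloc occupancies are static.
* Riding-H gradients are not propagated to parents within a minimization.
* The water-divergence generator moves or deletes whole waters; it does
  not model partially occupied or split solvent sites.
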