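"""Simulate a neutron crystal and refine a perturbed model against it.

Builds a 6-residue H/D-exchanged fixture, simulates 2.0 A neutron
amplitudes, perturbs the model by 0.3 A and refines it back.  The printed
R_work should fall to roughly the noise floor (~4% for 5% amplitude noise)
and the final coordinate r.m.s.d. to the generating model should be well
under 0.1 A.
"""

from jointxn import (PerturbationSpec, RefinementStrategy, all_atom_rmsd,
                     build_exchange_sites, make_toy_structure, perturb_model,
                     refine_macrocycles, simulate_data)

truth = build_exchange_sites(make_toy_structure(6, seed=1), "all-labile")
data = simulate_data(truth, "neutron", d_min=2.0, noise=0.05, seed=1,
                     free_fraction=0.1)
print(f"fixture: {len(truth)} atoms, {len(truth.exchange_sites())} exchange "
      f"sites, {len(data)} reflections to {data.d_min:.1f} A")

start = perturb_model(truth, PerturbationSpec(0.3, replicates=1, seed=2))[0]
print(f"starting r.m.s.d. from truth: {all_atom_rmsd(start, truth):.3f} A")

strategy = RefinementStrategy(h_mode="riding", macrocycles=3, max_iter=60)
refined, trace = refine_macrocycles(start, data, strategy, "neutron")
for i, row in enumerate(trace.rows):
    print(f"cycle {i}: R_work {row['r_work']:.4f}  R_free {row['r_free']:.4f}  "
          f"R_gap {row['r_gap']:+.4f}")
print(f"final r.m.s.d. from truth: {all_atom_rmsd(refined, truth):.3f} A")
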