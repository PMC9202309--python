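"""Find one multidirectional egress pathway on the straight-channel fixture.

Builds the synthetic receptor (a thick LJ shell with one open channel and a
calibrated binding well), runs the adaptive search-and-pull loop, and prints
the termination status, the pathway label against the ground-truth gate, and
the pulling work.
"""

import numpy as np

import depull as dp

spec = dp.standard_fixtures()["STRAIGHT"]
system, channels = dp.make_system(spec)
system.pulled_atom_id = dp.select_pulled_atom(system)
print(f"receptor atoms: {len(system.receptor)}, "
      f"bound-pose energy: {dp.compute_nonbonded(system, system.ligand_positions()).total:.1f} kJ/mol")

result = dp.find_path(
    system,
    pathfinder_cfg=dp.PathfinderConfig(max_intervals=50),
    de_cfg=dp.DEConfig(population_size=48, iterations=30),
    engine_cfg=dp.EngineConfig(timestep=0.01, temperature=0.0),
    seed=0,
)

work = dp.compute_work(result.profile)
label = dp.classify_pathways([result], gates=dp.channel_gates(channels))[0]
print(f"status: {result.status} after {result.intervals_used} intervals "
      f"({result.intervals_used * result.tau:.0f} ps)")
print(f"pathway label: {label}")
print(f"W_pull = {work.w_pull:.1f} kJ/mol ({work.w_pull_kcal:.1f} kcal/mol), "
      f"F_max = {work.f_max:.1f} kJ/mol/nm")
print("final ligand CoM (nm):", np.round(result.waypoints[-1], 2))
# W_pull is the spring work integrated over the egress; it scales with the
# binding-well depth (6 kJ/mol here) plus friction and wall-contact losses.
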