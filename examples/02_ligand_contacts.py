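"""Ligand contact occupancy, hotspots and binding episodes.

Generates a G159D bundle with a two-state Markov ligand planted at 93%
bound fraction (the EGCG-like condition) plus an 80% D159-R83 salt
bridge, then prints the attachment fraction, episode statistics, the
contact hotspots (residues contacted > 10% of frames) and the
salt-bridge occupancy.
"""

from tncoupling.contacts import attachment, contact_profile, hotspots
from tncoupling.geometry import pair_bond_occupancy
from tncoupling.synthetic import LigandSpec, TrajectorySpec, gen_trajectory

spec = TrajectorySpec(
    n_frames=3750, n_runs=1, variant="G159D",
    saltbridge_occupancy=0.801,
    ligand=LigandSpec.for_bound_fraction(0.93),
    seed=2,
)
bundle = gen_trajectory(spec)
traj, topo, regions = bundle.runs[0], bundle.topology, bundle.regions

summ = attachment(traj, topo, regions["ligand"], regions["protein"])
prof = contact_profile(traj, topo, regions["ligand"])
occ, _ = pair_bond_occupancy(traj, topo, regions["asp159_carboxylate"],
                             regions["arg83_guanidinium"])

n_bound = sum(1 for e in summ.episodes if e.bound)
print(f"fraction of time attached : {summ.fraction_attached:.3f} (planted 0.93)")
print(f"binding episodes          : {n_bound} bound, mean length "
      f"{summ.mean_bound_episode_length:.0f} frames")
print(f"contact hotspots (>10%)   : {hotspots(prof)}")
print(f"D159-R83 bond occupancy   : {occ:.3f} (planted 0.801)")
print("A high salt-bridge occupancy rigidifies the mutant hinge; recoupling")
print("ligands lower it even without binding near that site.")
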