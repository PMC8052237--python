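"""Validate the lattice-Boltzmann solver against Hagen-Poiseuille duct flow.

A voxelized circular duct at low Reynolds number must reproduce
dp = 8 mu L Q / (pi R^4); the relative error quantifies solver fidelity.
"""

from rhinoflow.benchmarks import grid_refinement_pair, poiseuille_duct

b = poiseuille_duct(radius_vox=11.0, length_vox=80, u_lat=0.01)
print(f"Reynolds number        : {b.reynolds:.2f}")
print(f"simulated dp           : {b.dp_sim_pa:.4f} Pa")
print(f"Hagen-Poiseuille dp    : {b.dp_analytic_pa:.4f} Pa")
print(f"relative error         : {100 * b.rel_err:.2f} %   (target < 5 %)")

coarse, fine = grid_refinement_pair()
change = abs(fine.dp_sim_pa - coarse.dp_sim_pa) / abs(fine.dp_sim_pa)
print(f"mesh convergence: dp changes {100 * change:.2f} % when dx is halved")
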