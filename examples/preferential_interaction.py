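"""Preferential interaction coefficients from a toy trajectory.

Generates a periodic box with a bead solute and cation/anion/water
beads, with the ions depleted in the solute's first solvation shell
(protectant-like preferential exclusion), then computes per-ion Gamma
values at R = 12 A and the combined co-solute Gamma_23.
"""

import numpy as np

from ilstab import (
    TrajectorySpec, gamma_species, generate_trajectory, mddf,
    preferential_interaction,
)

spec = TrajectorySpec(
    n_frames=20,
    shell_bias={"cation": 0.5, "anion": 0.5},   # exclusion from the shell
    seed=11,
)
frames, truth = generate_trajectory(spec)

for species in ("cation", "anion", "water"):
    g = gamma_species(frames, species, cutoff_r=12.0)
    print(f"Gamma_{species:<6s} = {g.gamma:+6.2f} +/- {g.se:.2f}")

pi = preferential_interaction(frames, z2=0.0, cutoff_r=12.0)
print(f"combined Gamma_23 (indistinguishable-ion) = {pi.gamma_23:+.2f} "
      f"+/- {pi.se:.2f}")

res = mddf(frames, "cation", bin_width=1.0, r_max=20.0)
shell = (res.bin_edges[:-1] >= 4) & (res.bin_edges[1:] <= 9)
print(f"cation MDDF density in the biased shell: "
      f"{np.nanmean(res.normalized_density[shell]):.2f} (bulk = 1)")
print("Negative Gamma_23 = net exclusion of the salt from the protein")
print("surface relative to bulk stoichiometry: protectant behaviour.")
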