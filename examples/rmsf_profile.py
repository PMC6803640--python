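"""Per-residue C-alpha RMSF from a trajectory with known flexibility.

Generates a synthetic trajectory whose residues fluctuate with a
prescribed per-residue amplitude (plus deliberate global tumbling), then
recovers the profile after Kabsch superposition.
"""

import numpy as np

from biophyskit.flexibility import rmsf_per_residue
from biophyskit.synthetic_data import fluctuation_trajectory

# stiff core (0.05 nm) with a floppy C-terminal tail (up to 0.25 nm),
# contaminated with random per-frame rigid tumbling
sigma = np.concatenate([np.full(14, 0.05), np.linspace(0.08, 0.25, 6)])
traj, truth = fluctuation_trajectory(n_residues=20, n_frames=4000,
                                     sigma_nm=sigma, rigid_motion=True,
                                     seed=3)
# measure against the equilibrated (noise-free) reference; using a noisy
# snapshot as reference would inflate every RMSF by sqrt(2)
equilibrated = np.array(truth["reference_coords"])
profile = rmsf_per_residue(traj, reference=equilibrated, fit=True)

print("residue   RMSF (nm)   expected sigma*sqrt(3) (nm)")
for i in (1, 5, 10, 15, 18, 20):
    exp = truth["expected_rmsf_nm"][i - 1]
    got = profile.rmsf_nm[profile.residue_indices == i][0]
    print(f"   {i:3d}     {got:6.3f}          {exp:6.3f}")
print("-> superposition removes the global tumbling entirely; the flexible "
      "tail stands out just as the floppy loops of a real Ca2+ sensor do.")
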