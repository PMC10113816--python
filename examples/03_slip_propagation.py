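"""Watch the slip front propagate from the contact periphery to the centre.

Prints the stick ratio (stuck in-contact area / total in-contact area) at a
few twist angles and the mean radius of newly slipping skin, showing the
front closing on the rotation centre until the stick ratio crosses the 0.03
full-slip cutoff.
"""

import numpy as np

import padtorsion as pt

params = pt.SynthParams(seed=11)
trial = pt.simulate_trial(params)
result = pt.analyze_simulated(trial)
slip = result.slip

print("twist (deg)   stick ratio")
for angle in [0, 5, 10, 15, 20, 25, 30, 35, 40]:
    j = np.argmin(np.abs(slip.twist_deg - angle))
    print(f"{slip.twist_deg[j]:8.0f}      {slip.stick_ratio[j]:.3f}")

print(f"\nfull slip detected at {slip.full_slip_angle_deg:.1f} deg "
      f"(ground truth {trial.ground_truth.full_slip_angle_deg:.1f} deg)")

# mean radius of newly slipped triangles: decreases -> periphery slips first
mesh = pt.build_mesh(pt.smooth_displacements(trial.trajectories))
rho = params.ellipse().rho(mesh.centroids(0))
prev = np.zeros(mesh.n_triangles, bool)
print("\ntwist (deg)   mean radius of newly slipped skin (fraction of contact radius)")
for j in range(slip.slip_flag.shape[1]):
    new = slip.slip_flag[:, j] & ~prev
    prev |= slip.slip_flag[:, j]
    if new.sum() >= 30 and j % 5 == 0:
        print(f"{slip.twist_deg[j]:8.0f}      {rho[new].mean():.2f}")
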