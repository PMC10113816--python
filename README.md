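# padtorsion

Surface mechanics of the human finger pad under torsion: a tested, reusable
pipeline from tracked contact-surface point trajectories, per-frame contact
masks and 1 kHz force/torque traces to surface strain fields, slip-front
propagation statistics, contact-area accounting, strain energy and
rotational-friction power-law fits.

## The problem

When a flat surface twists against the finger pad about the contact normal,
the skin does not give way all at once: slip starts at the contact periphery
and propagates inward as an annular *slip front* until the whole contact
slides (full slip, operationally a stick ratio below 0.03). The moving front
concentrates shear strain in a narrow band; the apparent contact area shrinks
through skin *peeling* at the edge and through in-plane deformation; the
friction torque rises to a plateau `T_slip`. These surface events carry the
tactile information that lets a person sense an impending rotational slip.
This package is for researchers in skin biomechanics and tactile
neuroscience who need those quantities computed reproducibly from contact
imagery and force data — and verified, since no public raw-video dataset
exists: a synthetic torsion-trial generator with analytic ground truth
stands in for the raw recordings so every stage is testable.

## The quantities

For each Delaunay triangle of tracked skin features, the affine map between
frames gives the deformation gradient **F** and the finite-strain tensor

    E = (Fᵀ F − I) / 2          (Green–Lagrange; exactly 0 for rigid motion)

with principal strains `e₁ ≥ e₂`, area invariant `e_a = (e₁+e₂)/2` (Mohr
circle centre), maximum shear `e_s = (e₁−e₂)/2` (Mohr circle radius), and a
plane-strain strain-energy density
`u_d = E(1−ν)/(2(1+ν)(1−2ν))(ϵxx²+ϵyy²) + Eν/((1+ν)(1−2ν))ϵxxϵyy + E/(1+ν)ϵxy²`
integrated as `U = p·Σ u_d·A` over the contact (E = 1 MPa, ν = 0.4,
depth p = 2 mm by convention). A triangle counts as slipping when its
rotation rate about its own centroid deviates from the plate's by more than
0.6°/frame (one frame per degree of rotation); the stick ratio is the stuck
fraction of in-contact area. Friction traces are zero-phase Butterworth
filtered (order 2, 5 Hz), `T_slip` is the mean |T| over the 0.5 s before 75°
of twist, `μ_rot = T_slip/F_N` (a length, reported in mm), and ladders over
normal force are summarized by `μ_rot = k·F_N^(n−1)` and `A₀ = a·F_N^b`.

## Worked example

```python
import padtorsion as pt

trial = pt.simulate_trial(pt.SynthParams(seed=7))   # 2 N, 20 deg/s, CCW
result = pt.analyze_simulated(trial)
s = result.summary
print(s["t_slip_nm"] * 1e3, s["mu_rot_mm"], s["full_slip_angle_deg"])
```

Running `python examples/01_simulate_and_analyze_trial.py` prints:

```
conditions: F_N = 2.0 N, omega = 20.0 deg/s, CCW
features tracked: 2988, triangles: 5920
initial contact area: 131.4 mm^2
torque plateau T_slip: 11.36 mN.m (analytic 11.36 mN.m)
rotational friction mu_rot = T_slip/F_N: 5.68 mm
full slip at 34.0 deg of twist (ground truth 34.0 deg)
contact area change over the rotation: -12.2 %
median cumulative max shear |e_s,end|: 52.6 %
surface strain energy U: 9.77 mJ; external work W: 13.70 mJ (W >= U)
```

The torque plateau matches the analytic traction integral of the generator,
the detected full-slip angle matches the ground-truth front schedule, and
the external work bounds the surface strain energy, as it must. The other
examples walk through the strain machinery on single triangles
(`02_strain_field_basics.py`), the inward march of the slip front
(`03_slip_propagation.py`), the peeling/deformation decomposition of the
area change (`04_contact_peeling_decomposition.py`) and the five-force
friction and area power laws (`05_friction_power_law.py`), which print
k ≈ 6.7 mm, n ≈ 0.76 and a ≈ 113.6 mm², b ≈ 0.21 under the default
conditions.

## Command line

The same pipeline is scriptable from a shell:

```bash
padtorsion simulate -c config.yaml -o trial_dir      # trajectories, masks, traces, ground truth
padtorsion analyze trial_dir -o results_dir          # strain/slip/contact/friction outputs
padtorsion sweep -c grid.yaml -o sweep_dir           # force/velocity ladders + power-law fits
```

Configs are YAML; a seed is mandatory for simulation; every analysis
constant (smoothing window, slip threshold, stick cutoff, filter settings,
elasticity) is overridable. Each run writes a manifest with a config hash
and file checksums, so identical seeds reproduce identical artefacts.

## Layout

- `src/padtorsion/synth.py` — synthetic torsion-trial generator + ground truth
- `src/padtorsion/strain.py` — smoothing, meshing, Green–Lagrange strains, invariants, energy
- `src/padtorsion/slip.py` — slip classification, stick ratio, full-slip event, front boundary
- `src/padtorsion/contact.py` — segmentation, area, tilt, peeling/deformation accounting
- `src/padtorsion/friction.py` — trace filtering, T_slip, μ_rot, power laws, work, SNR
- `src/padtorsion/{config,pipeline,cli}.py` — configuration, per-trial pipeline, CLI
- `docs/methods.md` — model assumptions, parameter choices, numerical notes, limitations
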