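"""Green-Lagrange strain on a single triangular skin element.

Builds the strain machinery up from one triangle: a rigid rotation produces
exactly zero strain, a uniaxial stretch gives the closed-form finite-strain
value, and a pure shear decomposes into principal strains at 45 degrees
whose Mohr invariants separate area change from maximum shear.
"""

import numpy as np

import padtorsion as pt

tri = np.array([[0.0, 0.0], [10.0, 2.0], [3.0, 9.0]])


def strains(p0, p1):
    traj = pt.TrajectorySet(
        np.stack([p0, p1]), np.array([0.0, 1.0]), np.zeros(2), px_per_mm=85.0
    )
    mesh = pt.build_mesh(traj)
    exx, eyy, exy, _ = pt.green_lagrange(mesh, 0, 1)
    return exx[0], eyy[0], exy[0]


# rigid rotation by 30 degrees: Green-Lagrange is exactly zero
theta = np.radians(30.0)
rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
exx, eyy, exy = strains(tri, tri @ rot.T)
print(f"rigid 30 deg rotation: exx={exx:.2e}, eyy={eyy:.2e}, exy={exy:.2e} (all ~0)")

# uniaxial stretch by 10%: exx = (lambda^2 - 1)/2 = 0.105
exx, eyy, exy = strains(tri, tri * np.array([1.1, 1.0]))
print(f"10% uniaxial stretch: exx={exx:.4f} (closed form 0.1050), eyy={eyy:.1e}")

# pure shear tensor: principal strains +/- s at 45 degrees
e1, e2, orient = pt.principal_strains(0.0, 0.0, 0.1)
e_a, e_s = pt.mohr_invariants(e1, e2)
print(f"pure shear exy=0.1: e1={e1:.2f}, e2={e2:.2f} at {orient:.0f} deg; "
      f"area invariant e_a={e_a:.2f}, max shear e_s={e_s:.2f}")

# strain energy density of that shear state at skin-like elasticity
u_d = pt.strain_energy_density(0.0, 0.0, 0.1, pt.ElasticParams(E=1e6, nu=0.4))
print(f"strain energy density at E=1 MPa, nu=0.4: u_d = {u_d:.1f} J/m^3")
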