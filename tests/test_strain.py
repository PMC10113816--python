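"""Strain-field tests: smoothing, meshing, Green-Lagrange, invariants, energy."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import padtorsion as pt
from padtorsion.strain import _gaussian_kernel, endpoint_strain, integrate_rate

from conftest import rigid_motion


def make_traj(frames: list[np.ndarray], px_per_mm: float = 85.0) -> pt.TrajectorySet:
    arr = np.stack(frames)
    n = arr.shape[0]
    return pt.TrajectorySet(arr, np.arange(n, dtype=float), np.zeros(n), px_per_mm)


# ---------------------------------------------------------------------------
# displacement smoothing
# ---------------------------------------------------------------------------

class TestSmoothing:
    def test_constant_trajectory_unchanged(self):
        pos = np.tile(np.array([[3.0, 4.0]]), (30, 1, 1))
        traj = make_traj(list(pos))
        out = pt.smooth_displacements(traj)
        np.testing.assert_allclose(out.positions, pos, atol=1e-12)

    def test_linear_trajectory_unchanged_away_from_edges(self):
        t = np.arange(40, dtype=float)
        pos = np.zeros((40, 1, 2))
        pos[:, 0, 0] = 2.0 * t
        pos[:, 0, 1] = -0.5 * t + 7.0
        out = pt.smooth_displacements(make_traj(list(pos)))
        np.testing.assert_allclose(out.positions[10:30], pos[10:30], atol=1e-10)

    def test_step_equals_direct_convolution_oracle(self):
        pos = np.zeros((50, 1, 2))
        pos[25:, 0, 0] = 1.0
        out = pt.smooth_displacements(make_traj(list(pos)), window_n=16, sigma_frames=0.75)
        k = _gaussian_kernel(16, 0.75)
        oracle = ndimage.convolve1d(pos[:, 0, 0], k, mode="reflect")
        np.testing.assert_allclose(out.positions[:, 0, 0], oracle, atol=1e-14)
        # smoothed step is the kernel's cumulative sum across the transition
        half = len(k) // 2
        np.testing.assert_allclose(
            out.positions[25 - half : 25 + half + 1, 0, 0],
            np.cumsum(k[::-1])[: 2 * half + 1],
            atol=1e-12,
        )

    def test_kernel_normalized_and_symmetric(self):
        k = _gaussian_kernel(16, 0.75)
        assert k.sum() == pytest.approx(1.0, abs=1e-14)
        np.testing.assert_allclose(k, k[::-1])

    def test_invalid_window_rejected(self):
        traj = make_traj([np.zeros((3, 2))] * 4)
        with pytest.raises(ValueError, match="window_n"):
            pt.smooth_displacements(traj, window_n=0)


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

class TestBuildMesh:
    def test_three_points_one_triangle(self):
        p = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        mesh = pt.build_mesh(make_traj([p, p]))
        assert mesh.n_triangles == 1
        assert np.all(mesh.signed_areas(0) > 0)

    def test_four_points_share_delaunay_legal_diagonal(self):
        """Empty-circumcircle oracle on the shared edge of a convex quad."""
        p = np.array([[0.0, 0.0], [20.0, 0.0], [24.0, 18.0], [2.0, 14.0]])
        mesh = pt.build_mesh(make_traj([p, p]))
        assert mesh.n_triangles == 2
        t0, t1 = (set(tri) for tri in mesh.triangles)
        shared = t0 & t1
        assert len(shared) == 2
        for tri, other in ((t0, t1), (t1, t0)):
            a, b, c = (p[i] for i in tri)
            d = p[next(iter(other - tri))]
            # in-circumcircle determinant: positive means d inside circle(a,b,c)
            rows = []
            for q in (a, b, c, d):
                rows.append([q[0], q[1], q[0] ** 2 + q[1] ** 2, 1.0])
            det = np.linalg.det(np.array(rows))
            ab, ac = b - a, c - a
            area2 = ab[0] * ac[1] - ab[1] * ac[0]
            assert det * np.sign(area2) <= 1e-6  # d not strictly inside

    def test_grid_4x4_has_18_triangles(self):
        """Euler count for a triangulated 4x4 lattice: 2n - 2 - hull = 18."""
        p = np.array([[x, y] for x in range(4) for y in range(4)], dtype=float) * 10
        mesh = pt.build_mesh(make_traj([p, p]))
        assert mesh.n_triangles == 18

    def test_collinear_points_rejected(self):
        p = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError):
            pt.build_mesh(make_traj([p, p]))


# ---------------------------------------------------------------------------
# Green-Lagrange tensors
# ---------------------------------------------------------------------------

TRI = np.array([[0.0, 0.0], [10.0, 2.0], [3.0, 9.0]])


class TestGreenLagrange:
    def test_identity_motion_zero_tensor(self, two_frame_traj):
        mesh = pt.build_mesh(two_frame_traj(TRI, TRI))
        exx, eyy, exy, valid = pt.green_lagrange(mesh, 0, 1)
        assert valid.all()
        np.testing.assert_allclose([exx, eyy, exy], 0.0, atol=1e-15)

    def test_rigid_rotation_exactly_zero(self, two_frame_traj):
        moved = rigid_motion(TRI, np.radians(30.0), np.array([5.0, -2.0]))
        mesh = pt.build_mesh(two_frame_traj(TRI, moved))
        exx, eyy, exy, _ = pt.green_lagrange(mesh, 0, 1)
        assert max(abs(exx[0]), abs(eyy[0]), abs(exy[0])) < 1e-12

    def test_uniaxial_stretch_closed_form(self, two_frame_traj):
        lam = 1.1
        stretched = TRI * np.array([lam, 1.0])
        mesh = pt.build_mesh(two_frame_traj(TRI, stretched))
        exx, eyy, exy, _ = pt.green_lagrange(mesh, 0, 1)
        assert exx[0] == pytest.approx((lam**2 - 1) / 2, abs=1e-12)  # 0.105
        assert eyy[0] == pytest.approx(0.0, abs=1e-12)
        assert exy[0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_triangle_flagged_invalid(self, two_frame_traj):
        bad = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [0.0, 5.0]])
        # force a degenerate triangle by hand-building the mesh
        moved = bad + 1.0
        traj = two_frame_traj(bad, moved)
        mesh = pt.TriangleMesh(
            triangles=np.array([[0, 1, 2], [0, 1, 3]]),
            positions=traj.positions,
            px_per_mm=85.0,
        )
        exx, _, _, valid = pt.green_lagrange(mesh, 0, 1)
        assert not valid[0] and valid[1]
        assert np.isnan(exx[0])

    @settings(derandomize=True, max_examples=60)
    @given(
        angle=st.floats(-np.pi, np.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_rigid_motion_nullity_property(self, angle, tx, ty):
        moved = rigid_motion(TRI, angle, np.array([tx, ty]))
        mesh = pt.build_mesh(make_traj([TRI, moved]))
        exx, eyy, exy, _ = pt.green_lagrange(mesh, 0, 1)
        assert max(abs(exx[0]), abs(eyy[0]), abs(exy[0])) < 1e-10


# ---------------------------------------------------------------------------
# principal strains & invariants
# ---------------------------------------------------------------------------

def rotate_tensor(exx, eyy, exy, alpha_rad):
    c, s = np.cos(alpha_rad), np.sin(alpha_rad)
    R = np.array([[c, -s], [s, c]])
    E = np.array([[exx, exy], [exy, eyy]])
    Er = R.T @ E @ R
    return Er[0, 0], Er[1, 1], Er[0, 1]


class TestPrincipalStrains:
    def test_pure_shear(self):
        e1, e2, orient = pt.principal_strains(0.0, 0.0, 0.1)
        assert e1 == pytest.approx(0.1)
        assert e2 == pytest.approx(-0.1)
        assert orient == pytest.approx(45.0)

    def test_isotropic_tie_break(self):
        e1, e2, orient = pt.principal_strains(0.02, 0.02, 0.0)
        assert e1 == e2 == pytest.approx(0.02)
        assert orient == 0.0

    def test_matches_brute_force_rotation_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            exx, eyy, exy = rng.normal(0, 0.05, 3)
            e1, e2, _ = pt.principal_strains(exx, eyy, exy)
            alphas = np.radians(np.arange(0.0, 180.0, 0.1))
            normals = np.array([rotate_tensor(exx, eyy, exy, a)[0] for a in alphas])
            assert e1 == pytest.approx(normals.max(), abs=1e-5)
            assert e2 == pytest.approx(normals.min(), abs=1e-5)

    @settings(derandomize=True, max_examples=60)
    @given(
        exx=st.floats(-0.3, 0.3),
        eyy=st.floats(-0.3, 0.3),
        exy=st.floats(-0.3, 0.3),
        alpha=st.floats(-89.0, 89.0),
    )
    def test_mohr_invariance_under_rotation(self, exx, eyy, exy, alpha):
        e1, e2, _ = pt.principal_strains(exx, eyy, exy)
        ea, es = pt.mohr_invariants(e1, e2)
        r = rotate_tensor(exx, eyy, exy, np.radians(alpha))
        e1r, e2r, _ = pt.principal_strains(*r)
        ear, esr = pt.mohr_invariants(e1r, e2r)
        assert abs(ea - ear) < 1e-9
        assert abs(es - esr) < 1e-9
        assert e1 >= e2 and es >= 0

    def test_orientation_shifts_with_coordinate_rotation(self):
        exx, eyy, exy = 0.08, -0.02, 0.03
        _, _, o0 = pt.principal_strains(exx, eyy, exy)
        alpha = 20.0
        # rotating coordinates by +alpha moves the eigenvector by -alpha in
        # the new frame
        r = rotate_tensor(exx, eyy, exy, np.radians(alpha))
        _, _, o1 = pt.principal_strains(*r)
        assert (o0 - o1) % 180.0 == pytest.approx(alpha, abs=1e-9)

    def test_invariant_formulas(self):
        ea, es = pt.mohr_invariants(0.1, -0.1)
        assert ea == 0.0 and es == pytest.approx(0.1)
        assert pt.mohr_invariants(0.0, 0.0) == (0.0, 0.0)


# ---------------------------------------------------------------------------
# strain energy
# ---------------------------------------------------------------------------

class TestStrainEnergy:
    def test_zero_tensor_zero_energy(self):
        assert pt.strain_energy_density(0.0, 0.0, 0.0) == 0.0

    def test_pure_shear_hand_evaluation(self):
        # u_d = E/(1+nu) * exy^2 = 1e6/1.4 * 0.01 ~ 7142.86 J/m^3
        u = pt.strain_energy_density(0.0, 0.0, 0.1, pt.ElasticParams(E=1e6, nu=0.4))
        assert u == pytest.approx(7142.857142857143, rel=1e-12)

    def test_symmetric_under_axis_swap(self):
        e = pt.ElasticParams()
        assert pt.strain_energy_density(0.03, -0.07, 0.01, e) == pytest.approx(
            pt.strain_energy_density(-0.07, 0.03, 0.01, e)
        )

    def test_incompressible_poisson_rejected(self):
        with pytest.raises(ValueError, match="nu"):
            pt.ElasticParams(nu=0.5)

    def test_total_energy_single_triangle(self):
        # u_d = 1000 J/m^3 over 1 mm^2 at 2 mm depth -> 2e-6 J
        assert pt.total_energy(np.array([1000.0]), np.array([1.0]), 2e-3) == pytest.approx(2e-6)

    def test_total_energy_zero_and_negative_area(self):
        assert pt.total_energy(np.zeros(5), np.ones(5)) == 0.0
        with pytest.raises(ValueError, match="area"):
            pt.total_energy(np.ones(2), np.array([1.0, -1.0]))

    def test_rate_series_integrates_back_to_total(self, small_trial, small_result):
        energy = small_result.energy
        U_end = energy["U"][-1]
        back = integrate_rate(energy["dU_dt"], energy["time_s"])
        assert back == pytest.approx(U_end, rel=1e-9)
        assert U_end > 0


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------

class TestAccumulation:
    def make_field(self, es_per_interval, n_int):
        n_tri = len(es_per_interval)
        exy = np.tile(np.asarray(es_per_interval)[:, None], (1, n_int))
        zeros = np.zeros_like(exy)
        e1, e2, orient = pt.principal_strains(zeros, zeros, exy)
        ea, es = pt.mohr_invariants(e1, e2)
        return pt.StrainField(
            exx=zeros, eyy=zeros, exy=exy, e1=e1, e2=e2, orientation_deg=orient,
            e_a=ea, e_s=es, u_d=np.zeros_like(exy), valid=np.ones_like(exy, bool),
        )

    def test_single_interval_equals_itself(self):
        sf = self.make_field([0.02, 0.05], 1)
        out = pt.accumulate_strain(sf)
        np.testing.assert_allclose(out["e_s_cum"], [0.02, 0.05])

    def test_n_identical_intervals_sum_linearly(self):
        sf = self.make_field([0.01], 7)
        out = pt.accumulate_strain(sf)
        assert out["e_s_cum"][0] == pytest.approx(0.07)

    def test_cumulative_shear_concentrates_where_front_passed(self, small_trial, small_result):
        """Triangles the front passed accumulate shear; the never-slipped centre does not."""
        gt = small_trial.ground_truth
        cum = small_result.cumulative["e_s_cum"]
        # map analysis triangles to front passage via centroid radius
        params = small_trial.params
        ell = params.ellipse()
        res_mesh = pt.build_mesh(
            pt.smooth_displacements(small_trial.trajectories)
        )
        rho_c = ell.rho(res_mesh.centroids(0))
        final_front = gt.stick_radius_mm_by_frame[-1] / ell.geo_radius_mm
        passed = rho_c > final_front + 0.15
        never = rho_c < max(final_front - 0.15, 0.0)
        if never.sum() >= 5:
            assert np.nanmedian(cum[passed]) > 5 * np.nanmedian(cum[never])
        else:
            assert np.nanmedian(cum[passed]) > 0.01

    def test_endpoint_alternative_agrees_for_small_motion(self, two_frame_traj):
        lam = 1.002
        stretched = TRI * np.array([lam, 1.0])
        mesh = pt.build_mesh(two_frame_traj(TRI, stretched))
        sf = pt.compute_strain_field(mesh)
        summed = pt.accumulate_strain(sf)
        direct = endpoint_strain(mesh)
        assert summed["e_s_cum"][0] == pytest.approx(direct["e_s_cum"][0], rel=1e-6)
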