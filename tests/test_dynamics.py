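"""Smoothing, polyhedral mass properties, angular momentum and torque."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fishtrack3d.dynamics import (
    InverseDynamics,
    SmootherConfig,
    angular_momentum,
    differentiate,
    mass_properties,
    second_derivative,
    smooth_series,
    tube_tetrahedra,
    _tet_volumes,
)
from fishtrack3d.kinematics import FishState, deform_and_pose
from fishtrack3d.morphology import SurfaceMesh, cylinder_surface_mesh


def mesh_vertices(mesh):
    return np.vstack([mesh.rings.reshape(-1, 3), mesh.centres])


class TestSmoother:
    def test_lambda_zero_identity(self, rng):
        y = rng.normal(size=(30, 2))
        out, _ = smooth_series(y, SmootherConfig(lam=0.0))
        assert np.allclose(out, y)

    @pytest.mark.parametrize("lam", [1.0, 1e4, 1e8])
    def test_cubic_null_space(self, lam):
        t = np.linspace(0, 1, 40)
        y = 2.0 - t + 3 * t ** 2 - 0.5 * t ** 3
        out, _ = smooth_series(y, SmootherConfig(lam=lam, reflect_pad=False))
        assert np.allclose(out[:, 0], y, atol=1e-7)

    def test_noise_reduction_on_sinusoid(self, rng):
        t = np.linspace(0, 1, 120)
        clean = np.sin(2 * np.pi * 3 * t)
        noisy = clean + rng.normal(0, 0.1, t.size)
        out, lams = smooth_series(noisy, SmootherConfig())
        rmse_in = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_out = np.sqrt(np.mean((out[:, 0] - clean) ** 2))
        assert rmse_out < rmse_in
        assert lams[0] > 0

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="short"):
            smooth_series(np.zeros(8), SmootherConfig())


class TestDerivatives:
    def test_linear_exact(self):
        t = np.arange(20) * 0.1
        y = 3.0 * t - 1.0
        assert np.allclose(differentiate(y, 0.1), 3.0)
        assert np.allclose(second_derivative(y, 0.1), 0.0, atol=1e-12)

    def test_quadratic_exact_including_ends(self):
        t = np.arange(15) * 0.2
        y = 1.0 + 2.0 * t + 4.0 * t ** 2
        assert np.allclose(differentiate(y, 0.2), 2.0 + 8.0 * t, atol=1e-10)
        assert np.allclose(second_derivative(y, 0.2), 8.0, atol=1e-10)

    def test_sinusoid_truncation_error_bound(self):
        fs, w = 2000.0, 2 * np.pi * 50.0
        t = np.arange(200) / fs
        y = np.sin(w * t)
        d = differentiate(y, 1 / fs)
        err = np.abs(d - w * np.cos(w * t))[2:-2].max()
        # central scheme truncation: (dt² ω³ / 6)·max|cos|
        bound = (1 / fs) ** 2 * w ** 3 / 6 * 1.05
        assert err <= bound


class TestMassProperties:
    def test_unit_cube(self):
        # cube as a degenerate "tube": square rings along z
        z = np.linspace(-0.5, 0.5, 21)
        sq = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        ring = np.vstack([np.linspace(sq[i], sq[(i + 1) % 4], 10,
                                      endpoint=False)
                          for i in range(4)])
        rings = np.zeros((23, 40, 3))
        centres = np.zeros((23, 3))
        rings[0] = [0, 0, -0.5]
        rings[-1] = [0, 0, 0.5]
        centres[0] = (0, 0, -0.5)
        centres[-1] = (0, 0, 0.5)
        for i, zi in enumerate(z):
            rings[i + 1, :, :2] = ring
            rings[i + 1, :, 2] = zi
            centres[i + 1] = (0, 0, zi)
        mesh = SurfaceMesh(rings, centres)
        mass, com, inertia = mass_properties(mesh, rho=1000.0)
        assert mass == pytest.approx(1000.0 * 1e-9, rel=1e-9)
        assert np.allclose(com, 0.0, atol=1e-9)
        expect = mass / 6.0 * (1e-3) ** 2  # m a²/6 per axis for a unit cube
        assert np.allclose(np.diag(inertia), expect, rtol=1e-6)
        assert np.allclose(inertia - np.diag(np.diag(inertia)), 0.0,
                           atol=1e-15)

    def test_cylinder_closed_forms(self, cylinder_mesh):
        R, L = 0.625e-3, 5e-3
        mass, com, inertia = mass_properties(cylinder_mesh, rho=1000.0)
        vol = np.pi * R * R * L
        # the P=40-gon ring underestimates the circle area by a known factor
        poly_factor = (40 / (2 * np.pi)) * np.sin(2 * np.pi / 40)
        assert mass == pytest.approx(1000 * vol * poly_factor, rel=1e-6)
        assert np.allclose(com, 0.0, atol=1e-9)
        i_axial = 0.5 * mass * R ** 2
        i_trans = mass * (3 * R ** 2 + L ** 2) / 12.0
        assert inertia[0, 0] == pytest.approx(i_axial, rel=0.01)
        assert inertia[1, 1] == pytest.approx(i_trans, rel=0.005)
        assert inertia[2, 2] == pytest.approx(i_trans, rel=0.005)

    def test_fish_against_column_raster_oracle(self, zebrafish_model):
        from conftest import column_volume_oracle
        mesh = zebrafish_model.straight_mesh()
        mass, com, _ = mass_properties(mesh, rho=1000.0)
        tm = mesh.to_trimesh()
        vol, centroid = column_volume_oracle(tm, n_xy=120)
        assert mass == pytest.approx(1000.0 * vol * 1e-9, rel=0.005)
        diag = np.linalg.norm(tm.extents)
        assert np.linalg.norm(com - centroid) < 0.002 * diag

    def test_tet_partition_volume_matches_surface_integral(self, zebrafish_model):
        mesh = zebrafish_model.straight_mesh()
        tets = tube_tetrahedra(mesh.n_sections, mesh.n_circumferential)
        vol_tets = _tet_volumes(mesh_vertices(mesh), tets).sum()
        assert vol_tets == pytest.approx(mesh.to_trimesh().volume, rel=5e-3)

    def test_open_mesh_rejected(self, cylinder_mesh):
        import trimesh
        tm = cylinder_mesh.to_trimesh()
        open_mesh = trimesh.Trimesh(tm.vertices, tm.faces[:-10],
                                    process=False)
        with pytest.raises(ValueError, match="watertight"):
            mass_properties(open_mesh)


class TestAngularMomentum:
    def test_rigid_spin_matches_inertia_tensor(self, cylinder_mesh):
        rho = 1000.0
        mass, com_mm, inertia = mass_properties(cylinder_mesh, rho)
        tets = tube_tetrahedra(cylinder_mesh.n_sections,
                               cylinder_mesh.n_circumferential)
        verts = mesh_vertices(cylinder_mesh) * 1e-3
        for omega in (np.array([0, 0, 1.0]), np.array([1.0, 0, 0]),
                      np.array([0.4, -0.2, 0.9])):
            vel = np.cross(omega, verts)
            L = angular_momentum(verts, vel, tets, rho, np.zeros(3),
                                 np.zeros(3))
            assert np.allclose(L, inertia @ omega, rtol=5e-3, atol=1e-16)

    def test_rigid_translation_zero(self, cylinder_mesh):
        rho = 1000.0
        _, _, inertia = mass_properties(cylinder_mesh, rho)
        tets = tube_tetrahedra(cylinder_mesh.n_sections,
                               cylinder_mesh.n_circumferential)
        verts = mesh_vertices(cylinder_mesh) * 1e-3
        vel = np.tile([0.1, -0.2, 0.05], (verts.shape[0], 1))
        L = angular_momentum(verts, vel, tets, rho, np.zeros(3),
                             np.array([0.1, -0.2, 0.05]))
        assert np.linalg.norm(L) <= 1e-9 * np.linalg.norm(inertia)

    def test_bending_rod_against_monte_carlo_oracle(self, capsule_model, rng):
        """Deforming body: the tet-partition integral must match Monte-Carlo
        volume sampling of ρ∭ r*×v* dV under the closed-form constant-
        curvature bending map of a capsule (independent continuum oracle)."""
        ell = capsule_model.length
        dt = 5e-4
        def state(c):
            return FishState(0, 0, 0, 0, 0, 0, np.full(7, c))
        c0, dc = 0.15, 0.02
        meshes = [deform_and_pose(capsule_model, state(c0 + k * dc))
                  for k in (-1, 0, 1)]
        verts = [mesh_vertices(m) * 1e-3 for m in meshes]
        vel = (verts[2] - verts[0]) / (2 * dt)
        rho = 1000.0
        tets = tube_tetrahedra(meshes[1].n_sections,
                               meshes[1].n_circumferential)
        L = angular_momentum(verts[1], vel, tets, rho, np.zeros(3),
                             np.zeros(3))

        # oracle: sample material points (s, u, v) in the straight capsule,
        # map them with the exact constant-curvature arc formulas
        #   C(s) = (−sin(cls)/c, (1−cos(cls))/c, 0),  û = (sin, cos, 0)
        # and weight by the bending volume element J = 1 − u·c
        R, L_len = 0.625, 5.0
        n_samp = 400_000
        x = rng.uniform(-L_len, 0.0, n_samp)
        y = rng.uniform(-R, R, n_samp)
        z = rng.uniform(-R, R, n_samp)
        d_end = np.minimum(-x, L_len + x)
        r_prof = np.where(d_end >= R, R,
                          np.sqrt(np.maximum(R**2 - (R - d_end)**2, 0.0)))
        inside = y**2 + z**2 <= r_prof**2
        s, u, v = -x[inside] / ell, y[inside], z[inside]

        def bent(c):
            th = c * ell * s
            cx = -np.sin(th) / c + u * np.sin(th)
            cy = (1.0 - np.cos(th)) / c + u * np.cos(th)
            return np.column_stack([cx, cy, v]) * 1e-3

        p_mid = bent(c0)
        v_mc = (bent(c0 + dc) - bent(c0 - dc)) / (2 * dt)
        w = 1.0 - u * c0
        V_tot = np.pi * R**2 * (L_len - 2 * R) + 4/3 * np.pi * R**3
        contrib = np.cross(p_mid, v_mc) * w[:, None]
        L_mc = rho * (V_tot * 1e-9) * contrib.sum(axis=0) / w.sum()
        assert np.linalg.norm(L_mc - L) <= 0.01 * max(
            np.linalg.norm(L), np.linalg.norm(L_mc))


class TestInverseDynamicsRigid:
    def test_uniform_motion_zero_force_and_torque(self, cylinder_mesh):
        T = 24
        dt = 5e-4
        meshes = []
        for t in range(T):
            shift = np.array([0.4, -0.2, 0.1]) * (t * dt) * 1e3
            meshes.append(SurfaceMesh(cylinder_mesh.rings + shift,
                                      cylinder_mesh.centres + shift))
        res = InverseDynamics.from_meshes(meshes, 1 / dt).fit()
        assert np.abs(res.force).max() < 1e-12
        assert np.abs(res.torque).max() < 1e-12
        assert res.volume_drift < 1e-12

    def test_constant_spin_constant_L(self, cylinder_mesh):
        T = 30
        dt = 5e-4
        omega = np.array([0.0, 0.0, 20.0])
        meshes = []
        for t in range(T):
            R = Rotation.from_rotvec(omega * t * dt).as_matrix()
            meshes.append(SurfaceMesh(cylinder_mesh.rings @ R.T,
                                      cylinder_mesh.centres @ R.T))
        res = InverseDynamics.from_meshes(meshes, 1 / dt).fit()
        _, _, inertia = mass_properties(cylinder_mesh, 1000.0)
        L_expect = inertia @ omega
        i = res.interior
        assert np.allclose(res.Lvec[i], L_expect, rtol=5e-3)
        tau_scale = np.linalg.norm(L_expect) / (T * dt)
        assert np.abs(res.torque[i]).max() < 5e-3 * tau_scale


class TestFishFrame:
    def test_straight_fish_axes(self, capsule_model):
        from fishtrack3d.dynamics import fish_frame_axes
        st = FishState(0, 0, 0, 0, 0, 0, np.zeros(7))
        mesh = deform_and_pose(capsule_model, st)
        _, com, _ = mass_properties(mesh)
        axes = fish_frame_axes(st, capsule_model, com)
        assert np.allclose(axes[0], [1, 0, 0], atol=1e-9)
        assert np.allclose(axes[2], [0, 0, 1], atol=1e-12)
        assert np.allclose(np.cross(axes[0], axes[1]), axes[2], atol=1e-9)

    def test_symmetric_bend_against_section_oracle(self, capsule_model):
        """For a uniform capsule bent at constant curvature the
        inertia-weighted resultant angle equals a dense per-section
        mass×distance²-weighted average computed independently."""
        from fishtrack3d.dynamics import fish_frame_axes, _polygon_area
        from fishtrack3d.kinematics import curvature_spline, \
            integrate_centerline
        c = 0.25
        st = FishState(0, 0, 0, 0, 0, 0, np.full(7, c))
        mesh = deform_and_pose(capsule_model, st)
        _, com, _ = mass_properties(mesh)
        axes = fish_frame_axes(st, capsule_model, com)
        alpha = np.arctan2(-axes[0][1], axes[0][0])

        spl = curvature_spline(st, capsule_model.stiff_fraction)
        centres, theta, _ = integrate_centerline(
            spl, capsule_model.length, capsule_model.s_values)
        areas = np.array([_polygon_area(s) for s in capsule_model.sections])
        ds = np.gradient(capsule_model.s_values) * capsule_model.length
        w = areas * ds * np.sum((centres - com) ** 2, axis=1)
        oracle = np.arctan2(np.sum(w * np.sin(theta)),
                            np.sum(w * np.cos(theta)))
        assert abs(np.rad2deg(alpha - oracle)) < 0.5

    def test_forward_force_is_projection_on_velocity(self, capsule_model):
        states = [FishState(0.1 * k + 0.005 * k * k, 0, 0, 0, 0, 0,
                            np.zeros(7)) for k in range(12)]
        dyn = InverseDynamics(states, capsule_model, 1000.0,
                              smoother=SmootherConfig(lam=0.0,
                                                      reflect_pad=False)).fit()
        speed = np.linalg.norm(dyn.vcom, axis=1)
        ok = speed > 1e-9
        expect = np.einsum("ti,ti->t", dyn.force, dyn.vcom)[ok] / speed[ok]
        assert np.allclose(dyn.forward_force[ok], expect, atol=1e-18)


class TestMassConstancy:
    def test_volume_drift_small_across_bending(self, small_zebrafish_model):
        ell = small_zebrafish_model.length
        vols = []
        for c in np.linspace(-np.pi / ell, np.pi / ell, 9):
            mesh = deform_and_pose(small_zebrafish_model,
                                   FishState(0, 0, 0, 0, 0, 0,
                                             np.full(7, c)))
            tets = tube_tetrahedra(mesh.n_sections, mesh.n_circumferential)
            vols.append(_tet_volumes(mesh_vertices(mesh), tets).sum())
        vols = np.array(vols)
        assert np.ptp(vols) / vols.mean() < 0.005
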