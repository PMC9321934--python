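import numpy as np
import pytest

from oracles import brute_local_thickness, cubical_euler, direct_box_counts
from osteovasc import morphometry as m
from osteovasc.phantom import PhantomSpec, generate_ideal_shape, generate_truth


def ball(radius, size=None):
    size = size or (2 * radius + 5)
    c = (size - 1) / 2
    zz, yy, xx = np.ogrid[:size, :size, :size]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


class TestVolumeFraction:
    def test_identity_null_and_truth(self):
        spec = PhantomSpec(dims=(64, 64, 64), cortex_outer_radius_um=100.0)
        truth = generate_truth(spec)
        marrow = truth.compartment_masks["marrow"]
        trab = truth.compartment_masks["trabecular"]
        assert m.volume_fraction(marrow, marrow) == 1.0
        assert m.volume_fraction(np.zeros_like(marrow), marrow) == 0.0
        assert m.volume_fraction(trab, marrow) == truth.true_tb_bv_marv

    def test_empty_reference_raises(self):
        z = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            m.volume_fraction(z, z)


class TestLocalThickness:
    @pytest.mark.parametrize("builder,descr", [
        (lambda: generate_ideal_shape("plate", 40, 5).data, "slab t=5"),
        (lambda: generate_ideal_shape("rod", 24, 6).data, "cylinder r=6"),
        (lambda: ball(10, 31), "ball r=10"),
    ])
    def test_matches_brute_force_maximal_sphere_oracle(self, builder, descr):
        mask = builder()
        got = m.local_thickness(mask)
        want = brute_local_thickness(mask)
        assert np.abs(got[mask] - want[mask]).max() <= 0.5, descr

    def test_slab_reads_its_own_width(self):
        mask = generate_ideal_shape("plate", 64, 5).data
        assert m.mean_thickness(m.local_thickness(mask)) == pytest.approx(5.0, abs=0.5)

    def test_ball_reads_its_diameter(self):
        # odd grid so the ball has an exact central voxel
        mask = ball(15, 45)
        th = m.local_thickness(mask, voxel_size_um=3.5)
        # one maximal sphere covers everything: the map is constant
        vals = th[mask]
        assert vals.min() == vals.max()
        assert m.mean_thickness(th) == pytest.approx(2 * 15 * 3.5, abs=3.5)

    def test_cylinder_core_close_to_its_diameter(self):
        # digital cylinders read ~7% under the continuous diameter: the
        # nearest background center sits almost on the continuous surface
        mask = generate_ideal_shape("rod", 40, 6).data
        th = m.local_thickness(mask)
        core = th[15:-15][th[15:-15] > 0]
        assert core.mean() == pytest.approx(12.0, abs=1.0)

    def test_voxel_size_scale_equivariance(self):
        mask = generate_ideal_shape("rod", 16, 4).data
        a = m.local_thickness(mask, voxel_size_um=1.0)
        b = m.local_thickness(mask, voxel_size_um=3.5)
        assert np.allclose(b, 3.5 * a)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            m.local_thickness(np.zeros((4, 4, 4), dtype=bool))


class TestBoxCountFD:
    def test_slab_surface_is_planar(self):
        mask = np.zeros((32, 128, 128), dtype=bool)
        mask[8:24] = True
        fit = m.box_count_fd(mask, (1, 2, 4, 8))
        assert fit.fd == pytest.approx(2.0, abs=0.1)
        assert fit.r_squared >= 0.98

    def test_line_counts_directly(self):
        mask = np.zeros((128, 8, 8), dtype=bool)
        mask[:, 4, 4] = True
        fit = m.box_count_fd(mask, (1, 2, 4, 8, 16), surface=False)
        assert fit.fd == pytest.approx(1.0, abs=0.1)

    def test_menger_sponge_matches_analytic_dimension(self):
        mask = generate_ideal_shape("menger", 27).data
        fit = m.box_count_fd(mask, (1, 3, 9, 27), surface=False)
        assert fit.fd == pytest.approx(np.log(20) / np.log(3), abs=0.15)
        assert fit.r_squared >= 0.98
        assert fit.counts == direct_box_counts(mask, (1, 3, 9, 27))

    def test_counts_non_increasing_and_fd_bounded(self):
        spec = PhantomSpec(dims=(64, 64, 64), cortex_outer_radius_um=100.0)
        truth = generate_truth(spec)
        fit = m.box_count_fd(truth.compartment_masks["trabecular"])
        assert all(a >= b for a, b in zip(fit.counts, fit.counts[1:]))
        assert 0.0 <= fit.fd <= 3.0

    def test_input_validation(self):
        mask = np.ones((16, 16, 16), dtype=bool)
        with pytest.raises(ValueError):
            m.box_count_fd(mask, (1, 2, 4))       # too few sizes
        with pytest.raises(ValueError):
            m.box_count_fd(np.zeros((8, 8, 8), bool))  # nothing to count


class TestSMI:
    def test_sphere_is_four(self):
        assert m.smi(ball(20, 51)) == pytest.approx(4.0, abs=0.15)

    def test_long_capsule_is_rod_like(self):
        mask = generate_ideal_shape("rod", 240, 6).data  # L = 40 r
        assert m.smi(mask) == pytest.approx(3.0, abs=0.2)

    def test_wide_slab_is_plate_like(self):
        mask = generate_ideal_shape("plate", 256, 5).data
        assert m.smi(mask) == pytest.approx(0.0, abs=0.2)

    def test_mean_curvature_matches_trimesh_estimator(self):
        """The edge-angle sum behind SMI equals trimesh's independent
        integral-mean-curvature on a closed interior surface."""
        from osteovasc.morphometry import _mesh_from_mask
        mask = ball(12, 31)
        mesh, border = _mesh_from_mask(mask, smooth_sigma=1.0)
        assert not border.any()  # fully interior: nothing sealed at walls
        edges = mesh.face_adjacency_edges
        angles = mesh.face_adjacency_angles.copy()
        angles[~mesh.face_adjacency_convex] *= -1
        lengths = np.linalg.norm(mesh.vertices[edges[:, 0]]
                                 - mesh.vertices[edges[:, 1]], axis=1)
        mine = abs(0.5 * float((lengths * angles).sum()))
        assert mine == pytest.approx(abs(float(mesh.integral_mean_curvature)),
                                     rel=1e-6)
        # and close to the analytic 4*pi*r of a sphere
        assert mine == pytest.approx(4 * np.pi * 12, rel=0.05)

    def test_error_decreases_with_resolution(self):
        errs = []
        for r in (8, 16):
            errs.append(abs(m.smi(ball(r, 2 * r + 7)) - 4.0))
        assert errs[1] < errs[0]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            m.smi(np.zeros((8, 8, 8), dtype=bool))


class TestEulerConnectivity:
    @pytest.mark.parametrize("builder,chi", [
        (lambda: ball(6, 17), 1),
        (lambda: generate_ideal_shape("torus", 32, 4).data, 0),
        (lambda: ball(4, 13) | np.roll(ball(4, 13), 0), 1),
    ])
    def test_octant_counting_matches_cubical_complex_oracle(self, builder, chi):
        mask = builder()
        assert m.euler_characteristic(mask) == cubical_euler(mask) == chi

    def test_two_disjoint_balls_are_additive(self):
        a = np.zeros((16, 32, 16), dtype=bool)
        a[4:12, 4:12, 4:12] = ball(3, 8)
        a[4:12, 20:28, 4:12] = ball(3, 8)
        assert m.euler_characteristic(a) == 2 == cubical_euler(a)
        assert m.connectivity(a) == 0

    def test_torus_has_one_handle(self):
        mask = generate_ideal_shape("torus", 32, 4).data
        assert m.connectivity(mask) == 1

    def test_hollow_ball_has_a_cavity_not_a_handle(self):
        mask = ball(8, 21) & ~ball(4, 21)
        assert m.euler_characteristic(mask) == 2  # beta0 + beta2
        assert m.connectivity(mask) == 0

    def test_connectivity_invariant_under_one_voxel_dilation(self):
        from scipy import ndimage
        mask = generate_ideal_shape("torus", 40, 5).data
        fat = ndimage.binary_dilation(mask)
        assert m.connectivity(fat) == m.connectivity(mask) == 1

    def test_conn_density_units(self):
        mask = generate_ideal_shape("torus", 32, 4).data
        tv_count = 100_000
        vol_mm3 = tv_count * (3.5e-3) ** 3
        assert m.conn_density(mask, tv_count, 3.5) == pytest.approx(1 / vol_mm3)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            m.euler_characteristic(np.zeros((4, 4, 4), dtype=bool))


class TestComputeRecord:
    def test_truth_masks_round_trip(self):
        spec = PhantomSpec(dims=(64, 64, 64), cortex_outer_radius_um=100.0)
        truth = generate_truth(spec)
        cm = truth.compartment_masks
        rec = m.compute_record(
            bone_mask=truth.label_volume == 1,
            vessel_mask=(truth.label_volume == 2) & ~truth.leak_mask,
            tv_mask=cm["tv"], marrow_mask=cm["marrow"],
            trabecular_mask=cm["trabecular"], voxel_size_um=3.5,
            sample_id="s", group="g")
        assert rec.bvtv == pytest.approx(truth.true_bvtv, abs=1e-9)
        assert rec.tb_bv_marv == pytest.approx(truth.true_tb_bv_marv, abs=1e-9)
        assert 0 < rec.smi < 3.4
        assert rec.tb_th_um > 0 and rec.v_th_um > 0

    def test_all_rod_lattice_smi_in_rod_range(self):
        spec = PhantomSpec(dims=(96, 96, 96), cortex_outer_radius_um=150.0,
                           trabecular_mix=0.0, geometry_seed=1)
        truth = generate_truth(spec)
        smi = m.smi(truth.compartment_masks["trabecular"])
        assert 2.3 <= smi <= 3.4

    def test_unbranched_vessel_path_has_zero_connectivity(self):
        mask = np.zeros((64, 16, 16), dtype=bool)
        yy, xx = np.ogrid[:16, :16]
        mask[:, (yy - 8) ** 2 + (xx - 8) ** 2 <= 4] = True
        assert m.connectivity(mask) == 0

    def test_empty_masks_leave_missing_fields(self, caplog):
        z = np.zeros((8, 8, 8), dtype=bool)
        tv = np.ones_like(z)
        with caplog.at_level("WARNING"):
            rec = m.compute_record(z, z, tv, tv, z, 3.5, sample_id="x")
        assert np.isnan(rec.tb_th_um) and np.isnan(rec.smi)
        assert rec.bvtv == 0.0
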