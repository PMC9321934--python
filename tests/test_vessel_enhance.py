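import numpy as np
import pytest
from scipy import integrate, ndimage

from osteovasc import morphometry
from osteovasc.phantom import PhantomSpec, generate_phantom
from osteovasc.vessel_enhance import (
    TubenessMap,
    partition_vessels,
    remove_leaks,
    tubeness,
)


def analytic_cylinder_response(r, sigma):
    """sigma^2 * |transverse eigenvalue| at the axis of a blurred disc."""
    def f(rho):
        return (np.exp(-rho ** 2 / (2 * sigma ** 2)) / (2 * np.pi * sigma ** 2)
                * (rho ** 2 / 2 - sigma ** 2) / sigma ** 4 * 2 * np.pi * rho)
    val, _ = integrate.quad(f, 0, r)
    return sigma ** 2 * abs(val)


def analytic_sphere_response(r, sigma):
    def f(rho):
        return (np.exp(-rho ** 2 / (2 * sigma ** 2))
                / ((2 * np.pi) ** 1.5 * sigma ** 3)
                * (rho ** 2 / 3 - sigma ** 2) / sigma ** 4 * 4 * np.pi * rho ** 2)
    val, _ = integrate.quad(f, 0, r)
    return sigma ** 2 * abs(val)


class TestTubeness:
    def test_matches_closed_form_on_cylinder_and_sphere(self):
        """Single-scale responses at the center of a bright cylinder and a
        bright ball agree with the closed-form Gaussian-Hessian integrals;
        the cylinder out-scores the equal-radius sphere."""
        r, height = 4.0, 64
        vol = np.zeros((height, 64, 64), np.float32)
        yy, xx = np.ogrid[:64, :64]
        vol[:, (yy - 20) ** 2 + (xx - 20) ** 2 <= r * r] = 100.0
        zz, yy, xx = np.ogrid[:height, :64, :64]
        vol[(zz - 40) ** 2 + (yy - 44) ** 2 + (xx - 44) ** 2 <= r * r] = 100.0
        sigma = r / np.sqrt(2)
        tb = tubeness(vol, (sigma,)).values
        cyl, sph = tb[32, 20, 20], tb[40, 44, 44]
        assert cyl == pytest.approx(100 * analytic_cylinder_response(r, sigma),
                                    rel=0.02)
        assert sph == pytest.approx(100 * analytic_sphere_response(r, sigma),
                                    rel=0.03)
        assert cyl > 1.2 * sph

    def test_constant_volume_gives_zero(self):
        assert tubeness(np.full((16, 16, 16), 9.0)).values.max() == 0.0

    def test_plate_midplane_response_vanishes(self):
        # only one strongly negative eigenvalue on a plate: its response is
        # single-precision noise, orders below a tube of matching width
        vol = np.zeros((64, 64, 64), np.float32)
        vol[30:34] = 100.0                        # plate, thickness 4
        yy, xx = np.ogrid[:64, :64]
        tube = (yy - 48) ** 2 + (xx - 48) ** 2 <= 2 ** 2
        vol[np.broadcast_to(tube, vol.shape) & (np.arange(64) < 20)[:, None, None]] = 100.0
        tb = tubeness(vol, (2.0,)).values
        assert tb[32, 10, 10] < 0.05 * tb[10, 48, 48]

    def test_multiscale_is_sum_of_single_scales(self, noisy_phantom):
        _, vol, _ = noisy_phantom
        data = vol.data[:48, :48, :48]
        sigmas = (1.0, 2.0, 4.0)
        multi = tubeness(data, sigmas).values
        summed = sum(tubeness(data, (s,)).values for s in sigmas)
        assert np.abs(multi - summed).max() < 1e-4 * max(multi.max(), 1.0)

    def test_roi_restriction_matches_full_run(self, noisy_phantom):
        _, vol, truth = noisy_phantom
        data = vol.data[:48, :48, :48]
        roi = truth.label_volume[:48, :48, :48] == 2
        full = tubeness(data).values
        part = tubeness(data, roi_mask=roi).values
        assert np.allclose(part[roi], full[roi], rtol=1e-3, atol=1e-3)
        assert (part[~roi] == 0).all()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            tubeness(np.zeros((16, 16, 16)), ())
        with pytest.raises(ValueError):
            tubeness(np.zeros((16, 16, 16)), (0.4,))
        with pytest.raises(ValueError):
            tubeness(np.zeros((3, 16, 16)))


@pytest.fixture(scope="module")
def leaky_phantom():
    """Phantom with contrast pools pushed clear of the vessel surface."""
    spec = PhantomSpec(dims=(96, 96, 96), cortex_outer_radius_um=150.0,
                       n_leaks=5, leak_offset_um=110.0, leak_radius_um=40.0,
                       noise_sd=0.0, geometry_seed=0)
    vol, truth = generate_phantom(spec)
    tb = tubeness(vol.data)
    return spec, vol, truth, tb


def centerline_coverage(truth, mask, dims):
    total = kept = 0
    vessel = (truth.label_volume == 2) & ~truth.leak_mask
    for pts, _ in truth.vessel_centerlines:
        ip = np.round(pts).astype(int)
        ip = ip[(ip >= 0).all(1) & (ip < dims).all(1)]
        inside = vessel[ip[:, 0], ip[:, 1], ip[:, 2]]
        total += int(inside.sum())
        kept += int((inside & mask[ip[:, 0], ip[:, 1], ip[:, 2]]).sum())
    return kept / total


class TestRemoveLeaks:
    def test_detached_blobs_removed_and_centerlines_kept(self, leaky_phantom):
        spec, vol, truth, tb = leaky_phantom
        # precondition: the five pools really are detached from the tree
        vessel_only = (truth.label_volume == 2) & ~truth.leak_mask
        dilated = ndimage.binary_dilation(
            vessel_only, ndimage.generate_binary_structure(3, 3))
        assert not (dilated & truth.leak_mask).any()
        _, n_pools = ndimage.label(
            truth.leak_mask, structure=ndimage.generate_binary_structure(3, 3))
        assert n_pools == 5
        vessel_with_leaks = truth.label_volume == 2
        cleaned = remove_leaks(vessel_with_leaks, tb)
        assert (cleaned & truth.leak_mask).sum() == 0
        assert centerline_coverage(truth, cleaned, np.array(spec.dims)) >= 0.99

    def test_no_leaks_is_identity(self):
        spec = PhantomSpec(dims=(64, 64, 64), cortex_outer_radius_um=100.0,
                           n_leaks=0, noise_sd=0.0)
        vol, truth = generate_phantom(spec)
        vessel = truth.label_volume == 2
        tb = tubeness(vol.data)
        assert (remove_leaks(vessel, tb) == vessel).all()

    def test_idempotent(self, leaky_phantom):
        _, _, truth, tb = leaky_phantom
        once = remove_leaks(truth.label_volume == 2, tb)
        twice = remove_leaks(once, tb)
        assert (twice == once).all()

    def test_attached_leak_preserves_vessel_continuity(self):
        spec = PhantomSpec(dims=(96, 96, 96), cortex_outer_radius_um=150.0,
                           n_leaks=4, leak_offset_um=0.0, noise_sd=0.0,
                           geometry_seed=3)
        vol, truth = generate_phantom(spec)
        vessel = truth.label_volume == 2
        tb = tubeness(vol.data)
        cleaned = remove_leaks(vessel, tb)
        s26 = ndimage.generate_binary_structure(3, 3)
        _, n_before = ndimage.label(vessel, structure=s26)
        _, n_after = ndimage.label(cleaned, structure=s26)
        assert n_after <= n_before

    def test_empty_mask_warns_and_returns_empty(self, caplog):
        tb = TubenessMap(np.zeros((16, 16, 16), np.float32), [1.0])
        with caplog.at_level("WARNING"):
            out = remove_leaks(np.zeros((16, 16, 16), bool), tb)
        assert not out.any()


class TestPartitionVessels:
    def test_thin_cylinder_is_all_capillary(self):
        # diameter ~8 um at 3.5 um voxels: well under the d1=10 cutoff
        mask = np.zeros((64, 16, 16), bool)
        yy, xx = np.ogrid[:16, :16]
        mask[:, (yy - 8) ** 2 + (xx - 8) ** 2 <= 1.3 ** 2] = True
        th = morphometry.local_thickness(mask, 3.5)
        part = partition_vessels(mask, th)
        assert part.counts["capillary"] == int(mask.sum())
        assert part.counts["sinusoid"] == 0 and part.counts["artery_vein"] == 0

    def test_default_tree_spans_all_three_classes(self):
        spec = PhantomSpec(dims=(96, 96, 96), cortex_outer_radius_um=150.0,
                           n_leaks=0)
        truth = __import__("osteovasc.phantom", fromlist=["generate_truth"]) \
            .generate_truth(spec)
        vessel = truth.label_volume == 2
        th = morphometry.local_thickness(vessel, spec.voxel_size_um)
        part = partition_vessels(vessel, th)
        assert all(v > 0 for v in part.counts.values())

    def test_partition_is_disjoint_cover(self, noisy_phantom):
        spec, _, truth = noisy_phantom
        vessel = (truth.label_volume == 2) & ~truth.leak_mask
        th = morphometry.local_thickness(vessel, spec.voxel_size_um)
        part = partition_vessels(vessel, th)
        assert ((part.labels > 0) == vessel).all()
        assert sum(part.counts.values()) == int(vessel.sum())

    def test_equal_cutoffs_rejected(self):
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError):
            partition_vessels(mask, np.ones((8, 8, 8)), 10.0, 10.0)

    def test_empty_mask_gives_empty_partition(self):
        part = partition_vessels(np.zeros((8, 8, 8), bool), np.zeros((8, 8, 8)))
        assert sum(part.counts.values()) == 0
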