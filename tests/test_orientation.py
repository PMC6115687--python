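"""Structure-tensor orientation extraction and downsampling."""
import numpy as np
import pytest

from atriasim import orientation as ori
from atriasim.phantoms import FiberPhantomSpec, make_fiber_phantom
from atriasim.volumes import ImageVolume, OrientationField


def _params(vol, sg=1.0, sw=4.0):
    vox_um = vol.spacing_mm * 1000.0
    return ori.StructureTensorParams(sg * vox_um, sw * vox_um)


class TestStructureTensor:
    def test_constant_volume_gives_zero_tensor(self):
        vol = ImageVolume(np.full((16, 16, 16), 3.7), 0.04)
        tf = ori.compute_structure_tensor(vol, _params(vol))
        assert np.allclose(tf.components, 0.0, atol=1e-12)

    def test_ramp_gives_rank_one_tensor_along_gradient(self):
        x = np.arange(24, dtype=float)
        vol = ImageVolume(np.broadcast_to(x[:, None, None], (24, 24, 24)).copy(),
                          0.04)
        tf = ori.compute_structure_tensor(vol, _params(vol))
        m = tf.as_matrices()[12, 12, 12]
        w, v = np.linalg.eigh(m)
        assert w[2] > 1e-6                      # one strong eigenvalue
        assert w[1] < 1e-9 * w[2]               # others vanish
        assert abs(v[:, 2] @ (1.0, 0.0, 0.0)) > 0.999

    def test_psd_within_tolerance_on_textured_volume(self, parallel_phantom):
        (vol, _), _ = parallel_phantom
        tf = ori.compute_structure_tensor(vol, _params(vol))
        rng2 = (vol.data.max() - vol.data.min()) ** 2
        assert tf.min_eigenvalue() > -1e-9 * rng2

    def test_gradient_energy_perpendicular_to_fibers(self, parallel_phantom):
        """Independent oracle: per-voxel outer products of np.gradient on a
        16^3 crop; the summed tensor's dominant eigenvector must be
        perpendicular to the fiber axis (1,0,0)."""
        (vol, _), _ = parallel_phantom
        crop = vol.data[16:32, 16:32, 16:32]
        gx, gy, gz = np.gradient(crop)
        J = np.zeros((3, 3))
        for a, ga in enumerate((gx, gy, gz)):
            for b, gb in enumerate((gx, gy, gz)):
                J[a, b] = np.sum(ga * gb)
        w, v = np.linalg.eigh(J)
        assert abs(v[:, 2] @ (1.0, 0.0, 0.0)) < 0.2
        # and the package's tensor agrees: its smallest-eigenvector at the
        # crop centre lies along the fiber
        tf = ori.compute_structure_tensor(vol, _params(vol))
        field = ori.extract_orientation(tf)
        assert abs(field.vectors[24, 24, 24] @ (1.0, 0.0, 0.0)) > 0.99

    def test_anisotropic_metadata_rejected(self):
        vol = ImageVolume(np.zeros((16, 16, 16)), 0.04,
                          meta={"anisotropic": True})
        with pytest.raises(ValueError, match="isotropic"):
            ori.compute_structure_tensor(vol, _params(vol))

    def test_window_smaller_than_gradient_scale_rejected(self):
        with pytest.raises(ValueError):
            ori.StructureTensorParams(40.0, 20.0)


class TestExtractOrientation:
    def test_parallel_phantom_recovered_below_two_degrees(self, parallel_phantom):
        (vol, truth), _ = parallel_phantom
        tf = ori.compute_structure_tensor(vol, _params(vol))
        field = ori.extract_orientation(tf)
        stats = ori.angular_error(field, truth)
        assert stats["median_deg"] < 2.0

    def test_circular_phantom_error_below_five_degrees_off_axis(self):
        vol, truth = make_fiber_phantom(
            FiberPhantomSpec(pattern="circular", grid_shape=(64, 64, 40),
                             fiber_texture_period_um=600.0, seed=5))
        tf = ori.compute_structure_tensor(vol, _params(vol))
        field = ori.extract_orientation(tf)
        # mask out the axis singularity (tangent undefined) and the boundary
        nx, ny = 64, 64
        x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        r = np.hypot(x - (nx - 1) / 2, y - (ny - 1) / 2)
        mask = np.zeros(vol.shape, bool)
        mask[5:-5, 5:-5, 4:-4] = True
        mask &= (r > 10)[:, :, None]
        stats = ori.angular_error(field, truth, mask)
        assert stats["median_deg"] < 5.0

    def test_isotropic_noise_has_near_zero_coherence(self):
        rng = np.random.default_rng(2)
        vol = ImageVolume(rng.standard_normal((32, 32, 32)), 0.04)
        tf = ori.compute_structure_tensor(vol, _params(vol))
        field = ori.extract_orientation(tf)
        assert np.median(field.coherence) < 0.1

    def test_rotation_equivariance_about_grid_axis(self, parallel_phantom):
        """Rotating the volume by 90 degrees rotates the extracted field."""
        (vol, _), _ = parallel_phantom
        tf = ori.compute_structure_tensor(vol, _params(vol))
        f0 = ori.extract_orientation(tf)
        rot = ImageVolume(np.rot90(vol.data, k=1, axes=(0, 1)).copy(),
                          vol.spacing_mm)
        f1 = ori.extract_orientation(ori.compute_structure_tensor(rot, _params(rot)))
        # rotate f0's vectors: (x,y,z) -> (-y,x,z), on the rotated grid
        v0 = np.rot90(f0.vectors, k=1, axes=(0, 1))
        v0r = np.stack([-v0[..., 1], v0[..., 0], v0[..., 2]], axis=-1)
        stats = ori.angular_error(f1.vectors, v0r)
        assert stats["median_deg"] < 2.0

    def test_noise_never_improves_recovery(self):
        """Median angular error is non-decreasing in the texture noise level
        (averaged over seeds)."""
        med = []
        for noise in (0.0, 0.15, 0.4):
            errs = []
            for seed in (0, 1, 2):
                vol, truth = make_fiber_phantom(
                    FiberPhantomSpec(grid_shape=(32, 32, 32), noise_sd=noise,
                                     seed=seed))
                tf = ori.compute_structure_tensor(vol, _params(vol))
                field = ori.extract_orientation(tf)
                errs.append(ori.angular_error(field, truth)["median_deg"])
            med.append(np.mean(errs))
        assert med[0] <= med[1] + 0.05 and med[1] <= med[2] + 0.05

    def test_tissue_mask_zeroes_background(self, parallel_phantom):
        (vol, _), _ = parallel_phantom
        tf = ori.compute_structure_tensor(vol, _params(vol))
        mask = np.zeros(vol.shape, bool)
        mask[:24] = True
        field = ori.extract_orientation(tf, mask)
        assert np.allclose(field.vectors[~mask], 0.0)
        assert np.allclose(np.linalg.norm(field.vectors[mask], axis=-1), 1.0)


class TestDownsampling:
    def test_uniform_fields_unchanged(self):
        vol = ImageVolume(np.full((24, 24, 24), 2.0), 0.075)
        out = ori.downsample_scalar(vol, 0.15)
        assert out.shape == (12, 12, 12)
        assert np.allclose(out.data, 2.0)
        vec = np.zeros((24, 24, 24, 3))
        vec[..., 0] = 1.0
        f = OrientationField(vec, np.ones((24, 24, 24)), 0.075)
        fo = ori.downsample_orientation(f, 0.15)
        assert np.allclose(np.abs(fo.vectors[..., 0]), 1.0)

    def test_axial_averaging_does_not_cancel_antipodal_vectors(self):
        vec = np.zeros((2, 2, 2, 3))
        vec[0, ..., 0] = 1.0
        vec[1, ..., 0] = -1.0
        f = OrientationField(vec, np.ones((2, 2, 2)), 0.075)
        fo = ori.downsample_orientation(f, 0.15)
        assert np.allclose(np.abs(fo.vectors[0, 0, 0, 0]), 1.0)

    def test_block_majority_vote_background_loses_ties(self):
        from atriasim.volumes import LabelVolume
        lab = np.zeros((2, 2, 2), np.int16)
        lab[0, 0, 0] = 3
        lab[0, 0, 1] = 3
        lab[0, 1, 0] = 3
        lab[0, 1, 1] = 3  # 4 tissue vs 4 background -> tissue wins
        out = ori.downsample_labels(LabelVolume(lab, 0.075), 0.15)
        assert out.data[0, 0, 0] == 3

    def test_two_fold_decimation_preserves_parallel_recovery(self, parallel_phantom):
        (vol, truth), _ = parallel_phantom
        tf = ori.compute_structure_tensor(vol, _params(vol))
        field = ori.extract_orientation(tf)
        full = ori.angular_error(field, truth)["median_deg"]
        f2 = ori.downsample_orientation(field, 2 * vol.spacing_mm)
        t2 = ori.downsample_orientation(truth, 2 * vol.spacing_mm)
        dec = ori.angular_error(f2, t2)["median_deg"]
        assert abs(dec - full) < 1.0

    def test_target_below_source_spacing_rejected(self):
        vol = ImageVolume(np.zeros((16, 16, 16)), 0.15)
        with pytest.raises(ValueError):
            ori.downsample_scalar(vol, 0.075)

    def test_label_majority_vote_matches_binomial_oracle(self):
        """Block majority voting amplifies the majority class: for iid
        voxels with tissue probability p=0.7 in 2x2x2 blocks, the output
        tissue fraction is P(Binomial(8, 0.7) >= 4) (ties go to tissue)."""
        from scipy.stats import binom

        from atriasim.volumes import LabelVolume
        rng = np.random.default_rng(0)
        lab = (rng.random((24, 24, 24)) < 0.7).astype(np.int16) * 5
        out = ori.downsample_labels(LabelVolume(lab, 0.075), 0.15)
        expected = binom.sf(3, 8, 0.7)  # P(X >= 4)
        assert np.mean(out.data == 5) == pytest.approx(expected, abs=0.03)


class TestAngularError:
    def test_identical_and_antipodal_fields_give_zero(self):
        vec = np.zeros((4, 4, 4, 3))
        vec[..., 2] = 1.0
        f = OrientationField(vec, np.ones((4, 4, 4)), 0.1)
        g = OrientationField(-vec, np.ones((4, 4, 4)), 0.1)
        assert ori.angular_error(f, f)["median_deg"] == 0.0
        assert ori.angular_error(f, g)["median_deg"] == 0.0

    def test_random_vectors_vs_fixed_axis_median_sixty_degrees(self):
        """For uniformly distributed axes, |cos(angle to a fixed axis)| is
        Uniform(0,1), so the median axial error is arccos(1/2) = 60 deg."""
        rng = np.random.default_rng(123)
        v = rng.standard_normal((20, 20, 20, 3))
        v /= np.linalg.norm(v, axis=-1, keepdims=True)
        truth = np.zeros_like(v)
        truth[..., 0] = 1.0
        stats = ori.angular_error(v, truth)
        assert stats["median_deg"] == pytest.approx(60.0, abs=2.0)

    def test_mismatched_grids_rejected(self):
        a = np.zeros((4, 4, 4, 3))
        b = np.zeros((5, 4, 4, 3))
        with pytest.raises(ValueError):
            ori.angular_error(a, b)
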