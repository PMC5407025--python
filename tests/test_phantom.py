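"""Phantom generator: geometry, determinism, corruption models."""

import numpy as np
import pytest

from vsoptrack import (
    ConfigurationError,
    PhantomConfig,
    RigidTransform,
    VolumeImage,
    apply_bias_field,
    apply_rigid,
    dice_coefficient,
    generate_phantom,
    migrate_speckles,
)
from vsoptrack.phantom import ellipsoid_volume_mm3


class TestGeneratePhantom:
    def test_structure_free_t2star_is_constant_over_brain(self, clean_config):
        _, t2star, truth = generate_phantom(clean_config())
        vals = t2star.data[truth.brain_mask]
        assert np.ptp(vals) == 0.0
        assert np.all(t2star.data[~truth.brain_mask] == 0.0)

    def test_identical_seed_is_bit_identical(self, small_config):
        cfg = small_config(seed=7, hyper_speckle_fraction=0.3)
        t2_a, t2star_a, truth_a = generate_phantom(cfg)
        t2_b, t2star_b, truth_b = generate_phantom(cfg)
        assert np.array_equal(t2_a.data, t2_b.data)
        assert np.array_equal(t2star_a.data, t2star_b.data)
        assert np.array_equal(truth_a.speckle_voxels_hypo,
                              truth_b.speckle_voxels_hypo)
        assert np.array_equal(truth_a.bias_field, truth_b.bias_field)

    def test_analytic_lesion_volume(self, clean_config):
        cfg = clean_config(lesion_axes_mm=(2.0, 2.0, 2.0))
        _, _, truth = generate_phantom(cfg)
        assert truth.lesion_volume_mm3 == pytest.approx(
            4.0 / 3.0 * np.pi * 8.0, abs=1e-9)
        assert truth.lesion_volume_mm3 == pytest.approx(33.51, abs=0.01)

    def test_speckle_counts_and_placement(self, small_config):
        cfg = small_config(n_speckles=50, hyper_speckle_fraction=0.2, seed=3)
        _, _, truth = generate_phantom(cfg)
        assert len(truth.speckle_voxels_hyper) == 10
        assert len(truth.speckle_voxels_hypo) == 40
        for vox in np.vstack([truth.speckle_voxels_hypo,
                              truth.speckle_voxels_hyper]):
            assert truth.brain_mask[tuple(vox)]
            # affected (right) hemisphere only
            assert vox[0] > truth.midline_plane

    def test_voxelized_volume_close_to_analytic(self, clean_config):
        """Voxelization error is bounded by the surface-voxel count."""
        _, _, truth = generate_phantom(clean_config())
        cfg = clean_config()
        vox_vol = float(np.prod(cfg.voxel_size_mm))
        voxelized = truth.lesion_mask.sum() * vox_vol
        from scipy import ndimage
        surface = truth.lesion_mask & ~ndimage.binary_erosion(truth.lesion_mask)
        bound = 3.0 * vox_vol * surface.sum()
        assert abs(voxelized - truth.lesion_volume_mm3) <= bound

    def test_lesion_outside_brain_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(lesion_center_mm=(5.0, 0.0, 0.0),
                          lesion_axes_mm=(2.5, 2.0, 3.0))

    def test_lesion_across_midline_rejected(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(lesion_center_mm=(1.0, 0.0, 0.0),
                          lesion_axes_mm=(2.0, 2.0, 3.0))

    def test_too_many_speckles_rejected(self, clean_config):
        with pytest.raises(ConfigurationError):
            generate_phantom(clean_config(n_speckles=10 ** 6))


class TestBiasField:
    def _flat(self, clean_config):
        _, t2star, truth = generate_phantom(clean_config())
        return t2star, truth.brain_mask

    def test_zero_amplitude_is_identity(self, clean_config):
        vol, mask = self._flat(clean_config)
        out, field = apply_bias_field(vol, amplitude=0.0, seed=5, mask=mask)
        assert np.array_equal(out.data, vol.data)
        assert np.all(field.data == 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_field_mean_is_one_over_mask(self, clean_config, seed):
        vol, mask = self._flat(clean_config)
        _, field = apply_bias_field(vol, amplitude=0.15, seed=seed, mask=mask)
        assert field.data[mask].mean() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_peak_deviation_tracks_amplitude(self, clean_config, seed):
        vol, mask = self._flat(clean_config)
        _, field = apply_bias_field(vol, amplitude=0.2, seed=seed, mask=mask)
        peak = np.abs(field.data[mask] - 1.0).max()
        assert 0.15 <= peak <= 0.25

    def test_negative_amplitude_rejected(self, clean_config):
        vol, mask = self._flat(clean_config)
        with pytest.raises(ConfigurationError):
            apply_bias_field(vol, amplitude=-0.1, mask=mask)


class TestApplyRigid:
    def test_identity_returns_input_bit_exact(self, clean_config):
        _, t2star, _ = generate_phantom(clean_config())
        out = apply_rigid(t2star, RigidTransform())
        assert np.array_equal(out.data, t2star.data)

    def test_translation_roundtrip(self, clean_config):
        _, t2star, _ = generate_phantom(clean_config())
        fwd = apply_rigid(t2star, RigidTransform(translation_vox=(2, 0, 0)))
        back = apply_rigid(fwd, RigidTransform(translation_vox=(-2, 0, 0)))
        interior = np.zeros(t2star.shape, bool)
        interior[3:-3, 3:-3, 3:-3] = True
        assert np.abs(back.data - t2star.data)[interior].max() < 1e-6

    def test_sphere_invariant_under_rotation(self):
        """A sphere about the rotation centre keeps its mask under rotation."""
        shape = (80, 80, 80)
        spacing = (0.15, 0.15, 0.15)
        center = (np.asarray(shape) - 1) / 2.0
        grid = np.indices(shape).astype(float)
        r = np.sqrt(sum((grid[i] - center[i]) ** 2 * spacing[i] ** 2
                        for i in range(3)))
        vol = VolumeImage(np.where(r <= 4.5, 1000.0, 0.0), spacing)
        rot = apply_rigid(vol, RigidTransform(rotation_deg=(0, 0, 10)))
        dice = dice_coefficient(rot.data > 500, vol.data > 500)
        assert dice >= 0.99

    def test_out_of_range_transform_rejected(self, clean_config):
        _, t2star, _ = generate_phantom(clean_config())
        with pytest.raises(ConfigurationError):
            apply_rigid(t2star, RigidTransform(rotation_deg=(35, 0, 0)))
        with pytest.raises(ConfigurationError):
            apply_rigid(t2star, RigidTransform(translation_vox=(40, 0, 0)))


class TestMigrateSpeckles:
    @pytest.fixture
    def truth(self, small_config):
        _, _, truth = generate_phantom(small_config(n_speckles=40, seed=2))
        return truth

    def test_zero_moves_is_identity(self, truth):
        out = migrate_speckles(truth, 0, (1.0, 0.0, 0.0))
        assert np.array_equal(out.speckle_voxels_hypo,
                              truth.speckle_voxels_hypo)

    @pytest.mark.parametrize("k", [1, 5, 15])
    def test_set_bookkeeping_and_conservation(self, truth, small_config, k):
        cfg = small_config()
        out = migrate_speckles(truth, k, (0.0, 1.0, 0.0), seed=4,
                               voxel_size_mm=cfg.voxel_size_mm)
        before = {tuple(v) for v in truth.speckle_voxels_hypo}
        after = {tuple(v) for v in out.speckle_voxels_hypo}
        assert len(after) == len(before)
        assert len(before - after) == k
        assert len(after - before) == k
        for vox in after:
            assert truth.brain_mask[vox]

    def test_outside_displacement_errors_when_requested(self, truth,
                                                        small_config):
        cfg = small_config()
        with pytest.raises(ConfigurationError):
            migrate_speckles(truth, 10, (6.0, 0.0, 0.0), seed=1,
                             voxel_size_mm=cfg.voxel_size_mm,
                             on_outside="error")
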