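"""T2* speckle re-analysis: filters, thresholding, classification,
longitudinal comparison."""

import dataclasses

import numpy as np
import pytest

from vsoptrack import (
    ConfigurationError,
    RigidTransform,
    SpeckleConfig,
    VolumeImage,
    build_speckle_map,
    classify_hypointense,
    compare_timepoints,
    correct_bias,
    extract_brain,
    generate_longitudinal,
    generate_phantom,
    median_residual,
    migrate_speckles,
    normalize_mean,
    plant_cluster,
    render_session,
    threshold_speckles,
    wiener_denoise,
)
from vsoptrack.roi_stats import split_hemispheres


# ---------------------------------------------------------------------------
# brute-force per-voxel oracles (reflective padding, direct window loops)
# ---------------------------------------------------------------------------

def median_residual_oracle(data, kernel):
    r = kernel // 2
    # numpy's "symmetric" equals the edge-including reflection used by the
    # implementation
    pad = np.pad(data, r, mode="symmetric")
    out = np.empty_like(data, dtype=float)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                win = pad[i:i + kernel, j:j + kernel, k:k + kernel]
                out[i, j, k] = abs(data[i, j, k] - np.median(win))
    return out


def wiener_oracle(data, window):
    r = window // 2
    pad = np.pad(data, r, mode="symmetric")
    mu = np.empty_like(data, dtype=float)
    var = np.empty_like(data, dtype=float)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                win = pad[i:i + window, j:j + window, k:k + window]
                mu[i, j, k] = win.mean()
                var[i, j, k] = win.var()
    nu = var.mean()
    gain = np.where(var > nu, (var - nu) / np.maximum(var, nu), 0.0)
    return mu + gain * (data - mu)


def _vol(data):
    return VolumeImage(np.asarray(data, float), (1.0, 1.0, 1.0))


class TestMedianResidual:
    def test_constant_volume_is_zero(self):
        out = median_residual(_vol(np.full((8, 8, 4), 7.0)))
        assert np.all(out.data == 0.0)

    def test_single_impulse(self):
        data = np.full((9, 9, 5), 100.0)
        data[4, 4, 2] += 50.0
        out = median_residual(_vol(data), kernel_vox=3)
        assert out.data[4, 4, 2] == pytest.approx(50.0)
        far = np.ones_like(data, bool)
        far[3:6, 3:6, 1:4] = False
        assert np.all(out.data[far] == 0.0)

    def test_linear_ramp_interior_is_zero(self):
        data = np.broadcast_to(np.arange(12, dtype=float)[:, None, None],
                               (12, 6, 6)).copy()
        out = median_residual(_vol(data))
        assert np.all(np.abs(out.data[1:-1]) < 1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            median_residual(_vol(np.zeros((4, 4, 4))), kernel_vox=4)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        data = rng.uniform(0, 100, (8, 8, 4))
        got = median_residual(_vol(data), kernel_vox=3).data
        want = median_residual_oracle(data, 3)
        assert np.abs(got - want).max() <= 1e-10


class TestWienerDenoise:
    def test_constant_input_unchanged(self):
        out = wiener_denoise(_vol(np.full((8, 8, 4), 3.0)))
        assert np.allclose(out.data, 3.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_reduces_noise_variance(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 1, (16, 16, 8))
        out = wiener_denoise(_vol(data))
        assert out.data.var() < data.var()

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            wiener_denoise(_vol(np.zeros((4, 4, 4))), window_vox=2)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        data = rng.uniform(0, 50, (8, 8, 4))
        got = wiener_denoise(_vol(data), window_vox=3).data
        want = wiener_oracle(data, 3)
        assert np.abs(got - want).max() <= 1e-10


class TestThresholdSpeckles:
    def test_constant_hemisphere_gives_empty_mask(self):
        vol = _vol(np.full((4, 4, 2), 5.0))
        hemi = np.ones((4, 4, 2), bool)
        mask, thr = threshold_speckles(vol, hemi)
        assert thr == pytest.approx(5.0)
        assert not mask.any()  # strict inequality

    def test_hand_computed_threshold(self):
        data = np.zeros((10, 1, 1))
        data[9] = 30.0
        vol = _vol(data)
        hemi = np.ones((10, 1, 1), bool)
        mask, thr = threshold_speckles(vol, hemi)
        # mean 3, sample SD sqrt(90) = 9.4868
        assert thr == pytest.approx(3 + 2 * np.sqrt(90.0), abs=1e-6)
        assert mask.sum() == 1 and mask[9, 0, 0]

    def test_mask_subset_of_hemisphere(self):
        rng = np.random.default_rng(1)
        vol = _vol(rng.normal(0, 1, (8, 8, 4)))
        hemi = np.zeros((8, 8, 4), bool)
        hemi[:4] = True
        mask, _ = threshold_speckles(vol, hemi)
        assert np.all(hemi[mask])


class TestClassifyHypointense:
    def test_empty_input_is_empty(self):
        vol = _vol(np.full((4, 4, 2), 1000.0))
        out = classify_hypointense(np.zeros((4, 4, 2), bool), vol, 1000.0)
        assert not out.any()

    def test_bimodal_split_keeps_low_class(self):
        data = np.full((10, 1, 1), 1000.0)
        data[:5] = 800.0
        data[5:] = 1200.0
        vol = _vol(data)
        speckled = np.ones((10, 1, 1), bool)
        out = classify_hypointense(speckled, vol, 1000.0)
        assert out[:5].all() and not out[5:].any()

    def test_all_hyperintense_gives_empty(self):
        data = np.full((10, 1, 1), 1200.0)
        data[:5] = 1100.0
        vol = _vol(data)
        out = classify_hypointense(np.ones((10, 1, 1), bool), vol, 1000.0)
        assert not out.any()

    def test_unimodal_hypointense_population_is_kept_whole(self):
        """A pure cell population must not be halved by the histogram split."""
        rng = np.random.default_rng(3)
        data = rng.normal(500.0, 10.0, (10, 1, 1))
        vol = _vol(data)
        out = classify_hypointense(np.ones((10, 1, 1), bool), vol, 1000.0)
        assert out.all()


def _analyze(t2star, config=None):
    mask = extract_brain(t2star)
    corrected, _ = correct_bias(t2star, mask)
    normalized = normalize_mean(corrected, mask)
    return build_speckle_map(normalized, mask, config), mask, normalized


class TestBuildSpeckleMap:
    def test_mask_nesting(self, small_config):
        _, t2star, _ = generate_phantom(small_config(seed=6))
        smap, mask, _ = _analyze(t2star)
        aff, _ = split_hemispheres(mask)
        assert np.all(smap.speckled_mask[smap.hypo_mask])
        assert np.all(aff[smap.speckled_mask])
        assert smap.voxel_count == int(smap.hypo_mask.sum())

    def test_recovers_planted_speckles(self, small_config):
        _, t2star, truth = generate_phantom(small_config(n_speckles=100,
                                                         seed=8))
        smap, _, _ = _analyze(t2star)
        planted = {tuple(v) for v in truth.speckle_voxels_hypo}
        detected = {tuple(v) for v in np.argwhere(smap.hypo_mask)}
        tp = len(planted & detected)
        assert tp / len(planted) >= 0.9
        assert tp / max(len(detected), 1) >= 0.9

    def test_hyper_speckles_rejected(self, small_config):
        _, t2star, truth = generate_phantom(
            small_config(n_speckles=100, hyper_speckle_fraction=0.5, seed=9))
        smap, _, _ = _analyze(t2star)
        hyper = {tuple(v) for v in truth.speckle_voxels_hyper}
        detected = {tuple(v) for v in np.argwhere(smap.hypo_mask)}
        if detected:
            assert len(detected & hyper) / len(detected) <= 0.05

    def test_count_invariant_to_global_rescaling(self, small_config):
        """Scaling raw data before normalization cannot change the count."""
        _, t2star, _ = generate_phantom(small_config(seed=10))
        smap_a, _, _ = _analyze(t2star)
        smap_b, _, _ = _analyze(t2star.with_data(t2star.data * 4.2))
        assert smap_a.voxel_count == smap_b.voxel_count

    def test_noise_driven_count_is_bounded(self, small_config):
        """Without speckles the self-referenced mean+2SD rule keeps roughly
        the Gaussian tail; the count stays a small fraction of the
        hemisphere (the analogue of nonzero counts in control animals)."""
        _, t2star, _ = generate_phantom(small_config(n_speckles=0, seed=11))
        smap, mask, _ = _analyze(t2star)
        aff, _ = split_hemispheres(mask)
        assert smap.voxel_count < 0.035 * aff.sum()

    @pytest.mark.parametrize("seeds", [range(5)])
    def test_sensitivity_monotone_in_contrast(self, small_config, seeds):
        sens = []
        for contrast in (0.1, 0.3, 0.5):
            vals = []
            for seed in seeds:
                _, t2star, truth = generate_phantom(
                    small_config(n_speckles=80, speckle_contrast=contrast,
                                 seed=100 + seed))
                smap, _, _ = _analyze(t2star)
                planted = {tuple(v) for v in truth.speckle_voxels_hypo}
                detected = {tuple(v) for v in np.argwhere(smap.hypo_mask)}
                vals.append(len(planted & detected) / len(planted))
            sens.append(np.mean(vals))
        assert sens[0] <= sens[1] <= sens[2]


class TestCompareTimepoints:
    def test_identical_maps_are_stable(self, small_config):
        cfg = small_config(seed=12)
        _, t2star, _ = generate_phantom(cfg)
        smap, _, _ = _analyze(t2star)
        report = compare_timepoints(smap, smap, RigidTransform(),
                                    voxel_size_mm=cfg.voxel_size_mm)
        assert report.relative_change_percent == 0.0
        assert not report.appeared and not report.disappeared
        assert len(report.matched) == len(smap.clusters)

    def test_migrated_cluster_detected(self, small_config):
        """One relocated cell deposit shows up as exactly one appeared and
        one disappeared cluster."""
        cfg = small_config(n_speckles=5, noise_sigma=0.01, seed=13)
        t2, t2star, truth = generate_phantom(cfg)
        center = np.asarray(np.argwhere(truth.lesion_mask).mean(axis=0),
                            dtype=int)
        # small deposit: every blob voxel keeps a background-dominated
        # median window, so the whole blob survives the residual filter
        t2star, truth = plant_cluster(truth, t2star, tuple(center),
                                      radius_mm=0.16, contrast=0.5)
        blob = truth.speckle_voxels_hypo[5:]
        moved = migrate_speckles(truth, len(blob), (0.0, 2.0, 0.0),
                                 voxel_size_mm=cfg.voxel_size_mm,
                                 voxels=blob, on_outside="error")
        _, t2star_9d = render_session(cfg, moved, seed=99)
        smap_a, _, _ = _analyze(t2star)
        smap_b, _, _ = _analyze(t2star_9d)
        report = compare_timepoints(smap_a, smap_b, RigidTransform(),
                                    voxel_size_mm=cfg.voxel_size_mm)
        assert len(report.appeared) == 1
        assert len(report.disappeared) == 1

    def test_grid_mismatch_rejected(self, small_config):
        _, t2star, _ = generate_phantom(small_config(seed=14))
        smap, _, _ = _analyze(t2star)
        other = dataclasses.replace(
            smap, hypo_mask=np.zeros((4, 4, 2), bool),
            speckled_mask=np.zeros((4, 4, 2), bool))
        with pytest.raises(Exception):
            compare_timepoints(smap, other, RigidTransform())
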