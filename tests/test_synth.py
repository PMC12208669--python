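"""Synthetic scene generators: determinism, noise statistics, render fidelity."""

import numpy as np
import pytest

from lfspim.synth import (
    FWHM_PER_SIGMA,
    CameraNoiseModel,
    make_bead_phantom,
    make_dot_grid,
    make_ronchi_stack,
)


class TestCameraNoiseModel:
    def test_photon_transfer_relation(self):
        # var(uniform patch) == gain * (mean - offset) + read_noise^2 within 5%
        model = CameraNoiseModel(offset=100.0, read_noise=3.0, gain=2.0)
        img = model.apply(np.full(10**6, 1000.0), rng=np.random.default_rng(0))
        mean, var = img.astype(float).mean(), img.astype(float).var()
        predicted = model.gain * (mean - model.offset) + model.read_noise**2
        assert var == pytest.approx(predicted, rel=0.05)

    def test_clipping_to_bit_depth(self):
        model = CameraNoiseModel(offset=100.0, read_noise=0.0, gain=1.0)
        out = model.apply(np.full(10, 1e6), rng=np.random.default_rng(0), bit_depth=12)
        assert out.max() == 2**12 - 1

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            CameraNoiseModel(read_noise=-1.0)
        with pytest.raises(ValueError):
            CameraNoiseModel(gain=0.0)


class TestBeadPhantom:
    def test_same_seed_bit_identical(self, default_noise):
        kwargs = dict(
            shape=(24, 64, 64), n_beads=5, fwhm_model=(2.0, 2.0, 3.0),
            noise=default_noise, seed=3, voxel_size_um=(1.0, 1.0, 1.0),
            placement="jittered_grid",
        )
        v1, t1 = make_bead_phantom(**kwargs)
        v2, t2 = make_bead_phantom(**kwargs)
        assert np.array_equal(v1.data, v2.data)
        assert t1.table.equals(t2.table)

    def test_zero_beads_is_pure_noise_at_offset(self, default_noise):
        vol, truth = make_bead_phantom(
            (32, 64, 64), 0, (2.0, 2.0, 3.0), noise=default_noise, seed=1
        )
        assert truth.table.empty
        assert vol.data.mean() == pytest.approx(default_noise.offset, abs=0.5)

    def test_rendered_profile_fwhm_matches_truth(self):
        # Axis sums of a noiseless single bead follow the 1-D integrated
        # Gaussian; moment-based sigma must match ground truth within 1%.
        fw = (2.0 * 0.75, 2.0 * 0.75, 4.0)  # (x, y, z) um -> 2, 2, 4 voxels
        vol, truth = make_bead_phantom(
            (41, 41, 41), 1, fw, peak_counts=1000.0, noise=None, seed=9,
            voxel_size_um=(1.0, 0.75, 0.75),
        )
        data = vol.data
        for axis, fwhm_vox in [(0, 4.0), (1, 2.0), (2, 2.0)]:
            other = tuple(a for a in range(3) if a != axis)
            prof = data.sum(axis=other)
            x = np.arange(prof.size)
            mu = (prof * x).sum() / prof.sum()
            var = (prof * (x - mu) ** 2).sum() / prof.sum()
            var -= 1.0 / 12.0  # cell-integration variance of the rendering
            measured = FWHM_PER_SIGMA * np.sqrt(var)
            assert measured == pytest.approx(fwhm_vox, rel=0.01)

    def test_peak_amplitude_of_centred_bead(self):
        vol, _ = make_bead_phantom(
            (21, 21, 21), 0, (2.0, 2.0, 2.0), noise=None, seed=0
        )
        canvas = vol.data.copy()
        # render one bead exactly at the centre via the private path: place a
        # phantom whose truth we control is overkill; use margins so the one
        # bead is centred by construction instead.
        vol2, truth = make_bead_phantom(
            (21, 21, 21), 1, (2.0, 2.0, 2.0), peak_counts=500.0, noise=None,
            seed=4, margin_vox=7.0,
        )
        peak = vol2.data.max()
        assert peak <= 500.0 * 1.0001
        assert peak >= 500.0 * 0.8  # sub-voxel offset can only lower the peak

    def test_density_refusal(self):
        with pytest.raises(ValueError, match="density"):
            make_bead_phantom((24, 48, 48), 60, (3.0, 3.0, 4.0), seed=2)

    def test_too_small_fwhm_rejected(self):
        with pytest.raises(ValueError, match="voxel"):
            make_bead_phantom((24, 48, 48), 1, (0.5, 0.5, 0.5), seed=2)


class TestRonchiStack:
    def test_same_seed_bit_identical(self, default_noise):
        kwargs = dict(
            shape=(21, 64, 64), period_px=8, focus_surface=10.0,
            noise=default_noise, seed=5,
        )
        v1, _ = make_ronchi_stack(**kwargs)
        v2, _ = make_ronchi_stack(**kwargs)
        assert np.array_equal(v1.data, v2.data)

    def test_flat_surface_peaks_mid_stack(self):
        vol, truth = make_ronchi_stack(
            (41, 64, 64), period_px=8, z_step_um=1.0, focus_surface=20.0, seed=0
        )
        from lfspim.curvature import contrast_curves

        for c in contrast_curves(vol.data, truth.z_positions_um, grid=(2, 2)):
            assert int(np.argmax(c.contrast)) == 20

    def test_contrast_decays_symmetrically(self):
        vol, truth = make_ronchi_stack(
            (41, 64, 64), period_px=8, focus_surface=20.0, seed=0
        )
        from lfspim.curvature import frame_contrast

        c = np.array([frame_contrast(f) for f in vol.data])
        assert np.argmax(c) == 20
        assert np.allclose(c[:20], c[21:][::-1], atol=1e-6)

    def test_surface_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            make_ronchi_stack((11, 32, 32), focus_surface=100.0, seed=0)

    def test_period_too_small_rejected(self):
        with pytest.raises(ValueError, match="period"):
            make_ronchi_stack((11, 32, 32), period_px=2, focus_surface=5.0, seed=0)

    def test_zero_blur_gives_constant_contrast(self):
        vol, _ = make_ronchi_stack(
            (21, 64, 64), focus_surface=10.0, sigma_fn=lambda dz: 0.0 * dz + 1.0,
            seed=0,
        )
        from lfspim.curvature import frame_contrast

        c = np.array([frame_contrast(f) for f in vol.data])
        assert np.ptp(c) < 1e-9


class TestDotGrid:
    def test_same_seed_bit_identical(self, default_noise):
        kwargs = dict(
            shape=(400, 400), spacing_px=80.0, dot_diameter_px=30.0,
            k1=1e-8, noise=default_noise, seed=6,
        )
        i1, _ = make_dot_grid(**kwargs)
        i2, _ = make_dot_grid(**kwargs)
        assert np.array_equal(i1, i2)

    def test_noiseless_centroids_match_truth(self):
        # Brute-force intensity-weighted centroid of the absorption image.
        image, truth = make_dot_grid(
            (600, 600), spacing_px=120.0, dot_diameter_px=40.0, k1=2e-8, seed=0
        )
        absorption = image.max() - image
        yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
        for _, row in truth.table.iterrows():
            x0, y0 = row.x_true, row.y_true
            win = (np.abs(xx - x0) < 30) & (np.abs(yy - y0) < 30)
            w = absorption * win
            cx = (w * xx).sum() / w.sum()
            cy = (w * yy).sum() / w.sum()
            assert abs(cx - x0) < 0.05
            assert abs(cy - y0) < 0.05

    def test_undistorted_grid_is_regular(self):
        image, truth = make_dot_grid(
            (500, 500), spacing_px=100.0, dot_diameter_px=40.0, seed=0
        )
        t = truth.table
        assert np.allclose(t.x_true, t.x_ideal)
        assert np.allclose(t.y_true, t.y_ideal)

    def test_distortion_out_of_frame_rejected(self):
        with pytest.raises(ValueError, match="out of the frame"):
            make_dot_grid((500, 500), spacing_px=100.0, dot_diameter_px=40.0,
                          k1=5e-6, seed=0)

    def test_spacing_must_exceed_diameter(self):
        with pytest.raises(ValueError, match="spacing"):
            make_dot_grid((500, 500), spacing_px=30.0, dot_diameter_px=40.0, seed=0)
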