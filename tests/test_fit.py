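"""Gaussian fitting, best-focus selection, local background, intensities."""

import numpy as np
import pytest

import speckler as sp
from speckler.fit import BackgroundConfig, GaussianFit

from conftest import render_gaussian, stack_from_array

PITCH = (100.0, 65.0, 65.0)  # (dz, dy, dx) nm


def _one_box(stack, threshold):
    boxes = sp.detect_particles(stack, 0, threshold)
    assert len(boxes) == 1
    return boxes[0]


def _spot_stack(center=(1000.0, 900.0, 800.0), sigma=(120.0, 150.0, 250.0),
                base=100.0, peak=900.0, shape=(16, 32, 32), theta_z=0.0):
    volume = render_gaussian(shape, PITCH, center, sigma, base, peak,
                             theta_z=theta_z)
    return stack_from_array(volume)


class TestFitGaussian:
    def test_noiseless_spot_recovered_to_1e4(self):
        center, sigma = (1000.0, 900.0, 800.0), (120.0, 150.0, 250.0)
        stack = _spot_stack(center, sigma)
        fit = sp.fit_gaussian(stack, _one_box(stack, 400.0), dims=3)
        assert fit.ok
        assert fit.center_nm == pytest.approx(center, rel=1e-4, abs=0.05)
        assert fit.sigma_nm == pytest.approx(sigma, rel=1e-4)
        assert fit.base == pytest.approx(100.0, rel=1e-3)
        assert fit.peak == pytest.approx(900.0, rel=1e-3)
        assert fit.resnorm < 1e-8

    def test_constant_offset_moves_base_only(self):
        center, sigma = (1000.0, 900.0, 800.0), (120.0, 150.0, 250.0)
        stack = _spot_stack(center, sigma)
        shifted = stack_from_array(np.asarray(stack.voxels[0]) + 50.0)
        f0 = sp.fit_gaussian(stack, _one_box(stack, 400.0), dims=3)
        f1 = sp.fit_gaussian(shifted, _one_box(shifted, 450.0), dims=3)
        assert f1.base - f0.base == pytest.approx(50.0, abs=0.05)
        assert f1.peak == pytest.approx(f0.peak, rel=1e-4)
        assert f1.center_nm == pytest.approx(tuple(f0.center_nm), rel=1e-4)
        assert f1.sigma_nm == pytest.approx(tuple(f0.sigma_nm), rel=1e-4)

    def test_inplane_rotation_recovered_mod_180(self):
        theta = np.deg2rad(30.0)
        stack = _spot_stack(sigma=(100.0, 180.0, 250.0), theta_z=theta)
        fit = sp.fit_gaussian(stack, _one_box(stack, 400.0), dims=3,
                              fit_theta=True)
        assert fit.ok
        # orientation defined mod 180 deg; sigmas may swap with a 90 deg shift
        want = theta % np.pi
        got = fit.theta_rad[2] % np.pi
        if abs(fit.sigma_nm[0] - 100.0) > abs(fit.sigma_nm[0] - 180.0):
            got = (got + np.pi / 2) % np.pi
        delta = abs(got - want)
        assert min(delta, np.pi - delta) < 0.02
        assert sorted(fit.sigma_nm[:2]) == pytest.approx([100.0, 180.0], rel=0.01)

    def test_translation_equivariance_one_voxel(self):
        stack = _spot_stack()
        rolled = stack_from_array(np.roll(np.asarray(stack.voxels[0]), 1, axis=2))
        f0 = sp.fit_gaussian(stack, _one_box(stack, 400.0), dims=3)
        f1 = sp.fit_gaussian(rolled, _one_box(rolled, 400.0), dims=3)
        assert f1.center_nm[0] - f0.center_nm[0] == pytest.approx(65.0, abs=0.05)
        assert f1.center_nm[1] == pytest.approx(f0.center_nm[1], abs=0.05)

    def test_flat_data_flags_failure(self):
        volume = np.full((10, 20, 20), 50.0)
        stack = stack_from_array(volume)
        box = sp.ParticleBox(
            channel=0, tight_lo=(2, 5, 5), tight_hi=(8, 15, 15),
            buf_lo=(1, 3, 3), buf_hi=(9, 17, 17), threshold_used=0.0,
            component_id=1,
        )
        fit = sp.fit_gaussian(stack, box, dims=3)
        assert not fit.ok

    def test_2d_fit_on_3d_stack_uses_best_focus(self):
        stack = _spot_stack(center=(1000.0, 900.0, 850.0))
        fit = sp.fit_gaussian(stack, _one_box(stack, 400.0), dims=2)
        assert fit.ok
        assert fit.dims == 2
        assert np.isnan(fit.sigma_nm[2])
        assert fit.focus_z == 8  # z center 850 nm lies on plane 8
        assert fit.center_nm[:2] == pytest.approx((1000.0, 900.0), abs=1.0)


class TestBestFocusPlane:
    def test_simulated_bead_plane(self, small_field):
        stack, truth = small_field
        t = sp.auto_threshold(stack, 0)
        boxes = sp.detect_particles(stack, 0, t)
        box = boxes[0]
        z = sp.best_focus_plane(stack, box)
        # the true bead nearest this box
        mid = (np.array(box.tight_lo) + np.array(box.tight_hi)) / 2 * \
            np.array([100.0, 65.0, 65.0])
        i = np.argmin(np.abs(truth.centers_nm[:, 2] - mid[0]))
        assert abs(z - truth.centers_nm[i, 2] / 100.0 + 0.5) <= 1

    def test_single_plane_box(self):
        stack = _spot_stack()
        box = sp.ParticleBox(
            channel=0, tight_lo=(5, 10, 10), tight_hi=(6, 20, 20),
            buf_lo=(5, 8, 8), buf_hi=(6, 22, 22), threshold_used=0.0,
            component_id=1,
        )
        assert sp.best_focus_plane(stack, box) == 5

    def test_tie_breaks_to_lower_index(self):
        volume = np.zeros((6, 10, 10))
        volume[2] = 5.0
        volume[4] = 5.0
        stack = stack_from_array(volume)
        box = sp.ParticleBox(
            channel=0, tight_lo=(0, 0, 0), tight_hi=(6, 10, 10),
            buf_lo=(0, 0, 0), buf_hi=(6, 10, 10), threshold_used=0.0,
            component_id=1,
        )
        assert sp.best_focus_plane(stack, box) == 2


class TestLocalBackground:
    def _box(self, lo, hi):
        return sp.ParticleBox(
            channel=0, tight_lo=lo, tight_hi=hi, buf_lo=lo, buf_hi=hi,
            threshold_used=0.0, component_id=1,
        )

    def test_isolated_bead_on_constant_background(self):
        volume = np.full((12, 24, 24), 100.0)
        volume[4:8, 8:14, 8:14] = 900.0
        stack = stack_from_array(volume)
        box = self._box((4, 8, 8), (8, 14, 14))
        value, ok = sp.local_background(stack, box, [box], BackgroundConfig())
        assert ok and value == pytest.approx(100.0)

    def test_neighbor_voxels_excluded_from_shell(self):
        volume = np.full((10, 30, 30), 100.0)
        volume[3:7, 5:11, 5:11] = 900.0    # particle of interest
        volume[3:7, 12:18, 5:11] = 5000.0  # bright neighbor next to the shell
        stack = stack_from_array(volume)
        box = self._box((3, 5, 5), (7, 11, 11))
        neighbor = self._box((3, 12, 5), (7, 18, 11))
        cfg = BackgroundConfig(bg_buffer_p=0.5)
        naive, _ = sp.local_background(stack, box, [box], cfg)
        guarded, ok = sp.local_background(stack, box, [box, neighbor], cfg)
        assert ok
        assert guarded == pytest.approx(100.0)
        assert naive >= guarded  # neighbor contaminates the naive shell

    def test_buffer_one_doubles_shell_box(self):
        # p = 1: enlarged box extent is exactly double per dimension
        volume = np.full((20, 40, 40), 100.0)
        volume[8:12, 18:22, 18:22] = 900.0
        stack = stack_from_array(volume)
        box = self._box((8, 18, 18), (12, 22, 22))
        from speckler.fit import _shell_pad

        pad = _shell_pad(np.array([4, 4, 4]), 1.0, False)
        assert tuple(pad) == (2, 2, 2)  # +2 per side on extent 4 -> extent 8

    def test_empty_shell_falls_back(self):
        volume = np.full((4, 6, 6), 100.0)
        stack = stack_from_array(volume)
        box = self._box((0, 0, 0), (4, 6, 6))  # box fills the whole image
        value, ok = sp.local_background(stack, box, [box], BackgroundConfig())
        assert not ok and value is None


class TestIntensities:
    def _fit_stub(self, base):
        return GaussianFit(
            center_nm=np.zeros(3), theta_rad=np.zeros(3),
            sigma_nm=np.ones(3), base=base, peak=1.0, resnorm=0.0, dims=3,
            box=None,
        )

    def test_uncorrected_integrated_is_plain_sum(self):
        volume = np.full((12, 20, 20), 7.0)
        stack = stack_from_array(volume)
        box = sp.ParticleBox(
            channel=0, tight_lo=(1, 5, 5), tight_hi=(11, 15, 15),
            buf_lo=(1, 5, 5), buf_hi=(11, 15, 15), threshold_used=0.0,
            component_id=1,
        )
        out = sp.measure_intensities(stack, box, self._fit_stub(7.0), bg=None)
        assert out["integrated"] == pytest.approx(7.0 * 10 * 10 * 10)
        assert out["max"] == 7.0

    def test_corrected_constant_image_integrates_to_zero(self):
        volume = np.full((12, 20, 20), 7.0)
        stack = stack_from_array(volume)
        box = sp.ParticleBox(
            channel=0, tight_lo=(2, 6, 6), tight_hi=(10, 14, 14),
            buf_lo=(2, 6, 6), buf_hi=(10, 14, 14), threshold_used=0.0,
            component_id=1,
        )
        out = sp.measure_intensities(
            stack, box, self._fit_stub(7.0), bg=BackgroundConfig(),
            all_boxes=[box],
        )
        assert out["integrated"] == pytest.approx(0.0)

    @pytest.mark.parametrize("offset", [13.0, 250.0])
    def test_offset_invariance_of_corrected_intensity(self, small_field, offset):
        stack, truth = small_field
        t = sp.auto_threshold(stack, 0)
        boxes = sp.detect_particles(stack, 0, t)
        shifted = stack_from_array(np.asarray(stack.voxels[0], dtype=float) + offset)
        box = boxes[0]
        bg = BackgroundConfig()
        fit0 = sp.fit_gaussian(stack, box, dims=3)
        fit1 = sp.fit_gaussian(shifted, box, dims=3)
        a = sp.measure_intensities(stack, box, fit0, bg=bg, all_boxes=boxes)
        b = sp.measure_intensities(shifted, box, fit1, bg=bg, all_boxes=boxes)
        assert b["integrated"] == pytest.approx(a["integrated"], rel=0.005)

    def test_integrated_intensity_linear_in_photon_budget(self):
        budgets = [500.0, 1000.0, 2000.0, 4000.0, 8000.0]
        sums = []
        for p in budgets:
            stack, truth = sp.simulate_bead_field(
                n_beads=4, shape=(20, 96, 96), seed=21, peak_photons=p,
                psf_sigma_xy_nm=80.0, psf_sigma_z_nm=200.0, noise=False,
            )
            t = float(truth.offset + 0.2 * p)
            boxes = sp.detect_particles(stack, 0, t)
            total = 0.0
            for box in boxes:
                fit = sp.fit_gaussian(stack, box, dims=3)
                out = sp.measure_intensities(
                    stack, box, fit, bg=BackgroundConfig(), all_boxes=boxes
                )
                total += out["integrated"]
            sums.append(total)
        r = np.corrcoef(budgets, sums)[0, 1]
        assert r**2 > 0.99
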