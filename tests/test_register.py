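"""Cross-channel matching, distance matrices, aberration models."""

import itertools

import numpy as np
import pytest

import speckler as sp
from speckler.errors import EmptyMatchingError, InsufficientBeadsError, ParseError


def _pts(array):
    return np.asarray(array, dtype=float).reshape(-1, 3)


class TestMatchPoints:
    def test_identical_sets_fully_matched(self):
        pts = _pts([[100, 100, 100], [900, 500, 300], [2000, 2000, 800]])
        m = sp.match_points({0: pts, 1: pts.copy()})
        assert m.n_matched == 3
        assert m.unmatched_removed == {0: 0, 1: 0}
        assert np.array_equal(m.rows[0], m.rows[1])

    def test_bead_missing_in_one_channel_removed_everywhere(self):
        pts = _pts([[100, 100, 100], [900, 500, 300], [2000, 2000, 800]])
        m = sp.match_points({0: pts, 1: pts + 5.0, 2: (pts + 3.0)[:2]})
        assert m.n_matched == 2
        assert m.unmatched_removed[0] == 1
        assert m.unmatched_removed[1] == 1
        assert m.unmatched_removed[2] == 0

    def test_matches_exhaustive_assignment_on_small_fixture(self):
        # brute-force minimal-cost assignment over all permutations, n <= 6
        rng = np.random.default_rng(4)
        ref = rng.uniform(0, 5000, (6, 3))
        perm_true = rng.permutation(6)
        other = ref[perm_true] + rng.normal(0, 10, (6, 3))
        m = sp.match_points({0: ref, 1: other}, max_dist_nm=200.0)

        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(6)):
            cost = sum(
                np.linalg.norm(ref[i] - other[perm[i]]) for i in range(6)
            )
            if cost < best_cost:
                best, best_cost = perm, cost
        got = {(int(i), int(j)) for i, j in zip(m.rows[0], m.rows[1])}
        want = {(i, best[i]) for i in range(6)}
        assert got == want

    def test_two_candidates_resolved_mutually(self):
        ref = _pts([[1000, 1000, 500]])
        other = _pts([[1030, 1000, 500], [1100, 1000, 500]])
        m = sp.match_points({0: ref, 1: other}, max_dist_nm=500.0)
        assert m.n_matched == 1
        assert int(m.rows[1][0]) == 0  # nearer candidate wins

    def test_symmetric_under_reference_swap(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 8000, (10, 3))
        jitter = pts + rng.normal(0, 5, pts.shape)
        m01 = sp.match_points({0: pts, 1: jitter}, ref_channel=0)
        m10 = sp.match_points({0: pts, 1: jitter}, ref_channel=1)
        pairs01 = {(int(i), int(j)) for i, j in zip(m01.rows[0], m01.rows[1])}
        pairs10 = {(int(i), int(j)) for i, j in zip(m10.rows[0], m10.rows[1])}
        assert pairs01 == pairs10

    def test_no_match_raises_with_diagnostic(self):
        with pytest.raises(EmptyMatchingError):
            sp.match_points(
                {0: _pts([[0, 0, 0]]), 1: _pts([[9000, 9000, 9000]])},
                max_dist_nm=100.0,
            )


class TestDistanceMatrices:
    def test_single_bead_self_distance_zero(self):
        a = _pts([[10, 20, 30]])
        assert np.allclose(sp.distance_matrices(a, a), [[0.0]])

    def test_known_3d_distance(self):
        a = _pts([[0, 0, 0]])
        b = _pts([[30, -20, 50]])
        assert sp.distance_matrices(a, b)[0, 0] == pytest.approx(61.6441, abs=1e-3)
        assert sp.distance_matrices(a, b, dims=2)[0, 0] == pytest.approx(
            np.hypot(30, 20)
        )

    def test_matches_scalar_brute_force(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(0, 1000, (7, 3))
        b = rng.uniform(0, 1000, (5, 3))
        mat = sp.distance_matrices(a, b)
        for i in range(7):
            for j in range(5):
                assert mat[i, j] == pytest.approx(
                    float(np.linalg.norm(a[i] - b[j])), rel=1e-9
                )


class TestAberrationStats:
    def test_channel_vs_itself_is_zero(self):
        pts = _pts([[100, 200, 300], [400, 500, 600]])
        m = sp.match_points({0: pts, 1: pts.copy()})
        stats = sp.aberration_stats(m, {0: pts, 1: pts.copy()})
        assert np.all(stats[1]["delta_nm"] == 0)
        assert stats[1]["mean_d3d_nm"] == 0.0

    def test_constant_shift_recovered(self, two_channel_result):
        stack, truth, shift, result = two_channel_result
        stats = result.aberration_stats[1]
        assert stats["mean_delta_nm"] == pytest.approx(shift, abs=2.0)
        assert stats["mean_d3d_nm"] == pytest.approx(
            np.linalg.norm(shift), abs=2.0
        )

    def test_field_dependent_shift_correlates_with_position(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 30000, (40, 3))
        shift_x = 10.0 + 0.002 * pts[:, 0]
        moved = pts.copy()
        moved[:, 0] += shift_x
        m = sp.match_points({0: pts, 1: moved}, max_dist_nm=500.0)
        stats = sp.aberration_stats(m, {0: pts, 1: moved})[1]
        r = np.corrcoef(pts[m.rows[0], 0], stats["delta_nm"][:, 0])[0, 1]
        assert r**2 > 0.9


class TestAberrationModel:
    def _affine_pair(self, n=20, seed=8):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 30000, (n, 3))
        angle = np.deg2rad(0.1)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]]) * 1.001
        shifted = pts @ rot.T + np.array([50.0, -30.0, 20.0])
        return pts, shifted, rot

    def test_known_affine_recovered(self):
        ref, moved, rot = self._affine_pair()
        m = sp.match_points({0: ref, 1: moved}, max_dist_nm=1e5)
        model = sp.fit_aberration(m, {0: ref, 1: moved}, kind="affine")
        # model maps channel-1 coords back onto the reference
        corrected = model.correct(1, moved)
        assert np.allclose(corrected, ref, atol=1e-6)
        assert model.fit_rms_nm[1] < 1e-6
        got_linear = model.params[1][:, :3]
        assert np.allclose(got_linear, np.linalg.inv(rot), rtol=1e-3, atol=1e-6)

    def test_poly_constant_shift_is_constant_term(self):
        rng = np.random.default_rng(9)
        ref = rng.uniform(0, 30000, (25, 3))
        moved = ref + np.array([40.0, -10.0, 25.0])
        m = sp.match_points({0: ref, 1: moved}, max_dist_nm=500.0)
        model = sp.fit_aberration(m, {0: ref, 1: moved}, kind="poly_surface",
                                  degree=2)
        coef = model.params[1]  # (3, n_terms); term 0 is the constant
        assert coef[:, 0] == pytest.approx([40.0, -10.0, 25.0], abs=1e-6)
        assert np.abs(coef[:, 1:]).max() < 1e-9

    def test_too_few_beads_rejected(self):
        ref = _pts([[0, 0, 0], [1000, 0, 0], [0, 1000, 0]])
        m = sp.match_points({0: ref, 1: ref + 5.0}, max_dist_nm=100.0)
        with pytest.raises(InsufficientBeadsError):
            sp.fit_aberration(m, {0: ref, 1: ref + 5.0}, kind="affine")

    def test_identity_model_leaves_points_untouched(self):
        pts = _pts([[123.4, 567.8, 910.1]])
        model = sp.AberrationModel(
            kind="affine", ref_channel=0,
            params={1: np.hstack([np.eye(3), np.zeros((3, 1))])},
            degree=None, fit_rms_nm={1: 0.0},
        )
        assert np.array_equal(model.correct(0, pts), pts)
        assert np.allclose(model.correct(1, pts), pts)

    def test_correction_reduces_residual_monotonically(self, two_channel_result):
        stack, truth, shift, result = two_channel_result
        stats = result.aberration_stats[1]
        moving = np.array(
            [result.per_channel_records[1][i].center_nm
             for i in result.matched.rows[1]]
        )
        ref = np.array(
            [result.per_channel_records[0][i].center_nm
             for i in result.matched.rows[0]]
        )
        corrected = sp.apply_aberration_points(result.aberration_model, moving, 1)
        before = np.linalg.norm(moving - ref, axis=1).mean()
        after = np.linalg.norm(corrected - ref, axis=1).mean()
        assert after < before
        assert after < 5.0


class TestApplyToImage:
    def test_integer_voxel_shift_corrected_in_interior(self):
        rng = np.random.default_rng(10)
        base = rng.integers(50, 500, (12, 24, 24)).astype(np.uint16)
        shifted = np.roll(base, 1, axis=2)  # +1 voxel along x
        stack = sp.ImageStack(
            voxels=np.stack([base, shifted]), dx_nm=65.0, dy_nm=65.0,
            dz_nm=100.0, wavelengths_nm=(510.0, 610.0),
        )
        # channel 1 is displaced by +65 nm in x; correction maps it back
        affine = np.hstack([np.eye(3), np.array([[-65.0], [0.0], [0.0]])])
        model = sp.AberrationModel(
            kind="affine", ref_channel=0, params={1: affine}, degree=None,
            fit_rms_nm={1: 0.0},
        )
        corrected = sp.apply_aberration_image(model, stack)
        interior = (slice(None), slice(1, -1), slice(1, -1))
        assert np.array_equal(
            corrected.voxels[1][interior], base[interior]
        )
        assert np.array_equal(corrected.voxels[0], base)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        model = sp.AberrationModel(
            kind="poly_surface", ref_channel=0,
            params={1: np.arange(18, dtype=float).reshape(3, 6)},
            degree=2, fit_rms_nm={1: 1.25},
        )
        path = tmp_path / "cal.json"
        sp.save_calibration(model, path)
        back = sp.load_calibration(path)
        assert back.kind == model.kind
        assert back.ref_channel == model.ref_channel
        assert back.degree == model.degree
        assert np.array_equal(back.params[1], model.params[1])
        assert back.fit_rms_nm == model.fit_rms_nm

    def test_unknown_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"kind": "teleport", "ref_channel": 0, "params": {}}')
        with pytest.raises(ParseError):
            sp.load_calibration(path)

    def test_calibration_transfers_to_second_dataset(self, two_channel_result):
        stack, truth, shift, result = two_channel_result
        model = result.aberration_model
        # an independent acquisition on the same simulated optics
        stack2, truth2 = sp.simulate_bead_field(
            n_beads=15, diameter_nm=100.0, shape=(26, 256, 256),
            dx_nm=65.0, dz_nm=100.0, wavelengths_nm=(510.0, 610.0),
            psf_sigma_xy_nm=80.0, psf_sigma_z_nm=200.0,
            chromatic_shift_nm={1: shift},
            snr=100.0, read_noise_sd=5.0, background_photons=400.0, seed=77,
        )
        result2 = sp.run_pipeline(stack2, sp.PipelineConfig(match=True))
        ref = np.array(
            [result2.per_channel_records[0][i].center_nm
             for i in result2.matched.rows[0]]
        )
        moving = np.array(
            [result2.per_channel_records[1][i].center_nm
             for i in result2.matched.rows[1]]
        )
        corrected = sp.apply_aberration_points(model, moving, 1)
        residual = np.linalg.norm(corrected - ref, axis=1).mean()
        assert residual < 10.0
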