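"""Trajectory, CAIPIRINHA band phasors, and the SMS radial encoding operator."""

import numpy as np
import pytest

from mtsms.encoding import (SLICE_KZ, SMSRadialOperator, Trajectory, band_phases,
                            estimate_coils, make_operator, power_method_norm,
                            radial_angles)
from mtsms.phantom import PhantomConfig, make_phantom, simulate_scan
from mtsms.sequence import GOLDEN_ANGLE_DEG, SequenceConfig, build_schedule


@pytest.fixture(scope="module")
def coils48():
    return make_phantom(PhantomConfig(grid_n=48, seed=3)).coil_maps()


def _random_op(coils, n_lines=40, seed=0):
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0, 360, n_lines)
    steps = rng.integers(0, 3, n_lines)
    return SMSRadialOperator(angles, steps, coils, 48)


class TestTrajectory:
    def test_golden_angle_sequence(self, small_schedule):
        ang = radial_angles(small_schedule)
        img = ang[~small_schedule.is_training]
        assert np.allclose(img[:4], [0.0, 111.24, 222.48, 333.72])
        assert img[4] == pytest.approx(84.96)

    def test_training_lines_at_zero(self, small_schedule):
        ang = radial_angles(small_schedule)
        assert np.all(ang[small_schedule.is_training] == 0.0)

    def test_azimuthal_coverage_after_100_lines(self):
        ang = np.sort((np.arange(100) * GOLDEN_ANGLE_DEG) % 180.0)
        gaps = np.diff(np.concatenate([ang, [ang[0] + 180.0]]))
        assert gaps.max() < 6.0

    def test_table_export(self, small_schedule):
        traj = Trajectory.from_schedule(small_schedule, grid_n=48)
        tab = traj.to_table()
        assert len(tab) == small_schedule.n_lines
        assert np.all(traj.dcf > 0)


class TestBandPhases:
    def test_step_zero_all_unity(self, small_schedule):
        ph = band_phases(small_schedule)
        tr = small_schedule.is_training
        assert np.allclose(ph[tr], 1.0)

    def test_step_three_wraps(self):
        inc = SLICE_KZ * 2 * np.pi / 3
        assert np.allclose(np.exp(1j * 3 * inc), 1.0)

    def test_three_by_three_is_dft_matrix(self):
        m = np.exp(1j * np.outer(np.arange(3), SLICE_KZ * 2 * np.pi / 3))
        # columns reordered by kz = (-1, 0, 1) -> compare against DFT of size 3
        f = np.exp(2j * np.pi * np.outer(np.arange(3), np.arange(3)) / 3)
        # each column of m must appear among DFT columns
        for col in m.T:
            match = [np.allclose(col, f[:, j]) for j in range(3)]
            assert any(match)
        assert np.abs(np.linalg.det(m)) == pytest.approx(np.abs(np.linalg.det(f)))

    def test_unsupported_band_count(self, small_schedule):
        with pytest.raises(NotImplementedError):
            band_phases(small_schedule, n_bands=4)


class TestOperator:
    def test_adjointness_random_probe(self, coils48):
        op = _random_op(coils48, seed=1)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, op.n_vox)) + 1j * rng.standard_normal((3, op.n_vox))
        y = rng.standard_normal((op.n_lines, op.n_samples, op.n_coils)) \
            + 1j * rng.standard_normal((op.n_lines, op.n_samples, op.n_coils))
        lhs = np.vdot(y, op.forward(x))
        rhs = np.vdot(op.adjoint(y), x)
        assert abs(lhs - rhs) <= 1e-6 * np.linalg.norm(op.forward(x)) * np.linalg.norm(y)

    def test_weighted_pair_adjointness(self, coils48):
        op = _random_op(coils48, seed=3)
        rng = np.random.default_rng(4)
        L = 5
        phi = rng.standard_normal((op.n_lines, L)) + 1j * rng.standard_normal((op.n_lines, L))
        u = rng.standard_normal((3, op.n_vox, L)) + 1j * rng.standard_normal((3, op.n_vox, L))
        y = rng.standard_normal((op.n_lines, op.n_samples, op.n_coils)) \
            + 1j * rng.standard_normal((op.n_lines, op.n_samples, op.n_coils))
        lhs = np.vdot(y, op.forward_weighted(u, phi))
        rhs = np.vdot(op.adjoint_weighted(y, phi), u)
        assert abs(lhs - rhs) <= 1e-6 * np.linalg.norm(y) * np.linalg.norm(u)

    def test_fused_gradient_matches_separate_calls(self, coils48):
        op = _random_op(coils48, n_lines=15, seed=5)
        rng = np.random.default_rng(6)
        L = 3
        phi = rng.standard_normal((op.n_lines, L)) + 1j * rng.standard_normal((op.n_lines, L))
        u = rng.standard_normal((3, op.n_vox, L)) + 1j * rng.standard_normal((3, op.n_vox, L))
        d = rng.standard_normal((op.n_lines, op.n_samples, op.n_coils)) * 1j
        g1, obj = op.gradient_weighted(u, phi, d)
        r = op.forward_weighted(u, phi) - d
        g2 = op.adjoint_weighted(r, phi)
        assert np.allclose(g1, g2)
        assert obj == pytest.approx(0.5 * np.linalg.norm(r) ** 2, rel=1e-10)

    def test_central_slice_theorem_angle_zero(self, coils48):
        # uniform single coil, mid slice only: the 0-deg line at integer k
        # equals the FFT of the y-projection of the image
        grid_n = 48
        coils = np.zeros((3, 1, grid_n, grid_n), dtype=complex)
        coils[:, 0] = 1.0
        op = SMSRadialOperator(np.array([0.0]), np.array([0]), coils, grid_n)
        rng = np.random.default_rng(7)
        img = rng.standard_normal((grid_n, grid_n)) + 1j * rng.standard_normal((grid_n, grid_n))
        x = np.zeros((3, grid_n, grid_n), dtype=complex)
        x[1] = img
        y = op.forward(x)[0, :, 0]
        proj = img.sum(axis=0)  # sum over y -> function of x
        # integer k positions are the even samples
        f = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(proj)))
        assert np.allclose(y[::2], f, rtol=1e-8, atol=1e-8)

    def test_three_point_dft_slice_separation(self, coils48):
        op = SMSRadialOperator(np.full(3, 45.0), np.arange(3), coils48, 48)
        rng = np.random.default_rng(8)
        x = rng.standard_normal((3, op.n_vox)) + 1j * rng.standard_normal((3, op.n_vox))
        y = op.forward(x)
        m = np.exp(1j * np.outer(np.arange(3), SLICE_KZ * 2 * np.pi / 3))
        sep = np.einsum("bj,jsc->bsc", np.linalg.inv(m), y)
        for b in range(3):
            xb = np.zeros_like(x)
            xb[b] = x[b]
            yb = op.forward(xb)[0]  # any line, phasor-free comparison below
            single = SMSRadialOperator(np.array([45.0]), np.array([0]), coils48, 48)
            yb = single.forward(xb)[0]
            assert np.allclose(sep[b], yb, rtol=1e-10, atol=1e-10)

    def test_operator_norm_stable_across_probe_seeds(self, coils48):
        op = _random_op(coils48, n_lines=30, seed=9)
        norms = [power_method_norm(op, n_iter=50, seed=s) for s in (0, 1, 2)]
        assert np.ptp(norms) / np.mean(norms) < 0.01

    def test_shape_mismatch_raises(self, coils48):
        with pytest.raises(ValueError):
            SMSRadialOperator(np.zeros(4), np.zeros(3, dtype=int), coils48, 48)
        with pytest.raises(ValueError):
            SMSRadialOperator(np.zeros(3), np.zeros(3, dtype=int), coils48, 32)


class TestCoilEstimation:
    @pytest.fixture(scope="class")
    def static_raw(self):
        cfg = PhantomConfig(grid_n=48, contraction=0.0, resp_amp_mm=0.0,
                            resp_drift=False, noise_rel=0.0, seed=3)
        sch = build_schedule(SequenceConfig(n_periods=6))
        return simulate_scan(make_phantom(cfg), sch)

    def test_truth_bypass_returns_stored_maps(self, static_raw):
        assert np.array_equal(estimate_coils(static_raw, use_truth=True),
                              static_raw.coils)

    def test_estimated_maps_correlate_with_truth(self, static_raw):
        est = estimate_coils(static_raw, smooth_sigma=1.0)
        truth = static_raw.coils
        sup = static_raw.truth["support"]
        for s in range(3):
            for c in range(truth.shape[1]):
                a, b = est[s, c][sup], truth[s, c][sup]
                w = np.abs(b) > 0.2 * np.abs(b).max()
                corr = np.abs(np.vdot(a[w], b[w])) / (
                    np.linalg.norm(a[w]) * np.linalg.norm(b[w]))
                assert corr > 0.99

    def test_rss_near_unity_inside_support(self, static_raw):
        est = estimate_coils(static_raw, smooth_sigma=0.0)
        sup = static_raw.truth["support"]
        rss = np.sqrt((np.abs(est) ** 2).sum(axis=1))
        assert np.abs(rss[:, sup] - 1.0).max() < 0.05

    def test_too_few_lines_raises(self, static_raw):
        import dataclasses

        small = dataclasses.replace(
            static_raw,
            imaging=static_raw.imaging[:10], imaging_lines=static_raw.imaging_lines[:10])
        with pytest.raises(ValueError, match="too few"):
            estimate_coils(small)
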