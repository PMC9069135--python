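"""Background subtraction, angular spectrum propagation, Z projection."""

import numpy as np
import pytest

from thermotrack.core import VideoStack
from thermotrack import reconstruction as rec


def _stack(frames, **kw):
    return VideoStack(np.asarray(frames, dtype=float), **kw)


def _blob(shape, cy, cx, sigma=2.0, amp=10.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))


class TestMedianSubtract:
    def test_constant_video_becomes_zero(self):
        stack = _stack(np.ones((5, 8, 8)) * 7.0)
        out = rec.median_subtract(stack)
        assert np.allclose(out.frames, 0.0)
        assert out.n_frames == 5

    def test_matches_explicit_per_pixel_median(self, rng):
        frames = rng.normal(5, 2, size=(9, 6, 7))
        out = rec.median_subtract(_stack(frames))
        expected = np.empty_like(frames)
        for r in range(6):
            for c in range(7):
                expected[:, r, c] = frames[:, r, c] - np.median(frames[:, r, c])
        assert np.allclose(out.frames, expected)

    def test_moving_blob_preserved_background_removed(self):
        frames = np.zeros((11, 32, 32))
        background = _blob((32, 32), 20, 20, amp=4.0)
        for i in range(11):
            frames[i] = background + _blob((32, 32), 8, 2 + 2 * i, amp=10.0)
        out = rec.median_subtract(_stack(frames))
        # background pixel (away from all blob positions) near zero
        assert abs(out.frames[5, 31, 0]) < 1e-9
        # the moving blob's center survives at nearly full amplitude
        assert out.frames[5, 8, 12] > 8.0

    def test_minority_blinker_survives(self):
        frames = np.zeros((10, 4, 4))
        frames[0, 2, 2] = frames[1, 2, 2] = 9.0  # present in 2/10 frames
        out = rec.median_subtract(_stack(frames))
        assert out.frames[0, 2, 2] == pytest.approx(9.0)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            rec.median_subtract(_stack(np.zeros((2, 4, 4))))


class TestFrameToFrameSubtract:
    def test_constant_video_zero_and_shorter(self):
        out = rec.frame_to_frame_subtract(_stack(np.full((6, 4, 4), 3.0)))
        assert out.n_frames == 5
        assert np.allclose(out.frames, 0.0)

    def test_immobile_object_vanishes(self):
        frame = _blob((16, 16), 8, 8)
        out = rec.frame_to_frame_subtract(_stack(np.stack([frame] * 7)))
        assert np.allclose(out.frames, 0.0)

    def test_matches_direct_differencing_and_dipole(self, rng):
        frames = np.zeros((5, 16, 32))
        for i in range(5):
            frames[i] = _blob((16, 32), 8, 4 + 5 * i, sigma=1.0)
        out = rec.frame_to_frame_subtract(_stack(frames))
        assert np.allclose(out.frames, np.diff(frames, axis=0))
        # dipole: negative at the vacated site, positive at the new site
        assert out.frames[0, 8, 4] < 0 < out.frames[0, 8, 9]

    def test_time_origin_shifts_one_interval(self):
        stack = _stack(np.zeros((4, 4, 4)), frame_interval=0.2)
        out = rec.frame_to_frame_subtract(stack)
        assert out.time_origin == pytest.approx(stack.time_origin + 0.2)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            rec.frame_to_frame_subtract(_stack(np.zeros((1, 4, 4))))


def test_frame_differencing_is_linear(rng):
    a = rng.normal(size=(7, 8, 8))
    b = rng.normal(size=(7, 8, 8))
    sub = lambda arr: rec.frame_to_frame_subtract(_stack(arr)).frames  # noqa: E731
    assert np.allclose(sub(a + b), sub(a) + sub(b), atol=1e-12)


@pytest.mark.parametrize("mode", ["median", "frame_to_frame"])
def test_subtraction_removes_static_background(mode, rng):
    # adding any time-constant image to the video leaves the output unchanged
    a = rng.normal(size=(7, 8, 8))
    static = rng.normal(size=(8, 8)) * 10
    sub = lambda arr: rec.subtract_background(_stack(arr), mode).frames  # noqa: E731
    assert np.allclose(sub(a + static), sub(a), atol=1e-9)


class TestAngularSpectrum:
    PIX, WL, N_IDX = 0.178, 0.520, 1.33

    def _field(self, rng, n=64, band_limited=False):
        f = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        if band_limited:
            # restrict to the propagating band (evanescent content cannot
            # survive any propagation, so round trips are only defined on it)
            fx = np.fft.fftfreq(n, d=self.PIX)
            band = (self.N_IDX / self.WL) ** 2 - fx[None, :] ** 2 - fx[:, None] ** 2 >= 0
            f = np.fft.ifft2(np.fft.fft2(f) * band)
        return f

    def test_zero_distance_is_identity(self, rng):
        f = self._field(rng)
        out = rec.angular_spectrum_propagate(f, 0.0, self.PIX, self.WL, self.N_IDX)
        assert np.allclose(out, f, atol=1e-12)

    def test_round_trip(self, rng):
        f = self._field(rng, band_limited=True)
        fwd = rec.angular_spectrum_propagate(f, 37.0, self.PIX, self.WL, self.N_IDX)
        back = rec.angular_spectrum_propagate(fwd, -37.0, self.PIX, self.WL, self.N_IDX)
        err = np.max(np.abs(back - f)) / np.max(np.abs(f))
        assert err < 1e-6

    def test_propagating_power_conserved(self, rng):
        # Parseval: total spectral power over propagating frequencies unchanged
        f = self._field(rng, n=48)
        spec0 = np.fft.fft2(f)
        fx = np.fft.fftfreq(48, d=self.PIX)
        radicand = (self.N_IDX / self.WL) ** 2 - fx[None, :] ** 2 - fx[:, None] ** 2
        band = radicand >= 0
        out = rec.angular_spectrum_propagate(f, 123.0, self.PIX, self.WL, self.N_IDX)
        spec1 = np.fft.fft2(out)
        p0 = np.sum(np.abs(spec0[band]) ** 2)
        p1 = np.sum(np.abs(spec1) ** 2)  # evanescent part is zeroed
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_kernel_unit_modulus_on_band(self, rng):
        # a pure propagating plane wave keeps unit amplitude for any z
        n = 32
        yy, xx = np.mgrid[:n, :n]
        f = np.exp(2j * np.pi * (3 * xx + 2 * yy) / n)
        out = rec.angular_spectrum_propagate(f, 55.0, self.PIX, self.WL, self.N_IDX)
        assert np.allclose(np.abs(out), 1.0, atol=1e-9)

    def test_non_finite_rejected(self):
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            rec.angular_spectrum_propagate(bad, 1.0, self.PIX, self.WL)


class TestReconstructVolume:
    def test_identity_plan_returns_raw_amplitudes(self, rng):
        frames = np.abs(rng.normal(size=(3, 16, 16))) + 1.0
        stack = _stack(frames)
        plan = rec.ReconstructionPlan(z_min=0, z_max=0, subtraction_mode="none")
        vol = rec.reconstruct_volume(stack, plan)
        assert vol.shape == (3, 1, 16, 16)
        assert np.allclose(vol[:, 0], np.abs(np.sqrt(frames)) ** 1)

    def test_point_source_focuses_at_its_plane(self):
        # focus field at z=+50: propagate a tight Gaussian source by -50 to
        # form the "hologram", then sweep and find the sharpest plane
        n, z_true = 128, 50.0
        src = _blob((n, n), n // 2, n // 2, sigma=1.0, amp=1.0).astype(complex)
        holo = rec.angular_spectrum_propagate(src, -z_true, 0.178, 0.520, 1.33)
        stack = VideoStack(holo[np.newaxis])
        plan = rec.ReconstructionPlan(z_min=0, z_max=100, z_step=10,
                                      subtraction_mode="none")
        vol = rec.reconstruct_volume(stack, plan)
        sharpness = [vol[0, zi].max() for zi in range(vol.shape[1])]
        best_z = plan.z_planes[int(np.argmax(sharpness))]
        assert best_z == pytest.approx(z_true, abs=plan.z_step / 2)

    def test_two_sources_focus_at_their_own_planes(self):
        n = 128
        s1 = _blob((n, n), 40, 40, sigma=1.0, amp=1.0).astype(complex)
        s2 = _blob((n, n), 90, 90, sigma=1.0, amp=1.0).astype(complex)
        holo = (rec.angular_spectrum_propagate(s1, -30.0, 0.178, 0.520, 1.33)
                + rec.angular_spectrum_propagate(s2, -80.0, 0.178, 0.520, 1.33))
        stack = VideoStack(holo[np.newaxis])
        plan = rec.ReconstructionPlan(z_min=0, z_max=110, z_step=10,
                                      subtraction_mode="none")
        vol = rec.reconstruct_volume(stack, plan)
        zs = plan.z_planes
        peak1 = [vol[0, zi, 35:46, 35:46].max() for zi in range(len(zs))]
        peak2 = [vol[0, zi, 85:96, 85:96].max() for zi in range(len(zs))]
        assert zs[int(np.argmax(peak1))] == pytest.approx(30.0, abs=5.0)
        assert zs[int(np.argmax(peak2))] == pytest.approx(80.0, abs=5.0)


class TestMaxZProjection:
    def test_single_plane_identity(self, rng):
        vol = rng.random((4, 1, 8, 8))
        assert np.array_equal(rec.max_z_projection(vol), vol[:, 0])

    def test_disjoint_spots_union(self):
        vol = np.zeros((1, 2, 8, 8))
        vol[0, 0, 2, 2] = 5.0
        vol[0, 1, 6, 6] = 7.0
        proj = rec.max_z_projection(vol)
        assert proj[0, 2, 2] == 5.0 and proj[0, 6, 6] == 7.0

    def test_matches_nested_loop_maximum(self, rng):
        vol = rng.random((3, 5, 6, 7))
        proj = rec.max_z_projection(vol)
        for t in range(3):
            for r in range(6):
                for c in range(7):
                    assert proj[t, r, c] == max(vol[t, z, r, c] for z in range(5))

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            rec.max_z_projection(np.empty((0, 0, 0, 0)))


def test_end_to_end_in_focus_passthrough(rng):
    """mode=none, z=0 only: projection is bit-identical to sqrt-amplitudes,
    and for an amplitude-encoded complex stack, to the input itself."""
    frames = (rng.random((4, 16, 16)) + 0.5).astype(complex)
    stack = VideoStack(frames)
    plan = rec.ReconstructionPlan(z_min=0, z_max=0, subtraction_mode="none")
    proj = rec.max_z_projection(rec.reconstruct_volume(stack, plan))
    assert np.array_equal(proj, np.abs(frames))


def test_plan_validation():
    with pytest.raises(ValueError):
        rec.ReconstructionPlan(z_min=10, z_max=0)
    with pytest.raises(ValueError):
        rec.ReconstructionPlan(z_step=0)
    with pytest.raises(ValueError):
        rec.ReconstructionPlan(subtraction_mode="bogus")
    plan = rec.ReconstructionPlan(z_min=-200, z_max=200, z_step=10)
    assert len(plan.z_planes) == 41
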