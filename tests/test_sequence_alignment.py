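"""Resampling, wrapped pairwise shifts, multi-pass absolute alignment."""
import numpy as np
import pytest

from heartsync._util import wrap_to_pm_pi
from heartsync.errors import AlignmentError, ParameterError
from heartsync.sequence_alignment import (
    AlignmentConfig,
    AlignmentState,
    RelativeShift,
    ResampledSequence,
    multipass_align,
    refresh_reference,
    relative_shift,
    resample_sequence,
)
from heartsync.synthetic_heart import SimulatedVideo, SyntheticHeartSpec

TWO_PI = 2 * np.pi


class TestResample:
    def test_exact_reproduction_when_L_equals_integer_period(self, reference_factory):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 100, (12, 5, 5)).astype(np.float32)
        rs = resample_sequence(reference_factory(stack), 12)
        np.testing.assert_allclose(rs.frames, stack, rtol=1e-6)

    def test_constant_frames_stay_constant(self, reference_factory):
        rs = resample_sequence(reference_factory(np.full((10, 4, 4), 3.0)), 25)
        np.testing.assert_allclose(rs.frames, 3.0, rtol=1e-6)

    def test_linear_ramp_pixel_interpolates_exactly(self, reference_factory):
        n, L = 10, 40
        stack = np.zeros((n, 3, 3), dtype=np.float32)
        stack[:, 1, 1] = np.arange(n, dtype=np.float32)  # ramp over the cycle
        rs = resample_sequence(reference_factory(stack), L)
        pos = np.arange(L) * (n / L)
        interior = pos <= n - 1
        np.testing.assert_allclose(rs.frames[interior, 1, 1], pos[interior], atol=1e-5)

    def test_L_below_four_rejected(self, reference_factory):
        with pytest.raises(ParameterError):
            resample_sequence(reference_factory(np.zeros((8, 4, 4))), 3)


class TestRelativeShift:
    def test_cyclic_roll_recovered_exactly(self, reference_factory):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 100, (20, 6, 6)).astype(np.float32)
        A = resample_sequence(reference_factory(stack, sequence_id=0), 20)
        for k in (1, 5, 13, 19):
            B = ResampledSequence(np.roll(A.frames, k, axis=0), source_id=1)
            sh = relative_shift(A, B)
            assert sh.dphi == pytest.approx(wrap_to_pm_pi(TWO_PI * k / 20), abs=1e-9)

    def test_cost_argmin_equals_correlation_argmax(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = rng.uniform(0, 50, (16, 6, 6))
            b = rng.uniform(0, 50, (16, 6, 6))
            costs = [((a - np.roll(b, -s, axis=0)) ** 2).sum() for s in range(16)]
            corr = np.fft.irfft(
                np.conj(np.fft.rfft(a, axis=0)) * np.fft.rfft(b, axis=0), n=16, axis=0
            ).sum(axis=(1, 2))
            assert int(np.argmin(costs)) == int(np.argmax(corr))

    def test_sub_sample_shift_recovered(self):
        spec = SyntheticHeartSpec(
            seed=0,
            period_jitter_cv=0.0,
            refractory_jitter_cv=0.0,
            morph_rate=0.0,
            drift_velocity=(0.0, 0.0),
            noise_sd=0.0,
            blood_speckle_rate=0.0,
        )
        video = SimulatedVideo(spec)
        video.schedule.ensure(5.0)
        L, P = 80, spec.mean_period
        tA = np.arange(L) / L * P
        A = ResampledSequence(np.stack([video.render(t) for t in tA]), source_id=0)
        for true_shift in (0.3, 0.7, 2.4):
            tB = (np.arange(L) - true_shift) / L * P % P
            B = ResampledSequence(np.stack([video.render(t) for t in tB]), source_id=1)
            rec = relative_shift(A, B).dphi / (TWO_PI / L)
            assert rec == pytest.approx(true_shift, abs=0.05)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        sa = rng.uniform(0, 50, (24, 5, 5)).astype(np.float32)
        A = ResampledSequence(sa, source_id=0)
        B = ResampledSequence(np.roll(sa, 7, axis=0) + rng.normal(0, 0.5, sa.shape).astype(np.float32), source_id=1)
        fwd = relative_shift(A, B).dphi
        bwd = relative_shift(B, A).dphi
        assert fwd == pytest.approx(bwd, abs=0.05)  # both reported as a<b

    def test_drift_correction_applied(self, reference_factory):
        rng = np.random.default_rng(4)
        stack = rng.uniform(0, 100, (20, 8, 8)).astype(np.float32)
        A = resample_sequence(reference_factory(stack, sequence_id=0), 20)
        translated = np.roll(np.roll(np.roll(A.frames, 4, axis=0), 2, axis=2), 1, axis=1)
        B = ResampledSequence(translated, source_id=1)
        sh = relative_shift(A, B, dx=2, dy=1)
        assert sh.dphi == pytest.approx(TWO_PI * 4 / 20, abs=1e-9)


class TestMultipass:
    def test_two_sequences_single_shift(self):
        ga = multipass_align([RelativeShift(0, 1, 0.7)])
        np.testing.assert_allclose(ga.x, [0.0, 0.7], atol=1e-12)

    def test_adjacent_chain_is_cumulative_sum(self):
        rng = np.random.default_rng(5)
        steps = rng.uniform(-0.4, 0.4, 8)
        shifts = [RelativeShift(i, i + 1, float(s)) for i, s in enumerate(steps)]
        ga = multipass_align(shifts, dt_schedule=(1,))
        np.testing.assert_allclose(ga.x, np.concatenate([[0], np.cumsum(steps)]), atol=1e-9)

    def test_wrapping_witness_recovered_where_naive_fails(self):
        n, step = 20, 0.8 * np.pi
        truth = np.arange(n) * step
        rng = np.random.default_rng(42)
        shifts = []
        for b in range(1, n):
            for a in range(max(0, b - 3), b):
                d = wrap_to_pm_pi(truth[b] - truth[a] + rng.normal(0, 0.02))
                shifts.append(RelativeShift(a, b, float(d)))
        ga = multipass_align(shifts, dt_schedule=(1, 3))
        err = (ga.x - truth) - (ga.x - truth)[0]
        assert np.abs(err).max() < 0.05
        # naive single least-squares on the wrapped system
        A = np.zeros((len(shifts), n - 1))
        for i, s in enumerate(shifts):
            if s.a > 0:
                A[i, s.a - 1] = -1
            if s.b > 0:
                A[i, s.b - 1] = 1
        sol, *_ = np.linalg.lstsq(A, np.array([s.dphi for s in shifts]), rcond=None)
        naive = np.concatenate([[0.0], sol])
        assert np.abs(naive - truth).max() > np.pi

    def test_final_residuals_within_pi(self):
        rng = np.random.default_rng(6)
        truth = np.cumsum(rng.uniform(0.5, 2.5, 12))
        shifts = []
        for b in range(1, 12):
            for a in range(max(0, b - 3), b):
                shifts.append(RelativeShift(a, b, float(wrap_to_pm_pi(truth[b] - truth[a]))))
        ga = multipass_align(shifts)
        assert (np.abs(ga.residuals) < np.pi).all()

    def test_gauge_invariance(self):
        # adding a constant to all true phases leaves dphi and hence x unchanged
        rng = np.random.default_rng(7)
        truth = np.cumsum(rng.uniform(-1, 1, 10))
        def build(offset):
            sh = []
            for b in range(1, 10):
                for a in range(max(0, b - 2), b):
                    sh.append(RelativeShift(a, b, float(wrap_to_pm_pi((truth[b] + offset) - (truth[a] + offset)))))
            return multipass_align(sh).x
        np.testing.assert_allclose(build(0.0), build(1.234), atol=1e-9)

    def test_disconnected_graph_names_unreachable_ids(self):
        with pytest.raises(AlignmentError, match="3"):
            multipass_align([RelativeShift(0, 1, 0.1), RelativeShift(3, 4, 0.1)])


class TestRefreshReference:
    def _make_ref(self, video, start, seq_id, n_frames=200):
        from heartsync.gating_controller import acquire_reference

        return acquire_reference(video.segment(start, n_frames), sequence_id=seq_id)

    def test_identical_reference_keeps_target(self, clean_spec):
        video = SimulatedVideo(clean_spec)
        ref0 = self._make_ref(video, 0, 0)
        state = AlignmentState(ref0, target_phase=1.3)
        ref1 = self._make_ref(video, 0, 1)  # same video position: identical content
        new_target, _ = refresh_reference(state, ref1, 1.3)
        assert new_target == pytest.approx(1.3, abs=0.02)

    def test_target_continuous_across_many_refreshes(self):
        spec = SyntheticHeartSpec(seed=9, drift_velocity=(0.0, 0.0))
        video = SimulatedVideo(spec)
        ref0 = self._make_ref(video, 0, 0)
        state = AlignmentState(ref0, target_phase=2.0)
        prev_target = 2.0
        start = 400
        for k in range(1, 12):
            ref = self._make_ref(video, start, k)
            new_target, _ = refresh_reference(state, ref, prev_target)
            # continuity: consecutive targets never jump by ~2*pi
            jump = abs(wrap_to_pm_pi(new_target - prev_target))
            assert jump < 1.5
            prev_target = new_target
            start += 400

    def test_refresh_tracks_truth_on_morphing_heart(self):
        """Across many refreshes of a strongly morphing (but rhythm-stable)
        heart, the re-anchored target stays within 0.1 rad of ground truth."""
        spec = SyntheticHeartSpec(
            seed=4, morph_rate=0.3, period_jitter_cv=0.0, refractory_jitter_cv=0.0,
            drift_velocity=(0.0, 0.0),
        )
        video = SimulatedVideo(spec)
        ref0 = self._make_ref(video, 0, 0)
        target = 1.0
        anchor = (video.truth.phase_at(ref0.acquired_at) + target) % TWO_PI
        state = AlignmentState(ref0, target_phase=target)
        start = 600
        for k in range(1, 31):
            ref = self._make_ref(video, start, k)
            target, _ = refresh_reference(state, ref, target)
            realized = (video.truth.phase_at(ref.acquired_at) + target) % TWO_PI
            dev = abs(wrap_to_pm_pi(realized - anchor))
            assert dev < 0.1
            start += 600
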