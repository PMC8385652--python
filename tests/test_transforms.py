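import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eitgest as eg
from eitgest.errors import DegenerateDataError, MissingReferenceError
from eitgest.frames import NEUTRAL_GESTURE
from eitgest.transforms import (
    ITERATION_LOCAL,
    SESSION_GLOBAL,
    circular_shift_values,
    compute_references,
    pair_with_reference,
)


class TestNormalizer:
    def test_maps_span_to_unit_interval(self, small_ds):
        span = small_ds.with_values(
            np.linspace(2, 6, small_ds.values.size).reshape(small_ds.values.shape))
        norm = eg.fit_normalizer(span)
        assert norm.transform_values(np.array([4.0])) == pytest.approx(0.5)
        assert norm.transform_values(np.array([2.0])) == pytest.approx(0.0)
        assert norm.transform_values(np.array([6.0])) == pytest.approx(1.0)
        # out-of-span test values are clipped
        assert norm.transform_values(np.array([7.0])) == pytest.approx(1.0)
        assert norm.transform_values(np.array([-1.0])) == pytest.approx(0.0)

    def test_constant_data_rejected(self, small_ds):
        const = small_ds.with_values(np.full_like(small_ds.values, 3.0))
        with pytest.raises(DegenerateDataError):
            eg.fit_normalizer(const)

    def test_normalize_then_calibrate_differs_from_reverse(self, small_ds):
        """The pipeline order (normalize first) is not interchangeable."""
        norm = eg.fit_normalizer(small_ds)
        a = eg.local_calibrate(norm.transform(small_ds)).values
        b = norm.transform(eg.local_calibrate(small_ds)).values
        assert not np.allclose(a, b)


class TestGlobalCalibration:
    def test_iteration1_neutral_mean_is_exactly_zero(self, small_ds):
        cal = eg.global_calibrate(small_ds)
        for subj, sess in cal.session_keys():
            sel = cal.mask(subject=subj, session=sess, iteration=1,
                           gesture=NEUTRAL_GESTURE)
            np.testing.assert_allclose(cal.values[sel].mean(axis=0), 0.0, atol=1e-12)

    def test_offset_only_centroids_become_session_invariant(
            self, noise_free_offsets_sim):
        ds, _ = noise_free_offsets_sim
        cal = eg.global_calibrate(ds)
        for g in (0, 5, 11):
            cents = np.stack([
                cal.values[cal.mask(session=s, gesture=g)].mean(axis=0)
                for _, s in cal.session_keys()])
            assert np.allclose(cents, cents[0], atol=1e-9)

    def test_missing_neutral_in_first_iteration_is_an_error(self, small_ds):
        trimmed = small_ds.take(np.flatnonzero(
            ~small_ds.mask(session="1", iteration=1, gesture=NEUTRAL_GESTURE)))
        with pytest.raises(MissingReferenceError, match="iteration 1"):
            eg.global_calibrate(trimmed)


class TestLocalCalibration:
    def test_every_iterations_neutral_mean_is_exactly_zero(self, small_ds):
        cal = eg.local_calibrate(small_ds)
        for (subj, sess, it), idx in cal.meta.groupby(
                ["subject", "session", "iteration"], sort=False).indices.items():
            sel = cal.mask(subject=subj, session=sess, iteration=it,
                           gesture=NEUTRAL_GESTURE)
            np.testing.assert_allclose(cal.values[sel].mean(axis=0), 0.0, atol=1e-12)

    def test_cancels_offset_and_drift_in_noise_free_run(self):
        """Drift is common to all gestures of an iteration, so the local
        neutral reference removes it: class centroids become independent of
        both session and iteration."""
        cfg = eg.SimConfig(sessions_per_subject=3, iterations_per_session=4,
                           frames_per_gesture=2, gain_spread=0.0, rotation_prob=0.0,
                           sigma_noise=0.0, seed=13)
        ds, _ = eg.simulate_dataset(cfg)
        cal = eg.local_calibrate(ds)
        for g in (1, 8):
            groups = cal.meta.groupby(["session", "iteration"], sort=False).indices
            cents = [cal.values[cal.mask(session=s, iteration=it, gesture=g)].mean(axis=0)
                     for (s, it) in groups]
            assert np.allclose(np.stack(cents), cents[0], atol=1e-9)

    def test_iteration_without_neutral_names_it(self, small_ds):
        trimmed = small_ds.take(np.flatnonzero(
            ~small_ds.mask(session="2", iteration=3, gesture=NEUTRAL_GESTURE)))
        with pytest.raises(MissingReferenceError, match="iteration 3"):
            eg.local_calibrate(trimmed)

    def test_coincides_with_global_on_single_iteration_sessions(self, small_ds):
        single = small_ds.select(iteration=1)
        assert np.allclose(eg.global_calibrate(single).values,
                           eg.local_calibrate(single).values)

    def test_recalibrating_calibrated_data_gives_zero_reference(self, small_ds):
        cal = eg.local_calibrate(small_ds)
        refs = compute_references(cal, ITERATION_LOCAL)
        for ref in refs.values():
            np.testing.assert_allclose(ref.values, 0.0, atol=1e-12)


class TestReferencePairing:
    def test_every_frame_paired_including_neutrals(self, small_ds):
        paired = pair_with_reference(small_ds, ITERATION_LOCAL)
        assert paired.references.shape == small_ds.values.shape
        # neutral frames are classified too, so they carry references as well
        assert small_ds.mask(gesture=NEUTRAL_GESTURE).any()
        # values stay uncalibrated: the network does the offsetting
        assert np.array_equal(paired.dataset.values, small_ds.values)

    def test_frames_of_one_iteration_share_one_reference(self, small_ds):
        paired = pair_with_reference(small_ds, ITERATION_LOCAL)
        sel = small_ds.mask(session="1", iteration=2)
        refs = paired.references[sel]
        assert np.allclose(refs, refs[0])

    def test_session_global_scope_available(self, small_ds):
        paired = pair_with_reference(small_ds, SESSION_GLOBAL)
        sel = small_ds.mask(session="1")
        assert np.allclose(paired.references[sel], paired.references[sel][0])


class TestCircularShift:
    @pytest.mark.parametrize("n", [8, 16])
    def test_shift_by_n_is_identity(self, n, rng):
        sched = eg.build_schedule(n)
        v = rng.random(sched.n_measurements)
        assert np.array_equal(circular_shift_values(v, n, sched), v)
        assert np.array_equal(circular_shift_values(v, 0, sched), v)

    def test_shifts_compose_additively(self, schedule16, rng):
        v = rng.random(208)
        a = circular_shift_values(circular_shift_values(v, 3, schedule16), 13, schedule16)
        assert np.array_equal(a, v)

    @given(st.integers(min_value=-40, max_value=40), st.integers(min_value=-40, max_value=40))
    @settings(deadline=None, max_examples=25)
    def test_group_action_of_z16(self, k1, k2):
        sched = eg.build_schedule(16)
        rng = np.random.default_rng(99)
        v = rng.random(208)
        lhs = circular_shift_values(circular_shift_values(v, k1, sched), k2, sched)
        rhs = circular_shift_values(v, (k1 + k2) % 16, sched)
        assert np.array_equal(lhs, rhs)

    def test_values_are_permuted_not_changed(self, schedule16, rng):
        v = rng.random(208)
        shifted = circular_shift_values(v, 5, schedule16)
        assert sorted(shifted) == sorted(v)

    def test_cycle_i_becomes_cycle_i_minus_k(self, schedule16):
        v = np.repeat(np.arange(16.0), 13)  # cycle index as value
        shifted = circular_shift_values(v, 4, schedule16).reshape(16, 13)
        for i in range(16):
            assert (shifted[i] == (i - 4) % 16).all()
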