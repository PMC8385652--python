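import numpy as np
import pytest

import eitgest as eg
from eitgest.synth import SimConfig, default_paper_like_config, simulate_dataset


class TestDeterminismAndShape:
    def test_same_seed_bit_identical(self, small_sim):
        ds, _ = small_sim
        cfg = SimConfig(sessions_per_subject=2, iterations_per_session=3,
                        frames_per_gesture=3, seed=7)
        ds2, _ = simulate_dataset(cfg)
        assert ds.equals(ds2)

    def test_distinct_seeds_differ(self):
        cfg = SimConfig(sessions_per_subject=1, iterations_per_session=1,
                        frames_per_gesture=2)
        a, _ = simulate_dataset(SimConfig(**{**vars(cfg), "seed": 1}))
        b, _ = simulate_dataset(SimConfig(**{**vars(cfg), "seed": 2}))
        assert not np.array_equal(a.values, b.values)

    def test_study_scale_size(self):
        cfg = default_paper_like_config(0)
        assert (cfg.sessions_per_subject * cfg.iterations_per_session
                * 12 * cfg.frames_per_gesture) == 5760

    def test_values_non_negative(self, small_ds):
        assert (small_ds.values >= 0).all()

    def test_truth_records_every_session(self, small_sim):
        ds, truth = small_sim
        assert set(truth.sessions) == set(ds.session_keys())
        for st in truth.sessions.values():
            assert st.offset.shape == (208,)
            assert st.gain.shape == (16,)
            assert np.isclose(np.linalg.norm(st.drift_direction), 1.0)


class TestDegenerateConfigs:
    def test_no_variance_sources_gives_identical_frames_per_class(self):
        cfg = SimConfig(sessions_per_subject=2, iterations_per_session=2,
                        frames_per_gesture=3, sigma_session=0.0, gain_spread=0.0,
                        rotation_prob=0.0, drift_amplitude=0.0, sigma_noise=0.0,
                        seed=5)
        ds, truth = simulate_dataset(cfg)
        for g in range(12):
            vals = ds.values[ds.mask(gesture=g)]
            assert np.allclose(vals, vals[0])
            assert np.allclose(vals[0], truth.prototypes[g])

    @pytest.mark.parametrize("field,value", [
        ("drift_tau", 0.0), ("sigma_noise", -1.0), ("rotation_prob", 1.5),
        ("frames_per_gesture", 0), ("n_electrodes", 4),
        ("drift_class_overlap", 2.0),
    ])
    def test_invalid_config_rejected(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ValueError):
            cfg.validate()


class TestDriftStructure:
    def test_centroid_steps_strictly_shrink_over_iterations(self):
        """Noise-free run: consecutive-iteration displacement of a class
        centroid follows the saturating-exponential profile, so each step is
        strictly smaller than the previous one."""
        cfg = SimConfig(sessions_per_subject=1, iterations_per_session=6,
                        frames_per_gesture=2, sigma_noise=0.0, gain_spread=0.0,
                        rotation_prob=0.0, seed=9)
        ds, truth = simulate_dataset(cfg)
        cents = [ds.values[ds.mask(gesture=0, iteration=t)].mean(axis=0)
                 for t in range(1, 7)]
        steps = [np.linalg.norm(b - a) for a, b in zip(cents, cents[1:])]
        assert all(s1 > s2 for s1, s2 in zip(steps, steps[1:]))
        # and the magnitudes match the closed form A(e^{-t/tau}-e^{-(t+1)/tau})
        A, tau = cfg.drift_amplitude, cfg.drift_tau
        expected = [A * (np.exp(-t / tau) - np.exp(-(t + 1) / tau)) for t in range(1, 6)]
        assert np.allclose(steps, expected, rtol=1e-6)

    def test_offset_only_sessions_differ_by_pure_translation(self, noise_free_offsets_sim):
        ds, truth = noise_free_offsets_sim
        keys = ds.session_keys()
        c0 = ds.values[ds.mask(session=keys[0][1], gesture=2)].mean(axis=0)
        c1 = ds.values[ds.mask(session=keys[1][1], gesture=2)].mean(axis=0)
        shift = truth.sessions[keys[1]].offset - truth.sessions[keys[0]].offset
        assert np.allclose(c1 - c0, shift, atol=1e-9)

    def test_global_calibration_collapses_offset_only_session_spread(
            self, noise_free_offsets_sim):
        """With offsets as the only session effect, subtracting the neutral
        reference must shrink cross-session centroid spread >= 90%."""
        ds, _ = noise_free_offsets_sim
        cal = eg.global_calibrate(ds)

        def spread(d):
            per_class = []
            for g in range(12):
                cents = np.stack([
                    d.values[d.mask(session=s, gesture=g)].mean(axis=0)
                    for _, s in d.session_keys()])
                per_class.append(np.linalg.norm(cents - cents.mean(axis=0), axis=1).mean())
            return np.mean(per_class)

        assert spread(cal) <= 0.1 * spread(ds)


@pytest.fixture(scope="module")
def study_ds():
    return simulate_dataset(default_paper_like_config(0))[0]


class TestStudyScaleRegime:
    """The default configuration must put a nearest-centroid oracle in the
    intended regime: within-session near-perfect, raw cross-session far
    below it (the generated session gap)."""

    @staticmethod
    def _nc_acc(tr_x, tr_y, te_x, te_y):
        cents = np.stack([tr_x[tr_y == c].mean(axis=0) for c in range(12)])
        d = ((te_x[:, None, :] - cents[None]) ** 2).sum(-1)
        return float((d.argmin(1) == te_y).mean())

    def test_within_session_oracle_above_95_percent(self, study_ds):
        from eitgest.evaluation import SplitSpec, make_split

        for subj, sess in study_ds.session_keys():
            s = study_ds.select(subject=subj, session=sess)
            sp = make_split(s, SplitSpec("stratified_random", seed=0))
            acc = self._nc_acc(sp.train.values, sp.train.labels,
                               sp.test.values, sp.test.labels)
            assert acc > 0.95, (subj, sess, acc)

    def test_cross_session_oracle_far_below_within(self, study_ds):
        from eitgest.evaluation import SplitSpec, make_split

        accs = []
        for key in study_ds.session_keys():
            sp = make_split(study_ds, SplitSpec("leave_one_session_out", holdout=key))
            accs.append(self._nc_acc(sp.train.values, sp.train.labels,
                                     sp.test.values, sp.test.labels))
        assert np.mean(accs) < 0.5  # far below the >0.95 within-session level


class TestRotation:
    def test_rotation_uses_cycle_shift_definition(self):
        cfg = SimConfig(sessions_per_subject=6, iterations_per_session=1,
                        frames_per_gesture=1, sigma_session=0.0, gain_spread=0.0,
                        drift_amplitude=0.0, sigma_noise=0.0, rotation_prob=1.0,
                        seed=2)
        ds, truth = simulate_dataset(cfg)
        from eitgest.transforms import circular_shift_values

        for (subj, sess), st in truth.sessions.items():
            got = ds.values[ds.mask(subject=subj, session=sess, gesture=4)][0]
            want = circular_shift_values(truth.prototypes[4], st.rotation, ds.schedule)
            assert np.allclose(got, want)
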