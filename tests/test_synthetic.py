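"""Synthetic-trial generator: geometry, Fitts law, trajectories, channels."""

import math

import numpy as np
import pytest
from scipy import stats

import fittsfusion as ff
from fittsfusion.synthetic import FittsCondition, FittsLawParams


class TestIndexOfDifficulty:
    @pytest.mark.parametrize(
        "d, w, expected",
        [(10, 5, 2.0), (320, 5, 7.0), (2.5, 5, 0.0), (40, 5, 4.0)],
    )
    def test_log_formula(self, d, w, expected):
        assert ff.index_of_difficulty(d, w) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("d, w", [(0, 5), (-1, 5), (10, 0), (10, -2)])
    def test_nonpositive_geometry_rejected(self, d, w):
        with pytest.raises(ValueError):
            ff.index_of_difficulty(d, w)

    def test_monotone_in_distance_and_width(self):
        assert ff.index_of_difficulty(20, 5) > ff.index_of_difficulty(10, 5)
        assert ff.index_of_difficulty(10, 8) < ff.index_of_difficulty(10, 5)

    def test_default_protocol_difficulties(self):
        """The six printed distances at W = 5 mm span 2..7 bits, with the
        180 mm condition at log2(72), not an integer."""
        cfg = ff.SynthConfig()
        ids = [c.difficulty for c in cfg.conditions]
        expected = [2.0, 3.0, 4.0, 5.0, math.log2(72.0), 7.0]
        assert ids == pytest.approx(expected, abs=1e-12)


class TestMovementTime:
    def test_noise_free_line(self):
        p = FittsLawParams(intercept=0.0, slope=1.0, mt_noise_sd=0.0)
        assert ff.sample_movement_time(p, 3.0, np.random.default_rng(0)) == 3.0
        p = FittsLawParams(intercept=0.2, slope=0.15, mt_noise_sd=0.0)
        assert ff.sample_movement_time(p, 7.0, np.random.default_rng(0)) == pytest.approx(1.25)

    def test_monte_carlo_recovery(self, rng):
        """OLS on sampled (ID, MT) pairs recovers (a, b) within 3 SE."""
        p = FittsLawParams(intercept=0.3, slope=0.2, mt_noise_sd=0.1)
        ids = rng.uniform(2.0, 7.0, 10_000)
        mts = np.array([ff.sample_movement_time(p, i, rng) for i in ids])
        res = stats.linregress(ids, mts)
        assert abs(res.intercept - 0.3) < 3 * res.intercept_stderr
        assert abs(res.slope - 0.2) < 3 * res.stderr

    def test_truncation_keeps_mt_positive(self, rng):
        p = FittsLawParams(intercept=0.05, slope=0.01, mt_noise_sd=2.0)
        draws = [ff.sample_movement_time(p, 2.0, rng) for _ in range(200)]
        assert min(draws) > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FittsLawParams(slope=0.0)
        with pytest.raises(ValueError):
            FittsLawParams(mt_noise_sd=-0.1)


class TestMinimumJerk:
    def test_boundary_and_midpoint(self):
        traj = ff.minimum_jerk_trajectory((1, 2, 0), (5, -2, 0), 1.0, 100.0)
        np.testing.assert_allclose(traj.samples[0], [1, 2, 0], atol=1e-12)
        np.testing.assert_allclose(traj.samples[-1], [5, -2, 0], atol=1e-12)
        mid = traj.samples[len(traj) // 2]
        np.testing.assert_allclose(mid, [3, 0, 0], atol=1e-9)

    def test_endpoint_velocity_zero(self):
        traj = ff.minimum_jerk_trajectory((0, 0, 0), (1, 0, 0), 1.0, 200.0)
        v = np.gradient(traj.samples[:, 0], 1.0 / traj.sampling_rate)
        assert abs(v[0]) < 1e-2 and abs(v[-1]) < 1e-2

    def test_coincident_endpoints_constant(self):
        traj = ff.minimum_jerk_trajectory((1, 1, 1), (1, 1, 1), 0.5, 100.0)
        assert np.ptp(traj.samples) == 0


class TestSynthPpg:
    def test_too_short_for_one_beat(self, rng):
        with pytest.raises(ValueError):
            ff.synth_ppg(60.0, 1.5, 512.0, rng)

    @pytest.mark.parametrize("hr", [60.0, 72.0])
    def test_round_trip_heart_rate(self, hr, rng):
        ppg = ff.synth_ppg(hr, 12.0, 512.0, rng, beat_jitter=0.0)
        recovered = ff.heart_rate_from_ppg(ppg, rest_heart_rate=60.0) * 60.0
        assert recovered == pytest.approx(hr, abs=1.0)


class TestGenerateDataset:
    def test_default_design_counts(self, default_dataset):
        assert len(default_dataset) == 420
        per_subject = {}
        for r in default_dataset:
            per_subject[r.subject_id] = per_subject.get(r.subject_id, 0) + 1
        assert set(per_subject.values()) == {30}

    def test_blocks_contain_every_condition(self, default_dataset):
        seen = {}
        for r in default_dataset:
            seen.setdefault((r.subject_id, r.block), set()).add(r.condition.distance)
        assert all(len(v) == 6 for v in seen.values())

    def test_same_seed_reproduces_dataset(self):
        cfg = ff.SynthConfig(n_subjects=2, repetitions=1, distances=(10.0, 80.0), seed=7)
        a, b = ff.generate_dataset(cfg), ff.generate_dataset(cfg)
        for ra, rb in zip(a, b):
            assert ra.movement_time == rb.movement_time
            np.testing.assert_array_equal(ra.trajectory.samples, rb.trajectory.samples)
            np.testing.assert_array_equal(ra.emg_pectm.samples, rb.emg_pectm.samples)
            assert ra.eeg_states == rb.eeg_states

    def test_different_seeds_differ(self):
        a = ff.generate_dataset(ff.SynthConfig(n_subjects=1, repetitions=1,
                                               distances=(80.0,), seed=1))
        b = ff.generate_dataset(ff.SynthConfig(n_subjects=1, repetitions=1,
                                               distances=(80.0,), seed=2))
        assert not np.array_equal(a[0].trajectory.samples, b[0].trajectory.samples)

    def test_trial_invariants(self, fixture_records):
        for r in fixture_records:
            assert abs(r.trajectory.duration - r.movement_time) < 2.0 / r.trajectory.sampling_rate
            assert all(0.0 <= p <= 1.0 for p in r.eeg_states.values())
            assert r.baselines.mvic_pectm > 0
            assert len(r.gsr) > 0 and len(r.ppg) > 0


class TestTrialStructure:
    def test_zero_perturbation_gives_straight_path(self):
        slopes = ff.ResponseSlopes(traj_noise_base_mm=0.0)
        cfg = ff.SynthConfig(slopes=slopes, seed=0)
        rng = np.random.default_rng(0)
        subj = ff.make_subject(cfg, 0, rng)
        rec = ff.generate_trial(cfg, subj, FittsCondition(80.0, 5.0), rng)
        assert ff.path_straight_deviation(rec.trajectory) == pytest.approx(0.0, abs=1e-9)
        assert ff.path_efficiency(rec.trajectory) == pytest.approx(1.0, abs=1e-9)

    def test_noise_free_config_affine_responses(self):
        """With every noise SD at zero, MT is exactly affine in ID and the
        sloped channel features correlate with ID essentially perfectly."""
        slopes = ff.ResponseSlopes(
            emg_trial_jitter=0.0, gsr_jitter=0.0, hr_jitter=0.0, ppg_beat_jitter=0.0,
            traj_noise_base_mm=0.0,
            eeg={k: (b, s, 0.0) for k, (b, s, _) in ff.ResponseSlopes().eeg.items()},
        )
        sv = ff.SubjectVariation(mt_intercept_sd=0.0, emg_sd=0.0, imu_sd=0.0,
                                 path_sd=0.0, mvic_sd=0.0, rest_hr_sd=0.0,
                                 sc_baseline_sd=0.0)
        cfg = ff.SynthConfig(
            n_subjects=3, repetitions=2, seed=5, subject_variation=sv,
            fitts=FittsLawParams(0.35, 0.22, 0.0), slopes=slopes,
        )
        tab = ff.build_feature_table(ff.generate_dataset(cfg))
        ids = tab["ID"].to_numpy()
        np.testing.assert_allclose(tab["MT"], 0.35 + 0.22 * ids, atol=1e-12)
        # channels with affine difficulty response correlate ~perfectly
        for metric in ("PectM_rms", "SC_vr", "HR"):
            r, _ = ff.pearson_r(tab[metric], ids)
            assert r > 0.99, metric
        # speed-driven limb metrics grow nonlinearly in ID: level means
        # are strictly increasing even though Pearson r < 1
        means = tab.groupby("ID")["AngVel_FA"].mean().to_numpy()
        assert np.all(np.diff(means) > 0)

    def test_emg_rms_rises_with_difficulty(self, default_feature_table):
        """Monte-Carlo sign check over the full default design."""
        r, p = ff.pearson_r(default_feature_table["PectM_rms"],
                            default_feature_table["ID"])
        assert r > 0 and p < 0.01

    def test_subject_subset_regenerates_identically(self):
        """Child seeding lets a smaller design reproduce the shared trials."""
        full = ff.SynthConfig(n_subjects=3, repetitions=2, seed=9)
        part = ff.SynthConfig(n_subjects=2, repetitions=2, seed=9)
        a = ff.generate_dataset(full)
        b = ff.generate_dataset(part)
        a_sub = [r for r in a if r.subject_id < 2]
        for ra, rb in zip(a_sub, b):
            assert ra.movement_time == rb.movement_time
            np.testing.assert_array_equal(ra.gsr.samples, rb.gsr.samples)
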