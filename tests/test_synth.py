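from datetime import datetime, timezone

import numpy as np
import pytest

from tremorkit import (
    MedEffectModel,
    ParticipantProfile,
    Regimen,
    TremorSimConfig,
    simulate_cohort,
    simulate_participant,
    simulate_session,
)
from tremorkit.spectral import band_auc, welch_psd
from tremorkit.preprocess import to_uniform_scalar


class TestConfigValidation:
    def test_rejects_non_finite_values(self):
        with pytest.raises(ValueError, match="finite"):
            TremorSimConfig(tremor_amp=np.inf)

    def test_rejects_out_of_range_frequency(self):
        with pytest.raises(ValueError):
            TremorSimConfig(tremor_freq_hz=30.0)

    def test_rejects_non_unit_gravity_axis(self):
        with pytest.raises(ValueError, match="unit"):
            TremorSimConfig(gravity_axis=(1.0, 1.0, 0.0))

    def test_rejects_unknown_jitter_model(self):
        with pytest.raises(ValueError, match="jitter_model"):
            TremorSimConfig(jitter_model="sawtooth")


class TestSimulateSession:
    def test_gravity_only_magnitude_is_constant(self):
        cfg = TremorSimConfig(tremor_amp=0.0, noise_sd=0.0, jitter_model="none")
        sess = simulate_session(cfg)
        np.testing.assert_allclose(sess.magnitude(), 9.81, atol=1e-12)

    def test_fixed_seed_is_bit_identical(self):
        cfg = TremorSimConfig(seed=42)
        a = simulate_session(cfg)
        b = simulate_session(cfg)
        assert np.array_equal(a.t, b.t)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.z, b.z)

    @pytest.mark.parametrize("jitter", ["none", "gaussian", "dropout-burst"])
    def test_timestamps_increasing_and_span_session(self, jitter):
        cfg = TremorSimConfig(jitter_model=jitter, seed=11)
        sess = simulate_session(cfg)
        assert np.all(np.diff(sess.t) > 0)
        assert sess.t[0] == 0.0
        assert sess.t[-1] == pytest.approx(10_000.0, rel=0.05)

    def test_no_jitter_gives_exact_nominal_intervals(self):
        cfg = TremorSimConfig(jitter_model="none")
        sess = simulate_session(cfg)
        np.testing.assert_allclose(np.diff(sess.t), 20.0, atol=1e-9)

    def test_noise_variance_matches_noise_sd(self):
        """Mean empirical variance over 100 seeds is within 5% of sd²."""
        cfg = TremorSimConfig(tremor_amp=0.0, noise_sd=0.3, jitter_model="none")
        ss = np.random.SeedSequence(21)
        # x axis is orthogonal to gravity: pure noise
        var = [
            np.var(simulate_session(cfg, rng=np.random.default_rng(c)).x)
            for c in ss.spawn(100)
        ]
        assert np.mean(var) == pytest.approx(0.3**2, rel=0.05)

    def test_doubling_amplitude_quadruples_band_power(self):
        """PSD power scales with amplitude squared (checked in 3-6 Hz)."""
        base = TremorSimConfig(tremor_amp=0.4, noise_sd=0.0, jitter_model="none",
                               freq_jitter_hz=0.0)
        aucs = {}
        for amp in (0.4, 0.8):
            sess = simulate_session(base.replace(tremor_amp=amp, seed=5))
            pg = welch_psd(to_uniform_scalar(sess, 50.0))
            aucs[amp] = band_auc(pg, 3.0, 6.0)
        assert aucs[0.8] / aucs[0.4] == pytest.approx(4.0, rel=0.10)

    def test_amp_multiplier_bounds_enforced(self):
        with pytest.raises(ValueError):
            simulate_session(TremorSimConfig(), amp_multiplier=1.5)


class TestMedEffectModel:
    def test_piecewise_shape(self):
        med = MedEffectModel(onset_min=15, peak_min=60, wearoff_min=240,
                             attenuation=0.4)
        assert med.amp_multiplier(None) == 1.0
        assert med.amp_multiplier(0.0) == 1.0
        assert med.amp_multiplier(14.9) == 1.0
        assert med.amp_multiplier(60.0) == pytest.approx(0.6)
        assert med.amp_multiplier(240.0) == 1.0
        assert med.amp_multiplier(500.0) == 1.0

    def test_hand_computed_interpolation_between_onset_and_peak(self):
        med = MedEffectModel(onset_min=15, peak_min=60, wearoff_min=240,
                             attenuation=0.5)
        # 30 min: a third of the way from onset to peak
        assert med.amp_multiplier(30.0) == pytest.approx(1 - 0.5 / 3)
        # 150 min: halfway through the wear-off ramp
        assert med.amp_multiplier(150.0) == pytest.approx(0.75)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            MedEffectModel(onset_min=60, peak_min=15, wearoff_min=240)

    def test_attenuation_range_enforced(self):
        with pytest.raises(ValueError):
            MedEffectModel(attenuation=1.5)


class TestRegimen:
    def test_length_must_match_count(self):
        from datetime import time

        with pytest.raises(ValueError):
            Regimen(intakes_per_day=2, intake_times=(time(8),))

    def test_evenly_spaced_helper(self):
        r = Regimen.evenly_spaced(3)
        assert r.intakes_per_day == 3
        assert [t.hour for t in r.intake_times] == [8, 14, 20]


def _profile(pid="S01", group="tremor", item=1):
    return ParticipantProfile(participant_id=pid, updrs2_total=10,
                              updrs_tremor_item=item, group=group)


class TestSimulateParticipant:
    def test_sessions_do_not_overlap(self):
        sessions, _, _ = simulate_participant(
            _profile(), Regimen.evenly_spaced(3), MedEffectModel(),
            TremorSimConfig(), n_days=3, sessions_per_day=6, seed=1,
        )
        starts = sorted(s.session_start for s in sessions)
        gaps = [(b - a).total_seconds() for a, b in zip(starts, starts[1:])]
        assert min(gaps) >= 10.0

    def test_zero_attenuation_keeps_multiplier_at_one(self):
        _, _, truth = simulate_participant(
            _profile(), Regimen.evenly_spaced(3),
            MedEffectModel(attenuation=0.0), TremorSimConfig(),
            n_days=2, sessions_per_day=4, seed=2,
        )
        assert (truth["amp_multiplier"] == 1.0).all()

    def test_multiplier_follows_the_effect_profile(self):
        med = MedEffectModel(attenuation=0.5)
        _, _, truth = simulate_participant(
            _profile(), Regimen.evenly_spaced(3), med, TremorSimConfig(),
            n_days=2, sessions_per_day=4, seed=3,
        )
        for row in truth.itertuples(index=False):
            expected = med.amp_multiplier(
                None if np.isnan(row.delta_min) else row.delta_min
            )
            assert row.amp_multiplier == pytest.approx(expected)

    def test_intake_log_matches_regimen(self):
        regimen = Regimen.evenly_spaced(2)
        _, logs, _ = simulate_participant(
            _profile(), regimen, MedEffectModel(), TremorSimConfig(),
            n_days=5, sessions_per_day=2, seed=4,
        )
        assert len(logs) == 10
        assert all(lg.intakes_per_day == 2 for lg in logs)
        assert all(lg.intake_time.tzinfo == timezone.utc for lg in logs)


class TestSimulateCohort:
    def test_cohort_is_deterministic(self):
        a = simulate_cohort(7, n_days=1, sessions_per_day=2)
        b = simulate_cohort(7, n_days=1, sessions_per_day=2)
        assert [s.session_id for s in a.sessions] == [s.session_id for s in b.sessions]
        np.testing.assert_array_equal(a.sessions[0].x, b.sessions[0].x)

    def test_cohort_structure_mirrors_study_groups(self):
        cohort = simulate_cohort(1, n_days=1, sessions_per_day=1)
        groups = [p.group for p in cohort.profiles]
        assert groups.count("no_tremor") == 3
        assert groups.count("tremor") == 4
        assert groups.count("hand_tremor") == 2
        assert groups.count("plays_with_hand_tremor") == 2
        assert len(cohort.sessions) == 11
        assert len(cohort.truth) == 11
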