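"""Simulator unit tests: cues, pools, spike sampling, templates, mixing."""

import numpy as np
import pytest

from mukin.errors import InvalidConfigError, InvalidInputError
from mukin.simulator import (
    CorruptionSpec,
    CueProfile,
    MotorUnitPool,
    SessionConfig,
    build_pool,
    corrupt_spike_trains,
    drive_from_kinematics,
    generate_cue,
    generate_templates,
    sample_spike_trains,
    simulate_session,
    synthesize_emg,
)
from mukin.types import KinematicsTrace, SpikeTrainSet


class TestGenerateCue:
    def test_peak_magnitude_equals_rom_both_directions(self):
        trace, _ = generate_cue(CueProfile(dof_index=0, ramp_duration=1.0, rom=60.0))
        assert trace.angles[0].max() == pytest.approx(60.0)
        assert trace.angles[0].min() == pytest.approx(-60.0)
        assert np.all(trace.angles[1:] == 0)

    def test_starts_and_ends_at_neutral(self):
        trace, _ = generate_cue(CueProfile(dof_index=2, ramp_duration=2.5))
        assert trace.angles[2, 0] == 0
        assert trace.angles[2, -1] == 0

    def test_zero_trials_is_pure_rest(self):
        profile = CueProfile(dof_index=1, ramp_duration=1.0, n_trials=0, rest_duration=2.0)
        trace, _ = generate_cue(profile)
        assert trace.n_samples == round(2.0 * profile.sample_rate)
        assert np.all(trace.angles == 0)

    def test_nonzero_slope_sample_count_matches_schedule(self):
        # one trial at 5 s ramps: each direction episode holds exactly
        # 2*round(5*fs) samples of nonzero slope
        fs = 2048.0
        trace, seg = generate_cue(
            CueProfile(dof_index=1, ramp_duration=5.0, n_trials=1, sample_rate=fs)
        )
        d = np.diff(trace.angles[1])
        assert np.count_nonzero(d) == 2 * 2 * round(5.0 * fs)  # two directions
        for row in seg.records.itertuples():
            span = trace.angles[1, row.start_sample : row.end_sample]
            assert np.count_nonzero(np.diff(span)) == 2 * round(5.0 * fs)

    def test_invalid_configuration_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_cue(CueProfile(dof_index=0, ramp_duration=-1.0))
        with pytest.raises(InvalidConfigError):
            generate_cue(CueProfile(dof_index=0, ramp_duration=1.0, sample_rate=0))

    def test_segmentation_partitions_block(self):
        trace, seg = generate_cue(CueProfile(dof_index=0, ramp_duration=1.0, n_trials=3))
        rec = seg.records.sort_values("start_sample")
        assert rec.iloc[0].start_sample == 0
        assert rec.iloc[-1].end_sample == trace.n_samples
        assert np.all(rec["end_sample"].to_numpy()[:-1] == rec["start_sample"].to_numpy()[1:])


class TestBuildPool:
    def test_threshold_ladder_ratio_equals_recruitment_range(self):
        pool = build_pool(n_units=30, recruitment_range=30.0)
        thr = pool.recruitment_thresholds
        assert np.all(np.diff(thr) > 0)
        assert thr[-1] / thr[0] == pytest.approx(30.0, abs=1e-9)

    def test_single_unit_sits_at_ladder_top(self):
        pool = build_pool(n_units=1, recruitment_range=30.0)
        assert pool.recruitment_thresholds[0] == pytest.approx(1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidConfigError):
            build_pool(n_units=0, recruitment_range=30.0)
        with pytest.raises(InvalidConfigError):
            build_pool(n_units=5, recruitment_range=0.5)


class TestDriveFromKinematics:
    @pytest.fixture()
    def kin(self):
        angles = np.zeros((3, 4))
        angles[0] = [0.0, 60.0, -30.0, 15.0]
        return KinematicsTrace(angles=angles, sample_rate=100.0)

    def test_clip_formula(self, kin):
        d_pos = drive_from_kinematics(kin, dof=0, direction=1, rom=60.0)
        d_neg = drive_from_kinematics(kin, dof=0, direction=-1, rom=60.0)
        assert d_pos.tolist() == [0.0, 1.0, 0.0, 0.25]
        assert d_neg.tolist() == [0.0, 0.0, 0.5, 0.0]

    def test_neutral_gives_zero_drive(self, kin):
        assert np.all(drive_from_kinematics(kin, dof=1, direction=1, rom=60.0) == 0)

    def test_invalid_dof_rejected(self, kin):
        with pytest.raises(InvalidInputError):
            drive_from_kinematics(kin, dof=3, direction=1, rom=60.0)


class TestSampleSpikeTrains:
    def _pool(self, n=5, isi_cov=0.0):
        return build_pool(n_units=n, recruitment_range=10.0, isi_cov=isi_cov, seed=0)

    def test_subthreshold_drive_is_silent(self):
        pool = self._pool()
        trains = sample_spike_trains(pool, np.zeros(2048), fs=2048.0, seed=0)
        assert all(t.size == 0 for t in trains.trains.values())

    def test_units_never_fire_below_threshold(self):
        pool = self._pool(isi_cov=0.2)
        drive = np.clip(np.sin(np.linspace(0, 4 * np.pi, 40960)), 0, 1)
        trains = sample_spike_trains(pool, drive, fs=2048.0, seed=3)
        for j, idx in trains.trains.items():
            assert np.all(drive[idx] >= pool.recruitment_thresholds[j])

    def test_deterministic_rate_recovery(self):
        # constant full drive, no ISI variability: counts match the rate model
        pool = MotorUnitPool(
            recruitment_thresholds=np.array([0.1, 0.3, 0.5]),
            min_rate=8.0, peak_rate=35.0, rate_gain=40.0, isi_cov=0.0,
        )
        fs, dur = 2048.0, 10.0
        trains = sample_spike_trains(pool, np.ones(int(fs * dur)), fs=fs, seed=0)
        for j in range(3):
            rate = min(35.0, 8.0 + 40.0 * (1.0 - pool.recruitment_thresholds[j]))
            assert trains.trains[j].size == pytest.approx(rate * dur, abs=1.0)

    def test_isi_cov_recovered_from_long_run(self):
        pool = MotorUnitPool(
            recruitment_thresholds=np.array([0.1]), min_rate=8.0, peak_rate=20.0,
            rate_gain=20.0, isi_cov=0.15,
        )
        fs = 2048.0
        trains = sample_spike_trains(pool, np.ones(int(fs * 100)), fs=fs, seed=1)
        isi = np.diff(trains.trains[0])
        assert isi.std() / isi.mean() == pytest.approx(0.15, abs=0.03)

    def test_recruitment_order_preserved(self):
        pool = self._pool(n=8, isi_cov=0.0)
        drive = np.linspace(0, 1, 40960)
        trains = sample_spike_trains(pool, drive, fs=2048.0, seed=0)
        first = [trains.trains[j][0] for j in range(8)]
        assert all(a <= b for a, b in zip(first, first[1:]))

    def test_invalid_rate_rejected(self):
        with pytest.raises(InvalidConfigError):
            sample_spike_trains(self._pool(), np.ones(100), fs=0.0)


class TestGenerateTemplates:
    def test_center_channel_has_largest_peak(self):
        pool = MotorUnitPool(
            recruitment_thresholds=np.array([0.5]),
            territory_centers=np.array([[4.0, 4.0]]),
        )
        bank = generate_templates(pool, grid_shape=(8, 8), seed=0)
        peaks = np.max(np.abs(bank.templates[0]), axis=1)
        assert np.argmax(peaks) == 4 * 8 + 4

    def test_peak_scales_with_amplitude_scale(self):
        pool = MotorUnitPool(
            recruitment_thresholds=np.array([0.3, 0.6]),
            territory_centers=np.array([[4.0, 4.0], [4.0, 4.0]]),
            amplitude_scales=np.array([1.0, 2.0]),
        )
        bank = generate_templates(pool, seed=0)
        # same waveform shape is not guaranteed, but channel peaks must scale
        p0 = np.max(np.abs(bank.templates[0]))
        p1 = np.max(np.abs(bank.templates[1]))
        assert p1 / p0 == pytest.approx(2.0, abs=1e-9)

    def test_amplitude_decays_with_distance(self):
        pool = MotorUnitPool(
            recruitment_thresholds=np.array([0.5]),
            territory_centers=np.array([[0.0, 0.0]]),
        )
        bank = generate_templates(pool, seed=0)
        peaks = np.max(np.abs(bank.templates[0]), axis=1).reshape(8, 8)
        d = np.hypot(*np.meshgrid(np.arange(8), np.arange(8), indexing="ij"))
        order = np.argsort(d.ravel())
        assert np.all(np.diff(peaks.ravel()[order]) <= 1e-12)

    def test_too_short_template_rejected(self):
        pool = MotorUnitPool(recruitment_thresholds=np.array([0.5]))
        with pytest.raises(InvalidInputError):
            generate_templates(pool, template_length=2)


class TestSynthesizeEMG:
    def test_single_impulse_copies_template(self, sparse_noiseless):
        _, _, bank = sparse_noiseless
        spikes = SpikeTrainSet({0: np.array([100])})
        emg = synthesize_emg(spikes, bank, n_samples=400, noise_snr_db=None)
        t = bank.templates[0]
        assert np.allclose(emg.samples[:, 100 : 100 + t.shape[1]], t, atol=1e-6)
        assert np.all(emg.samples[:, :100] == 0)
        assert np.all(emg.samples[:, 100 + t.shape[1] :] == 0)

    def test_superposition_is_linear(self, sparse_noiseless):
        _, _, bank = sparse_noiseless
        a = SpikeTrainSet({0: np.array([50, 80])})  # closer than template length
        b = SpikeTrainSet({1: np.array([60])})
        both = SpikeTrainSet({0: np.array([50, 80]), 1: np.array([60])})
        ea = synthesize_emg(a, bank, n_samples=400, noise_snr_db=None)
        eb = synthesize_emg(b, bank, n_samples=400, noise_snr_db=None)
        eab = synthesize_emg(both, bank, n_samples=400, noise_snr_db=None)
        assert np.allclose(
            eab.samples.astype(np.float64),
            ea.samples.astype(np.float64) + eb.samples.astype(np.float64),
            atol=1e-6,
        )

    def test_no_units_yields_configured_noise_floor(self):
        emg = synthesize_emg(
            SpikeTrainSet({}), None, n_samples=20000, noise_snr_db=10.0,
            absolute_noise_sd=0.5, seed=0,
        )
        assert emg.samples.std() == pytest.approx(0.5, rel=0.05)

    def test_snr_matches_request(self, sparse_noiseless):
        _, spikes, bank = sparse_noiseless
        emg = synthesize_emg(spikes, bank, n_samples=120_000, noise_snr_db=12.0, seed=0)
        clean = synthesize_emg(spikes, bank, n_samples=120_000, noise_snr_db=None)
        noise = emg.samples.astype(np.float64) - clean.samples.astype(np.float64)
        active = np.any(np.abs(clean.samples) > 0, axis=0)
        p_sig = np.mean(clean.samples.astype(np.float64)[:, active] ** 2, axis=1)
        snr = np.mean(10 * np.log10(p_sig / noise.var()))
        assert snr == pytest.approx(12.0, abs=0.5)

    def test_out_of_bounds_spike_rejected(self, sparse_noiseless):
        _, _, bank = sparse_noiseless
        with pytest.raises(InvalidInputError):
            synthesize_emg(SpikeTrainSet({0: np.array([500])}), bank, n_samples=400)

    def test_deterministic_under_seed(self, sparse_noiseless):
        _, spikes, bank = sparse_noiseless
        e1 = synthesize_emg(spikes, bank, n_samples=120_000, noise_snr_db=15.0, seed=42)
        e2 = synthesize_emg(spikes, bank, n_samples=120_000, noise_snr_db=15.0, seed=42)
        assert np.array_equal(e1.samples, e2.samples)


class TestCorruptSpikeTrains:
    @pytest.fixture()
    def spikes(self):
        rng = np.random.default_rng(0)
        return SpikeTrainSet(
            {u: np.sort(rng.choice(200_000, size=1000, replace=False)) for u in range(5)}
        )

    def test_identity_corruption(self, spikes):
        spec = CorruptionSpec()
        out = corrupt_spike_trains(
            spikes, spec, {u: 0.5 for u in range(5)}, 200_000, 2048.0, seed=0
        )
        assert out.unit_ids == spikes.unit_ids
        for u in range(5):
            assert np.array_equal(out.trains[u], spikes.trains[u])

    def test_total_deletion_leaves_empty_units(self, spikes):
        spec = CorruptionSpec(miss_rate=1.0)
        out = corrupt_spike_trains(
            spikes, spec, {u: 0.5 for u in range(5)}, 200_000, 2048.0, seed=0
        )
        assert all(t.size == 0 for t in out.trains.values())

    def test_miss_rate_binomial_mean(self):
        # 20% miss over a 1000-spike unit: retained count near 800
        train = SpikeTrainSet({0: np.arange(0, 100_000, 100)})
        spec = CorruptionSpec(miss_rate=0.2)
        kept = [
            corrupt_spike_trains(train, spec, {0: 0.5}, 100_000, 2048.0, seed=s)
            .trains[0].size
            for s in range(50)
        ]
        assert np.mean(kept) == pytest.approx(800.0, abs=25.0)

    def test_detected_fraction_biased_to_high_thresholds(self, spikes):
        thresholds = {u: [0.01, 0.02, 0.05, 0.5, 1.0][u] for u in range(5)}
        spec = CorruptionSpec(detected_fraction=0.4, high_threshold_bias=3.0)
        kept = [
            tuple(
                corrupt_spike_trains(spikes, spec, thresholds, 200_000, 2048.0, seed=s).unit_ids
            )
            for s in range(40)
        ]
        high = sum(4 in k for k in kept)
        low = sum(0 in k for k in kept)
        assert high > low

    def test_invalid_spec_rejected(self, spikes):
        with pytest.raises(InvalidConfigError):
            corrupt_spike_trains(
                spikes, CorruptionSpec(miss_rate=1.5), {u: 0.5 for u in range(5)},
                200_000, 2048.0,
            )


class TestSimulateSession:
    def test_session_determinism(self):
        cfg = SessionConfig(ramp_duration=1.0, units_per_pool=4, n_trials=1, snr_db=15.0)
        s1 = simulate_session(cfg, seed=9)
        s2 = simulate_session(cfg, seed=9)
        assert np.array_equal(s1.emg.samples, s2.emg.samples)
        assert s1.spikes.unit_ids == s2.spikes.unit_ids
        for u in s1.spikes.unit_ids:
            assert np.array_equal(s1.spikes.trains[u], s2.spikes.trains[u])

    def test_session_layout(self, small_session):
        s = small_session
        assert s.emg.n_samples == s.kinematics.n_samples
        assert s.emg.n_channels == 64
        trials = s.segmentation.trials()
        assert len(trials) == 9  # 3 DoFs x 3 trials
        assert s.segmentation.records.shape[0] == 18  # two direction episodes each
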