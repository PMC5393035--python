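import numpy as np
import pytest
from dataclasses import replace
from scipy import signal as sps

from wristssr.preprocessing import (apply_filters, auto_bad_channels,
                                    check_min_periods, exclude_bad_channels,
                                    rereference_common_average,
                                    reject_periods_by_torque, segment_periods)
from wristssr.signal_design import build_default_spec
from wristssr.synthetic_data import (SessionRecording, make_ground_truth,
                                     simulate_session)

FS = 2048.0


def make_recording(eeg, fs=FS, task="passive", target=0.0, torque=None,
                   labels=None):
    n_ch, n_samp = eeg.shape
    labels = labels or tuple(f"ch{i}" for i in range(n_ch))
    return SessionRecording(
        eeg=eeg, electrode_labels=labels,
        torque=torque if torque is not None else np.zeros(n_samp),
        emg=np.zeros((2, n_samp)), sample_rate_hz=fs,
        trial_boundaries=((0, n_samp),), task=task, target_torque_nm=target)


class TestFilters:
    # edge samples ring after bidirectional filtering; the analysis discards
    # leading transient periods, so suppression is judged on the trial core
    CORE = slice(int(2.5 * FS), -int(2.5 * FS))

    def test_line_noise_suppressed(self):
        t = np.arange(int(12.5 * FS)) / FS
        rec = make_recording(np.sin(2 * np.pi * 50 * t)[None, :])
        out = apply_filters(rec)
        assert (np.sqrt(np.mean(out.eeg[0][self.CORE] ** 2))
                < 0.01 * np.sqrt(np.mean(rec.eeg[0][self.CORE] ** 2)))

    def test_passband_preserved_zero_phase(self):
        t = np.arange(int(12.5 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        out = apply_filters(make_recording(x[None, :])).eeg[0]
        ratio = np.sqrt(np.mean(out[self.CORE]**2) / np.mean(x[self.CORE]**2))
        assert ratio >= 0.95
        xc = np.correlate(out[self.CORE], x[self.CORE], mode="full")
        assert abs(np.argmax(xc) - (len(out[self.CORE]) - 1)) == 0  # zero lag

    def test_band_edges_on_white_noise(self):
        # forward-backward filtering squares the magnitude response, so the
        # design cutoffs are where the empirical power gain crosses 0.25
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(60 * FS))
        out = apply_filters(make_recording(x[None, :])).eeg[0]
        nper = 8 * 2048
        f, pin = sps.welch(x, fs=FS, nperseg=nper)
        _, pout = sps.welch(out, fs=FS, nperseg=nper)
        h = pout / pin
        ref = np.median(h[(f > 5) & (f < 40)])
        bin_hz = f[1] - f[0]
        above = h >= 0.25 * ref
        low_crossing = f[(f > 0) & above][0]       # first bin in the pass band
        high_crossing = f[(f < 130) & above][-1]   # last bin in the pass band
        assert abs(low_crossing - 0.8) <= 2 * bin_hz
        assert abs(high_crossing - 120.0) <= 2 * bin_hz

    def test_short_trial_rejected(self):
        rec = make_recording(np.zeros((1, 32)))
        with pytest.raises(ValueError, match="warm-up"):
            apply_filters(rec)


class TestBadChannels:
    def test_named_exclusion(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.standard_normal((64, 1000)),
                             labels=tuple(f"E{i}" for i in range(64)))
        out = exclude_bad_channels(rec, bad=["E0"])
        assert out.n_channels == 63
        assert "E0" not in out.electrode_labels

    def test_unknown_label_rejected(self):
        rec = make_recording(np.zeros((2, 100)))
        with pytest.raises(ValueError, match="not in montage"):
            exclude_bad_channels(rec, bad=["Oz"])

    def test_auto_flags_nothing_on_clean_data(self):
        flagged = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rec = make_recording(rng.standard_normal((32, 4000)))
            flagged.append(len(auto_bad_channels(rec)))
        assert sum(f == 0 for f in flagged) >= 9

    def test_auto_flags_the_loud_channel(self):
        rng = np.random.default_rng(2)
        eeg = rng.standard_normal((32, 4000))
        eeg[5] *= 20.0
        rec = make_recording(eeg)
        assert auto_bad_channels(rec) == ["ch5"]

    def test_all_flagged_is_an_error(self):
        rec = make_recording(np.zeros((2, 100)))
        with pytest.raises(ValueError, match="all channels"):
            exclude_bad_channels(rec, bad=["ch0", "ch1"])


class TestCommonAverage:
    def test_mean_is_zero(self):
        rng = np.random.default_rng(3)
        out = rereference_common_average(make_recording(rng.standard_normal((8, 500))))
        assert np.max(np.abs(out.eeg.mean(axis=0))) < 1e-12

    def test_identical_channels_vanish(self):
        x = np.sin(np.linspace(0, 10, 300))
        out = rereference_common_average(make_recording(np.tile(x, (4, 1))))
        assert np.max(np.abs(out.eeg)) < 1e-12

    def test_two_channel_hand_case(self):
        a, b = np.arange(5.0), np.ones(5)
        out = rereference_common_average(make_recording(np.vstack([a, b])))
        assert np.allclose(out.eeg[0], (a - b) / 2)
        assert np.allclose(out.eeg[1], (b - a) / 2)


class TestSegmentation:
    def session(self, n_trials=20, fs=256.0):
        spec = build_default_spec(0)
        truth = make_ground_truth("control", spec=spec, sample_rate_hz=fs, seed=0)
        return simulate_session(truth, spec, "passive", seed=1,
                                n_trials=n_trials, sample_rate_hz=fs), spec

    def test_study_bookkeeping_160(self):
        rec, spec = self.session()
        assert segment_periods(rec, spec, discard_first=2).P == 160

    def test_no_discard_gives_200(self):
        rec, spec = self.session()
        assert segment_periods(rec, spec, discard_first=0).P == 200

    def test_kept_indices_single_trial(self):
        rec, spec = self.session(n_trials=1)
        st = segment_periods(rec, spec, discard_first=2)
        assert list(st.kept_period_index) == list(range(2, 10))

    def test_segment_commutes_with_filtering(self):
        rec, spec = self.session(n_trials=2)
        a = segment_periods(apply_filters(rec), spec)
        filtered = apply_filters(rec)
        b = segment_periods(filtered, spec)
        assert np.array_equal(a.data, b.data)

    def test_non_integer_trial_rejected(self):
        rec, spec = self.session(n_trials=1)
        bad = replace(rec, trial_boundaries=((0, rec.n_samples - 5),))
        with pytest.raises(ValueError, match="integer number of periods"):
            segment_periods(bad, spec)


class TestTorqueRejection:
    def stack_with_means(self, means, target=1.0, fs=256.0):
        spec = build_default_spec(0)
        n_per = int(fs * spec.period_s)
        n_trials = len(means) // 10
        truth = make_ground_truth("control", spec=spec, sample_rate_hz=fs, seed=0)
        rec = simulate_session(truth, spec, "active", seed=2, n_trials=n_trials,
                               sample_rate_hz=fs, target_torque_nm=target,
                               violation_fraction=0.0)
        torque = np.repeat(np.asarray(means, float), n_per)
        st = segment_periods(rec, spec, discard_first=0)
        return st, torque

    @pytest.mark.parametrize("factor,kept", [
        (1.4, True), (1.6, False), (0.6, True), (0.4, False),
        (1.5, True), (0.5, True),  # the ±50% boundary is closed
    ])
    def test_boundary_semantics(self, factor, kept):
        means = np.ones(10)
        means[3] = factor
        st, torque = self.stack_with_means(means)
        out = reject_periods_by_torque(st, torque, 1.0)
        assert (3 in out.kept_period_index) is kept

    def test_counting_oracle(self):
        rng = np.random.default_rng(5)
        means = np.ones(160)
        bad = rng.choice(160, size=30, replace=False)
        means[bad] = 2.0
        st, torque = self.stack_with_means(means)
        out = reject_periods_by_torque(st, torque, 1.0)
        assert out.P == 130
        assert np.all(np.diff(out.kept_period_index) > 0)

    def test_passive_task_rejected(self):
        spec = build_default_spec(0)
        truth = make_ground_truth("control", spec=spec, sample_rate_hz=256, seed=0)
        rec = simulate_session(truth, spec, "passive", seed=1, n_trials=1,
                               sample_rate_hz=256)
        st = segment_periods(rec, spec)
        with pytest.raises(ValueError, match="active"):
            reject_periods_by_torque(st, rec.torque, 1.0)


class TestMinimumPeriods:
    @pytest.mark.parametrize("p,valid", [(80, True), (79, False), (160, True)])
    def test_threshold(self, p, valid, stack_factory):
        st = stack_factory(np.zeros((1, p, 4)), task="active")
        assert check_min_periods(st) is valid
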