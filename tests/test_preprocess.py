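import numpy as np
import pandas as pd
import pytest

from luckydoor.eeg_sim import EpochSet
from luckydoor.preprocess import (
    BANDS,
    PERIODS,
    band_decompose_and_average,
    bandpass_filter,
    baseline_correct,
    mask_group_outliers,
    reject_trials,
    resample_and_filter,
    summarize_periods,
)

CH = ("Fz", "Cz", "Pz", "P3", "P4", "POz")


def make_epochs(data, sfreq=250.0, tmin=-0.5, ch_names=CH):
    n = data.shape[0]
    meta = pd.DataFrame({"trial": np.arange(1, n + 1), "choice": "RareG"})
    return EpochSet("S000", data, sfreq, tmin, ch_names, meta)


def sine_epochs(freq, amp=1.0, sfreq=250.0, n_trials=3, duration=2.0, phase=None):
    t = -0.5 + np.arange(int(duration * sfreq)) / sfreq
    data = np.zeros((n_trials, len(CH), len(t)))
    for tr in range(n_trials):
        ph = 0.0 if phase is None else phase[tr]
        data[tr, :, :] = amp * np.sin(2 * np.pi * freq * t + ph)
    return make_epochs(data, sfreq=sfreq)


class TestResampleAndFilter:
    def test_rate_arithmetic(self):
        n = 1000
        data = np.random.default_rng(0).normal(size=(2, len(CH), n))
        ep = EpochSet("S000", data, 500.0, -0.5,
                      CH, pd.DataFrame({"trial": [1, 2], "choice": "RareG"}))
        out = resample_and_filter(ep, target_rate=250.0)
        assert out.data.shape[-1] == n // 2
        assert out.sfreq == 250.0

    @pytest.mark.parametrize("design", ["iir", "fir"])
    def test_drift_attenuated_20db(self, design):
        # long signal so a 0.2 Hz drift completes many cycles
        sfreq, dur = 250.0, 60.0
        t = np.arange(int(dur * sfreq)) / sfreq
        drift = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass_filter(drift, sfreq, 1.0, 45.0, design=design)
        mid = slice(int(5 * sfreq), int(55 * sfreq))
        ratio = np.sqrt(np.mean(out[mid] ** 2)) / np.sqrt(np.mean(drift[mid] ** 2))
        assert 20 * np.log10(ratio) <= -20

    @pytest.mark.parametrize("design", ["iir", "fir"])
    def test_10hz_preserved_within_5pct(self, design):
        sfreq, dur = 250.0, 20.0
        t = np.arange(int(dur * sfreq)) / sfreq
        sig = np.sin(2 * np.pi * 10 * t)
        out = bandpass_filter(sig, sfreq, 1.0, 45.0, design=design)
        mid = slice(int(2 * sfreq), int(18 * sfreq))
        ratio = np.sqrt(np.mean(out[mid] ** 2)) / np.sqrt(np.mean(sig[mid] ** 2))
        assert abs(ratio - 1.0) <= 0.05

    def test_zero_phase_preserves_peak_latency(self):
        sfreq = 250.0
        t = np.arange(int(4 * sfreq)) / sfreq
        burst = np.exp(-0.5 * ((t - 2.0) / 0.15) ** 2) * np.sin(2 * np.pi * 10 * (t - 2.0))
        env = np.abs(burst)
        out = bandpass_filter(burst, sfreq, 8.0, 13.0)
        peak_in = np.argmax(env)
        peak_out = np.argmax(np.abs(out))
        assert abs(int(peak_in) - int(peak_out)) <= 1

    def test_sub_nyquist_input_rejected(self):
        ep = sine_epochs(10, sfreq=60.0, duration=2.0)
        with pytest.raises(ValueError):
            resample_and_filter(ep, target_rate=60.0, band=(1, 45))


class TestRejectTrials:
    def test_clean_epochs_no_rejections(self):
        rng = np.random.default_rng(1)
        data = np.clip(rng.normal(0, 10, size=(20, len(CH), 500)), -40, 40)
        out, log = reject_trials(make_epochs(data))
        assert out.n_trials == 20 and log == []

    def test_amplitude_rule_removes_exactly_violators(self):
        rng = np.random.default_rng(2)
        data = np.clip(rng.normal(0, 10, size=(20, len(CH), 500)), -40, 40)
        data[7, 2, 100] = 150.0
        data[13, 0, 40] = -120.0
        out, log = reject_trials(make_epochs(data))
        amp = sorted(e["trial"] for e in log if e["reason"] == "amplitude")
        assert amp == [8, 14]  # 1-based trial labels
        assert out.n_trials == 18

    def test_high_variance_trial_caught_by_sd_rule(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 5, size=(40, len(CH), 500))
        data[11] = rng.normal(0, 18, size=(len(CH), 500))  # stays under 100 µV
        assert np.abs(data).max() < 100
        out, log = reject_trials(make_epochs(data))
        assert any(e["trial"] == 12 and "SD" in e["reason"] for e in log)

    def test_log_accounts_for_every_dropped_trial(self):
        rng = np.random.default_rng(4)
        data = rng.normal(0, 10, size=(30, len(CH), 500))
        data[3, 1, 10] = 200.0
        data[22] *= 6.0
        ep = make_epochs(data)
        out, log = reject_trials(ep)
        assert ep.n_trials - out.n_trials == len(log)
        assert len({e["trial"] for e in log}) == len(log)

    def test_all_rejected_raises(self):
        data = np.full((3, len(CH), 500), 150.0)
        with pytest.raises(ValueError, match="all trials rejected"):
            reject_trials(make_epochs(data))


class TestBandAverage:
    def test_identical_trials_average_equals_single(self):
        ep = sine_epochs(10, n_trials=5)
        act = band_decompose_and_average(ep, "alpha")
        single = bandpass_filter(ep.data[0], ep.sfreq, *BANDS["alpha"])
        np.testing.assert_allclose(act.waveform, single, atol=1e-12)

    def test_phase_randomized_alpha_cancels(self):
        rng = np.random.default_rng(5)
        ep = sine_epochs(10, n_trials=200, phase=rng.uniform(0, 2 * np.pi, 200))
        act = band_decompose_and_average(ep, "alpha")
        locked = band_decompose_and_average(sine_epochs(10, n_trials=200), "alpha")
        assert np.abs(act.waveform).max() < 0.15 * np.abs(locked.waveform).max()

    def test_band_outside_envelope_rejected(self):
        ep = sine_epochs(10)
        with pytest.raises(ValueError):
            band_decompose_and_average(ep, (30, 70))


class TestBaselineAndPeriods:
    def test_constant_signal_zeroed(self):
        data = np.full((2, len(CH), 500), 5.0)
        act = band_decompose_and_average(make_epochs(data), (1, 45))
        # bypass filtering effects: apply baseline to a constant waveform
        act.waveform = np.full_like(act.waveform, 5.0)
        out = baseline_correct(act)
        np.testing.assert_allclose(out.waveform, 0.0, atol=1e-12)

    def test_baseline_window_mean_exactly_zero(self):
        rng = np.random.default_rng(6)
        act = band_decompose_and_average(
            make_epochs(rng.normal(size=(4, len(CH), 500))), "alpha"
        )
        out = baseline_correct(act)
        times = out.times
        mask = (times >= -0.25) & (times <= -0.05)
        np.testing.assert_allclose(out.waveform[:, mask].mean(axis=1), 0.0, atol=1e-9)

    def test_offset_invariance(self):
        rng = np.random.default_rng(7)
        act = band_decompose_and_average(
            make_epochs(rng.normal(size=(4, len(CH), 500))), "alpha"
        )
        shifted = baseline_correct(
            type(act)(act.subject_id, act.band, act.waveform + 3.7, act.sfreq,
                      act.tmin, act.ch_names, act.n_retained, act.n_rejected)
        )
        base = baseline_correct(act)
        np.testing.assert_allclose(shifted.waveform, base.waveform, atol=1e-12)

    def test_periods_tile_post_choice_interval(self):
        windows = sorted(PERIODS.values())
        assert windows[0][0] == 0.0 and windows[-1][1] == 1.5
        for (lo1, hi1), (lo2, hi2) in zip(windows, windows[1:]):
            assert hi1 == lo2  # no gap, no overlap

    def test_indicator_waveform_summaries(self):
        act = band_decompose_and_average(
            make_epochs(np.zeros((2, len(CH), 500))), "alpha"
        )
        times = act.times
        wave = np.zeros_like(act.waveform)
        wave[:, (times >= 0) & (times < 0.5)] = 1.0
        act.waveform = wave
        act.baseline_corrected = True
        df = summarize_periods(act, measure="mean")
        assert df.loc["Pz", "choice"] == pytest.approx(1.0)
        assert df.loc["Pz", "immediate_reward"] == pytest.approx(0.0)
        assert df.loc["Pz", "cumulative_reward"] == pytest.approx(0.0)

    def test_cluster_scalar_is_mean_of_channel_scalars(self):
        rng = np.random.default_rng(8)
        act = band_decompose_and_average(
            make_epochs(rng.normal(size=(4, len(CH), 500))), "alpha"
        )
        for measure in ("mean", "envelope"):
            df = summarize_periods(act, measure=measure)
            expected = df.loc[["Pz", "P3", "P4", "POz"]].mean(axis=0)
            pd.testing.assert_series_equal(
                df.loc["parietal_cluster"], expected, check_names=False
            )

    def test_missing_cluster_channel_rejected(self):
        act = band_decompose_and_average(
            make_epochs(np.zeros((2, 3, 500)), ch_names=("Fz", "Cz", "Pz")), "alpha"
        )
        with pytest.raises(ValueError):
            summarize_periods(act)


class TestMaskGroupOutliers:
    def test_constructed_outlier_masked(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        df.iloc[5, 2] = df["c"].mean() + 10 * df["c"].std(ddof=1)
        out = mask_group_outliers(df)
        assert np.isnan(out.iloc[5, 2])
        assert out.drop(index=5).notna().all().all() or out.notna().sum().sum() >= 198

    def test_homogeneous_data_mostly_unmasked(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(50, 6)))
        out = mask_group_outliers(df)
        # P(|z| > 5) ~ 6e-7: expect zero masked values at this n
        assert out.notna().all().all()

    def test_degenerate_sd_masks_nothing(self):
        df = pd.DataFrame(np.ones((10, 3)))
        out = mask_group_outliers(df)
        assert out.notna().all().all()
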