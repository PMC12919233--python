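"""Binning, channel screening, normalization chain, and SBP construction."""

import numpy as np
import pandas as pd
import pytest

from crossarea import preprocess
from crossarea.containers import EmptySelectionError, TrialTable


def make_table(touches):
    n = len(touches)
    t = np.asarray(touches, dtype=float)
    return TrialTable(pd.DataFrame({
        "reach_onset": t - 0.45, "touch": t, "retract": t + 0.3,
        "success": True, "attempted": True, "grasp_attempts": 1}))


class TestBinSpikes:
    def test_two_second_window_gives_100_bins(self):
        table = make_table([10.0, 20.0])
        out = preprocess.bin_spikes([np.array([10.0])], table)
        assert out.n_bins == 100
        assert out.values.shape == (2, 100, 1)

    def test_no_spikes_all_zero(self):
        table = make_table([5.0])
        out = preprocess.bin_spikes([np.array([]), np.array([])], table)
        assert np.all(out.values == 0)

    def test_spike_count_conserved_and_placed(self):
        table = make_table([10.0])
        # spikes at known offsets from touch; window end excluded (half-open)
        st = np.array([9.0, 9.99, 10.0, 10.5, 10.9999, 11.0, 12.0])
        out = preprocess.bin_spikes([st], table)
        in_window = (st >= 9.0) & (st < 11.0)
        assert out.values.sum() == in_window.sum()
        # spike at touch falls in bin [0, 20 ms) => bin index 50
        assert out.values[0, 50, 0] >= 1

    def test_homogeneous_poisson_rate(self):
        rng = np.random.default_rng(0)
        dur = 3000.0
        st = np.sort(rng.uniform(0, dur, int(10 * dur)))  # 10 Hz
        table = make_table(np.arange(50.0, 2950.0, 50.0))
        out = preprocess.bin_spikes([st], table)
        assert out.values.mean() == pytest.approx(0.2, rel=0.05)

    def test_missing_touch_excluded_with_warning(self):
        df = make_table([5.0, 10.0]).df.copy()
        df.loc[1, "touch"] = np.nan
        table = TrialTable(df)
        with pytest.warns(UserWarning, match="without touch"):
            out = preprocess.bin_spikes([np.array([5.0])], table)
        assert out.n_trials == 1

    def test_nonfinite_spikes_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            preprocess.bin_spikes([np.array([np.nan])], make_table([5.0]))


class TestFilterChannels:
    def test_all_retained_above_threshold(self):
        table = make_table([10.0])
        rng = np.random.default_rng(1)
        chans = [np.sort(rng.uniform(9, 11, 10)) for _ in range(4)]  # 5 Hz
        out = preprocess.filter_channels(preprocess.bin_spikes(chans, table))
        assert out.n_channels == 4

    def test_silent_channel_dropped(self):
        table = make_table([10.0])
        chans = [np.linspace(9.1, 10.9, 20), np.array([])]
        out = preprocess.filter_channels(preprocess.bin_spikes(chans, table))
        assert out.n_channels == 1
        assert out.channel_ids.tolist() == [0]

    def test_relaxed_half_hz_threshold(self):
        table = make_table([10.0])
        # 0.5 Hz within the epoch: dropped at 1 Hz, kept at 0.5 Hz
        chans = [np.linspace(9.1, 10.9, 20), np.array([9.5])]
        binned = preprocess.bin_spikes(chans, table)
        assert preprocess.filter_channels(binned, 1.0).n_channels == 1
        assert preprocess.filter_channels(binned, 0.5).n_channels == 2

    def test_all_removed_raises(self):
        table = make_table([10.0])
        binned = preprocess.bin_spikes([np.array([])], table)
        with pytest.raises(EmptySelectionError):
            preprocess.filter_channels(binned, 1.0)


class TestNormalize:
    def test_sqrt_then_zscore_hand_computed(self):
        table = make_table([10.0])
        binned = preprocess.bin_spikes([np.array([])], table, bin_width=500.0)
        binned.values = np.array([0.0, 1.0, 4.0, 9.0]).reshape(1, 4, 1)
        out = preprocess.normalize_activity(binned)
        # sqrt -> [0,1,2,3]; z-scoring is scale invariant so rate
        # normalization does not change the result
        expect = (np.array([0.0, 1, 2, 3]) - 1.5) / np.sqrt(1.25)
        np.testing.assert_allclose(out.values[0, :, 0], expect, atol=1e-12)

    def test_zscore_invariants(self):
        rng = np.random.default_rng(2)
        table = make_table(np.arange(10.0, 60.0, 10.0))
        chans = [np.sort(rng.uniform(0, 60, 600)) for _ in range(3)]
        out = preprocess.normalize_activity(
            preprocess.bin_spikes(chans, table))
        flat = out.values.reshape(-1, out.n_channels)
        np.testing.assert_allclose(flat.mean(0), 0, atol=1e-6)
        np.testing.assert_allclose(flat.std(0), 1, atol=1e-6)

    def test_constant_channel_dropped(self):
        table = make_table([10.0])
        binned = preprocess.bin_spikes([np.array([]), np.linspace(9.1, 10.9, 40)],
                                       table)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = preprocess.normalize_activity(binned)
        assert out.n_channels == 1

    def test_out_of_order_stage_rejected(self):
        table = make_table([10.0])
        out = preprocess.normalize_activity(
            preprocess.bin_spikes([np.linspace(9.1, 10.9, 40)], table))
        with pytest.raises(ValueError, match="raw"):
            preprocess.normalize_activity(out)
        with pytest.raises(ValueError, match="raw"):
            preprocess.filter_channels(out)

    def test_smoothing_recorded_and_applied(self):
        rng = np.random.default_rng(3)
        table = make_table([10.0, 20.0])
        chans = [np.sort(rng.uniform(9, 21, 300))]
        raw = preprocess.bin_spikes(chans, table)
        sm = preprocess.normalize_activity(raw, smooth_sd=40.0)
        un = preprocess.normalize_activity(raw)
        assert sm.smoothed_sd == 40.0
        # smoothing reduces bin-to-bin roughness
        assert np.abs(np.diff(sm.values, axis=1)).mean() < \
            np.abs(np.diff(un.values, axis=1)).mean()


class TestLowSBP:
    fs = 1017.25

    def _burst_voltage(self, q=8, f0=400.0, dur=20.0, seed=0):
        """White-noise channels with a tone burst on channel 0 around t=10 s."""
        rng = np.random.default_rng(seed)
        n = int(dur * self.fs)
        v = rng.standard_normal((n, q))
        t = np.arange(n) / self.fs
        burst = (t >= 9.5) & (t <= 10.5)
        v[burst, 0] += 6.0 * np.sin(2 * np.pi * f0 * t[burst])
        return v

    def test_tone_burst_elevates_band_power(self):
        v = self._burst_voltage(f0=400.0)
        table = make_table([10.0])
        sbp = preprocess.compute_low_sbp(v, table, fs=self.fs)
        vals = sbp.values[0, :, 0]
        inside = (sbp.time_axis >= -450) & (sbp.time_axis <= 450)
        elev = vals[inside].mean() - vals[~inside].mean()
        assert elev > 3.0 * vals[~inside].std()

    def test_out_of_band_burst_not_detected(self):
        # 150 Hz sits below the 240 Hz high-pass and the 300-500 Hz band
        v = self._burst_voltage(f0=150.0)
        table = make_table([10.0])
        sbp = preprocess.compute_low_sbp(v, table, fs=self.fs)
        vals = sbp.values[0, :, 0]
        inside = (sbp.time_axis >= -450) & (sbp.time_axis <= 450)
        elev = vals[inside].mean() - vals[~inside].mean()
        assert elev < 3.0 * vals[~inside].std()

    def test_band_frequencies_honored_exactly(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((int(4 * self.fs), 2))
        table = make_table([2.0])
        sbp = preprocess.compute_low_sbp(v, table, fs=self.fs,
                                         band=(300.0, 500.0))
        nperseg = int(round(0.02 * self.fs))
        freqs = np.fft.rfftfreq(nperseg, 1.0 / self.fs)
        expected = freqs[(freqs >= 300.0) & (freqs <= 500.0)]
        np.testing.assert_array_equal(sbp.freqs_averaged, expected)
        assert sbp.band == (300.0, 500.0)

    def test_identical_bank_signal_cancelled_by_median(self):
        rng = np.random.default_rng(4)
        n = int(4.0 * self.fs)
        common = rng.standard_normal(n)
        v = np.tile(common[:, None], (1, 16))
        table = make_table([2.0])
        with np.errstate(all="ignore"):
            sbp = preprocess.compute_low_sbp(v, table, fs=self.fs)
        # identical signals vanish after bank-median subtraction
        assert np.nanmax(np.abs(sbp.values)) < 1e-12

    def test_sampling_rate_mismatch_rejected(self):
        v = np.zeros((1000, 2))
        with pytest.raises(ValueError, match="sampling rate"):
            preprocess.compute_low_sbp(v, make_table([0.5]), fs=900.0)
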