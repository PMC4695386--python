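import numpy as np
import pytest

import replayvta as rv
from replayvta.signals import FrameConfig, frame_threshold


FS = 1000.0


def _tone(freq, duration=10.0, fs=FS, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return t, amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_preserves_amplitude(self):
        _, x = _tone(8.0)
        out = rv.bandpass(rv.LfpChannel(x, FS), (4, 12)).samples
        mid = slice(2000, -2000)
        assert np.abs(out[mid]).max() > 0.95

    def test_stopband_rejects(self):
        _, x = _tone(8.0)
        out = rv.bandpass(rv.LfpChannel(x, FS), (100, 300)).samples
        assert np.sqrt(np.mean(out**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_mixture_dominant_frequency(self):
        t, x = _tone(150.0)
        x = x + _tone(8.0)[1]
        out = rv.bandpass(rv.LfpChannel(x, FS), (100, 300)).samples
        spec = np.abs(np.fft.rfft(out))
        freqs = np.fft.rfftfreq(out.size, 1 / FS)
        assert np.isclose(freqs[np.argmax(spec)], 150.0, atol=1.0)

    def test_band_outside_nyquist_rejected(self):
        _, x = _tone(8.0)
        with pytest.raises(ValueError):
            rv.bandpass(rv.LfpChannel(x, FS), (100, 600))


class TestMua:
    def test_uniform_rate(self):
        spikes = np.linspace(0.005, 9.995, 100)
        mua = rv.compute_mua(spikes, (0, 10), sigma=0.0)
        assert np.isclose(mua.mean_rate, 10.0, rtol=0.01)

    def test_zero_sigma_equals_histogram(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 5, 200))
        mua = rv.compute_mua(spikes, (0, 5), sigma=0.0)
        counts, _ = np.histogram(spikes, bins=np.arange(0, 5.01, 0.01))
        assert np.allclose(mua.rate, counts / 0.01)

    def test_poisson_mean_within_3se(self):
        rng = np.random.default_rng(1)
        n = rng.poisson(20 * 50)
        spikes = np.sort(rng.uniform(0, 50, n))
        mua = rv.compute_mua(spikes, (0, 50))
        se = np.sqrt(20 / 50)
        assert abs(mua.mean_rate - 20.0) < 3 * se


class TestDetectSpwr:
    def _flat_speed(self, v=0.0):
        t = np.arange(0, 60, 1 / 30)
        return t, np.full(t.size, v)

    def test_constant_rate_no_events(self):
        spikes = np.arange(0, 60, 0.01)  # perfectly regular
        mua = rv.compute_mua(spikes, (0, 60), sigma=0.0)
        t, v = self._flat_speed()
        with pytest.warns(UserWarning):
            ev = rv.detect_spwr(mua, t, v)
        assert len(ev) == 0

    def _bump_session(self, rng, bump_at=30.0):
        """Poisson background plus one strong burst."""
        base = np.sort(rng.uniform(0, 60, 600))  # 10 Hz background
        burst = np.sort(rng.uniform(bump_at, bump_at + 0.1, 80))
        return np.sort(np.concatenate([base, burst]))

    def test_injected_bump_boundaries(self):
        rng = np.random.default_rng(2)
        spikes = self._bump_session(rng)
        mua = rv.compute_mua(spikes, (0, 60))
        t, v = self._flat_speed()
        ev = rv.detect_spwr(mua, t, v)
        assert len(ev) == 1
        s, e = ev.data[0]
        assert s <= 30.0 + 0.02 and e >= 30.08
        # boundaries sit at mean crossings: rate just outside is below mean
        ri = np.searchsorted(mua.times, s) - 2
        assert mua.rate[ri] <= mua.mean_rate + 1e-9

    def test_peak_recomputed_matches_threshold(self):
        rng = np.random.default_rng(3)
        spikes = self._bump_session(rng)
        mua = rv.compute_mua(spikes, (0, 60))
        t, v = self._flat_speed()
        ev = rv.detect_spwr(mua, t, v, threshold_sd=4)
        for s, e in ev:
            sel = (mua.times >= s) & (mua.times < e)
            assert mua.rate[sel].max() >= mua.mean_rate + 4 * mua.sd_rate

    def test_high_speed_excludes_event(self):
        rng = np.random.default_rng(2)
        spikes = self._bump_session(rng)
        mua = rv.compute_mua(spikes, (0, 60))
        t, v = self._flat_speed(20.0)  # running: burst must be rejected
        ev = rv.detect_spwr(mua, t, v)
        assert len(ev) == 0


class TestRipplePower:
    def test_ripple_burst_zscore_matches_direct_computation(self):
        from scipy.signal import hilbert

        rng = np.random.default_rng(4)
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 150 * t)
        burst = (t >= 10.0) & (t < 10.2)
        x[burst] *= 5.0
        lfp = rv.LfpChannel(x, FS)
        events = rv.IntervalSet(np.array([[10.0, 10.2]]), "spwr")
        baseline = ~burst
        z = rv.ripple_power_z(lfp, events, baseline)
        env = np.abs(hilbert(x))
        expect = (env[burst].max() - env[baseline].mean()) / env[baseline].std()
        assert np.isclose(z[0], expect)
        assert z[0] > 2.0

    def test_zero_variance_baseline_errors(self):
        lfp = rv.LfpChannel(np.zeros(1000), FS)
        events = rv.IntervalSet(np.array([[0.1, 0.2]]), "spwr")
        with pytest.raises(ValueError):
            rv.ripple_power_z(lfp, events, np.ones(1000, bool))


class TestSws:
    def test_pure_delta_is_sws_pure_theta_is_not(self):
        t = np.arange(0, 60, 1 / FS)
        delta = rv.LfpChannel(np.sin(2 * np.pi * 2 * t), FS)
        theta = rv.LfpChannel(np.sin(2 * np.pi * 8 * t), FS)
        sws = rv.detect_sws(delta, True)
        assert len(sws) == 1 and sws.total_duration > 40
        assert len(rv.detect_sws(theta, True)) == 0
        assert len(rv.detect_sws(delta, False)) == 0  # posture gates

    def test_alternating_blocks_boundaries(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 240, 1 / FS)
        x = np.where((t // 60) % 2 == 0, 60 * np.cos(2 * np.pi * 2 * t),
                     60 * np.cos(2 * np.pi * 8 * t))
        x = x + 5 * rng.standard_normal(t.size)
        sws = rv.detect_sws(rv.LfpChannel(x, FS), True)
        assert len(sws) == 2
        # interior boundaries within 2 s of the true 60 s block edges
        assert abs(sws.data[0, 1] - 60.0) < 2.0
        assert abs(sws.data[1, 0] - 120.0) < 2.0
        assert abs(sws.data[1, 1] - 180.0) < 2.0


class TestFrames:
    def test_alternating_blocks_recovered_exactly(self):
        # 20 spikes per 10 ms bin in odd seconds, silence in even seconds
        spikes = []
        for sec in range(1, 10, 2):
            bins = np.arange(sec, sec + 1, 0.01)
            spikes.append(np.repeat(bins, 20) + 0.005)
        spikes = np.sort(np.concatenate(spikes))
        sws = rv.IntervalSet(np.array([[0.0, 10.0]]), "sws")
        frames = rv.detect_frames(spikes, sws, FrameConfig(sigma=0.0))
        assert len(frames) == 5
        for k, (s, e) in enumerate(frames):
            assert abs(s - (1 + 2 * k)) <= 0.011
            assert abs(e - (2 + 2 * k)) <= 0.011

    def test_bimodal_threshold_between_modes(self):
        rng = np.random.default_rng(6)
        low = rng.poisson(0.02, 5000)  # near-silent 10 ms bins
        high = rng.poisson(4.0, 5000)  # population burst bins
        counts = np.concatenate([low, high])
        th = frame_threshold(counts)
        assert 0 < th < 4.0

    def test_unimodal_falls_back_with_warning(self):
        counts = np.zeros(1000)
        with pytest.warns(UserWarning):
            th = frame_threshold(counts)
        assert th == 0.0

    def test_offset_invariance(self):
        """Frame boundaries are unchanged by a constant count offset."""
        rng = np.random.default_rng(7)
        sws = rv.IntervalSet(np.array([[0.0, 20.0]]), "sws")
        spikes = []
        for sec in range(0, 20, 2):
            n = rng.poisson(300)
            spikes.append(rng.uniform(sec, sec + 1, n))
        base = np.sort(np.concatenate(spikes))
        frames_a = rv.detect_frames(base, sws)
        # add a uniform 'offset' train: one extra spike per 10 ms everywhere
        offset = np.arange(0.005, 20, 0.01)
        frames_b = rv.detect_frames(np.sort(np.concatenate([base, offset])), sws)
        assert len(frames_a) == len(frames_b)
        assert np.allclose(frames_a.data, frames_b.data, atol=0.02)


class TestEventTriggeredLfp:
    def test_fixed_deflection_latency(self):
        fs = 2000.0
        t = np.arange(0, 100, 1 / fs)
        x = np.zeros(t.size)
        starts = np.arange(5.0, 95.0, 2.0)
        for s in starts:
            x -= 50.0 * np.exp(-0.5 * ((t - (s + 0.084)) / 0.01) ** 2)
        lfp = rv.LfpChannel(x, fs)
        events = rv.IntervalSet(np.column_stack([starts, starts + 0.15]), "spwr")
        _, _, latency, dropped = rv.event_triggered_lfp(lfp, events)
        assert dropped == 0
        assert abs(latency - 84.0) <= 1.0

    def test_noise_average_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(8)
        fs = 500.0
        x = rng.standard_normal(int(600 * fs))
        lfp = rv.LfpChannel(x, fs)
        starts = np.arange(1.0, 500.0, 0.5)
        ev1000 = rv.IntervalSet(np.column_stack([starts, starts + 0.1]), "spwr")
        ev10 = rv.IntervalSet(np.column_stack([starts[:10], starts[:10] + 0.1]),
                              "spwr")
        _, avg_many, _, _ = rv.event_triggered_lfp(lfp, ev1000)
        _, avg_few, _, _ = rv.event_triggered_lfp(lfp, ev10)
        ratio = np.std(avg_few) / np.std(avg_many)
        assert 0.5 * np.sqrt(99.8) ** 0.5 < ratio  # roughly sqrt(n) shrinkage
        assert np.isclose(ratio, np.sqrt(len(ev1000) / 10), rtol=0.4)

    def test_single_event_is_identity(self):
        fs = 1000.0
        rng = np.random.default_rng(9)
        x = rng.standard_normal(int(10 * fs))
        lfp = rv.LfpChannel(x, fs)
        events = rv.IntervalSet(np.array([[5.0, 5.2]]), "spwr")
        lags, avg, _, _ = rv.event_triggered_lfp(lfp, events, (-0.1, 0.3))
        i0 = int(5.0 * fs)
        assert np.allclose(avg, x[i0 - 100 : i0 + 300])
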